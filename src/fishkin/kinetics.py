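"""Steady-state kinetic inference from per-cell smFISH counts.

Given a cell's nascent signal N (transcription-focus intensity in units of
one mature transcript), mature count M, the probe-library weighting factor
K, the elongation rate v (nt/h) and gene length L (nt), the per-cell
estimates are

    transcription rate  beta  = ((N / K) * v) / L          [mRNA/h]
    decay rate          delta = (phi * beta * c) / M       [1/h]
    half-life           t_half = (ln 2 / delta) * 60       [min]

N / K is the number of engaged polymerases; beta follows because a
polymerase takes L / v hours to finish. delta follows from the steady-state
balance production = degradation. The steady-state assumption is a caveat,
not a correction: a growing, dividing cell never quite reaches it, and every
result table carries a metadata note saying so.

`SteadyStateKinetics` wraps the per-cell arithmetic in a model object whose
`fit()` returns a `KineticsResults` with per-cell estimates, group
summaries (mean, s.e.m., n) and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probemap import TranscriptModel, weighting_factor

__all__ = [
    "KineticParams",
    "KineticEstimate",
    "transcription_rate",
    "decay_rate",
    "half_life",
    "estimate_cell",
    "estimate_cells",
    "summarise_groups",
    "SteadyStateKinetics",
    "KineticsResults",
]

LN2 = float(np.log(2.0))

STEADY_STATE_NOTE = (
    "Estimates assume steady state (production = degradation) and a constant "
    "elongation rate without pausing or pulsing; a growing, dividing cell is "
    "unlikely to reach a true steady state."
)


@dataclass(frozen=True)
class KineticParams:
    """Fixed kinetic constants.

    elongation_rate_v : nt/h (default 90000 = 1.5 kb/min; supported range in
        the literature is 1.1-1.5 kb/min).
    chromosome_fraction_phi : fraction of scorable alleles actively
        transcribing, in (0, 1]. Default 1.0: cells without a called focus
        are excluded from half-life estimates rather than folded into phi.
        Set ``phi_from_focus_fraction`` in the model to use the population
        focus-positive fraction instead.
    chromosome_copies_c : scorable allele count (1 for X-linked, male).
    """

    elongation_rate_v: float = 90_000.0
    chromosome_fraction_phi: float = 1.0
    chromosome_copies_c: int = 1

    def __post_init__(self) -> None:
        if self.elongation_rate_v <= 0:
            raise ValueError("elongation rate must be > 0")
        if not 0 < self.chromosome_fraction_phi <= 1:
            raise ValueError("chromosome fraction must be in (0, 1]")
        if self.chromosome_copies_c < 1:
            raise ValueError("chromosome copies must be >= 1")


@dataclass(frozen=True)
class KineticEstimate:
    beta: float          # mRNA/h
    delta: float         # 1/h
    half_life_min: float # minutes
    flag: str = ""


def transcription_rate(
    N: float, K: float, params: KineticParams, model: TranscriptModel
) -> float:
    """beta = ((N / K) * v) / L, in mRNA/h."""
    if K <= 0:
        raise ValueError("weighting factor must be > 0")
    if model.length_nt <= 0:
        raise ValueError("gene length must be > 0")
    if N < 0:
        raise ValueError("nascent count must be >= 0")
    return (N / K) * params.elongation_rate_v / model.length_nt


def decay_rate(beta: float, M: int, params: KineticParams) -> float:
    """delta = (phi * beta * c) / M, in 1/h."""
    if M <= 0:
        raise ValueError("no mature transcripts; decay rate undefined")
    return params.chromosome_fraction_phi * beta * params.chromosome_copies_c / M


def half_life(delta: float) -> float:
    """t_half = (ln 2 / delta) * 60, in minutes."""
    if delta <= 0:
        raise ValueError("decay rate must be > 0 for a half-life")
    return LN2 / delta * 60.0


def estimate_cell(
    N: float,
    M: int,
    model: TranscriptModel,
    params: KineticParams | None = None,
    K: float | None = None,
    focus_called: bool = True,
) -> KineticEstimate:
    """Chain transcription_rate -> decay_rate -> half_life for one cell.

    Cells failing a precondition yield a flagged record, never a silent
    drop: no nascent signal gives beta = delta = 0 with half-life NaN and
    flag "no nascent signal"; M = 0 flags "no mature transcripts"; an
    uncalled focus flags "no focus called".
    """
    params = params or KineticParams()
    K = K if K is not None else weighting_factor(model)
    if not focus_called:
        return KineticEstimate(np.nan, np.nan, np.nan, flag="no focus called")
    if M <= 0:
        return KineticEstimate(np.nan, np.nan, np.nan, flag="no mature transcripts")
    if N <= 0:
        return KineticEstimate(0.0, 0.0, np.nan, flag="no nascent signal")
    beta = transcription_rate(N, K, params, model)
    delta = decay_rate(beta, M, params)
    return KineticEstimate(beta, delta, half_life(delta))


def estimate_cells(
    table: pd.DataFrame,
    model: TranscriptModel,
    params: KineticParams | None = None,
    K: float | None = None,
) -> pd.DataFrame:
    """Vectorised estimate_cell over a DataFrame with columns N, M.

    Optional boolean column ``focus_called`` marks cells whose transcription
    focus passed the calling threshold; uncalled cells are flagged and get
    NaN estimates. Returns the input plus beta_mRNA_per_hr, delta_per_hr,
    half_life_min and flags columns. The returned frame carries the
    steady-state caveat in ``.attrs["note"]``.
    """
    params = params or KineticParams()
    K = K if K is not None else weighting_factor(model)
    called = (
        table["focus_called"].to_numpy(dtype=bool)
        if "focus_called" in table.columns
        else np.ones(len(table), dtype=bool)
    )
    recs = [
        estimate_cell(n, m, model, params, K, focus_called=c)
        for n, m, c in zip(table["N"], table["M"], called)
    ]
    out = table.copy()
    out["beta_mRNA_per_hr"] = [r.beta for r in recs]
    out["delta_per_hr"] = [r.delta for r in recs]
    out["half_life_min"] = [r.half_life_min for r in recs]
    out["flags"] = [r.flag for r in recs]
    out.attrs["note"] = STEADY_STATE_NOTE
    out.attrs["weighting_factor"] = K
    return out


def summarise_groups(
    estimates: pd.DataFrame,
    value: str = "half_life_min",
    group: str = "group",
) -> pd.DataFrame:
    """Per-group arithmetic mean, s.e.m. and n of a per-cell estimate.

    Flagged (NaN) cells are excluded from the summary; groups need at least
    two contributing cells.
    """
    if group not in estimates.columns:
        raise ValueError(f"no '{group}' column in estimates")
    rows = []
    for label, sub in estimates.groupby(group, sort=True):
        vals = sub[value].dropna().to_numpy()
        if len(vals) < 2:
            raise ValueError(f"group '{label}' has fewer than 2 usable cells")
        rows.append(
            {
                group: label,
                "mean": float(np.mean(vals)),
                "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


class SteadyStateKinetics:
    """Steady-state transcription-kinetics model for a batch of cells.

    Parameters
    ----------
    data : DataFrame
        Per-cell table with columns ``N`` (nascent count, mature-transcript
        equivalents) and ``M`` (mature count); optional ``group`` labels and
        boolean ``focus_called``.
    transcript : TranscriptModel
        Gene length and probe layout; supplies the weighting factor unless
        ``K`` overrides it.
    params : KineticParams, optional
    K : float, optional
        Probe-library weighting factor; computed from the transcript when
        omitted.
    phi_from_focus_fraction : bool
        When True, phi is set to the fraction of focus-positive cells in the
        batch (the alternative reading of "chromosome fraction") instead of
        the configured constant.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        transcript: TranscriptModel,
        params: KineticParams | None = None,
        K: float | None = None,
        phi_from_focus_fraction: bool = False,
    ) -> None:
        missing = {"N", "M"} - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.transcript = transcript
        self.K = K if K is not None else weighting_factor(transcript)
        params = params or KineticParams()
        if phi_from_focus_fraction:
            if "focus_called" not in data.columns:
                raise ValueError(
                    "phi_from_focus_fraction requires a 'focus_called' column"
                )
            frac = float(data["focus_called"].mean())
            if not 0 < frac <= 1:
                raise ValueError("no focus-positive cells; phi undefined")
            params = KineticParams(
                elongation_rate_v=params.elongation_rate_v,
                chromosome_fraction_phi=frac,
                chromosome_copies_c=params.chromosome_copies_c,
            )
        self.params = params

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        transcript: TranscriptModel,
        nascent_col: str = "N",
        mature_col: str = "M",
        **kwargs,
    ) -> "SteadyStateKinetics":
        renamed = data.rename(columns={nascent_col: "N", mature_col: "M"})
        return cls(renamed, transcript, **kwargs)

    def fit(self) -> "KineticsResults":
        estimates = estimate_cells(self.data, self.transcript, self.params, self.K)
        return KineticsResults(self, estimates)


class KineticsResults:
    """Per-cell kinetic estimates and their group summaries."""

    def __init__(self, model: SteadyStateKinetics, estimates: pd.DataFrame) -> None:
        self.model = model
        self.estimates = estimates
        self.note = STEADY_STATE_NOTE

    @property
    def half_life_min(self) -> pd.Series:
        return self.estimates["half_life_min"]

    def group_summary(self, value: str = "half_life_min") -> pd.DataFrame:
        table = self.estimates
        if "group" not in table.columns:
            table = table.assign(group="all")
        return summarise_groups(table, value=value)

    def mean_half_life(self, group: str | None = None) -> float:
        """Mean per-cell half-life (minutes) over estimable cells."""
        table = self.estimates
        if group is not None:
            table = table[table["group"] == group]
        return float(table["half_life_min"].dropna().mean())

    def summary(self) -> str:
        lines = [
            "Steady-state transcription kinetics",
            "=" * 60,
            f"gene: {self.model.transcript.gene_id}   "
            f"L = {self.model.transcript.length_nt} nt   "
            f"probes = {self.model.transcript.n_probes}",
            f"K = {self.model.K:.5f}   "
            f"v = {self.model.params.elongation_rate_v:.0f} nt/h   "
            f"phi = {self.model.params.chromosome_fraction_phi:.3f}   "
            f"c = {self.model.params.chromosome_copies_c}",
            "-" * 60,
        ]
        for value, unit in [
            ("beta_mRNA_per_hr", "mRNA/h"),
            ("delta_per_hr", "1/h"),
            ("half_life_min", "min"),
        ]:
            for _, row in self.group_summary(value).iterrows():
                lines.append(
                    f"{value:<18} {row['group']:<12} "
                    f"mean {row['mean']:>10.3f} {unit:<7} "
                    f"sem {row['sem']:>8.3f}  n {int(row['n'])}"
                )
        flagged = (self.estimates["flags"] != "").sum()
        lines.append("-" * 60)
        lines.append(f"flagged cells: {flagged} / {len(self.estimates)}")
        lines.append(self.note)
        return "\n".join(lines)

    def plot_half_life(self, ax=None):
        """Strip plot of per-cell half-lives by group with mean +/- s.e.m."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.estimates
        if "group" not in table.columns:
            table = table.assign(group="all")
        rng = np.random.default_rng(0)
        for i, (label, sub) in enumerate(table.groupby("group", sort=True)):
            vals = sub["half_life_min"].dropna().to_numpy()
            x = i + rng.uniform(-0.15, 0.15, size=len(vals))
            ax.plot(x, vals, "o", ms=3, alpha=0.4, color="grey")
            ax.errorbar(
                [i], [vals.mean()],
                yerr=[vals.std(ddof=1) / np.sqrt(len(vals))],
                fmt="_", color="black", capsize=4, ms=20,
            )
        groups = sorted(table["group"].unique())
        ax.set_xticks(range(len(groups)), groups)
        ax.set_ylabel("half-life (min)")
        return ax
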