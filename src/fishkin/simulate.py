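"""Synthetic single-cell smFISH datasets with known kinetic ground truth.

The generative model is the steady-state view of constitutive transcription:
a gene on c chromosome copies, of which a fraction phi actively transcribes,
produces mature mRNA at total rate beta_tot = phi * c * beta_per_allele and
each molecule decays independently at rate delta. At stationarity the mature
count M is Poisson(beta_tot / delta). The scored transcription focus carries
a Poisson(beta_per_allele * L / v) number of engaged polymerases (Little's
law: arrival rate beta, residence time L/v) at i.i.d. uniform positions
along the gene; the focus signal, in mature-transcript equivalents, is the
sum over polymerases of the fraction of probe sites already synthesised.

Defaults mirror the myc-long study conditions in Drosophila type I
neuroblasts: a 9 kb transcript, a 3'-biased probe library with weighting
factor K = 0.15264, elongation at 1.5 kb/min, one X-linked allele, and a
transcription rate giving ~100 mature transcripts at the wild-type
half-life of 18.6 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .probemap import TranscriptModel, weighting_factor

__all__ = [
    "SimConfig",
    "myc_like_transcript",
    "wild_type_like_config",
    "config_for_half_life",
    "simulate_counts",
    "simulate_covariates",
    "simulate_population",
    "LN2",
]

LN2 = float(np.log(2.0))

#: Default elongation rate, nt/h (1.5 kb/min; literature range 1.1-1.5 kb/min).
DEFAULT_ELONGATION_NT_PER_H = 90_000.0


def myc_like_transcript(
    length_nt: int = 9000, n_probes: int = 48, target_k: float = 0.15264
) -> TranscriptModel:
    """Synthetic stand-in for the myc-long transcript + probe library.

    Places ``n_probes`` evenly through a 3' window of width 2*K*L so that the
    weighting factor of the layout equals ``target_k`` (up to integer
    rounding of probe centres). This is a constructed layout, not the
    published probe set; it reproduces the study's weighting factor and the
    3' bias of a UTR-directed library.
    """
    window = 2.0 * target_k * length_nt
    centres = length_nt - window * (np.arange(1, n_probes + 1) - 0.5) / n_probes
    positions = tuple(int(round(c)) for c in centres)
    return TranscriptModel(
        gene_id="myc-like",
        length_nt=length_nt,
        probe_positions=positions,
        probe_length_nt=20,
        chromosome_copies=1,
        name="synthetic myc-long-like transcript",
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the steady-state single-cell simulator.

    beta_per_allele : mRNA/h produced per actively transcribing allele.
    delta : mRNA decay rate, 1/h.
    elongation_rate : polymerase speed v, nt/h.
    transcript : TranscriptModel carrying L and the probe positions.
    chromosome_fraction : phi, fraction of scorable alleles active, in (0, 1].
    """

    n_cells: int
    beta_per_allele: float
    delta: float
    transcript: TranscriptModel
    elongation_rate: float = DEFAULT_ELONGATION_NT_PER_H
    chromosome_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.beta_per_allele < 0:
            raise ValueError("beta_per_allele must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.elongation_rate <= 0:
            raise ValueError("elongation_rate must be > 0")
        if not 0 < self.chromosome_fraction <= 1:
            raise ValueError("chromosome_fraction must be in (0, 1]")

    @property
    def beta_total(self) -> float:
        """Whole-cell production rate phi * c * beta_per_allele, mRNA/h."""
        return (
            self.chromosome_fraction
            * self.transcript.chromosome_copies
            * self.beta_per_allele
        )

    @property
    def expected_mature(self) -> float:
        return self.beta_total / self.delta

    @property
    def expected_polymerases(self) -> float:
        """Mean polymerase load on one allele: beta * L / v (Little's law)."""
        return self.beta_per_allele * self.transcript.length_nt / self.elongation_rate

    @property
    def true_half_life_min(self) -> float:
        return LN2 / self.delta * 60.0


def wild_type_like_config(
    n_cells: int = 200,
    half_life_min: float = 18.6,
    expected_mature_at_wt: float = 100.0,
    wt_half_life_min: float = 18.6,
    transcript: TranscriptModel | None = None,
    seed: int = 0,
) -> SimConfig:
    """Study-condition config: decay set from a printed half-life.

    The transcription rate is fixed at the wild-type value (chosen so the
    wild-type population has ``expected_mature_at_wt`` mature transcripts);
    only delta varies between conditions, matching the observation that
    nascent counts are unchanged between genotypes while stability moves
    the mature count.
    """
    transcript = transcript if transcript is not None else myc_like_transcript()
    delta_wt = LN2 / (wt_half_life_min / 60.0)
    beta = expected_mature_at_wt * delta_wt
    delta = LN2 / (half_life_min / 60.0)
    return SimConfig(
        n_cells=n_cells,
        beta_per_allele=beta,
        delta=delta,
        transcript=transcript,
        seed=seed,
    )


# Backwards-friendly alias: a config parameterised by its half-life.
config_for_half_life = wild_type_like_config


def simulate_counts(config: SimConfig, return_positions: bool = False):
    """Draw a steady-state population of cells.

    Per cell: M ~ Poisson(beta_tot/delta); polymerase count on the scored
    allele ~ Poisson(beta * L / v) with positions i.i.d. uniform on [0, L];
    focus signal = sum of per-polymerase hybridisable probe fractions, in
    mature-transcript equivalents.

    Returns a DataFrame with columns cell_id, M, n_polymerases,
    focus_signal, true_half_life_min, seed; with ``return_positions`` also
    returns the per-cell polymerase position arrays.
    """
    rng = np.random.default_rng(config.seed)
    model = config.transcript
    n = config.n_cells

    M = rng.poisson(config.expected_mature, size=n)
    n_pol = rng.poisson(config.expected_polymerases, size=n)
    total = int(n_pol.sum())
    pos = rng.uniform(0.0, model.length_nt, size=total)
    probe_sorted = np.sort(np.asarray(model.probe_positions))
    frac = np.searchsorted(probe_sorted, pos, side="right") / model.n_probes
    owner = np.repeat(np.arange(n), n_pol)
    focus = np.bincount(owner, weights=frac, minlength=n)

    table = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:04d}" for i in range(n)],
            "M": M.astype(int),
            "n_polymerases": n_pol.astype(int),
            "focus_signal": focus,
            "true_half_life_min": config.true_half_life_min,
            "seed": config.seed,
        }
    )
    if return_positions:
        splits = np.cumsum(n_pol)[:-1]
        return table, [p for p in np.split(pos, splits)]
    return table


def simulate_covariates(
    n: int,
    target_r: float,
    means: Sequence[float] = (0.0, 0.0),
    sds: Sequence[float] = (1.0, 1.0),
    seed: int = 0,
    names: Sequence[str] = ("covariate_a", "covariate_b"),
    half_life_link: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Draw paired per-cell covariates from a bivariate normal.

    The population correlation is ``target_r``. With ``half_life_link=(lo,
    hi)`` the second covariate is additionally mapped (monotonically, by
    rank-preserving affine transform of its z-score through a logistic) onto
    a per-cell half-life in minutes between lo and hi, so an Imp-like level
    and half-life co-vary.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sds[0] ** 2, target_r * sds[0] * sds[1]],
            [target_r * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    draws = rng.multivariate_normal(np.asarray(means, dtype=float), cov, size=n)
    out = pd.DataFrame({names[0]: draws[:, 0], names[1]: draws[:, 1]})
    if half_life_link is not None:
        lo, hi = half_life_link
        z = (draws[:, 1] - means[1]) / sds[1]
        out["half_life_min"] = lo + (hi - lo) / (1.0 + np.exp(-z))
        out["delta_per_hr"] = LN2 / (out["half_life_min"] / 60.0)
    return out


def simulate_population(
    group_specs: Sequence[tuple[str, SimConfig]],
) -> pd.DataFrame:
    """Concatenate simulate_counts over labelled groups.

    Raises on duplicate labels. Cell ids are prefixed by group label.
    """
    labels = [label for label, _ in group_specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    frames = []
    for label, cfg in group_specs:
        t = simulate_counts(cfg)
        t.insert(0, "group", label)
        t["cell_id"] = label + ":" + t["cell_id"]
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
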