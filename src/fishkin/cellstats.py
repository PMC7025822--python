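"""Per-cell / per-brain statistics: correlations, ANOVA + Dunnett, t-tests, FDR.

Conventions follow the GraphPad-style defaults used in the source analyses:
pooled-variance two-sided t-tests (Welch via flag), two-sided Dunnett
comparisons against a single control, pairwise-complete Pearson
correlations, and Benjamini-Hochberg FDR at 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "correlation_matrix",
    "AnovaDunnettResult",
    "anova_dunnett",
    "t_test",
    "fdr_adjust",
]


@dataclass
class CorrelationResult:
    """Pairwise-complete Pearson correlation matrices: r, p and n per pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def tidy(self) -> pd.DataFrame:
        rows = []
        feats = list(self.r.index)
        for i, a in enumerate(feats):
            for b in feats[i + 1:]:
                rows.append(
                    {
                        "feature_a": a,
                        "feature_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n": self.n.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, features: list[str] | None = None
) -> CorrelationResult:
    """Pairwise-complete Pearson r with two-sided p-values.

    p comes from t = r * sqrt((n-2)/(1-r^2)) on n-2 df. Each pair uses the
    rows where both features are present (pairwise-complete observations);
    at least 3 complete pairs are required. A constant feature has an
    undefined r, reported as NaN with a warning.
    """
    features = features or [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    k = len(features)
    r = pd.DataFrame(np.eye(k), index=features, columns=features)
    p = pd.DataFrame(np.zeros((k, k)), index=features, columns=features)
    n = pd.DataFrame(0, index=features, columns=features, dtype=int)
    for f in features:
        n.loc[f, f] = int(table[f].notna().sum())
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            both = table[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(both)
            if len(both) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({a}, {b})"
                )
            x, y = both[a].to_numpy(), both[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant feature in pair ({a}, {b}); r undefined",
                    stacklevel=2,
                )
                rv, pv = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rv, pv = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return CorrelationResult(r=r, p=p, n=n)


@dataclass
class AnovaDunnettResult:
    F: float
    p_anova: float
    comparisons: pd.DataFrame  # group, mean_diff, t, p_adjusted
    control: str

    def significant(self, alpha: float = 0.05) -> list[str]:
        sel = self.comparisons["p_adjusted"] <= alpha
        return list(self.comparisons.loc[sel, "group"])


def anova_dunnett(
    table: pd.DataFrame,
    feature: str,
    control_group: str,
    group: str = "group",
) -> AnovaDunnettResult:
    """One-way ANOVA plus Dunnett's two-sided comparisons to control.

    The ANOVA is the fixed-effects pooled-variance F test. Dunnett adjusted
    p-values use the equicoordinate multivariate-t tail probability with the
    correlation structure implied by group sizes (scipy's implementation;
    integration tolerance well below 1e-3).
    """
    groups = {
        str(label): sub[feature].dropna().to_numpy()
        for label, sub in table.groupby(group, sort=True)
    }
    if control_group not in groups:
        raise ValueError(f"control group '{control_group}' not present")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs at least 2 observations")
    if all(np.ptp(v) == 0 for v in groups.values()):
        raise ValueError("zero within-group variance in all groups; tests degenerate")

    control = groups[control_group]
    others = {lbl: v for lbl, v in groups.items() if lbl != control_group}

    F, p_anova = stats.f_oneway(*groups.values())
    # seeded QMC integration of the multivariate-t tail -> deterministic p
    dunn = stats.dunnett(
        *others.values(), control=control, alternative="two-sided", rng=0
    )
    comparisons = pd.DataFrame(
        {
            "group": list(others.keys()),
            "mean_diff": [float(np.mean(v) - np.mean(control)) for v in others.values()],
            "t": np.atleast_1d(dunn.statistic).astype(float),
            "p_adjusted": np.atleast_1d(dunn.pvalue).astype(float),
        }
    )
    return AnovaDunnettResult(
        F=float(F), p_anova=float(p_anova), comparisons=comparisons,
        control=control_group,
    )


def t_test(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sided t-test; pooled-variance by default.

    Returns (t, df, p). ``paired`` requires equal lengths;``welch`` applies
    the Welch-Satterthwaite correction (unpaired only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        res = stats.ttest_rel(x, y)
        df = len(x) - 1
    else:
        res = stats.ttest_ind(x, y, equal_var=not welch)
        df = float(res.df) if hasattr(res, "df") else len(x) + len(y) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def fdr_adjust(pvalues, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment with discovery flags at q."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {"p": p, "p_adjusted": adj, "discovery": adj <= q}
    )
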