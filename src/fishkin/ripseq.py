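"""RIP-seq enrichment ranking over input RNA-seq and GO-keyword categories.

Works on a genes x libraries count matrix whose libraries are labelled IP
(immunoprecipitation) or input (baseline RNA-seq). The ranking stage:
median-of-ratios library-size correction, a low-abundance filter on the raw
input counts, the IP/input mean-normalised-count ratio with a pseudo-count,
and descending rank. Overlapping non-coding RNAs are flagged and excluded
from top-N views only. Differential significance (DESeq2-style padj/log2FC)
is accepted as optional input columns and applied as a filter, never
recomputed here.

GO categorisation assigns each gene to seven keyword-defined categories by
case-insensitive substring match on its GO term names: cell growth, cell
size, cell division, cell cycle, neural development ("nervous system
development" or "neurogenesis"), RNA binding, DNA binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GO_CATEGORIES",
    "CountMatrix",
    "size_factors",
    "low_abundance_filter",
    "enrichment_rank",
    "go_categorize",
    "simulate_rip_counts",
    "read_count_matrix_tsv",
    "read_go_map_tsv",
]

logger = logging.getLogger(__name__)

GO_CATEGORIES: dict[str, tuple[str, ...]] = {
    "cell growth": ("cell growth",),
    "cell size": ("cell size",),
    "cell division": ("cell division",),
    "cell cycle": ("cell cycle",),
    "neural development": ("nervous system development", "neurogenesis"),
    "RNA binding": ("rna binding",),
    "DNA binding": ("dna binding",),
}

PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Genes x libraries counts with IP/input group labels.

    counts : DataFrame, genes as index, libraries as columns, ints >= 0.
    groups : mapping library -> "IP" | "input".
    flags : optional set of gene ids flagged as overlapping non-coding RNAs.
    extra : optional per-gene columns (padj, log2FC) from an external
        differential test.
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    flags: set[str] = field(default_factory=set)
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"libraries without group label: {sorted(missing)}")
        present = set(self.groups[c] for c in self.counts.columns)
        if not {"IP", "input"} <= present:
            raise ValueError("need at least one IP and one input library")

    def libraries(self, group: str) -> list[str]:
        return [c for c in self.counts.columns if self.groups[c] == group]


def size_factors(counts: pd.DataFrame, min_reference_genes: int = 50) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference for each gene is the geometric mean of its counts across
    libraries, over genes that are nonzero everywhere; each library's factor
    is the median ratio to that reference. With fewer than
    ``min_reference_genes`` all-nonzero genes, falls back to total-count
    scaling (factors proportional to column sums, geometric mean 1), logged.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    nonzero = (mat > 0).all(axis=1)
    if nonzero.sum() < min_reference_genes:
        logger.warning(
            "only %d all-nonzero genes; falling back to total-count scaling",
            int(nonzero.sum()),
        )
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        sub = mat[nonzero]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def low_abundance_filter(
    matrix: CountMatrix, min_total: int = 10
) -> CountMatrix:
    """Drop genes with summed raw input (RNA-seq) count below ``min_total``."""
    input_libs = matrix.libraries("input")
    keep = matrix.counts[input_libs].sum(axis=1) >= min_total
    extra = matrix.extra.loc[keep[keep].index.intersection(matrix.extra.index)] if matrix.extra is not None else None
    return CountMatrix(
        counts=matrix.counts.loc[keep],
        groups=matrix.groups,
        flags=matrix.flags,
        extra=extra,
    )


def enrichment_rank(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
    padj_max: float = 0.01,
    log2fc_min: float = 2.0,
) -> pd.DataFrame:
    """Rank genes by IP/input enrichment after library-size correction.

    ratio = (mean normalised IP + eps) / (mean normalised input + eps) with
    eps = 0.5 pseudo-count; genes ranked by descending log2 ratio, ties
    broken by gene id. Overlapping-ncRNA flags populate an ``excluded``
    column (for top-N views; the full table keeps every gene). When the
    matrix carries external padj/log2FC columns, ``significant`` marks genes
    passing padj < ``padj_max`` and log2FC > ``log2fc_min``.

    ``factors`` are the per-library size factors; they default to
    median-of-ratios on this matrix but are accepted as an input so a
    calibration computed before low-abundance filtering can be reused (the
    per-gene ratio then does not depend on which other genes survive).
    """
    sf = factors if factors is not None else size_factors(matrix.counts)
    norm = matrix.counts.div(sf, axis=1)
    ip = norm[matrix.libraries("IP")].mean(axis=1)
    inp = norm[matrix.libraries("input")].mean(axis=1)
    log2_ratio = np.log2((ip + pseudocount) / (inp + pseudocount))
    out = pd.DataFrame(
        {
            "gene": matrix.counts.index,
            "mean_norm_ip": ip.to_numpy(),
            "mean_norm_input": inp.to_numpy(),
            "log2_enrichment": log2_ratio.to_numpy(),
            "excluded": [g in matrix.flags for g in matrix.counts.index],
        }
    )
    out = out.sort_values(
        ["log2_enrichment", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if matrix.extra is not None and {"padj", "log2FC"} <= set(matrix.extra.columns):
        ex = matrix.extra.reindex(out["gene"])
        out["padj"] = ex["padj"].to_numpy()
        out["log2FC"] = ex["log2FC"].to_numpy()
        out["significant"] = (out["padj"] < padj_max) & (out["log2FC"] > log2fc_min)
    return out


def top_candidates(ranked: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Top-N view: flagged overlapping ncRNAs are not considered."""
    return ranked[~ranked["excluded"]].head(n).reset_index(drop=True)


def go_categorize(
    genes: list[str] | pd.Series,
    go_map: dict[str, set[str]],
    categories: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Gene x category boolean table plus per-gene category count (0-7).

    A category is true when any of the gene's GO term names contains one of
    the category's keywords (case-insensitive substring). Genes absent from
    the map get all-false rows.
    """
    categories = categories or GO_CATEGORIES
    rows = []
    for gene in genes:
        terms = [t.lower() for t in go_map.get(gene, set())]
        row = {"gene": gene}
        for cat, keywords in categories.items():
            row[cat] = any(kw in term for term in terms for kw in keywords)
        row["n_categories"] = sum(bool(row[c]) for c in categories)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_rip_counts(
    n_genes: int = 500,
    n_ip: int = 3,
    n_input: int = 3,
    enriched_fraction: float = 0.1,
    log2_enrichment: float = 3.0,
    mean_expression: float = 200.0,
    dispersion: float = 0.1,
    seed: int = 0,
    true_log2=None,
) -> tuple[CountMatrix, pd.Series]:
    """Negative-binomial count matrix with planted IP enrichment.

    Gene baselines are log-normal around ``mean_expression``. By default a
    random ``enriched_fraction`` of genes get their IP mean multiplied by
    2**``log2_enrichment``; alternatively ``true_log2`` supplies a per-gene
    log2 enrichment array (e.g. a graded spectrum, so rank recovery is
    meaningful). Counts are NB with gene-level dispersion
    (var = mu + dispersion * mu^2). Returns the matrix and the per-gene true
    log2 enrichment.
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"gene_{i:04d}" for i in range(n_genes)], name="gene")
    base = mean_expression * rng.lognormal(0.0, 0.8, size=n_genes)
    if true_log2 is not None:
        true_lfc = np.asarray(true_log2, dtype=float)
        if true_lfc.shape != (n_genes,):
            raise ValueError("true_log2 must have one value per gene")
    else:
        true_lfc = np.zeros(n_genes)
        enriched = rng.random(n_genes) < enriched_fraction
        true_lfc[enriched] = log2_enrichment

    def nb(mu):
        # NB2 parameterisation: var = mu + dispersion * mu^2
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    data = {}
    for j in range(n_input):
        data[f"input_{j}"] = nb(base)
    for j in range(n_ip):
        data[f"ip_{j}"] = nb(base * 2.0 ** true_lfc)
    counts = pd.DataFrame(data, index=genes)
    groups = {c: ("IP" if c.startswith("ip") else "input") for c in counts.columns}
    return CountMatrix(counts=counts, groups=groups), pd.Series(true_lfc, index=genes)


# ---------------------------------------------------------------------------
# I/O: TSV with a 2-line header (library names, then group labels)

def read_count_matrix_tsv(path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_line = fh.readline().rstrip("\n").split("\t")
        body = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    libs = header[1:]
    groups = dict(zip(libs, group_line[1:]))
    body.columns = libs
    body.index.name = "gene"
    return CountMatrix(counts=body.astype(int), groups=groups)


def write_count_matrix_tsv(matrix: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        libs = list(matrix.counts.columns)
        fh.write("gene\t" + "\t".join(libs) + "\n")
        fh.write("group\t" + "\t".join(matrix.groups[c] for c in libs) + "\n")
        matrix.counts.to_csv(fh, sep="\t", header=False)


def read_go_map_tsv(path) -> dict[str, set[str]]:
    """2-column TSV (gene, term name), one row per term."""
    mapping: dict[str, set[str]] = {}
    table = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    for gene, term in zip(table["gene"], table["term"]):
        mapping.setdefault(str(gene), set()).add(str(term))
    return mapping
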