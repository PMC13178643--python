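"""Single-nucleus count QC, normalization, projection classification and
the balanced-bootstrap differential-expression counting comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps

from . import stats

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "BootstrapConfig",
    "DEGCountDistribution",
    "EmptyFilterError",
    "qc_filter",
    "normalize_log1p",
    "classify_projection",
    "rank_genes_wilcoxon",
    "bootstrap_deg_counts",
    "compare_regions",
    "gene_sex_comparison",
    "DEFAULT_MARKERS",
]

DEFAULT_MARKERS = ("Calb1", "Sox6", "Aldh1a1")

PROJECTION_LABELS = ("core", "shell", "ambiguous", "unassigned")


class EmptyFilterError(ValueError):
    """A QC rule removed every remaining cell."""


@dataclass
class CountMatrix:
    """Genes × nuclei integer counts plus per-nucleus metadata."""

    counts: sparse.spmatrix
    gene_ids: list[str]
    nucleus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.nucleus_meta)):
            raise ValueError("counts shape inconsistent with gene_ids / nucleus_meta")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """log1p of counts scaled to ``target_sum`` per nucleus."""

    values: sparse.spmatrix
    gene_ids: list[str]
    nucleus_meta: pd.DataFrame
    target_sum: float = 1_000_000.0

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)

    def gene_row(self, gene: str) -> np.ndarray:
        idx = self.gene_ids.index(gene)
        return np.asarray(self.values[idx].todense()).ravel()


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 50
    n_per_sex: int = 30
    lfc_threshold: float = 0.5
    alpha: float = 0.025  # 0.05 Bonferroni-corrected for the 2 regions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_per_sex < 2:
            raise ValueError("require n_boot >= 1 and n_per_sex >= 2")


@dataclass(frozen=True)
class DEGCountDistribution:
    counts: tuple[int, ...]
    region: str

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("DEG counts must be non-negative")


def qc_filter(
    raw: CountMatrix,
    mito_gene_set: Sequence[str] = (),
    min_genes: int = 200,
    min_cells: int = 3,
    max_genes_percentile: float = 98.0,
    max_mito_frac: float = 0.05,
    per_sample: bool = True,
) -> tuple[CountMatrix, dict[str, int]]:
    """Apply the four QC rules in order and report per-rule removals.

    Rules: (1) cells expressing >= ``min_genes`` genes are kept; (2) genes
    expressed in >= ``min_cells`` cells are kept; (3) cells above the
    ``max_genes_percentile`` of genes-per-cell (computed after rule 1,
    per sample when metadata carries one) are removed; (4) cells with a
    mitochondrial count fraction > ``max_mito_frac`` are removed.
    """
    if raw.n_nuclei == 0 or raw.n_genes == 0:
        raise ValueError("empty count matrix")
    counts = raw.counts.tocsc()
    gene_ids = list(raw.gene_ids)
    meta = raw.nucleus_meta.reset_index(drop=True)
    report: dict[str, int] = {}

    genes_per_cell = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_cells = genes_per_cell >= min_genes
    report["min_genes"] = int((~keep_cells).sum())
    if not keep_cells.any():
        raise EmptyFilterError("min_genes rule removed every cell")
    counts = counts[:, keep_cells]
    meta = meta.loc[keep_cells].reset_index(drop=True)

    cells_per_gene = np.asarray((counts > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= min_cells
    report["min_cells"] = int((~keep_genes).sum())
    counts = counts[keep_genes, :]
    gene_ids = [g for g, k in zip(gene_ids, keep_genes) if k]

    genes_per_cell = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_cells = np.ones(counts.shape[1], dtype=bool)
    if per_sample and "sample" in meta.columns:
        for _, idx in meta.groupby("sample").groups.items():
            idx = np.asarray(idx)
            cutoff = np.percentile(genes_per_cell[idx], max_genes_percentile)
            keep_cells[idx] = genes_per_cell[idx] <= cutoff
    else:
        cutoff = np.percentile(genes_per_cell, max_genes_percentile)
        keep_cells = genes_per_cell <= cutoff
    report["max_genes_percentile"] = int((~keep_cells).sum())
    if not keep_cells.any():
        raise EmptyFilterError("max_genes_percentile rule removed every cell")
    counts = counts[:, keep_cells]
    meta = meta.loc[keep_cells].reset_index(drop=True)

    mito_rows = np.array([g in set(mito_gene_set) for g in gene_ids], dtype=bool)
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_counts = (
        np.asarray(counts[mito_rows, :].sum(axis=0)).ravel().astype(float)
        if mito_rows.any()
        else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-12), 0.0)
    keep_cells = frac <= max_mito_frac
    report["max_mito_frac"] = int((~keep_cells).sum())
    if not keep_cells.any():
        raise EmptyFilterError("max_mito_frac rule removed every cell")
    counts = counts[:, keep_cells]
    meta = meta.loc[keep_cells].reset_index(drop=True)

    return CountMatrix(counts.tocsr(), gene_ids, meta), report


def normalize_log1p(
    filtered: CountMatrix, target_sum: float = 1_000_000.0
) -> NormalizedMatrix:
    """value = log(1 + count / cell_total * target_sum) per entry."""
    totals = np.asarray(filtered.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts cannot be normalized")
    x = filtered.counts.tocsc().astype(float)
    scale = target_sum / totals
    x = x.multiply(sparse.csr_matrix(scale[None, :]))
    x = x.log1p()
    return NormalizedMatrix(
        x.tocsr(), list(filtered.gene_ids), filtered.nucleus_meta.reset_index(drop=True),
        float(target_sum),
    )


def classify_projection(
    norm: NormalizedMatrix,
    markers: Sequence[str] = DEFAULT_MARKERS,
    threshold: float = 0.0,
) -> np.ndarray:
    """Marker-coexpression projection call per nucleus.

    core = Calb1 & Sox6, shell = Calb1 & Aldh1a1 (value > ``threshold``
    counts as expressed); nuclei matching both are 'ambiguous', neither
    'unassigned'.
    """
    calb1, sox6, aldh1a1 = markers
    for m in markers:
        if m not in norm.gene_ids:
            raise ValueError(f"marker gene {m!r} absent from the matrix")
    e_calb1 = norm.gene_row(calb1) > threshold
    e_sox6 = norm.gene_row(sox6) > threshold
    e_aldh = norm.gene_row(aldh1a1) > threshold
    core = e_calb1 & e_sox6
    shell = e_calb1 & e_aldh
    labels = np.full(norm.values.shape[1], "unassigned", dtype=object)
    labels[core & ~shell] = "core"
    labels[shell & ~core] = "shell"
    labels[core & shell] = "ambiguous"
    return labels


def _tie_term(row: np.ndarray) -> float:
    _, cnt = np.unique(row, return_counts=True)
    return float(((cnt**3) - cnt).sum())


def rank_genes_wilcoxon(
    values: np.ndarray | sparse.spmatrix,
    gene_ids: Sequence[str],
    group1_idx: np.ndarray,
    group2_idx: np.ndarray,
    lfc_threshold: float = 0.5,
    alpha: float = 0.025,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test (tie-corrected normal approximation).

    log2fc compares group means on the expm1-back-transformed scale with
    pseudo-count ``eps``; p-values are BH-adjusted across genes and
    ``significant`` requires both |log2fc| > ``lfc_threshold`` and
    padj < ``alpha``.
    """
    group1_idx = np.asarray(group1_idx)
    group2_idx = np.asarray(group2_idx)
    n1, n2 = group1_idx.size, group2_idx.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 nuclei")
    if sparse.issparse(values):
        x = np.asarray(values[:, np.concatenate([group1_idx, group2_idx])].todense())
    else:
        x = np.asarray(values)[:, np.concatenate([group1_idx, group2_idx])]
    n = n1 + n2
    ranks = sps.rankdata(x, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    tie_terms = np.apply_along_axis(_tie_term, 1, x)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (u1 - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = np.where(var > 0, 2.0 * sps.norm.sf(np.abs(z)), 1.0)
    p = np.minimum(p, 1.0)

    m1 = np.expm1(x[:, :n1]).mean(axis=1)
    m2 = np.expm1(x[:, n1:]).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2((m1 + eps) / (m2 + eps))

    padj = stats.benjamini_hochberg(p)
    significant = (np.abs(log2fc) > lfc_threshold) & (padj < alpha)
    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "statistic": u1,
            "p_value": p,
            "padj": padj,
            "log2fc": log2fc,
            "significant": significant,
        }
    )


def bootstrap_deg_counts(
    norm: NormalizedMatrix,
    sex_labels: Sequence[str] | None = None,
    config: BootstrapConfig = BootstrapConfig(),
    region: str = "",
    nucleus_mask: np.ndarray | None = None,
) -> DEGCountDistribution:
    """Balanced-bootstrap DEG counts between sexes.

    Each iteration resamples ``n_per_sex`` nuclei with replacement from
    each sex, runs the rank-sum DEG screen, and records the number of
    significant genes.
    """
    if sex_labels is None:
        sex_labels = norm.nucleus_meta["sex"].to_numpy()
    sex_labels = np.asarray(sex_labels)
    mask = (
        np.ones(sex_labels.size, dtype=bool) if nucleus_mask is None
        else np.asarray(nucleus_mask, dtype=bool)
    )
    f_idx = np.where(mask & (sex_labels == "F"))[0]
    m_idx = np.where(mask & (sex_labels == "M"))[0]
    if f_idx.size == 0 or m_idx.size == 0:
        raise ValueError("both sexes must be present in the population")
    rng = np.random.default_rng(config.seed)
    counts = []
    for _ in range(config.n_boot):
        take_f = rng.choice(f_idx, size=config.n_per_sex, replace=True)
        take_m = rng.choice(m_idx, size=config.n_per_sex, replace=True)
        table = rank_genes_wilcoxon(
            norm.values,
            norm.gene_ids,
            take_f,
            take_m,
            lfc_threshold=config.lfc_threshold,
            alpha=config.alpha,
        )
        counts.append(int(table["significant"].sum()))
    return DEGCountDistribution(tuple(counts), region)


def compare_regions(
    core: DEGCountDistribution, shell: DEGCountDistribution
) -> stats.RankTestResult:
    """Two-sided Mann-Whitney U on the per-bootstrap DEG counts.

    U follows the first-sample, larger-is-bigger convention: complete
    separation with core above shell gives U = n_core * n_shell.
    """
    return stats.mann_whitney_u(core.counts, shell.counts)


@dataclass(frozen=True)
class GateTestResult:
    method: str  # "t_test" | "mann_whitney" | "degenerate"
    statistic: float
    p_value: float
    flagged: bool = False


def gene_sex_comparison(
    values: Sequence[float],
    sex_labels: Sequence[str],
    normality_alpha: float = 0.05,
    max_var_ratio: float = 4.0,
) -> GateTestResult:
    """Normality/variance-gated two-group comparison for one gene.

    Shapiro-Wilk on each group plus an F-ratio gate select an unpaired
    t test; otherwise Mann-Whitney.  Degenerate (all-equal) input yields
    p = 1 with a flag.
    """
    values = np.asarray(values, dtype=float)
    sex_labels = np.asarray(sex_labels)
    a = values[sex_labels == "F"]
    b = values[sex_labels == "M"]
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 nuclei per sex")
    if np.ptp(values) == 0:
        return GateTestResult("degenerate", 0.0, 1.0, flagged=True)
    normal = True
    for g in (a, b):
        if np.ptp(g) == 0:
            normal = False
            break
        if sps.shapiro(g).pvalue <= normality_alpha:
            normal = False
            break
    va, vb = a.var(ddof=1), b.var(ddof=1)
    equal_var = min(va, vb) > 0 and max(va, vb) / min(va, vb) < max_var_ratio
    if normal and equal_var:
        res = sps.ttest_ind(a, b)
        return GateTestResult("t_test", float(res.statistic), float(res.pvalue))
    res = stats.mann_whitney_u(a, b)
    return GateTestResult("mann_whitney", res.statistic, res.p_value)
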