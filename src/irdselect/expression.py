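"""Cell-type expression summaries from labelled single-cell counts.

Provides the standard depth-normalization (scale each cell to a common
total, then log1p), highly-variable-gene selection by binned normalized
dispersion, dot-plot statistics (fraction of cells expressing and mean
normalized expression per gene and cell type), and the tau specificity
index that turns the visual "ubiquitous vs cell-type-specific" call into a
number in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, DataIntegrityError, DomainError

DEFAULT_TARGET_SUM = 10_000.0


@dataclass
class LabeledCounts:
    """Sparse cells x genes integer count matrix with per-cell type labels."""

    matrix: sp.csr_matrix
    cell_types: np.ndarray
    gene_symbols: list[str]

    def __post_init__(self):
        self.matrix = sp.csr_matrix(self.matrix)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_types) != n_cells:
            raise DataIntegrityError(
                f"{n_cells} cells but {len(self.cell_types)} labels"
            )
        if len(self.gene_symbols) != n_genes:
            raise DataIntegrityError(
                f"{n_genes} matrix columns but {len(self.gene_symbols)} gene symbols"
            )
        if len(set(self.gene_symbols)) != n_genes:
            seen, dup = set(), set()
            for g in self.gene_symbols:
                (dup if g in seen else seen).add(g)
            raise DataIntegrityError(f"duplicate gene symbols: {sorted(dup)}")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise DataIntegrityError("counts must be non-negative")

    @property
    def types(self) -> list[str]:
        return sorted(set(self.cell_types))

    @classmethod
    def from_files(
        cls,
        mtx_path,
        features_path,
        cells_path,
        orientation: str = "cells_by_genes",
    ) -> "LabeledCounts":
        """Read Matrix Market counts plus sidecar feature/cell tables.

        ``orientation`` says whether the matrix rows are cells
        (``cells_by_genes``) or genes (``genes_by_cells``).
        """
        from scipy.io import mmread

        matrix = sp.csr_matrix(mmread(str(mtx_path)))
        if orientation == "genes_by_cells":
            matrix = matrix.T.tocsr()
        elif orientation != "cells_by_genes":
            raise ConfigurationError(f"unknown orientation {orientation!r}")
        features = pd.read_csv(features_path, sep="\t")
        cells = pd.read_csv(cells_path, sep="\t")
        return cls(
            matrix=matrix,
            cell_types=cells["cell_type"].to_numpy(),
            gene_symbols=features["gene"].tolist(),
        )


@dataclass(frozen=True)
class HVGParams:
    """Mean window and dispersion cutoff for highly-variable-gene selection.

    Means and dispersions are computed on the de-logged normalized scale;
    dispersions are z-scored within ``n_bins`` equal-frequency mean bins
    before the ``min_disp`` cutoff is applied.
    """

    min_mean: float = 0.0125
    max_mean: float = 3.0
    min_disp: float = 0.5
    n_bins: int = 20

    def __post_init__(self):
        if not self.min_mean < self.max_mean:
            raise ConfigurationError("min_mean must be < max_mean")
        if not np.isfinite(self.min_disp):
            raise ConfigurationError("min_disp must be finite")
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")


def normalize(
    counts: LabeledCounts, target_sum: float = DEFAULT_TARGET_SUM
) -> sp.csr_matrix:
    """Depth-normalize each cell to ``target_sum`` total counts, then log1p.

    Scaling is per cell, so multiplying all counts of one cell by a constant
    leaves its normalized vector unchanged.  Cells with zero total counts
    are rejected.
    """
    totals = np.asarray(counts.matrix.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise DomainError(
            f"{zero.size} cell(s) with zero total counts (first index {zero[0]})"
        )
    scaled = sp.diags(target_sum / totals) @ counts.matrix
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    return scaled


def _per_gene_moments(normalized: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance per gene of expm1(normalized) (the de-logged scale)."""
    delogged = normalized.copy()
    delogged.data = np.expm1(delogged.data)
    n = delogged.shape[0]
    mean = np.asarray(delogged.mean(axis=0)).ravel()
    sq = delogged.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(
    normalized: sp.csr_matrix,
    gene_symbols: list[str],
    params: HVGParams = HVGParams(),
) -> pd.DataFrame:
    """Highly-variable-gene selection by binned normalized dispersion.

    Per gene, mean and dispersion (variance/mean) are computed on the
    de-logged normalized scale; dispersions are z-scored within
    equal-frequency mean bins; a gene is kept iff
    ``min_mean < mean < max_mean`` and its normalized dispersion is at least
    ``min_disp``.  Returns a per-gene table with columns
    ``gene, mean, dispersion, dispersion_norm, highly_variable``.
    """
    mean, var = _per_gene_moments(normalized)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)

    n_bins = params.n_bins
    if n_bins > len(gene_symbols):
        warnings.warn(
            f"n_bins={n_bins} exceeds gene count {len(gene_symbols)}; reducing"
        )
        n_bins = max(len(gene_symbols), 1)
    # equal-frequency bins on the mean; duplicate edges collapse; NaN-safe
    bins = pd.qcut(pd.Series(mean), q=n_bins, duplicates="drop", labels=False)
    disp_norm = np.zeros_like(dispersion)
    for b in pd.unique(bins.dropna()):
        idx = np.flatnonzero(bins.to_numpy() == b)
        mu = dispersion[idx].mean()
        sd = dispersion[idx].std(ddof=1) if idx.size > 1 else 0.0
        disp_norm[idx] = (dispersion[idx] - mu) / sd if sd > 0 else 0.0

    keep = (mean > params.min_mean) & (mean < params.max_mean) & (
        disp_norm >= params.min_disp
    )
    return pd.DataFrame(
        {
            "gene": gene_symbols,
            "mean": mean,
            "dispersion": dispersion,
            "dispersion_norm": disp_norm,
            "highly_variable": keep,
        }
    )


def dot_statistics(
    normalized: sp.csr_matrix,
    counts: LabeledCounts,
    genes: list[str],
) -> pd.DataFrame:
    """Dot-plot statistics per requested gene and cell type.

    ``fraction_expressing`` is the share of cells of the type with a raw
    count above zero; ``mean_expression`` is the mean normalized
    log-expression over all cells of the type (expressing or not).  A
    requested gene absent from the matrix gets zero rows for every type.
    """
    gene_index = {g: j for j, g in enumerate(counts.gene_symbols)}
    raw = counts.matrix.tocsc()
    norm = sp.csc_matrix(normalized)
    rows = []
    for gene in genes:
        j = gene_index.get(gene)
        for cell_type in counts.types:
            mask = counts.cell_types == cell_type
            n_t = int(mask.sum())
            if j is None or n_t == 0:
                frac, mean_expr = 0.0, 0.0
            else:
                raw_col = np.asarray(raw[:, j].todense()).ravel()[mask]
                norm_col = np.asarray(norm[:, j].todense()).ravel()[mask]
                frac = float((raw_col > 0).sum() / n_t)
                mean_expr = float(norm_col.mean())
            rows.append(
                {
                    "gene": gene,
                    "cell_type": cell_type,
                    "fraction_expressing": frac,
                    "mean_expression": mean_expr,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "cell_type", "fraction_expressing", "mean_expression"]
    )


def specificity_tau(mean_by_type: np.ndarray) -> float:
    """Tau specificity index of a per-type mean-expression vector.

    ``tau = sum_t (1 - m_t / max_t m_t) / (T - 1)``: 0 for perfectly uniform
    expression, 1 for single-type expression.  Invariant to positive
    rescaling.  An all-zero vector is treated as uniform (tau = 0).
    """
    m = np.asarray(mean_by_type, dtype=float)
    if m.size < 2:
        raise DomainError("tau requires at least two cell types")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise DomainError("mean expression values must be finite and non-negative")
    peak = m.max()
    if peak == 0:
        return 0.0
    return float(np.sum(1.0 - m / peak) / (m.size - 1))


def specificity_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Tau per gene from a dot-statistics table (mean_expression column)."""
    rows = []
    for gene, grp in summary.groupby("gene", sort=True):
        tau = specificity_tau(grp["mean_expression"].to_numpy())
        rows.append({"gene": gene, "specificity_tau": tau})
    return pd.DataFrame(rows, columns=["gene", "specificity_tau"])
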