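"""Pooled diagnostic-yield ranking across sequencing cohorts.

Studies reporting per-gene molecular-diagnosis counts are filtered by the
inclusion criteria (NGS panel or whole-exome platform, cohort size strictly
greater than 50, per-gene counts present, uniform diagnostic criteria),
per-gene yields are standardized to diagnoses per screened proband, and
yields are combined by a weighted average with weights defaulting to cohort
size.  A gene missing from a study is treated as not assayed (excluded from
that gene's weighted mean), not as a zero; a reported zero count stays a
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ConfigurationError, DataIntegrityError

INCLUDED_PLATFORMS = frozenset({"NGS_panel", "WES"})
MIN_COHORT_SIZE = 50  # inclusion requires cohort_size strictly greater
DEFAULT_TOP_K = 10

REASON_PLATFORM = "platform"
REASON_SAMPLE_SIZE = "sample_size"
REASON_CRITERIA = "criteria"
REASON_NO_COUNTS = "no_counts"


@dataclass
class StudyFilterResult:
    included: pd.DataFrame
    excluded: pd.DataFrame  # columns: study_id, reasons (comma-joined codes)


def _study_table(studies: pd.DataFrame) -> pd.DataFrame:
    per_study = (
        studies.groupby("study_id")
        .agg(
            cohort_size=("cohort_size", "first"),
            platform=("platform", "first"),
            total_diagnosed=("diagnosed_count", lambda s: s.dropna().sum()),
            n_gene_rows=("diagnosed_count", lambda s: s.notna().sum()),
        )
        .reset_index()
    )
    bad = per_study[per_study["total_diagnosed"] > per_study["cohort_size"]]
    if len(bad):
        raise DataIntegrityError(
            "diagnosed counts exceed cohort size in studies: "
            + ", ".join(bad["study_id"].astype(str))
        )
    return per_study


def filter_studies(
    studies: pd.DataFrame, min_size: int = MIN_COHORT_SIZE
) -> StudyFilterResult:
    """Apply the inclusion criteria; excluded studies carry reason codes.

    A study is included iff its platform is an NGS panel or WES, its cohort
    size is strictly greater than ``min_size``, it reports per-gene counts,
    and (if a ``nonuniform_criteria`` column is present) its diagnostic
    criteria are uniform.  Violations are reported as comma-joined codes in
    the order platform, sample_size, criteria, no_counts.
    """
    per_study = _study_table(studies)
    criteria_flags = {}
    if "nonuniform_criteria" in studies.columns:
        criteria_flags = (
            studies.groupby("study_id")["nonuniform_criteria"].any().to_dict()
        )
    reasons: dict[str, list[str]] = {}
    for row in per_study.itertuples():
        r = []
        if row.platform not in INCLUDED_PLATFORMS:
            r.append(REASON_PLATFORM)
        if row.cohort_size <= min_size:
            r.append(REASON_SAMPLE_SIZE)
        if criteria_flags.get(row.study_id, False):
            r.append(REASON_CRITERIA)
        if row.n_gene_rows == 0:
            r.append(REASON_NO_COUNTS)
        if r:
            reasons[row.study_id] = r
    excluded = pd.DataFrame(
        {
            "study_id": list(reasons),
            "reasons": [",".join(r) for r in reasons.values()],
        }
    )
    included = studies[~studies["study_id"].isin(reasons)].reset_index(drop=True)
    return StudyFilterResult(included=included, excluded=excluded)


def standardize_yields(included: pd.DataFrame) -> pd.DataFrame:
    """Per-study yields y = diagnosed / cohort_size.

    Genes absent from a study simply have no row; a reported zero count
    yields an explicit 0.0 row.
    """
    out = included.copy()
    out = out[out["diagnosed_count"].notna()]
    out["yield"] = out["diagnosed_count"] / out["cohort_size"]
    if ((out["yield"] < 0) | (out["yield"] > 1)).any():
        raise DataIntegrityError("per-study yields must lie in [0, 1]")
    cols = ["study_id", "cohort_size", "platform", "gene", "diagnosed_count", "yield"]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra].reset_index(drop=True)


def weighted_rank(
    yields: pd.DataFrame, weights: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pool per-study yields by weighted averaging and rank genes.

    Weights default to cohort size; an explicit ``weights`` table
    (``study_id, weight``) overrides, e.g. to fold in a sequencing-depth
    multiplier.  The pooled yield of gene g is
    ``sum_s w_s * y_gs / sum_s w_s`` over the studies reporting g.  Ranks are
    descending by pooled yield; ties break by more reporting studies, then by
    gene symbol.
    """
    if len(yields) == 0:
        warnings.warn("no yields to pool; returning empty ranking")
        return pd.DataFrame(
            columns=["gene", "pooled_yield", "weight_sum", "n_studies", "rank"]
        )
    df = yields.copy()
    if weights is not None:
        w = weights.set_index("study_id")["weight"]
        missing = set(df["study_id"]) - set(w.index)
        if missing:
            raise ConfigurationError(f"no weight for studies: {sorted(missing)}")
        df["weight"] = df["study_id"].map(w).astype(float)
    else:
        df["weight"] = df["cohort_size"].astype(float)
    df["wy"] = df["weight"] * df["yield"]
    pooled = (
        df.groupby("gene")
        .agg(
            weight_sum=("weight", "sum"),
            wy_sum=("wy", "sum"),
            n_studies=("study_id", "nunique"),
        )
        .reset_index()
    )
    pooled["pooled_yield"] = pooled["wy_sum"] / pooled["weight_sum"]
    pooled = pooled.sort_values(
        ["pooled_yield", "n_studies", "gene"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    pooled["rank"] = np.arange(1, len(pooled) + 1)
    return pooled[["gene", "pooled_yield", "weight_sum", "n_studies", "rank"]]


def top_k(pooled: pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """First ``k`` genes of the pooled ranking (all genes if k >= n)."""
    if k < 0:
        raise ConfigurationError("k must be non-negative")
    return pooled.sort_values("rank")["gene"].head(k).tolist()


def rank_cohorts(
    studies: pd.DataFrame,
    min_size: int = MIN_COHORT_SIZE,
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """filter -> standardize -> weighted_rank in one call."""
    filtered = filter_studies(studies, min_size=min_size)
    if len(filtered.included) == 0:
        raise ConfigurationError("no studies remain after filtering")
    return weighted_rank(standardize_yields(filtered.included), weights=weights)


def sensitivity_analysis(
    studies: pd.DataFrame,
    thresholds: list[int],
    k: int = DEFAULT_TOP_K,
    baseline_min_size: int = MIN_COHORT_SIZE,
) -> pd.DataFrame:
    """Stability of the ranking under alternative minimum cohort sizes.

    For each threshold the filter+rank pipeline is re-run and compared with
    the baseline via Spearman correlation of pooled yields over the common
    genes and Jaccard overlap of the top-k sets.
    """
    baseline = rank_cohorts(studies, min_size=baseline_min_size)
    base_top = set(top_k(baseline, k))
    rows = []
    for threshold in thresholds:
        ranked = rank_cohorts(studies, min_size=threshold)
        common = sorted(set(baseline["gene"]) & set(ranked["gene"]))
        if len(common) < 2:
            rho = float("nan")
        else:
            b = baseline.set_index("gene").loc[common, "pooled_yield"]
            r = ranked.set_index("gene").loc[common, "pooled_yield"]
            rho = float(spearmanr(b, r).statistic)
        this_top = set(top_k(ranked, k))
        union = base_top | this_top
        overlap = len(base_top & this_top) / len(union) if union else 1.0
        rows.append(
            {"threshold": threshold, "spearman": rho, "top_k_overlap": overlap}
        )
    return pd.DataFrame(rows, columns=["threshold", "spearman", "top_k_overlap"])
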