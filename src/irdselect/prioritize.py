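"""Gene-therapy candidate selection and burden-vs-attention export.

A gene is a gene-supplementation candidate when, jointly:

* its transcript fits the AAV packaging capacity (default 4700 nt, the
  conventional ~4.7 kb single-vector cargo limit);
* its global disease burden — expected affected individuals (EAI) — strictly
  exceeds that of a reference gene (default RPE65, the gene behind the first
  approved ocular gene therapy);
* it codes for an enzyme (optional but on by default: partial restoration of
  catalytic activity is often therapeutic).

The module also exports the scatter data contrasting disease burden with
research intensity (publication counts), whose rank correlation quantifies
how misaligned research attention is with clinical burden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ConfigurationError, DataIntegrityError
from .prevalence import GLOBAL

DEFAULT_CARGO_LIMIT_NT = 4700  # ~4.7 kb AAV packaging capacity, 1 kb = 1000 nt


@dataclass(frozen=True)
class PrioritizationConfig:
    cargo_limit_nt: int = DEFAULT_CARGO_LIMIT_NT
    reference_gene: str = "RPE65"
    require_enzyme: bool = True
    strict_burden: bool = True  # EAI must strictly exceed the reference's

    def __post_init__(self):
        if self.cargo_limit_nt <= 0:
            raise ConfigurationError("cargo_limit_nt must be positive")


@dataclass
class JoinResult:
    joined: pd.DataFrame
    unmatched_prevalence: list[str]
    unmatched_annotations: list[str]


def collapse_transcripts(
    annotations: pd.DataFrame, rule: str = "max"
) -> pd.DataFrame:
    """Reduce a multi-transcript annotation table to one length per gene.

    ``rule="max"`` (default) keeps the longest transcript — conservative for
    cargo fit; ``rule="min"`` keeps the shortest.  Other columns take their
    first value per gene.
    """
    if rule not in ("max", "min"):
        raise ConfigurationError(f"unknown transcript rule {rule!r}")
    agg = {c: "first" for c in annotations.columns if c != "gene"}
    agg["transcript_length_nt"] = rule
    return annotations.groupby("gene", as_index=False).agg(agg)[annotations.columns]


def _check_unique(genes: pd.Series, side: str) -> None:
    dup = genes[genes.duplicated()].unique().tolist()
    if dup:
        raise DataIntegrityError(f"duplicate gene symbols in {side} table: {dup}")


def join_gene_table(
    prevalence: pd.DataFrame,
    annotations: pd.DataFrame,
    normalize_case: bool = False,
) -> JoinResult:
    """Inner-join global burden estimates with gene annotations.

    Uses the GLOBAL prevalence rows (one per gene).  Symbols are matched
    exactly unless ``normalize_case`` upper-cases both sides first.
    Unmatched genes on either side are reported, not dropped silently.
    """
    glob = prevalence[prevalence["population"] == GLOBAL].copy()
    if len(glob) == 0:
        glob = prevalence.copy()  # caller already passed per-gene global rows
    ann = annotations.copy()
    if normalize_case:
        glob["gene"] = glob["gene"].str.upper()
        ann["gene"] = ann["gene"].str.upper()
    _check_unique(glob["gene"], "prevalence")
    _check_unique(ann["gene"], "annotations")
    joined = glob.merge(ann, on="gene", how="inner")
    matched = set(joined["gene"])
    return JoinResult(
        joined=joined.reset_index(drop=True),
        unmatched_prevalence=sorted(set(glob["gene"]) - matched),
        unmatched_annotations=sorted(set(ann["gene"]) - matched),
    )


def candidate_filter(
    joined: pd.DataFrame, config: PrioritizationConfig = PrioritizationConfig()
) -> pd.DataFrame:
    """Apply the three candidate criteria and rank candidates by burden.

    Adds boolean columns ``size_ok`` (transcript within cargo limit),
    ``burden_ok`` (EAI above the reference gene; strict by default, so the
    reference itself never qualifies), ``enzyme_ok``, their conjunction
    ``candidate``, and ``eai_rank`` (1 = highest-burden candidate, ties by
    symbol; NA for non-candidates).
    """
    if config.reference_gene not in set(joined["gene"]):
        raise ConfigurationError(
            f"reference gene {config.reference_gene!r} absent from joined table"
        )
    out = joined.copy()
    ref_eai = float(
        out.loc[out["gene"] == config.reference_gene, "expected_affected"].iloc[0]
    )
    out["size_ok"] = out["transcript_length_nt"] <= config.cargo_limit_nt
    if config.strict_burden:
        out["burden_ok"] = out["expected_affected"] > ref_eai
    else:
        out["burden_ok"] = out["expected_affected"] >= ref_eai
    out["enzyme_ok"] = out["enzyme_flag"] if config.require_enzyme else True
    out["candidate"] = out["size_ok"] & out["burden_ok"] & out["enzyme_ok"]

    out["eai_rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    cand = out[out["candidate"]].sort_values(
        ["expected_affected", "gene"], ascending=[False, True]
    )
    out.loc[cand.index, "eai_rank"] = np.arange(1, len(cand) + 1)
    return out


def burden_vs_attention(table: pd.DataFrame) -> tuple[pd.DataFrame, float, bool]:
    """EAI vs publication-count pairs and their Spearman correlation.

    Computed across all genes, without thresholding.  Returns
    ``(pairs, correlation, computable)``; ``computable`` is False when ranks
    are degenerate (e.g. identical publication counts everywhere), in which
    case the correlation is NaN.
    """
    pairs = table[["gene", "expected_affected", "publication_count"]].copy()
    eai = pairs["expected_affected"].to_numpy(dtype=float)
    pubs = pairs["publication_count"].to_numpy(dtype=float)
    if len(pairs) < 2 or np.all(eai == eai[0]) or np.all(pubs == pubs[0]):
        return pairs, float("nan"), False
    rho = float(spearmanr(eai, pubs).statistic)
    return pairs, rho, bool(np.isfinite(rho))


def scatter_export(
    table: pd.DataFrame,
    config: PrioritizationConfig = PrioritizationConfig(),
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Plot data for the burden-vs-transcript-size scatter.

    One row per gene: x = transcript length (nt), y = EAI, bubble size =
    publication count, colour class = enzyme flag.  The metadata carries the
    vertical cargo-limit reference line and log-scale hints; the data values
    themselves are left untransformed.  When ``path`` is given, writes a TSV
    plus a JSON metadata sidecar.
    """
    cols = {
        "gene": table["gene"] if len(table) else pd.Series(dtype=object),
        "transcript_length_nt": table.get("transcript_length_nt", pd.Series(dtype=int)),
        "expected_affected": table.get("expected_affected", pd.Series(dtype=float)),
        "publication_count": table.get("publication_count", pd.Series(dtype=int)),
        "enzyme_flag": table.get("enzyme_flag", pd.Series(dtype=bool)),
    }
    data = pd.DataFrame(cols)
    meta = {
        "reference_line_nt": config.cargo_limit_nt,
        "x": "transcript_length_nt",
        "y": "expected_affected",
        "size": "publication_count",
        "color": "enzyme_flag",
        "x_scale_hint": "log",
        "y_scale_hint": "log",
    }
    if path is not None:
        path = Path(path)
        from .io import write_table

        write_table(data, path)
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
    return data, meta


def plot_scatter(data: pd.DataFrame, meta: dict, path: str | Path) -> None:
    """Render the burden-vs-size scatter to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for enzyme, grp in data.groupby("enzyme_flag"):
        ax.scatter(
            grp["transcript_length_nt"],
            grp["expected_affected"].clip(lower=1e-3),
            s=5 + np.sqrt(grp["publication_count"].clip(lower=0)) * 4,
            alpha=0.6,
            label="enzyme" if enzyme else "non-enzyme",
        )
    ax.axvline(meta["reference_line_nt"], color="grey", linestyle="--", linewidth=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("transcript length (nt)")
    ax.set_ylabel("expected affected individuals")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
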