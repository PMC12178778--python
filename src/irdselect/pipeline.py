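"""Stage orchestration: simulate -> prevalence -> rank -> expression -> prioritize.

Each stage reads/writes the TSV artifacts defined in :mod:`irdselect.io`;
``run_all`` chains them and writes a JSON run-manifest (package version,
seed, config hash, per-artifact SHA-256) sufficient to re-execute the run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__, cohorts, expression, io, prevalence, prioritize
from .config import PipelineConfig
from .errors import ConfigurationError
from .simulate import simulate_all

log = logging.getLogger("irdselect")


def _write_counts(matrix: sp.csr_matrix, genes: list[str], cells: pd.DataFrame,
                  out_dir: Path) -> list[Path]:
    mtx = out_dir / "counts.mtx"
    scipy.io.mmwrite(
        str(mtx), sp.coo_matrix(matrix),
        comment="cells x genes raw counts", field="integer",
    )
    features = io.write_table(pd.DataFrame({"gene": genes}), out_dir / "features.tsv",
                              io.FEATURES)
    cells_path = io.write_table(cells, out_dir / "cells.tsv", io.CELLS)
    return [mtx, features, cells_path]


def stage_simulate(config: PipelineConfig, out_dir: Path) -> list[Path]:
    """Generate all synthetic inputs into ``out_dir``."""
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_all(config.simulation)
    paths = [
        io.write_table(bundle["alleles"], out_dir / "alleles.tsv", io.ALLELES),
        io.write_table(bundle["populations"], out_dir / "populations.tsv", io.POPULATIONS),
        io.write_table(bundle["cohorts"], out_dir / "cohorts.tsv", io.COHORTS),
        io.write_table(bundle["annotations"], out_dir / "annotations.tsv", io.ANNOTATIONS),
    ]
    paths += _write_counts(bundle["counts"], bundle["count_genes"], bundle["cells"], out_dir)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(bundle["manifest"], indent=2, sort_keys=True) + "\n"
    )
    paths.append(manifest_path)
    return paths


def stage_prevalence(out_dir: Path, alleles_path: Path | None = None,
                     populations_path: Path | None = None) -> Path:
    alleles = io.read_table(alleles_path or out_dir / "alleles.tsv", io.ALLELES)
    pops = io.read_table(populations_path or out_dir / "populations.tsv", io.POPULATIONS)
    table = prevalence.compute_prevalence(alleles, pops)
    return io.write_table(table, out_dir / "prevalence.tsv", io.PREVALENCE)


def stage_rank_cohorts(config: PipelineConfig, out_dir: Path,
                       cohorts_path: Path | None = None) -> list[Path]:
    studies = io.read_table(cohorts_path or out_dir / "cohorts.tsv", io.COHORTS)
    ranked = cohorts.rank_cohorts(studies)
    paths = [io.write_table(ranked, out_dir / "ranking.tsv", io.RANKING)]
    sens = cohorts.sensitivity_analysis(
        studies, list(config.sensitivity_thresholds), k=config.top_k
    )
    paths.append(io.write_table(sens, out_dir / "sensitivity.tsv", io.SENSITIVITY))
    return paths


def stage_expression(config: PipelineConfig, out_dir: Path,
                     genes: list[str] | None = None) -> list[Path]:
    counts = expression.LabeledCounts.from_files(
        out_dir / "counts.mtx", out_dir / "features.tsv", out_dir / "cells.tsv"
    )
    if genes is None:
        ranking = io.read_table(out_dir / "ranking.tsv", io.RANKING)
        genes = cohorts.top_k(ranking, config.top_k)
    norm = expression.normalize(counts)
    dot = expression.dot_statistics(norm, counts, genes)
    dot.attrs["mean_over"] = "all_cells"
    paths = [io.write_table(dot, out_dir / "dotstats.tsv", io.DOTSTATS)]
    tau = expression.specificity_table(dot)
    paths.append(io.write_table(tau, out_dir / "specificity.tsv", io.SPECIFICITY))
    hvg = expression.select_hvg(norm, counts.gene_symbols, config.hvg)
    paths.append(io.write_table(hvg, out_dir / "hvg.tsv"))
    return paths


def stage_prioritize(config: PipelineConfig, out_dir: Path) -> list[Path]:
    prev = io.read_table(out_dir / "prevalence.tsv", io.PREVALENCE)
    ann = io.read_table(out_dir / "annotations.tsv", io.ANNOTATIONS)
    joined = prioritize.join_gene_table(prev, ann)
    if joined.unmatched_prevalence or joined.unmatched_annotations:
        log.warning(
            "unmatched genes: %d prevalence-only, %d annotation-only",
            len(joined.unmatched_prevalence), len(joined.unmatched_annotations),
        )
    table = prioritize.candidate_filter(joined.joined, config.prioritization)
    paths = [io.write_table(table, out_dir / "candidates.tsv")]
    _, meta = prioritize.scatter_export(
        table, config.prioritization, out_dir / "scatter.tsv"
    )
    paths += [out_dir / "scatter.tsv", out_dir / "scatter.meta.json"]
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write the run manifest.

    Returns the manifest dict; the artifact set is byte-identical across
    invocations with the same config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    artifacts += stage_simulate(config, out_dir)
    artifacts.append(stage_prevalence(out_dir))
    artifacts += stage_rank_cohorts(config, out_dir)
    artifacts += stage_expression(config, out_dir)
    artifacts += stage_prioritize(config, out_dir)
    manifest = {
        "package": "irdselect",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
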