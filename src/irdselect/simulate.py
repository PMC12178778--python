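"""Synthetic pipeline inputs with planted ground truth.

Real burden-prioritization runs consume external resources: population
allele-frequency matrices, census demographics, pooled diagnostic-yield
cohorts, gene annotations, and a labelled retinal single-cell count matrix.
This module generates statistically analogous stand-ins for all of them,
with known structure planted so every downstream stage can be validated
offline:

* ``planted_candidates`` are built to pass every prioritization criterion
  (burden above the reference gene, transcript within the AAV cargo limit,
  enzyme-coding), and three decoys are placed just outside the boundary —
  a transcript one nucleotide over the limit, a gene whose burden exactly
  ties the reference, and a non-enzyme gene with high burden;
* ``planted_top_genes`` receive inflated diagnostic yields so they dominate
  the pooled cohort ranking;
* each simulated cell type receives marker genes expressed almost
  exclusively in that type, alongside a ubiquitously expressed gene set.

Each generator draws from its own RNG stream, derived from the master seed
by a fixed offset, so the four outputs are independently reproducible; a
fixed seed yields byte-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .prevalence import compute_prevalence

# stream offsets from the master seed (fixed so each generator is
# independently reproducible)
_STREAM_ALLELES = 0
_STREAM_COHORTS = 1
_STREAM_ANNOTATIONS = 2
_STREAM_COUNTS = 3

PLATFORMS = ("NGS_panel", "WES", "other")

CELL_TYPE_VOCAB = (
    "rod",
    "cone",
    "RPE",
    "bipolar",
    "muller_glia",
    "amacrine",
    "horizontal",
    "ganglion",
    "microglia",
    "astrocyte",
    "endothelium",
    "pericyte",
)

# gene roles used to plant recoverable structure
ROLE_REFERENCE = "reference"
ROLE_CANDIDATE = "candidate"
ROLE_SIZE_DECOY = "size_decoy"       # passes burden+enzyme, transcript 1 nt over
ROLE_TIE_DECOY = "tie_decoy"         # burden exactly equal to the reference
ROLE_ENZYME_DECOY = "enzyme_decoy"   # passes burden+size, not enzyme-coding
ROLE_BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of all four generators.

    The defaults describe the baseline study conditions used throughout the
    test-suite: 60 genes (including the RPE65-style reference) across 5
    population strata, 8 cohort studies of 200-2000 probands, and a 600-cell
    count matrix over 6 retinal cell types.
    """

    seed: int = 0
    n_genes: int = 60
    n_populations: int = 5
    n_variants_per_gene: tuple[int, int] = (2, 8)
    allele_freq_log10_range: tuple[float, float] = (-6.0, -2.0)
    n_studies: int = 8
    cohort_size_range: tuple[int, int] = (200, 2000)
    excluded_study_fraction: float = 0.25
    diagnostic_rate: float = 0.6
    n_cells: int = 600
    n_cell_types: int = 6
    markers_per_type: int = 2
    reference_gene: str = "RPE65"
    planted_candidates: tuple[str, ...] | None = None
    planted_top_genes: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_populations < 1:
            raise ConfigurationError("n_populations must be >= 1")
        lo, hi = self.n_variants_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError(
                f"invalid n_variants_per_gene range {self.n_variants_per_gene}"
            )
        flo, fhi = self.allele_freq_log10_range
        if flo > fhi:
            raise ConfigurationError(
                f"invalid allele_freq_log10_range {self.allele_freq_log10_range}: min > max"
            )
        if 10.0 ** fhi > 0.05:
            raise ConfigurationError(
                "allele frequencies must stay within (0, 0.05]; "
                f"10^{fhi} exceeds 0.05"
            )
        clo, chi = self.cohort_size_range
        if not (1 <= clo <= chi):
            raise ConfigurationError(f"invalid cohort_size_range {self.cohort_size_range}")
        if not 0.0 <= self.excluded_study_fraction < 1.0:
            raise ConfigurationError("excluded_study_fraction must be in [0, 1)")
        if not 0.0 < self.diagnostic_rate < 1.0:
            raise ConfigurationError("diagnostic_rate must be in (0, 1)")
        if not 2 <= self.n_cell_types <= len(CELL_TYPE_VOCAB):
            raise ConfigurationError(
                f"n_cell_types must be in [2, {len(CELL_TYPE_VOCAB)}]"
            )
        genes = set(self.genes())
        # fill defaults derived from the gene list
        if self.planted_candidates is None:
            object.__setattr__(self, "planted_candidates", self._default_candidates())
        if self.planted_top_genes is None:
            object.__setattr__(self, "planted_top_genes", self._default_top_genes())
        for name, planted in (
            ("planted_candidates", self.planted_candidates),
            ("planted_top_genes", self.planted_top_genes),
        ):
            missing = [g for g in planted if g not in genes]
            if missing:
                raise ConfigurationError(f"{name} not in gene set: {missing}")
        if self.reference_gene in self.planted_candidates:
            raise ConfigurationError("reference gene cannot be a planted candidate")

    def genes(self) -> list[str]:
        """Gene universe: the reference gene followed by numbered symbols."""
        return [self.reference_gene] + [f"IRD{i:03d}" for i in range(1, self.n_genes)]

    def _default_top_genes(self) -> tuple[str, ...]:
        return tuple(self.genes()[1:11])

    def _default_candidates(self) -> tuple[str, ...]:
        return tuple(self.genes()[11:17])

    def cell_types(self) -> list[str]:
        return list(CELL_TYPE_VOCAB[: self.n_cell_types])


def gene_roles(config: SimulationConfig) -> dict[str, str]:
    """Deterministic role per gene, shared by the allele and annotation
    generators so planted structure is mutually consistent."""
    roles = {g: ROLE_BACKGROUND for g in config.genes()}
    roles[config.reference_gene] = ROLE_REFERENCE
    for g in config.planted_candidates:
        roles[g] = ROLE_CANDIDATE
    decoy_roles = [ROLE_SIZE_DECOY, ROLE_TIE_DECOY, ROLE_ENZYME_DECOY]
    free = [g for g, r in roles.items() if r == ROLE_BACKGROUND]
    for g, r in zip(free, decoy_roles):
        roles[g] = r
    return roles


def _role_log10_subrange(role: str, lo: float, hi: float) -> tuple[float, float]:
    """Role-specific sub-interval of the log10 frequency range.

    High-burden roles draw from the top of the range, the reference from the
    middle, background from the bottom, keeping per-population pooled
    frequencies strictly ordered candidate > reference > background.  With a
    degenerate range (lo == hi) every sub-interval collapses to the point.
    """
    w = hi - lo
    if role in (ROLE_CANDIDATE, ROLE_SIZE_DECOY, ROLE_ENZYME_DECOY):
        return hi - 0.075 * w, hi
    if role in (ROLE_REFERENCE, ROLE_TIE_DECOY):
        return hi - 0.375 * w, hi - 0.3 * w
    return lo, hi - 0.5 * w


def simulate_allele_matrices(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathogenic allele-frequency matrix and population sizes.

    Returns
    -------
    alleles
        Columns ``gene, population, variant_id, allele_frequency``; at least
        one variant per (gene, population); frequencies log-uniform within
        the configured range; per-(gene, population) pooled frequency < 0.5.
    populations
        Columns ``population, population_size`` (positive integers).
    """
    rng = np.random.default_rng(config.seed + _STREAM_ALLELES)
    lo, hi = config.allele_freq_log10_range
    n_lo, n_hi = config.n_variants_per_gene
    roles = gene_roles(config)
    populations = [f"POP{j:02d}" for j in range(1, config.n_populations + 1)]
    sizes = rng.integers(5_000_000, 1_500_000_000, size=config.n_populations)

    # draw the reference gene first so the tie decoy can replicate its
    # frequencies exactly (equal burden by construction)
    ref_freqs: dict[str, np.ndarray] = {}
    rlo, rhi = _role_log10_subrange(ROLE_REFERENCE, lo, hi)
    for population in populations:
        ref_freqs[population] = 10.0 ** rng.uniform(rlo, rhi, size=n_hi)

    rows = []
    for gene in config.genes():
        role = roles[gene]
        glo, ghi = _role_log10_subrange(role, lo, hi)
        for population in populations:
            if role in (ROLE_REFERENCE, ROLE_TIE_DECOY):
                freqs = ref_freqs[population]
            elif role == ROLE_BACKGROUND:
                n_var = int(rng.integers(n_lo, n_hi + 1))
                freqs = 10.0 ** rng.uniform(glo, ghi, size=n_var)
            else:  # high-burden roles: fixed variant count for a tight bound
                freqs = 10.0 ** rng.uniform(glo, ghi, size=n_hi)
            if freqs.sum() >= 0.5:  # unreachable under the (0, 0.05] precondition
                raise ConfigurationError(
                    f"pooled frequency for {gene}/{population} reached 0.5"
                )
            for k, q in enumerate(freqs, start=1):
                rows.append(
                    {
                        "gene": gene,
                        "population": population,
                        "variant_id": f"{gene}_{population}_v{k}",
                        "allele_frequency": float(q),
                    }
                )
    alleles = pd.DataFrame(
        rows, columns=["gene", "population", "variant_id", "allele_frequency"]
    )
    pops = pd.DataFrame(
        {"population": populations, "population_size": sizes.astype(int)}
    )
    return alleles, pops


def simulate_cohorts(
    config: SimulationConfig, gene_eai: pd.DataFrame
) -> pd.DataFrame:
    """Cohort diagnostic-yield table: one row per (study, diagnosed gene).

    Diagnosed counts are multinomial with per-gene probabilities proportional
    to the supplied burden weights (column ``expected_affected`` or
    ``weight``), except that ``planted_top_genes`` are inflated far above
    every other gene so their pooled yields strictly dominate.  An
    ``undiagnosed`` category absorbs ``1 - diagnostic_rate`` of each cohort,
    so per-study diagnosed totals never exceed the cohort size.

    A configurable fraction of studies violates the downstream inclusion
    criteria (cohort size <= 50, including one exactly at the boundary, or a
    non-NGS platform) to exercise the study filter.
    """
    if gene_eai is None or len(gene_eai) == 0:
        raise ConfigurationError("gene_eai is empty: no gene weights to sample from")
    weight_col = "expected_affected" if "expected_affected" in gene_eai else "weight"
    if weight_col not in gene_eai:
        raise ConfigurationError(
            "gene_eai must have an 'expected_affected' or 'weight' column"
        )
    rng = np.random.default_rng(config.seed + _STREAM_COHORTS)
    weights = (
        gene_eai.set_index("gene")[weight_col].astype(float).clip(lower=1e-12)
    )
    genes = list(weights.index)
    planted = [g for g in config.planted_top_genes if g in weights.index]
    non_planted = weights.drop(index=planted)
    ceiling = float(non_planted.max()) if len(non_planted) else 1.0
    # graded boost: strict pooled dominance plus a rough planted ordering
    for rank_idx, g in enumerate(planted):
        weights.loc[g] = ceiling * (30.0 + 3.0 * (len(planted) - rank_idx))
    probs = np.append(
        config.diagnostic_rate * weights.to_numpy() / weights.sum(),
        1.0 - config.diagnostic_rate,  # undiagnosed remainder
    )

    n_violators = int(round(config.excluded_study_fraction * config.n_studies))
    n_violators = min(n_violators, max(config.n_studies - 1, 0))
    violations = ["boundary_size", "platform", "small_size"]

    rows = []
    clo, chi = config.cohort_size_range
    for s in range(config.n_studies):
        study_id = f"S{s + 1:02d}"
        cohort_size = int(rng.integers(clo, chi + 1))
        platform = str(rng.choice(["NGS_panel", "WES"]))
        if s < n_violators:
            kind = violations[s % len(violations)]
            if kind == "boundary_size":
                cohort_size = 50  # excluded under the strict > 50 rule
            elif kind == "platform":
                platform = "other"
            else:
                cohort_size = int(rng.integers(10, 50))
        counts = rng.multinomial(cohort_size, probs)[:-1]  # drop undiagnosed
        for gene, d in zip(genes, counts):
            if d > 0:  # genes not diagnosed in a study are missing, not zero
                rows.append(
                    {
                        "study_id": study_id,
                        "cohort_size": cohort_size,
                        "platform": platform,
                        "gene": gene,
                        "diagnosed_count": int(d),
                    }
                )
    cohorts = pd.DataFrame(
        rows, columns=["study_id", "cohort_size", "platform", "gene", "diagnosed_count"]
    )
    cohorts["nonuniform_criteria"] = False
    return cohorts


def simulate_gene_annotations(config: SimulationConfig) -> pd.DataFrame:
    """Transcript length, enzyme class and publication count per gene.

    Planted candidates get transcripts within the 4.7 kb AAV cargo limit and
    the enzyme flag; the size decoy sits exactly 1 nt over the limit; the
    enzyme decoy is a high-burden non-enzyme gene.  Publication counts are
    heavy-tailed and drawn independently of burden, mirroring the mismatch
    between research intensity and clinical burden.
    """
    rng = np.random.default_rng(config.seed + _STREAM_ANNOTATIONS)
    roles = gene_roles(config)
    rows = []
    for gene in config.genes():
        role = roles[gene]
        if role == ROLE_SIZE_DECOY:
            length = 4701
            enzyme = True
        elif role in (ROLE_CANDIDATE, ROLE_TIE_DECOY, ROLE_REFERENCE):
            length = int(rng.integers(1200, 4701))
            enzyme = True
        elif role == ROLE_ENZYME_DECOY:
            length = int(rng.integers(1200, 4701))
            enzyme = False
        else:
            length = int(np.clip(rng.lognormal(8.2, 0.8), 300, 200_000))
            enzyme = bool(rng.random() < 0.4)
        publications = int((rng.pareto(1.2) + 1.0) * 8.0)
        rows.append(
            {
                "gene": gene,
                "transcript_length_nt": length,
                "enzyme_flag": enzyme,
                "publication_count": publications,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "transcript_length_nt", "enzyme_flag", "publication_count"]
    )


# negative-binomial mean levels of the count model
_MEAN_BACKGROUND = 0.2
_MEAN_UBIQUITOUS = 3.0
_MEAN_ABUNDANT = 30.0     # first ubiquitous gene, rhodopsin-like
_MEAN_MARKER_ON = 25.0
_MEAN_MARKER_OFF = 0.01
_NB_DISPERSION = 2.0


def simulate_counts(
    config: SimulationConfig,
) -> tuple[sp.csr_matrix, pd.DataFrame, list[str], dict]:
    """Labelled single-cell count matrix with planted markers.

    Counts are negative-binomial.  Each cell type receives
    ``markers_per_type`` marker genes (high mean in the type, near-zero
    elsewhere); the planted top genes double as a ubiquitously expressed set
    with one abundantly expressed member.  Genes with all-zero counts are
    dropped from the output.

    Returns ``(matrix, cells, gene_symbols, manifest)`` with ``matrix`` a
    cells x genes sparse integer matrix, ``cells`` a DataFrame of
    ``cell_id, cell_type``, and ``manifest`` recording markers per type, the
    ubiquitous set, and any dropped genes.
    """
    rng = np.random.default_rng(config.seed + _STREAM_COUNTS)
    genes = config.genes()
    types = config.cell_types()
    roles = gene_roles(config)

    # balanced type assignment, then shuffled
    reps = math.ceil(config.n_cells / len(types))
    labels = np.tile(np.array(types, dtype=object), reps)[: config.n_cells]
    labels = labels[rng.permutation(config.n_cells)]

    ubiquitous = [g for g in config.planted_top_genes]
    marker_pool = [
        g
        for g in genes
        if roles[g] == ROLE_BACKGROUND and g not in set(ubiquitous)
    ]
    needed = len(types) * config.markers_per_type
    if len(marker_pool) < needed:
        raise ConfigurationError(
            f"need {needed} marker genes but only {len(marker_pool)} background "
            "genes are available; increase n_genes or lower markers_per_type"
        )
    chosen = rng.choice(len(marker_pool), size=needed, replace=False)
    markers: dict[str, list[str]] = {}
    for i, t in enumerate(types):
        markers[t] = sorted(
            marker_pool[j]
            for j in chosen[i * config.markers_per_type : (i + 1) * config.markers_per_type]
        )
    marker_type = {g: t for t, gs in markers.items() for g in gs}

    mean = np.full((config.n_cells, len(genes)), _MEAN_BACKGROUND)
    for j, gene in enumerate(genes):
        if gene in marker_type:
            own = labels == marker_type[gene]
            mean[:, j] = np.where(own, _MEAN_MARKER_ON, _MEAN_MARKER_OFF)
        elif gene in ubiquitous:
            mean[:, j] = _MEAN_ABUNDANT if gene == ubiquitous[0] else _MEAN_UBIQUITOUS
    r = _NB_DISPERSION
    counts = rng.negative_binomial(r, r / (r + mean))

    keep = counts.sum(axis=0) > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    counts = counts[:, keep]
    kept_genes = [g for g, k in zip(genes, keep) if k]

    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(config.n_cells)],
            "cell_type": labels.astype(str),
        }
    )
    manifest = {
        "cell_types": types,
        "markers": markers,
        "ubiquitous": ubiquitous,
        "abundant": ubiquitous[0] if ubiquitous else None,
        "dropped_all_zero": dropped,
    }
    return sp.csr_matrix(counts.astype(np.int64)), cells, kept_genes, manifest


def simulate_all(config: SimulationConfig) -> dict:
    """Run all four generators; cohort weights come from the simulated
    alleles via the prevalence model (burden-proportional diagnostic yields).
    """
    alleles, populations = simulate_allele_matrices(config)
    prevalence = compute_prevalence(alleles, populations)
    gene_eai = (
        prevalence[prevalence["population"] == "GLOBAL"][["gene", "expected_affected"]]
        .reset_index(drop=True)
    )
    cohorts = simulate_cohorts(config, gene_eai)
    annotations = simulate_gene_annotations(config)
    matrix, cells, gene_symbols, manifest = simulate_counts(config)
    return {
        "alleles": alleles,
        "populations": populations,
        "cohorts": cohorts,
        "annotations": annotations,
        "counts": matrix,
        "cells": cells,
        "count_genes": gene_symbols,
        "manifest": manifest,
    }
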