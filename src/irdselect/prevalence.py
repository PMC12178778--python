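"""Autosomal-recessive disease burden from pathogenic allele frequencies.

For a gene with pathogenic allele frequencies ``q_1 .. q_k`` in a panmictic
population, write ``Q = sum_i q_i`` for the pooled pathogenic allele
frequency.  Under Hardy-Weinberg random mating,

* genetic prevalence (GP) — the probability of being affected, i.e. of
  carrying two pathogenic alleles (homozygous or compound heterozygous):
  ``GP = sum_i q_i^2 + sum_{i<j} 2 q_i q_j = Q^2``;
* carrier frequency (CF) — the probability of being heterozygous for at
  least one pathogenic allele: ``CF = 2 Q (1 - Q)``;
* expected affected individuals (EAI) — ``GP`` scaled by census population
  size and summed over ancestry strata: ``EAI = sum_p GP_p * N_p``.

Both the closed form of GP and an explicit enumeration over genotype
combinations are exposed; the enumeration exists as an independent check and
is quadratic in the number of variants, so it is only meant for small sets.

Variants are treated as independent sites within the gene: no linkage or
in-cis correction is applied, and each population is modelled as panmictic
with no cross-population mating.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DomainError, MissingPopulationError

GLOBAL = "GLOBAL"

CfMode = Literal["exact", "approx"]


def _as_valid_freqs(frequencies: Iterable[float]) -> np.ndarray:
    q = np.asarray(list(frequencies), dtype=float)
    if q.size == 0:
        return q
    if not np.all(np.isfinite(q)):
        raise DomainError("allele frequencies must be finite")
    if np.any(q < 0):
        raise DomainError(f"negative allele frequency: min={q.min()}")
    if np.any(q > 1):
        raise DomainError(f"allele frequency above 1: max={q.max()}")
    total = math.fsum(q)  # exactly-rounded sum: zero entries are true no-ops
    if total > 1.0:
        raise DomainError(
            f"summed pathogenic allele frequency Q={total:.6g} exceeds 1"
        )
    return q


def total_frequency(frequencies: Iterable[float]) -> float:
    """Pooled pathogenic allele frequency Q = sum of per-variant frequencies."""
    return math.fsum(_as_valid_freqs(frequencies))


def genetic_prevalence(frequencies: Iterable[float]) -> float:
    """Closed-form genetic prevalence GP = Q**2.

    Equals the sum over all homozygous and compound-heterozygous genotype
    combinations (see :func:`genetic_prevalence_enumerated`).
    """
    return total_frequency(frequencies) ** 2


def genetic_prevalence_enumerated(frequencies: Iterable[float]) -> float:
    """GP by explicit enumeration of biallelic pathogenic genotypes.

    Sums q_i**2 over homozygotes and 2*q_i*q_j over every unordered
    compound-heterozygous pair i < j.  Quadratic in the number of variants;
    intended as an independent cross-check of :func:`genetic_prevalence`.
    """
    q = _as_valid_freqs(frequencies)
    gp = 0.0
    for i in range(q.size):
        gp += q[i] * q[i]
        for j in range(i + 1, q.size):
            gp += 2.0 * q[i] * q[j]
    return gp


def carrier_frequency(frequencies: Iterable[float], mode: CfMode = "exact") -> float:
    """Carrier frequency of the pooled pathogenic allele class.

    ``mode="exact"`` returns the Hardy-Weinberg heterozygote frequency
    ``2 Q (1 - Q)``; ``mode="approx"`` returns the rare-allele approximation
    ``2 Q`` sometimes used in published burden estimates.  The two agree to
    first order for small Q.
    """
    Q = total_frequency(frequencies)
    if mode == "exact":
        return 2.0 * Q * (1.0 - Q)
    if mode == "approx":
        return 2.0 * Q
    raise DomainError(f"unknown carrier-frequency mode {mode!r}")


def two_carrier_transmission(frequencies: Iterable[float], mode: CfMode = "exact") -> float:
    """Probability that a random couple are both carriers and transmit
    two pathogenic alleles to a child: CF**2 / 4.

    A cross-check quantity: with CF = 2Q(1-Q) it equals GP * (1-Q)**2
    identically, so its ratio to GP tends to 1 as Q -> 0.
    """
    cf = carrier_frequency(frequencies, mode=mode)
    return cf * cf / 4.0


def gene_population_estimates(
    alleles: pd.DataFrame, cf_mode: CfMode = "exact"
) -> pd.DataFrame:
    """Per-(gene, population) CF and GP from a long allele-frequency table.

    Parameters
    ----------
    alleles
        Columns ``gene``, ``population``, ``allele_frequency`` (one row per
        pathogenic variant).  A (gene, population) pair absent from the table
        contributes nothing; an empty frequency list would mean CF = GP = 0.
    """
    rows = []
    for (gene, population), grp in alleles.groupby(["gene", "population"], sort=True):
        q = grp["allele_frequency"].to_numpy()
        try:
            cf = carrier_frequency(q, mode=cf_mode)
            gp = genetic_prevalence(q)
        except DomainError as exc:
            raise DomainError(f"gene {gene!r}, population {population!r}: {exc}") from exc
        rows.append(
            {
                "gene": gene,
                "population": population,
                "carrier_frequency": cf,
                "genetic_prevalence": gp,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "population", "carrier_frequency", "genetic_prevalence"]
    )


def _demographics_series(demographics: pd.DataFrame) -> pd.Series:
    if demographics["population"].duplicated().any():
        dupes = demographics.loc[
            demographics["population"].duplicated(), "population"
        ].tolist()
        raise DomainError(f"duplicate population labels in demographics: {dupes}")
    sizes = demographics.set_index("population")["population_size"]
    if (sizes < 0).any():
        raise DomainError("population sizes must be non-negative")
    return sizes.astype(float)


def expected_affected(
    gp_by_population: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Scale per-population CF/GP by census sizes and add per-gene GLOBAL rows.

    ``expected_affected = GP_p * N_p`` and ``expected_carriers = CF_p * N_p``
    per population; the GLOBAL row carries the sums across populations and the
    population-size-weighted mean CF and GP (so GLOBAL GP * total N equals the
    summed EAI).

    Raises
    ------
    MissingPopulationError
        If a population in ``gp_by_population`` has no demographics row.
    """
    sizes = _demographics_series(demographics)
    for population in gp_by_population["population"].unique():
        if population not in sizes.index:
            raise MissingPopulationError(str(population))

    est = gp_by_population.copy()
    n_p = est["population"].map(sizes)
    est["expected_carriers"] = est["carrier_frequency"] * n_p
    est["expected_affected"] = est["genetic_prevalence"] * n_p

    total_n = float(sizes.loc[est["population"].unique()].sum()) if len(est) else 0.0
    global_rows = []
    for gene, grp in est.groupby("gene", sort=True):
        carriers = float(grp["expected_carriers"].sum())
        affected = float(grp["expected_affected"].sum())
        global_rows.append(
            {
                "gene": gene,
                "population": GLOBAL,
                "carrier_frequency": carriers / total_n if total_n > 0 else 0.0,
                "genetic_prevalence": affected / total_n if total_n > 0 else 0.0,
                "expected_carriers": carriers,
                "expected_affected": affected,
            }
        )
    out = pd.concat([est, pd.DataFrame(global_rows, columns=est.columns)], ignore_index=True)
    return out.sort_values(["gene", "population"], ignore_index=True)


def compute_prevalence(
    alleles: pd.DataFrame, demographics: pd.DataFrame, cf_mode: CfMode = "exact"
) -> pd.DataFrame:
    """Full prevalence table (per-population and GLOBAL rows) from raw inputs."""
    per_pop = gene_population_estimates(alleles, cf_mode=cf_mode)
    return expected_affected(per_pop, demographics)


def aggregate_carriers(
    estimates: pd.DataFrame,
    demographics: pd.DataFrame,
    mode: Literal["union", "sum"] = "union",
) -> float:
    """Total carrier count across genes and populations.

    ``mode="union"`` counts each individual once — the expected number of
    people heterozygous for at least one gene, assuming independence across
    genes within a population: ``sum_p N_p * (1 - prod_g (1 - CF_gp))``.
    ``mode="sum"`` adds per-gene carrier counts, double-counting multi-gene
    carriers: ``sum_g sum_p N_p * CF_gp``.  Union is never larger than sum.
    """
    sizes = _demographics_series(demographics)
    per_pop = estimates[estimates["population"] != GLOBAL]
    for population in per_pop["population"].unique():
        if population not in sizes.index:
            raise MissingPopulationError(str(population))
    if mode == "sum":
        n_p = per_pop["population"].map(sizes)
        return float((per_pop["carrier_frequency"] * n_p).sum())
    if mode == "union":
        total = 0.0
        for population, grp in per_pop.groupby("population"):
            non_carrier = float(np.prod(1.0 - grp["carrier_frequency"].to_numpy()))
            total += float(sizes[population]) * (1.0 - non_carrier)
        return total
    raise DomainError(f"unknown aggregation mode {mode!r}")
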