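"""Schema-checked TSV reading/writing shared by all pipeline stages.

All tables are tab-separated with a header row; floats are written with 12
significant digits so artifacts are byte-reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from .errors import SchemaError

FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class TableSchema:
    """Required columns (name -> pandas dtype string) plus row validators.

    ``optional`` columns are coerced when present but neither required nor
    warned about.
    """

    name: str
    columns: dict[str, str]
    validators: tuple[tuple[str, Callable[[pd.Series], pd.Series]], ...] = field(
        default_factory=tuple
    )
    optional: dict[str, str] = field(default_factory=dict)


def _positive(s: pd.Series) -> pd.Series:
    return s > 0


def _non_negative(s: pd.Series) -> pd.Series:
    return s >= 0


def _unit_interval(s: pd.Series) -> pd.Series:
    return (s >= 0) & (s <= 1)


def _open_unit_interval(s: pd.Series) -> pd.Series:
    return (s > 0) & (s < 1)


ALLELES = TableSchema(
    "alleles",
    {"gene": "str", "population": "str", "variant_id": "str", "allele_frequency": "float"},
    (("allele_frequency in (0,1)", lambda df: _open_unit_interval(df["allele_frequency"])),),
)
POPULATIONS = TableSchema(
    "populations",
    {"population": "str", "population_size": "int"},
    (("population_size >= 0", lambda df: _non_negative(df["population_size"])),),
)
COHORTS = TableSchema(
    "cohorts",
    {
        "study_id": "str",
        "cohort_size": "int",
        "platform": "str",
        "gene": "str",
        "diagnosed_count": "int",
    },
    (
        ("cohort_size > 0", lambda df: _positive(df["cohort_size"])),
        ("diagnosed_count >= 0", lambda df: _non_negative(df["diagnosed_count"])),
    ),
    optional={"nonuniform_criteria": "bool"},
)
ANNOTATIONS = TableSchema(
    "annotations",
    {
        "gene": "str",
        "transcript_length_nt": "int",
        "enzyme_flag": "bool",
        "publication_count": "int",
    },
    (
        ("transcript_length_nt > 0", lambda df: _positive(df["transcript_length_nt"])),
        ("publication_count >= 0", lambda df: _non_negative(df["publication_count"])),
    ),
)
PREVALENCE = TableSchema(
    "prevalence",
    {
        "gene": "str",
        "population": "str",
        "carrier_frequency": "float",
        "genetic_prevalence": "float",
        "expected_carriers": "float",
        "expected_affected": "float",
    },
    (
        ("carrier_frequency in [0,1]", lambda df: _unit_interval(df["carrier_frequency"])),
        ("genetic_prevalence in [0,1]", lambda df: _unit_interval(df["genetic_prevalence"])),
    ),
)
RANKING = TableSchema(
    "ranking",
    {
        "gene": "str",
        "pooled_yield": "float",
        "weight_sum": "float",
        "n_studies": "int",
        "rank": "int",
    },
    (("pooled_yield in [0,1]", lambda df: _unit_interval(df["pooled_yield"])),),
)
SENSITIVITY = TableSchema(
    "sensitivity",
    {"threshold": "int", "spearman": "float", "top_k_overlap": "float"},
)
DOTSTATS = TableSchema(
    "dotstats",
    {
        "gene": "str",
        "cell_type": "str",
        "fraction_expressing": "float",
        "mean_expression": "float",
    },
    (
        ("fraction_expressing in [0,1]", lambda df: _unit_interval(df["fraction_expressing"])),
        ("mean_expression >= 0", lambda df: _non_negative(df["mean_expression"])),
    ),
)
SPECIFICITY = TableSchema(
    "specificity",
    {"gene": "str", "specificity_tau": "float"},
    (("tau in [0,1]", lambda df: _unit_interval(df["specificity_tau"])),),
)
CELLS = TableSchema("cells", {"cell_id": "str", "cell_type": "str"})
FEATURES = TableSchema("features", {"gene": "str"})


def read_table(path: str | Path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a TSV and validate it against a schema.

    Missing required columns raise :class:`SchemaError` naming them; unknown
    extra columns are preserved with a warning; row validators flag offending
    values with the validator's description.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if schema is None:
        return df
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name} table {path.name}: missing required column(s) {missing}"
        )
    extra = [
        c for c in df.columns if c not in schema.columns and c not in schema.optional
    ]
    if extra:
        warnings.warn(
            f"{schema.name} table {path.name}: unknown column(s) {extra} preserved"
        )
    typed = dict(schema.columns)
    typed.update({c: t for c, t in schema.optional.items() if c in df.columns})
    for col, dtype in typed.items():
        try:
            if dtype == "bool" and df[col].dtype == object:
                df[col] = df[col].map(
                    {"True": True, "False": False, True: True, False: False}
                )
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{schema.name} table {path.name}: column {col!r} is not {dtype}: {exc}"
            ) from exc
    for desc, validator in schema.validators:
        ok = validator(df)
        if not bool(ok.all()):
            raise SchemaError(
                f"{schema.name} table {path.name}: {int((~ok).sum())} row(s) violate {desc}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> Path:
    """Write a TSV with deterministic column order and fixed float format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema is not None:
        missing = [c for c in schema.columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{schema.name}: cannot write without column(s) {missing}")
        ordered = list(schema.columns) + [c for c in df.columns if c not in schema.columns]
        df = df[ordered]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path
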