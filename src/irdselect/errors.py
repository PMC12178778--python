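"""Exception hierarchy shared across the pipeline stages."""


class IrdSelectError(Exception):
    """Base class for all errors raised by irdselect."""


class ConfigurationError(IrdSelectError, ValueError):
    """A configuration object or parameter combination is invalid."""


class DomainError(IrdSelectError, ValueError):
    """An input value falls outside the mathematical domain of an operation
    (e.g. negative allele frequencies, summed frequency above 1)."""


class DataIntegrityError(IrdSelectError, ValueError):
    """A table violates an internal consistency constraint
    (e.g. diagnosed counts exceeding the cohort size)."""


class SchemaError(IrdSelectError, ValueError):
    """A table is missing required columns or contains ill-typed values."""


class MissingPopulationError(IrdSelectError, KeyError):
    """A population referenced by an estimate has no demographics row."""

    def __init__(self, population: str):
        super().__init__(population)
        self.population = population

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return f"no demographics row for population {self.population!r}"
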