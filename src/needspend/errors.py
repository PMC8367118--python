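"""Exception hierarchy for the needspend pipeline."""


class NeedSpendError(Exception):
    """Base class for all pipeline errors."""


class MissingDataError(NeedSpendError):
    """Required input rows, years or snapshots are absent."""


class SchemaError(NeedSpendError):
    """A structured input (coefficient table, config, modifier file) violates
    its schema.  The message carries the path of the first violation."""


class DomainError(NeedSpendError):
    """A value is outside the mathematically admissible domain of an
    operation (zero totals, negative rates, inconsistent cohorts...)."""
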