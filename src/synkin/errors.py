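"""Exception hierarchy for the synkin pipeline."""


class SynkinError(Exception):
    """Base class for all synkin errors."""


class SchemaError(SynkinError):
    """A table or matrix does not conform to the 17-joint schema."""


class StructureError(SynkinError):
    """Labels or segment structure are inconsistent (e.g. a repetition
    block is split or overlaps another)."""


class ParameterError(SynkinError):
    """An argument is outside its valid domain."""


class DataError(SynkinError):
    """Numeric input is unusable (non-finite values, zero variance...)."""


class DegenerateRetentionError(DataError):
    """No principal component passed the eigenvalue > 1 retention rule."""
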