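"""Exception hierarchy for mosatwin.

All readers/validators raise subclasses of :class:`MosatwinError` so the CLI
can map them onto its exit codes (validation errors -> 2, stage failures -> 3).
"""


class MosatwinError(Exception):
    """Base class for all package errors."""


class ParseError(MosatwinError):
    """Malformed on-disk input; message names the offending line where known."""


class ValidationError(MosatwinError):
    """Semantically invalid values (bad coordinates, rates, thresholds...)."""


class ConfigError(MosatwinError):
    """Inconsistent configuration: unknown samples, mismatched designs, ..."""


class UnsupportedRecordError(ParseError):
    """A record outside the supported subset (e.g. multi-allelic VCF rows)."""


class SizingError(ValidationError):
    """A simulation request that cannot fit in the configured genome."""


class AuditError(MosatwinError):
    """A cross-check required by an audit step is impossible (missing data)."""


class ComparabilityError(MosatwinError):
    """Scores compared against a distribution built from a different locus set."""
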