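"""Exception hierarchy shared across the toolkit."""


class MitorearrError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MitorearrError):
    """Malformed input file (missing column, bad token, unparsable line)."""


class ValidationError(MitorearrError):
    """Structurally invalid annotation or feature (coordinates, codons)."""


class UndefinedSkewError(MitorearrError):
    """Skew requested for a composition whose denominator is zero."""


class RegionLookupError(MitorearrError):
    """Requested feature name or class not present in the annotation."""


class ComparisonError(MitorearrError):
    """Gene orders share no labels, or are otherwise incomparable."""


class ConfigError(MitorearrError):
    """Inconsistent synthesis configuration."""
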