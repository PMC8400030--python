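"""Exception hierarchy shared across the pipeline."""


class HaloNitroError(Exception):
    """Base class for all package errors."""


class ConfigError(HaloNitroError, ValueError):
    """Invalid configuration or parameter value."""


class ParseError(HaloNitroError, ValueError):
    """Malformed input file; readers reject rather than repair."""


class FormatError(ParseError):
    """A table or alignment violates its structural contract."""


class AmbiguityError(HaloNitroError):
    """A single protein matched mutually exclusive marker families."""


class ContextError(HaloNitroError):
    """Genetic-context verification could not be carried out (distinct
    from a negative verification result)."""


class ConsistencyError(HaloNitroError):
    """Cross-file inconsistency, e.g. a species present in the taxonomy
    that claims a genome but supplies no proteome."""


class DegeneratePairError(HaloNitroError):
    """A sequence pair shares no comparable alignment columns."""
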