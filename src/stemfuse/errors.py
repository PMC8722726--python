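"""Exception hierarchy shared across the package."""


class StemfuseError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(StemfuseError):
    """Malformed FASTA input; message names the offending line."""


class AnnotationError(StemfuseError):
    """Invalid or inconsistent gene annotation."""


class RangeError(StemfuseError):
    """Coordinate outside the bounds of its sequence."""


class DesignError(StemfuseError):
    """Chimeric-RNA design constraint violated."""


class CassetteError(StemfuseError):
    """Expression-cassette constraint violated."""


class FusionError(StemfuseError):
    """Invalid fusion event for the modeled class (e.g. exonic breakpoint)."""


class SpecError(StemfuseError):
    """Invalid synthetic-data specification."""


class ConfigError(StemfuseError):
    """Invalid pipeline configuration."""
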