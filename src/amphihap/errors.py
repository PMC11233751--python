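"""Exception hierarchy shared by all pipeline stages."""


class AmphihapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AmphihapError):
    """A file does not conform to its declared format (FASTA/FASTQ/GFF3/TSV)."""


class AlignmentError(AmphihapError):
    """An aligned-FASTA invariant is violated (e.g. ragged rows)."""


class SpecError(AmphihapError):
    """A simulation specification is internally inconsistent or infeasible."""


class AmbiguityError(AmphihapError):
    """A query matches more than one target where exactly one is required."""


class PairingError(AmphihapError):
    """Two genomes share no homologous regions that can be paired by name."""


class InputError(AmphihapError):
    """A record carries a field value outside its controlled vocabulary."""


class ConfigError(AmphihapError):
    """The configuration document is not a flat key/value mapping."""
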