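"""Exception hierarchy shared across the package."""


class HybridPanelError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HybridPanelError):
    """Input violates a documented contract (dimensions, alleles, labels...)."""


class GenotypeParseError(HybridPanelError):
    """A genotype/annotation file could not be parsed under the named dialect."""


class CalibrationError(HybridPanelError):
    """The synthetic frequency generator could not satisfy its constraints."""


class EmptyPanelError(HybridPanelError):
    """A filtering step removed every locus."""


class SelectionError(HybridPanelError):
    """Panel selection was asked for more loci than are available."""
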