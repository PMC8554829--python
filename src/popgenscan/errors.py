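"""Exception types shared across the package."""


class PopgenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PopgenError):
    """An invalid configuration value; the message names the offending field."""


class VcfParseError(PopgenError):
    """A malformed VCF record; the message carries the 1-based line number."""


class AnnotationError(PopgenError):
    """A site is missing a required quality or annotation field."""


class RegionError(PopgenError):
    """An empty or out-of-bounds genomic region."""


class SampleLookupError(PopgenError):
    """A sample id is absent from the table or population map."""


class GridMismatchError(PopgenError):
    """Two window grids that must align do not."""


class WindowError(PopgenError):
    """A window request that cannot be satisfied (e.g. more SNPs than exist)."""
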