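"""Exception hierarchy shared across the pipeline."""


class TopomapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TopomapError, ValueError):
    """Invalid configuration value, file format, or parameter combination."""


class NoNucleusError(TopomapError, RuntimeError):
    """The DAPI channel contains no segmentable nucleus."""


class DegenerateFitError(TopomapError, RuntimeError):
    """Intensity data cannot support the requested number of mixture components."""


class EmptyMaskError(TopomapError, ValueError):
    """An operation that requires in-mask voxels received an empty mask."""


class EmptyProfileError(TopomapError, ValueError):
    """A class profile was requested for an empty voxel/spot collection."""


class PhantomError(TopomapError, RuntimeError):
    """The phantom generator cannot satisfy the requested configuration."""
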