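"""Exception hierarchy shared across the package."""


class DXBError(Exception):
    """Base class for all dxblink errors."""


class ReflectionInaccessibleError(DXBError):
    """The requested reflection cannot be excited at this wavelength (lambda >= 2d)."""


class GeometryError(DXBError):
    """Invalid detector/ring geometry."""


class EmptyMaskError(GeometryError):
    """The Bragg-ring arc does not intersect the active detector area."""


class ConfigError(DXBError):
    """Invalid or inconsistent configuration."""


class FormatError(DXBError):
    """A file does not satisfy the expected on-disk contract."""


class UndefinedACFError(DXBError):
    """The autocorrelation is undefined (identically-zero trajectory)."""


class EmptySelectionError(DXBError):
    """No curve survived the k > 0, A > 0, T > 0 selection."""


class PipelineError(DXBError):
    """A pipeline stage failed; the message carries the stage label."""
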