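"""Exception hierarchy shared across the package."""


class GridscapeError(Exception):
    """Base class for all package errors."""


class ValidationError(GridscapeError, ValueError):
    """An input violates a documented contract (negative count, bad code, ...)."""


class AlignmentError(GridscapeError, ValueError):
    """Rasters do not share shape, cell size, and origin."""


class GridFormatError(GridscapeError, ValueError):
    """A file on disk is not in the expected raster format."""


class ConfigError(GridscapeError, ValueError):
    """A scenario or run configuration is degenerate or inconsistent."""


class FitError(GridscapeError, RuntimeError):
    """A statistical fit cannot be performed (e.g. all-zero design matrix)."""
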