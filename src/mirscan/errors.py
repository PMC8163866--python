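"""Exception hierarchy shared across the package."""


class MirscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirscanError):
    """Invalid or inconsistent configuration (geometry, parameters, config keys)."""


class DataError(MirscanError):
    """Invalid measurement data (shape mismatch, nonpositive background, degeneracy)."""


class GeometryError(MirscanError):
    """Physical-extent mismatch between phantom, scan field or resampling grids."""


class RangeError(MirscanError):
    """Quantity outside its physically meaningful range."""


class AlignmentError(MirscanError):
    """Image alignment failed or produced an implausible shift."""


class FormatError(MirscanError):
    """On-disk file does not match its declared format."""


class LookupError_(MirscanError):
    """Requested cluster / channel does not exist or was rejected."""
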