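"""Exception hierarchy shared by all pipeline stages."""


class CrossAtlasError(Exception):
    """Base class for all package errors."""


class FormatError(CrossAtlasError):
    """A file on disk violates its declared format (MTX header, id files...)."""


class SchemaError(CrossAtlasError):
    """A table is missing required columns or has malformed keys."""


class SpecError(CrossAtlasError):
    """A simulation spec is internally inconsistent."""


class ConfigError(CrossAtlasError):
    """An unknown stage/platform/scope or invalid parameter combination."""


class InputError(CrossAtlasError):
    """Runtime inputs violate a stage precondition (unlabeled cells, empty scope...)."""


class DetectionError(CrossAtlasError):
    """Density-ridge detection found no usable ridge or an ambiguous anchor."""
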