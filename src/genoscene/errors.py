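"""Exception hierarchy shared by all genoscene modules."""


class GenosceneError(Exception):
    """Base class for all genoscene errors."""


class UnknownNameError(GenosceneError):
    """A reference-sequence name is neither canonical nor a known alias."""


class RegionError(GenosceneError):
    """A region is malformed or falls outside its sequence."""


class FormatError(GenosceneError):
    """A file does not conform to its declared format."""


class TagError(GenosceneError):
    """A SAM auxiliary tag (MM/ML/SA/...) is malformed."""


class PolicyError(GenosceneError):
    """An unknown read filter/sort/color policy was requested."""


class FilterExpressionError(GenosceneError):
    """A table filter expression cannot be parsed or names an unknown column."""


class ConfigError(GenosceneError):
    """A config or session document violates the schema."""


class LocstringError(GenosceneError):
    """A location string cannot be interpreted against the assembly."""


class RenderError(GenosceneError):
    """A scene cannot be constructed from the given inputs."""
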