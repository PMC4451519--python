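"""Exception hierarchy for sbgnfocus."""


class SbgnError(Exception):
    """Base class for all sbgnfocus errors."""


class SbgnParseError(SbgnError):
    """Malformed SBGN-ML input (XML syntax, wrong root, wrong language)."""


class UnsupportedLanguageError(SbgnParseError):
    """Map language is not SBGN Process Description."""


class UnknownClassError(SbgnParseError):
    """A glyph or arc carries a class outside the PD vocabulary."""


class DanglingReferenceError(SbgnParseError):
    """An arc endpoint, compartmentRef or port refers to a nonexistent element."""


class UnknownGlyphError(SbgnError, KeyError):
    """A node-group member id does not exist in the map."""


class ValidationError(SbgnError):
    """A map failed structural validation where a valid map is required."""


class ConfigError(SbgnError, ValueError):
    """An unsatisfiable generator or layout configuration."""


class EmptySelectionError(SbgnError, ValueError):
    """A user operation requires at least one selected node."""
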