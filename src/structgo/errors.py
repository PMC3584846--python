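"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented contract (shapes, hierarchy, ids...)."""


class OboParseError(ValidationError):
    """The OBO file could not be parsed."""


class ParseError(ValueError):
    """A tabular input file contains a malformed cell."""
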