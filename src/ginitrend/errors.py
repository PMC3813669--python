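"""Exception types raised across the package."""


class GinitrendError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GinitrendError, ValueError):
    """A required column is missing from an input table."""


class ParseError(GinitrendError, ValueError):
    """A cell could not be coerced to the required type."""


class CrosswalkError(GinitrendError, ValueError):
    """A boundary crosswalk is incomplete or merges across regions."""


class UndefinedGiniError(GinitrendError, ValueError):
    """The Gini coefficient is undefined (no providers in the group)."""
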