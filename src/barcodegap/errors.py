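"""Exception hierarchy shared across the package."""


class BarcodegapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BarcodegapError, ValueError):
    """A file could not be parsed in the expected format."""


class AlignmentError(BarcodegapError, ValueError):
    """Sequences are not a valid alignment (e.g. ragged lengths)."""


class IdentityError(BarcodegapError, ValueError):
    """Specimen identifiers are duplicated or otherwise invalid."""


class SchemaError(BarcodegapError, ValueError):
    """A required column or method name is missing from a table."""


class InputError(BarcodegapError, ValueError):
    """An operation received arguments violating its preconditions."""


class NoStructureError(BarcodegapError):
    """No prior in the scan produced a barcode gap: no partition structure."""
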