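"""Exception types shared across the package."""


class GlycoshockError(Exception):
    """Base class for all package errors."""


class SpecValidationError(GlycoshockError, ValueError):
    """A generator/analysis specification failed validation.

    Carries the offending field name so callers can report precisely.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid field '{field}': {message}")


class CompositionParseError(GlycoshockError, ValueError):
    """A glycan composition string could not be tokenized."""

    def __init__(self, text: str, offset: int, message: str):
        self.text = text
        self.offset = offset
        super().__init__(f"cannot parse {text!r} at offset {offset}: {message}")


class CatalogMismatchError(GlycoshockError, KeyError):
    """Profile references structure ids absent from the catalog."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"structure ids missing from catalog: {self.missing}")


class MalformedSpectrumError(GlycoshockError, ValueError):
    """An MGF block violated the format contract."""

    def __init__(self, block_index: int, message: str):
        self.block_index = block_index
        super().__init__(f"malformed MGF block {block_index}: {message}")
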