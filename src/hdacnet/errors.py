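"""Exception hierarchy.

All input-related failures derive from :class:`InputError` so the CLI can
map them to a distinct exit code (2) versus internal faults (1).
"""


class HdacnetError(Exception):
    """Base class for package errors."""


class InputError(HdacnetError):
    """Bad user input (malformed file, missing gene, invalid config)."""


class FormatError(InputError):
    """A file could not be parsed in the declared dialect."""


class EmptyInputError(InputError):
    """Parsing succeeded but no usable data rows remain."""


class MissingGeneError(InputError):
    """A required gene symbol is absent from an expression matrix."""
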