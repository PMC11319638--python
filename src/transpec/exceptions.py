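"""Error types shared across the package.

Two failure families are distinguished so callers (and the CLI exit codes)
can tell "your input is malformed" apart from "something broke at run time":

* :class:`ValidationError` — the input violates a documented contract
  (duplicate identifiers, out-of-range RIN, unknown strand, ...).
* :class:`FormatError` — a file does not parse as the format it claims to be
  (bad GCT header, undeclared column count, ...).
"""


class TranspecError(Exception):
    """Base class for all package errors."""


class ValidationError(TranspecError):
    """An input value or combination of inputs violates a documented contract."""


class FormatError(TranspecError):
    """A file is structurally malformed for its declared format."""
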