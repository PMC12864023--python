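"""Exception hierarchy shared across the package.

Validation problems (bad inputs, broken invariants) and format problems
(unparseable files) are kept distinct so the CLI can map them to stable
exit codes (2 and 2) while backend failures map to 3.
"""


class StigmaScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(StigmaScreenError):
    """An input violates a documented contract or invariant."""


class FormatError(ValidationError):
    """A file could not be parsed into the expected record structure."""


class BackendError(StigmaScreenError):
    """A language-model backend failed to produce a response."""
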