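"""Exception hierarchy for popprs."""


class PopprsError(Exception):
    """Base class for all popprs errors."""


class FormatError(PopprsError, ValueError):
    """A file or table does not conform to the expected layout."""


class ValidationError(PopprsError, ValueError):
    """Input data violate a domain invariant (bounds, uniqueness, coverage)."""
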