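"""Exception hierarchy shared across the package."""


class GofuncError(Exception):
    """Base class for all package errors."""


class ParseError(GofuncError):
    """A file could not be parsed (malformed stanza, wrong column count)."""


class ValidationError(GofuncError):
    """Input violated a documented contract (cycle, unknown code, bad residue)."""


class LookupError_(GofuncError):
    """An identifier was not found where the contract requires it."""


class CalibrationError(GofuncError):
    """Threshold relaxation could not proceed (an empty helper class)."""


class FitError(GofuncError):
    """A classifier could not be trained (e.g. a single-class training set)."""
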