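"""Exception hierarchy shared by all silacsig modules."""


class SilacSigError(Exception):
    """Base class for all errors raised by silacsig."""


class ConfigurationError(SilacSigError):
    """A configuration value is out of its valid range or inconsistent."""


class FormatError(SilacSigError):
    """An input table does not conform to the expected dialect."""


class ValidationError(SilacSigError):
    """A record or row violates a domain invariant."""


class InsufficientDataError(SilacSigError):
    """Too few quantified observations to perform the requested computation."""


class ContractViolationError(SilacSigError):
    """A function received input outside its documented contract."""
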