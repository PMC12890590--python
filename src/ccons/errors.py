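"""Exception hierarchy shared by all ccons modules."""


class CconsError(Exception):
    """Base class for all ccons errors."""


class ParseError(CconsError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CconsError):
    """Input data violates an invariant (negative counts, duplicate ids, ...)."""


class ConfigError(CconsError):
    """A parameter is outside its admissible range."""
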