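"""Exception hierarchy shared by all dcmpanel modules."""


class DCMPanelError(Exception):
    """Base class for all errors raised by dcmpanel."""


class FormatError(DCMPanelError):
    """A file violates the expected on-disk format (carries file coordinates)."""


class InputError(DCMPanelError):
    """In-memory inputs violate a precondition (shapes, labels, identifiers)."""


class ParameterError(DCMPanelError):
    """A tuning parameter is outside its legal range or names an unknown option."""
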