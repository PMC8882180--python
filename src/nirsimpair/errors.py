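"""Exception hierarchy shared across the package."""


class NirsimpairError(Exception):
    """Base class for all package errors."""


class ValidationError(NirsimpairError):
    """A domain object violates one of its invariants."""


class FormatError(NirsimpairError):
    """An on-disk artifact is malformed or inconsistent with its layout."""


class ConfigurationError(NirsimpairError):
    """A parameter set is unusable (e.g. singular extinction matrix)."""


class LeakageError(NirsimpairError):
    """Training and evaluation sets share participants."""
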