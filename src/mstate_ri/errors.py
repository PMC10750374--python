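"""Exception hierarchy shared across the package."""


class MstateError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MstateError, ValueError):
    """A parameter violates an operation precondition."""


class DimensionError(MstateError, ValueError):
    """Array shapes or channel counts do not line up."""


class FormatError(MstateError, ValueError):
    """A file exists but cannot be interpreted."""


class ManifestError(MstateError, ValueError):
    """Study manifest is inconsistent (duplicates, missing conditions...)."""


class EmptyResultError(MstateError, ValueError):
    """An operation produced no usable output (e.g. no epochs, no peaks)."""


class UndefinedStatisticError(MstateError, ValueError):
    """Statistic undefined on this input (zero variance, zero margin...)."""
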