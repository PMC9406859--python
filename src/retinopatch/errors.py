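"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: configuration/parameter problems -> 2,
data/contract problems -> 3, numerical failures -> 4.
"""


class RetinopatchError(Exception):
    """Base class for all package errors."""


class ParameterError(RetinopatchError, ValueError):
    """A caller-supplied parameter violates its documented constraints."""


class ConfigError(ParameterError):
    """A run configuration is malformed or inconsistent."""


class InputError(RetinopatchError, ValueError):
    """An input file or dataset cannot be read or is malformed."""


class ContractError(RetinopatchError, ValueError):
    """An inter-stage contract is violated (wrong shape, wrong dtype, ...)."""


class BackendUnavailableError(RetinopatchError, RuntimeError):
    """An embedding backend's runtime dependencies are not installed."""


class NumericalError(RetinopatchError, RuntimeError):
    """A numerical routine produced non-finite values or diverged."""
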