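"""Exception hierarchy shared across the package.

Three error families map onto the distinct CLI exit codes: malformed or
inconsistent *input data* (files, labels, ids), invalid *parameters*
(k, a, grid values), and internal *validation* failures (e.g. a partition
that does not cover the node set).
"""


class KanonError(Exception):
    """Base class for all package errors."""


class InputError(KanonError):
    """Malformed or cross-inconsistent input data (CLI exit code 2)."""


class ParameterError(KanonError):
    """Invalid algorithm parameter such as k or a (CLI exit code 3)."""


class ValidationError(KanonError):
    """An object violates a structural invariant (e.g. partition cover)."""


class PreconditionError(KanonError):
    """An operation was called outside its stated precondition."""
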