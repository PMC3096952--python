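"""Exception hierarchy shared across the package.

Validation problems (bad specs, missing columns, out-of-range values) raise
:class:`ValidationError`; data that is structurally fine but cannot support the
requested computation (no usable events in a test fold, degenerate strata)
raises :class:`UnevaluableDataError`.  The CLI maps these to exit codes 2 and 3.
"""


class CoxSelectError(Exception):
    """Base class for package errors."""


class ValidationError(CoxSelectError, ValueError):
    """An input violates a documented precondition; message names the field."""


class UnevaluableDataError(CoxSelectError, RuntimeError):
    """The data cannot support the requested evaluation (e.g. a test fold
    with no event that has both cases and controls)."""


class EliminationError(CoxSelectError, RuntimeError):
    """Backward elimination could not proceed (all candidate fits failed)."""
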