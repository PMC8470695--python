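"""Exception hierarchy for the toolkit.

The CLI maps :class:`InputError` (and subclasses) to exit code 2 and
:class:`NumericalError` (and subclasses) to exit code 3.
"""


class CRCKineticsError(Exception):
    """Base class for all package errors."""


class InputError(CRCKineticsError, ValueError):
    """Invalid user input: bad parameters, malformed files, schema violations."""


class SchemaError(InputError):
    """A file violates the on-disk schema; message names the offending row/field."""


class NumericalError(CRCKineticsError, RuntimeError):
    """A numerical routine failed (integrator breakdown, singular system, ...)."""


class DegenerateRatesError(NumericalError):
    """Closed-form chain solution requested with (near-)equal rate constants.

    The sum-of-exponentials solution has pairwise rate differences in its
    denominators; use the numerical engine (``method="ode"``) instead.
    """


class NonConvergenceError(NumericalError):
    """No optimizer start converged.  Carries the best partial result, if any."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class HorizonError(NumericalError):
    """A curve feature (half-maximum crossing, peak) was not reached within
    the evaluation horizon."""
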