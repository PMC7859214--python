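"""Package-wide exception types."""


class VertperfError(Exception):
    """Base class for all vertperf errors."""


class InvalidParameterError(VertperfError, ValueError):
    """A physical or acquisition parameter is outside its valid domain."""


class FitError(VertperfError, RuntimeError):
    """A nonlinear fit failed to converge.

    Carries the optimizer result (including the residual history available
    from it) on the ``result`` attribute when one exists.
    """

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


class NoBolusError(VertperfError, RuntimeError):
    """No detectable contrast bolus in a concentration time curve."""
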