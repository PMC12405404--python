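"""Exception hierarchy for glut4queue."""


class Glut4QueueError(Exception):
    """Base class for all package errors."""


class ValidationError(Glut4QueueError, ValueError):
    """A parameter or argument violates an invariant; the message names the field."""


class ConfigurationError(Glut4QueueError, KeyError):
    """A requested insulin level (or similar configuration key) is not defined."""


class InternalConsistencyError(Glut4QueueError, RuntimeError):
    """The simulator was asked to do something its state forbids."""


class AlignmentError(Glut4QueueError, ValueError):
    """Model and data sample-time grids do not line up; lists the missing times."""

    def __init__(self, message, missing_times=()):
        super().__init__(message)
        self.missing_times = tuple(missing_times)


class CoverageError(Glut4QueueError, ValueError):
    """An observation set does not cover every configured experiment."""


class SchemaError(Glut4QueueError, ValueError):
    """An observation table violates the file schema; carries offending row numbers."""

    def __init__(self, message, rows=()):
        super().__init__(message)
        self.rows = tuple(rows)


class DegenerateSampleError(Glut4QueueError, ZeroDivisionError):
    """A normalisation constant is zero (no vesicle ever reached the membrane)."""


class IncompatibleArchitectureError(Glut4QueueError, ValueError):
    """A sequestration target exceeds what the microtubule architecture can hold."""
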