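"""Exception hierarchy for lungrt."""


class LungRTError(Exception):
    """Base class for all lungrt errors."""


class InputError(LungRTError, ValueError):
    """A precondition on user input was violated."""


class ConfigError(LungRTError, ValueError):
    """A configuration file failed validation; the message names the field."""


class SimulationError(LungRTError, RuntimeError):
    """The ODE solver failed.

    Carries ``last_time``, the last time point that integrated cleanly,
    so a caller can diagnose where the trajectory broke down.
    """

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time
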