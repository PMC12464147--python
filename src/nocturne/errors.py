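"""Exceptions shared across the nocturne modules."""


class ConfigurationError(ValueError):
    """A configuration field is missing, inconsistent, or out of range."""


class GenerationError(RuntimeError):
    """A synthetic waveform cannot be realised with the requested parameters."""


class InsufficientValidSignal(RuntimeError):
    """Less than the required amount of artifact-free overnight signal.

    Carries the number of valid hours actually available.
    """

    def __init__(self, valid_hours: float, required_hours: float = 3.0):
        self.valid_hours = float(valid_hours)
        self.required_hours = float(required_hours)
        super().__init__(
            f"only {valid_hours:.2f} h of valid PPG signal "
            f"(> {required_hours:g} h required)"
        )


class RecordUnusable(RuntimeError):
    """Too few plausible ambulatory blood-pressure readings in 24 h."""


class DiaryMissing(ValueError):
    """Bedtime/wake-up diary times are required but absent."""


class EmptyPeriod(ValueError):
    """A blood-pressure period contains no valid readings."""


class DegenerateRegression(ValueError):
    """Regression input with zero predictor variance or too few points."""


class DegenerateInput(ValueError):
    """Statistical input outside the domain of the requested test."""


class DegenerateDesign(ValueError):
    """Rank-deficient regression design matrix."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {self.columns}")
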