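"""Exception hierarchy shared across the package."""


class AsymfoldError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AsymfoldError, ValueError):
    """An input lies outside the physically meaningful domain of an operation."""


class InconsistencyError(AsymfoldError, ValueError):
    """Inputs that are individually valid but mutually contradictory."""


class FitError(AsymfoldError, RuntimeError):
    """A curve fit failed to converge from every starting point."""


class LowAmplitudeError(FitError):
    """The fitted transition amplitude is too small to locate a midpoint."""


class NoTransitionError(FitError):
    """A melting curve shows no resolvable transition above the noise floor."""


class DegenerateCalibrationError(AsymfoldError, ValueError):
    """Reference/calibration inputs that cannot distinguish the states."""


class TrainingError(AsymfoldError, RuntimeError):
    """Ensemble training could not produce enough members under the MAE cutoff."""

    def __init__(self, message: str, member_maes=None):
        super().__init__(message)
        self.member_maes = list(member_maes or [])
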