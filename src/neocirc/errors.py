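"""Exception hierarchy for neocirc."""


class NeocircError(Exception):
    """Base class for all neocirc errors."""


class ConfigurationError(NeocircError):
    """A parameter set was used before calibration, or is inconsistent."""


class CalibrationError(NeocircError):
    """The parameter combination admits no physical baseline fixed point."""


class DomainBoundError(NeocircError, ValueError):
    """A state variable or input violates its physical bounds."""


class OxygenSupplyExhaustedError(NeocircError):
    """Venous saturation would fall below zero; supply cannot meet demand."""


class SteadyStateError(NeocircError):
    """The steady-state solver failed to converge."""


class SimulationError(NeocircError):
    """Time integration failed or hit an unphysical state."""


class GridResolutionError(NeocircError, ValueError):
    """The time grid is too coarse to resolve the response kernel."""


class AmplitudeError(NeocircError, ValueError):
    """Stimulus amplitudes violate positivity of demand or radius."""


class ScenarioLookupError(NeocircError, KeyError):
    """Unknown scenario name."""


class AlignmentError(NeocircError, ValueError):
    """Trajectories are not on identical time grids."""


class TraceDataError(NeocircError, ValueError):
    """Measured traces contain invalid (non-finite, unordered) data."""
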