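"""Exception hierarchy for icmsim."""


class IcmsimError(Exception):
    """Base class for all icmsim errors."""


class InvalidGeometryError(IcmsimError):
    """Coincident or otherwise degenerate cell geometry."""


class StepInstabilityError(IcmsimError):
    """A single integration step moved a cell further than one cell radius."""


class NonProgressError(IcmsimError):
    """The simulation failed to reach the target cell count."""


class DegenerateInputError(IcmsimError):
    """Point cloud unsuitable for a 3D Delaunay triangulation."""


class InfeasibleHypothesisError(IcmsimError):
    """Back-solved initial proportions leave the probability simplex."""

    def __init__(self, message: str, proportions=None, offending_index=None):
        super().__init__(message)
        self.proportions = proportions
        self.offending_index = offending_index


class FitError(IcmsimError):
    """Transition-rate optimisation failed to converge."""

    def __init__(self, message: str, best_rates=None):
        super().__init__(message)
        self.best_rates = best_rates
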