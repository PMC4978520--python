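"""Exception and warning types shared across the package."""


class ConfigurationError(ValueError):
    """A circuit/protocol description references unknown parameters or populations."""


class AblationError(ConfigurationError):
    """An ablation targets an absent population or is applied twice."""


class SimulationDivergenceError(RuntimeError):
    """A state variable became non-finite during integration.

    Carries the first offending neuron and the simulation time at which the
    divergence was detected.
    """

    def __init__(self, population, side, cell, t_ms):
        self.population = population
        self.side = side
        self.cell = cell
        self.t_ms = t_ms
        super().__init__(
            f"non-finite membrane potential in {population}/{side} cell {cell} "
            f"at t = {t_ms:.3f} ms"
        )


class FitError(RuntimeError):
    """A trace-analysis fit failed to converge or received degenerate input."""


class DegenerateDataError(ValueError):
    """A statistical routine received data with no usable information."""


class SuprathresholdWarning(UserWarning):
    """A nominally subthreshold computation produced a value above spike threshold."""


class ExtrapolationWarning(UserWarning):
    """A regression is being evaluated outside the range of its data."""
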