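"""Exception hierarchy shared across the package."""


class HBridgeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HBridgeError, ValueError):
    """Invalid model, settings or run-configuration values."""


class FormatError(HBridgeError, ValueError):
    """Malformed trajectory or descriptor-table input."""


class GeometryError(HBridgeError, ValueError):
    """Degenerate cells or impossible geometric requests."""


class SelectionError(HBridgeError, ValueError):
    """Atom/bridge selections referencing unknown or duplicate atoms."""


class DataError(HBridgeError, ValueError):
    """Well-formed input that cannot support the requested analysis."""


class RangeError(HBridgeError, ValueError):
    """Out-of-range windows, trims or bin specifications."""


class IntegrationFailureError(HBridgeError, RuntimeError):
    """Numerical blow-up during time integration."""

    def __init__(self, step: int, energy: float):
        self.step = step
        self.energy = energy
        super().__init__(
            f"integration diverged at step {step}: |E| = {energy:.3e} kcal/mol"
        )
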