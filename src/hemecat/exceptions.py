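"""Exception and warning types used across the package."""


class HemecatError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HemecatError, ValueError):
    """A sweep or spectrum table could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(HemecatError, ValueError):
    """Required metadata or configuration is missing or inconsistent."""


class PeakDetectionError(HemecatError, RuntimeError):
    """No redox peak could be located above the noise floor."""


class FitConvergenceError(HemecatError, RuntimeError):
    """Nonlinear fit failed to converge after bounded restarts."""

    def __init__(self, message: str, residual_rms: float | None = None):
        self.residual_rms = residual_rms
        super().__init__(message)


class AmbiguousAssignmentError(HemecatError, ValueError):
    """A fitted band center falls inside more than one assignment window."""

    def __init__(self, center: float, candidates: list[str]):
        self.center = center
        self.candidates = candidates
        super().__init__(
            f"component at {center:.1f} cm^-1 matches several assignment windows: "
            + ", ".join(candidates)
        )


class BaselineWarning(UserWarning):
    """Anchor windows look inconsistent with the sweep's tail slope."""


class GridWarning(UserWarning):
    """A synthetic grid is too coarse to resolve the requested feature."""
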