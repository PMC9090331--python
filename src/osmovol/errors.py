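"""Exception types shared across the package."""


class OsmovolError(Exception):
    """Base class for all package-specific failures."""


class ConvergenceError(OsmovolError):
    """A root solve or least-squares fit failed to converge.

    Carries the final residuals so callers can diagnose the failure
    rather than receiving a silent bad answer.
    """

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class GeometryError(OsmovolError):
    """A shape is degenerate or outside the solvable regime."""


class StabilityError(OsmovolError):
    """Requested output step cannot resolve the fastest dynamics."""


class VolumeCollapseError(OsmovolError):
    """Cell volume dropped to the osmotically inactive floor during a simulation."""

    def __init__(self, message: str, t_collapse: float):
        super().__init__(message)
        self.t_collapse = t_collapse
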