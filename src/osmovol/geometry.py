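"""Spherical-cap geometry of a spreading cell.

A cell spreading on a flat substrate is approximated as a spherical cap:
a sphere truncated by the adhesion plane.  The cap is parameterized by the
contact radius ``a`` (set by the measured contact area ``Ac = pi a^2``) and
the cap height ``h``.  Its volume and total surface area (contact disc plus
curved cap) are

    V    = (pi h / 6) (3 a^2 + h^2)
    Atot = Ac + pi (a^2 + h^2)

Given measured (V, Ac), h is the unique positive root of the monotone cubic
``h^3 + 3 a^2 h - 6 V / pi = 0``.  The logarithmic derivatives of Atot with
respect to V (at fixed Ac) and Ac (at fixed V) — ``f1`` and ``f2`` — are what
couple shape change to membrane-tension dynamics in the mechanosensitive
pump-and-leak model.

Also included: the sphere and cylinder surface estimates used for
non-adherent and confined cells, and the volume-to-area excess ratio used to
interpret membrane rupture under extreme hypo-osmotic swelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = [
    "CapShape",
    "cap_from_volume_contact",
    "cap_area_derivatives",
    "sphere_area_from_volume",
    "cylinder_area_from_volume",
    "rupture_area_ratio",
]

#: Relative tolerance for the cubic residual in cap_from_volume_contact.
_CUBIC_TOL = 1e-12


@dataclass(frozen=True)
class CapShape:
    """A spherical cap: volume, contact area, and derived lengths/areas.

    Attributes
    ----------
    V : float
        Cell volume (µm³).
    Ac : float
        Contact (adhesion) area (µm²).
    a : float
        Contact radius, ``sqrt(Ac/pi)`` (µm).
    h : float
        Cap height (µm).
    Atot : float
        Total surface area, contact disc + curved cap (µm²).
    """

    V: float
    Ac: float
    a: float
    h: float
    Atot: float

    def as_dict(self) -> dict:
        return {"V": self.V, "Ac": self.Ac, "a": self.a, "h": self.h, "Atot": self.Atot}


def _cap_volume(a: float, h: float) -> float:
    return math.pi * h / 6.0 * (3.0 * a * a + h * h)


def cap_from_volume_contact(V: float, Ac: float) -> CapShape:
    """Solve the spherical cap with volume ``V`` and contact area ``Ac``.

    The height solves the monotone cubic ``h^3 + 3 a^2 h = 6 V / pi``, which
    has exactly one positive root.  Solved by Newton iteration from an upper
    bound with a bisection safeguard; the residual is polished to
    ``_CUBIC_TOL`` relative.

    Parameters
    ----------
    V : float
        Volume (µm³), > 0.
    Ac : float
        Contact area (µm²), > 0.  For a detached cell (zero contact) use
        :func:`sphere_area_from_volume` instead.

    Returns
    -------
    CapShape
    """
    if not (V > 0):
        raise ValueError(f"V must be > 0, got {V}")
    if not (Ac > 0):
        raise ValueError(
            f"Ac must be > 0, got {Ac}; use sphere_area_from_volume for detached cells"
        )
    a = math.sqrt(Ac / math.pi)
    q = 6.0 * V / math.pi
    a2 = a * a

    def f(h: float) -> float:
        return h * (h * h + 3.0 * a2) - q

    # Bracket: f(0) = -q < 0; h_hi = q ** (1/3) gives f >= 0.
    lo, hi = 0.0, q ** (1.0 / 3.0)
    h = min(hi, q / (3.0 * a2))  # start from whichever bound is tighter
    for _ in range(100):
        res = f(h)
        if res > 0:
            hi = h
        else:
            lo = h
        step = res / (3.0 * h * h + 3.0 * a2)
        h_new = h - step
        if not (lo < h_new < hi):
            h_new = 0.5 * (lo + hi)
        if abs(h_new - h) <= 1e-15 * max(1.0, h):
            h = h_new
            break
        h = h_new
    if abs(f(h)) > _CUBIC_TOL * max(1.0, q):
        raise GeometryError(
            f"cap height solve did not reach tolerance: residual {f(h):.3e} at h={h}"
        )
    Atot = Ac + math.pi * (a2 + h * h)
    return CapShape(V=V, Ac=Ac, a=a, h=h, Atot=Atot)


def cap_area_derivatives(shape: CapShape) -> tuple[float, float]:
    """Logarithmic area sensitivities ``(f1, f2)`` of a spherical cap.

    ``f1 = (1/Atot) dAtot/dV`` at fixed contact area (units µm⁻³) and
    ``f2 = (1/Atot) dAtot/dAc`` at fixed volume (dimensionless), using the
    closed forms

        dAtot/dV|Ac  = 4 h / (a^2 + h^2)
        dAtot/dAc|V  = 2 a^2 / (a^2 + h^2)

    These convert the rates of volume and contact-area change into the rate
    of relative total-area change that drives tension.
    """
    a, h = shape.a, shape.h
    if h <= 0 or not math.isfinite(h):
        raise GeometryError(f"degenerate cap shape (h={h}); derivatives undefined")
    s = a * a + h * h
    dAtot_dV = 4.0 * h / s
    dAtot_dAc = 2.0 * a * a / s
    return dAtot_dV / shape.Atot, dAtot_dAc / shape.Atot


def sphere_area_from_volume(V: float) -> float:
    """Surface area of a sphere of volume ``V``: ``(36 pi)^(1/3) V^(2/3)``.

    Used for non-adherent (detached) cells.
    """
    if V < 0:
        raise ValueError(f"V must be >= 0, got {V}")
    return (36.0 * math.pi) ** (1.0 / 3.0) * V ** (2.0 / 3.0)


def cylinder_area_from_volume(V: float, height: float) -> float:
    """Surface area of a cylinder of volume ``V`` and given height.

    Used for cells flattened under a confiner of known height:
    ``r = sqrt(V / (pi height))``, area ``2 pi r^2 + 2 pi r height``.
    """
    if not (V > 0):
        raise ValueError(f"V must be > 0, got {V}")
    if not (height > 0):
        raise ValueError(f"height must be > 0, got {height}")
    r = math.sqrt(V / (math.pi * height))
    return 2.0 * math.pi * r * r + 2.0 * math.pi * r * height


def rupture_area_ratio(volume_ratio: float) -> float:
    """Relative membrane area required to accommodate a volume ratio.

    Under the spherical assumption a cell swollen to ``volume_ratio`` times
    its initial volume needs ``volume_ratio^(2/3)`` times its initial surface
    area; the value at rupture measures the cell's membrane-area reserve.
    """
    if volume_ratio < 1:
        raise ValueError(f"volume_ratio must be >= 1, got {volume_ratio}")
    return volume_ratio ** (2.0 / 3.0)
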