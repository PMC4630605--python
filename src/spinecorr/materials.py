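"""Material definitions for the instrumented-spine finite element model.

Linear isotropic elastic constants for the bony tissues and disk ground
substances, plus the piecewise-linear tension-only curves used for ligaments
and annulus fibers.  Units: MPa for moduli, N and mm for curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Elastic", "LigamentCurve", "MaterialTable", "default_material_table"]


@dataclass(frozen=True)
class Elastic:
    """Linear isotropic material: Young's modulus E (MPa), Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")

    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class LigamentCurve:
    """Tension-only piecewise-linear force-deflection curve.

    ``points`` are (elongation mm, force N) pairs starting at (0, 0); the
    force is zero for negative elongation (slack) and extrapolates with the
    last segment's slope beyond the final point.  Curves must be monotone
    non-decreasing.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("curve needs >= 2 (elongation, force) points")
        if abs(pts[0, 0]) > 1e-12 or abs(pts[0, 1]) > 1e-12:
            raise ValueError("curve must start at (0, 0): zero force at reference length")
        if np.any(np.diff(pts[:, 0]) <= 0) or np.any(np.diff(pts[:, 1]) < 0):
            raise ValueError("curve must be monotone non-decreasing")

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.asarray(self.points, dtype=float)
        return pts[:, 0], pts[:, 1]

    def force(self, elongation) -> np.ndarray:
        """Force at the given elongation(s); zero in compression."""
        x, f = self._arrays()
        e = np.asarray(elongation, dtype=float)
        slope_end = (f[-1] - f[-2]) / (x[-1] - x[-2])
        out = np.interp(e, x, f)
        beyond = e > x[-1]
        out = np.where(beyond, f[-1] + slope_end * (e - x[-1]), out)
        return np.where(e <= 0.0, 0.0, out)

    def stiffness(self, elongation) -> np.ndarray:
        """Tangent stiffness dF/de; zero when slack."""
        x, f = self._arrays()
        slopes = np.diff(f) / np.diff(x)
        e = np.asarray(elongation, dtype=float)
        seg = np.clip(np.searchsorted(x, e, side="right") - 1, 0, len(slopes) - 1)
        out = slopes[seg]
        return np.where(e <= 0.0, 0.0, out)

    def scaled(self, factor: float) -> "LigamentCurve":
        return LigamentCurve(tuple((x, factor * f) for x, f in self.points))


def _toe_curve(k: float, toe_mm: float = 0.5, toe_factor: float = 0.2) -> LigamentCurve:
    """Default stand-in nonlinear curve: a low-stiffness toe region followed
    by a linear region of stiffness ``k`` (N/mm per spring)."""
    f_toe = toe_factor * k * toe_mm
    return LigamentCurve(((0.0, 0.0), (toe_mm, f_toe), (toe_mm + 10.0, f_toe + 10.0 * k)))


@dataclass
class MaterialTable:
    """Elastic constants per tissue and per-spring ligament curves.

    The bone and disk moduli are the literature values used for every model;
    the ligament curves are calibration stand-ins shipped with the package
    (only their tension-only, toe-then-linear shape is prescribed).
    """

    cortical: Elastic = field(default_factory=lambda: Elastic(12000.0, 0.3))
    trabecular: Elastic = field(default_factory=lambda: Elastic(200.0, 0.315))
    posterior_elements: Elastic = field(default_factory=lambda: Elastic(3500.0, 0.25))
    annulus_ground: Elastic = field(default_factory=lambda: Elastic(4.2, 0.45))
    annulus_ground_soft: Elastic = field(default_factory=lambda: Elastic(2.1, 0.45))
    nucleus: Elastic = field(default_factory=lambda: Elastic(1.0, 0.499))
    fiber_modulus: float = 25.0  # MPa, healthy annulus fibers
    fiber_modulus_soft: float = 12.5  # MPa, unstable disk
    rod: Elastic = field(default_factory=lambda: Elastic(110000.0, 0.3))  # Ti alloy
    ligament_curves: dict[str, LigamentCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = {
            "ALL": _toe_curve(10.0),
            "PLL": _toe_curve(7.0),
            "LF": _toe_curve(8.0),
            "ISL": _toe_curve(4.0),
            "SSL": _toe_curve(8.0),
            "CL": _toe_curve(8.0),
        }
        for k, v in defaults.items():
            self.ligament_curves.setdefault(k, v)

    def bone(self, label: str) -> Elastic:
        return {
            "cortical": self.cortical,
            "trabecular": self.trabecular,
            "posterior_elements": self.posterior_elements,
        }[label]


def default_material_table() -> MaterialTable:
    return MaterialTable()
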