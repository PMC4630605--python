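"""Pedicle screws, posterior rods, and screw-rod connections.

Screws are monoaxial: the head moves rigidly with the shaft.  A screw is not
meshed as a solid; instead it is a rigid body whose reference node (at the
head) is kinematically coupled to every vertebra mesh node within a capture
radius of the shaft — equivalent, at the resultant-force level reported by
the postprocessor, to meshing the threaded solid, and it keeps the bone mesh
topology identical across correction strategies.

Rods are interpolating cubic splines through the (planned) screw-head
positions, chord-length parameterized with natural end conditions, meshed
into 2-node beam elements at equal arc-length intervals with circular
cross-section properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import SpineModel, ValidationError
from .materials import Elastic

__all__ = [
    "Screw",
    "EmbeddedScrew",
    "RodCurve",
    "RodSection",
    "RodModel",
    "place_pedicle_screw",
    "embed_screw",
    "fit_rod_curve",
    "mesh_rod",
    "connect_screws_to_rod",
    "default_screw_layout",
]

DEFAULT_SCREW_LENGTH = 45.0  # mm
DEFAULT_SCREW_DIAMETER = 6.0  # mm
DEFAULT_HEAD_OFFSET = 5.0  # mm behind the entry point
DEFAULT_MEDIAL_ANGLE_DEG = 15.0
# capture radius for the embedded coupling: a quarter more than the shaft
# diameter so that at the coarse default mesh resolution the captured cloud
# spans at least one node layer in every direction around the shaft
DEFAULT_CAPTURE_FACTOR = 1.25


@dataclass
class Screw:
    """Monoaxial pedicle screw (rigid head-shaft unit)."""

    vertebra: str
    side: str  # 'left' | 'right'
    entry: np.ndarray  # entry point on the posterior cortex (assembled frame)
    axis: np.ndarray  # unit vector pointing into the bone
    length: float
    diameter: float
    head_offset: float = DEFAULT_HEAD_OFFSET
    rigid_head: bool = True  # monoaxial by construction

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n < 1e-12:
            raise ValidationError("screw direction must be a non-zero vector")
        self.axis = a / n
        if self.length <= 0 or self.diameter <= 0:
            raise ValidationError("screw length and diameter must be > 0")

    @property
    def tip(self) -> np.ndarray:
        return self.entry + self.length * self.axis

    @property
    def head(self) -> np.ndarray:
        return self.entry - self.head_offset * self.axis

    @property
    def name(self) -> str:
        return f"{self.vertebra}:{self.side}"


@dataclass
class EmbeddedScrew:
    """Rigid coupling of a screw to the captured vertebra mesh nodes."""

    screw: Screw
    captured_nodes: np.ndarray  # vertebra volume-mesh node indices
    weights: np.ndarray  # per captured node, sum to 1
    capture_radius: float


@dataclass
class RodCurve:
    """Interpolating 3-D cubic spline through ordered control points."""

    points: np.ndarray  # (n, 2+) control points, caudal -> cranial
    _t: np.ndarray = field(init=False)
    _splines: list = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValidationError("rod curve needs >= 2 control points in 3-D")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-9):
            raise ValidationError("duplicate consecutive rod control points")
        self.points = pts
        t = np.concatenate([[0.0], np.cumsum(seg)])  # chord-length parameter
        self._t = t
        if len(pts) == 2:
            self._splines = None  # straight segment
        else:
            from scipy.interpolate import CubicSpline

            self._splines = [CubicSpline(t, pts[:, k], bc_type="natural") for k in range(3)]

    @property
    def t_end(self) -> float:
        return float(self._t[-1])

    def eval(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self._splines is None:
            p0, p1 = self.points
            u = (t / self.t_end)[..., None]
            return p0 * (1 - u) + p1 * u
        return np.stack([s(t) for s in self._splines], axis=-1)

    def derivative(self, t, order: int = 1) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self._splines is None:
            d = (self.points[1] - self.points[0]) / self.t_end
            if order == 1:
                return np.broadcast_to(d, t.shape + (3,)).copy()
            return np.zeros(t.shape + (3,))
        return np.stack([s.derivative(order)(t) for s in self._splines], axis=-1)

    def speed(self, t) -> np.ndarray:
        return np.linalg.norm(self.derivative(t), axis=-1)

    def arc_length(self, t0: float | None = None, t1: float | None = None) -> float:
        """Adaptive-quadrature arc length between parameters (default: whole)."""
        from scipy.integrate import quad

        t0 = 0.0 if t0 is None else t0
        t1 = self.t_end if t1 is None else t1
        val, _ = quad(lambda s: float(self.speed(np.atleast_1d(s))[0]), t0, t1, limit=200)
        return float(val)

    def max_curvature(self, n_samples: int = 400) -> float:
        ts = np.linspace(0.0, self.t_end, n_samples)
        d1 = self.derivative(ts, 1)
        d2 = self.derivative(ts, 2)
        num = np.linalg.norm(np.cross(d1, d2), axis=1)
        den = np.linalg.norm(d1, axis=1) ** 3
        return float(np.max(num / np.maximum(den, 1e-30)))

    def interpolation_residual(self) -> float:
        return float(np.abs(self.eval(self._t) - self.points).max())


@dataclass(frozen=True)
class RodSection:
    """Circular beam section: diameter (mm) and elastic constants."""

    diameter: float = 5.5
    elastic: Elastic = field(default_factory=lambda: Elastic(110000.0, 0.3))

    @property
    def area(self) -> float:
        return np.pi * self.diameter**2 / 4.0

    @property
    def I(self) -> float:  # noqa: E743 - conventional symbol
        return np.pi * self.diameter**4 / 64.0

    @property
    def J(self) -> float:
        return np.pi * self.diameter**4 / 32.0


@dataclass
class RodModel:
    """Beam-meshed posterior rod."""

    side: str
    head_points: np.ndarray  # ordered controlling screw-head points
    curve: RodCurve
    nodes: np.ndarray  # (n+1, 3) beam nodes at equal arc-length stations
    elements: np.ndarray  # (n, 2) node index pairs
    section: RodSection
    node_params: np.ndarray  # spline parameter of each node
    fixed_caudal_end: bool = True

    def element_lengths(self) -> np.ndarray:
        return np.linalg.norm(
            self.nodes[self.elements[:, 1]] - self.nodes[self.elements[:, 0]], axis=1
        )


# ---------------------------------------------------------------------------
# screw placement and embedding
# ---------------------------------------------------------------------------


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of each point to the segment [a, b]."""
    d = b - a
    L2 = float(d @ d)
    t = np.clip((points - a) @ d / L2, 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def _point_in_tets(p: np.ndarray, nodes: np.ndarray, tets: np.ndarray) -> bool:
    """True if p lies inside (or on) any tet of the mesh."""
    v0 = nodes[tets[:, 0]]
    m = np.stack(
        [nodes[tets[:, k]] - v0 for k in (1, 2, 3)], axis=-1
    )  # (n,3,3) columns are edge vectors
    try:
        bary = np.linalg.solve(m, (p - v0)[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        return False
    tol = 1e-9
    ok = (bary >= -tol).all(axis=1) & (bary.sum(axis=1) <= 1 + tol)
    return bool(ok.any())


def place_pedicle_screw(
    model: SpineModel,
    level: str,
    side: str,
    entry: np.ndarray | str = "auto",
    direction: np.ndarray | str = "auto",
    length: float = DEFAULT_SCREW_LENGTH,
    diameter: float = DEFAULT_SCREW_DIAMETER,
    head_offset: float = DEFAULT_HEAD_OFFSET,
) -> Screw:
    """Place a monoaxial pedicle screw on one side of a vertebra.

    With ``entry='auto'`` the posed pedicle-entry landmark is used; with
    ``direction='auto'`` the shaft points anteriorly with a 15-degree medial
    inclination in the vertebra's own frame.  The shaft must pass through
    the pedicle node cloud (within half a diameter) and the tip must stay
    inside the vertebra.
    """
    if level not in model.levels:
        raise ValidationError(f"unknown vertebra {level!r}")
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    surf = model.vertebrae[level]
    pose = model.poses[level]
    if isinstance(entry, str) and entry == "auto":
        entry_pt = model.landmark_position(level, f"{side}_pedicle_entry")
    else:
        entry_pt = np.asarray(entry, dtype=float)
    if isinstance(direction, str) and direction == "auto":
        a = np.deg2rad(DEFAULT_MEDIAL_ANGLE_DEG)
        sgn = -1.0 if side == "left" else 1.0
        d_local = np.array([np.cos(a), sgn * np.sin(a), 0.0])
        d = pose.rotation @ d_local
    else:
        d = np.asarray(direction, dtype=float)
    screw = Screw(
        vertebra=level,
        side=side,
        entry=entry_pt,
        axis=d,
        length=length,
        diameter=diameter,
        head_offset=head_offset,
    )

    ped = pose.apply(surf.vertices[surf.region_sets[f"{side}_pedicle"]])
    dist = _segment_distance(ped, screw.entry, screw.tip)
    if dist.min() > diameter / 2.0:
        raise ValidationError(
            f"screw axis misses the {side} pedicle of {level} "
            f"(closest pedicle node {dist.min():.2f} mm from the shaft)"
        )
    vol = surf.volume
    posed_nodes = pose.apply(vol.nodes)
    if not _point_in_tets(screw.tip, posed_nodes, vol.tets):
        raise ValidationError(
            f"screw too long: tip protrudes beyond the anterior surface of {level}"
        )
    return screw


def embed_screw(
    screw: Screw,
    vertebra_nodes: np.ndarray,
    capture_radius: float | None = None,
) -> EmbeddedScrew:
    """Capture the mesh nodes rigidly coupled to the screw.

    ``vertebra_nodes`` are the posed volume-mesh node coordinates of the
    screw's vertebra.  Every node within the capture radius of the shaft
    segment follows the head node as a rigid body; weights are uniform and
    sum to one.
    """
    if capture_radius is None:
        capture_radius = DEFAULT_CAPTURE_FACTOR * screw.diameter
    pts = np.asarray(vertebra_nodes, dtype=float)
    dist = _segment_distance(pts, screw.entry, screw.tip)
    captured = np.nonzero(dist <= capture_radius)[0]
    if len(captured) == 0:
        raise ValidationError(
            f"screw {screw.name}: no mesh nodes captured within {capture_radius:.1f} mm"
        )
    w = np.full(len(captured), 1.0 / len(captured))
    return EmbeddedScrew(
        screw=screw, captured_nodes=captured, weights=w, capture_radius=float(capture_radius)
    )


# ---------------------------------------------------------------------------
# rods
# ---------------------------------------------------------------------------


def fit_rod_curve(head_points: np.ndarray) -> RodCurve:
    """Interpolating cubic spline through screw heads (caudal to cranial)."""
    return RodCurve(points=np.asarray(head_points, dtype=float))


def mesh_rod(
    curve: RodCurve,
    n_elements: int = 24,
    section: RodSection | None = None,
    side: str = "",
    head_points: np.ndarray | None = None,
) -> RodModel:
    """Mesh a rod curve into 2-node beam elements.

    Nodes sit at equal arc-length intervals (cumulative Simpson table of the
    spline speed, refined by Newton steps), so the summed element lengths
    reproduce the adaptive-quadrature arc length to well within 0.1% for the
    gentle curvatures of posterior rods.
    """
    if n_elements < 1:
        raise ValidationError("a rod needs at least one beam element")
    section = section or RodSection()
    ts = np.linspace(0.0, curve.t_end, max(40 * n_elements, 200))
    sp = curve.speed(ts)
    cum = np.concatenate([[0.0], np.cumsum((sp[1:] + sp[:-1]) / 2.0 * np.diff(ts))])
    total = cum[-1]
    s_targets = np.linspace(0.0, total, n_elements + 1)
    t_nodes = np.interp(s_targets, cum, ts)
    for _ in range(3):  # Newton refinement of the inverse arc-length map
        s_now = np.interp(t_nodes, ts, cum)
        v = np.maximum(curve.speed(t_nodes), 1e-12)
        t_nodes = np.clip(t_nodes - (s_now - s_targets) / v, 0.0, curve.t_end)
    t_nodes[0], t_nodes[-1] = 0.0, curve.t_end
    nodes = curve.eval(t_nodes)
    elements = np.stack([np.arange(n_elements), np.arange(1, n_elements + 1)], axis=1)
    return RodModel(
        side=side,
        head_points=curve.points if head_points is None else np.asarray(head_points, float),
        curve=curve,
        nodes=nodes,
        elements=elements,
        section=section,
        node_params=t_nodes,
    )


def connect_screws_to_rod(rod: RodModel, screws: list[Screw]) -> list[tuple[str, int]]:
    """Select the rod node coupled to each chosen screw.

    Returns (screw name, nearest rod node index) pairs; a screw from the
    opposite side is rejected.  Unselected screws simply stay uncoupled.
    """
    out = []
    for s in screws:
        if rod.side and s.side != rod.side:
            raise ValidationError(
                f"screw {s.name} is on the {s.side} side, rod is {rod.side}"
            )
        d = np.linalg.norm(rod.nodes - s.head, axis=1)
        out.append((s.name, int(np.argmin(d))))
    return out


def default_screw_layout(
    model: SpineModel,
    levels: list[str] | None = None,
    length: float = DEFAULT_SCREW_LENGTH,
    diameter: float = DEFAULT_SCREW_DIAMETER,
) -> list[Screw]:
    """Bilateral auto-placed screws at the requested (default: all) levels."""
    levels = list(levels or model.levels)
    screws = []
    for lv in levels:
        for side in ("left", "right"):
            screws.append(
                place_pedicle_screw(model, lv, side, length=length, diameter=diameter)
            )
    return screws
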