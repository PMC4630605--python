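"""Correction planning: per-vertebra rigid transforms, deformity metrics and
the six benchmark configurations.

A plan maps each vertebra to a rigid transform in the global (assembled)
frame; untouched vertebrae carry the identity.  The benchmark spondylo-
listhesis configurations combine a purely translational posterior reduction
of the two cranial vertebrae (partial = half the measured slip, complete =
all of it) with a healthy, softened or removed disk at the slipped level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import SpineModel, ValidationError
from .geometry import RigidTransform, intrinsic_yxz

__all__ = [
    "CorrectionPlan",
    "Configuration",
    "apply_vertebral_transform",
    "measure_slip",
    "build_configuration",
    "CONFIGURATION_NAMES",
]

CONFIGURATION_NAMES = ("P-H", "P-S", "P-D", "C-H", "C-S", "C-D")


@dataclass
class CorrectionPlan:
    """Planned correction: global-frame rigid transform per vertebra."""

    levels: tuple[str, ...]
    transforms: dict[str, RigidTransform] = field(default_factory=dict)
    discectomy_levels: list[str] = field(default_factory=list)
    connected_screws: str | list[str] = "all"  # screw names, or all of them
    external_load: dict | None = None  # step-iii load spec

    def transform(self, level: str) -> RigidTransform:
        return self.transforms.get(level, RigidTransform.identity())

    def planned_pose(self, model: SpineModel, level: str) -> RigidTransform:
        return self.transform(level).compose(model.poses[level])

    def planned_point(self, model: SpineModel, level: str, point: np.ndarray) -> np.ndarray:
        return self.transform(level).apply(point)

    def is_identity(self, level: str) -> bool:
        t = self.transform(level)
        return bool(
            np.allclose(t.rotation, np.eye(3), atol=1e-12)
            and np.allclose(t.translation, 0.0, atol=1e-12)
        )


def apply_vertebral_transform(
    plan: CorrectionPlan,
    vertebra_ids: list[str],
    translation=(0.0, 0.0, 0.0),
    rotation_deg=(0.0, 0.0, 0.0),
    pivot: np.ndarray | None = None,
) -> CorrectionPlan:
    """Compose one rigid map onto the planned transforms of a vertebra group.

    ``rotation_deg`` = (sagittal, coronal, axial) intrinsic Y-X-Z angles about
    ``pivot`` (required for non-zero rotations); the same map is applied to
    every listed vertebra, composed onto whatever the plan already holds.
    """
    for vid in vertebra_ids:
        if vid not in plan.levels:
            raise ValidationError(f"unknown vertebra {vid!r}")
    R = intrinsic_yxz(*rotation_deg)
    if np.allclose(R, np.eye(3), atol=1e-15):
        M = RigidTransform.from_translation(translation)
    else:
        if pivot is None:
            raise ValidationError("a pivot point is required for planned rotations")
        M = RigidTransform.about_point(R, pivot, translation)
    for vid in vertebra_ids:
        plan.transforms[vid] = M.compose(plan.transform(vid))
    return plan


# ---------------------------------------------------------------------------
# deformity metrics
# ---------------------------------------------------------------------------


def _slip_frame(model: SpineModel, junction_name: str, plan: CorrectionPlan | None):
    j = model.junction_by_name(junction_name)
    lo_pose = model.poses[j.caudal]
    hi_pose = model.poses[j.cranial]
    if plan is not None:
        lo_pose = plan.transform(j.caudal).compose(lo_pose)
        hi_pose = plan.transform(j.cranial).compose(hi_pose)
    for lv in (j.cranial, j.caudal):
        if "body_center" not in model.vertebrae[lv].landmarks:
            raise ValidationError(f"missing body_center landmark on {lv}")
    c_lo = lo_pose.apply(
        model.vertebrae[j.caudal].vertices[model.vertebrae[j.caudal].landmarks["body_center"]]
    )
    c_hi = hi_pose.apply(
        model.vertebrae[j.cranial].vertices[model.vertebrae[j.cranial].landmarks["body_center"]]
    )
    normal = lo_pose.rotation[:, 2]  # caudal superior-endplate normal
    ap_axis = lo_pose.rotation[:, 0]  # caudal anteroposterior axis
    return c_lo, c_hi, normal, ap_axis


def measure_slip(
    model: SpineModel, junction_name: str, plan: CorrectionPlan | None = None
) -> float:
    """Signed anteroposterior slip (mm, + = anterior) at a junction.

    The cranial body-center offset relative to the caudal one is projected
    onto the caudal superior-endplate plane and measured along the caudal
    anteroposterior axis.  With a plan, the planned geometry is measured.
    """
    c_lo, c_hi, normal, ap_axis = _slip_frame(model, junction_name, plan)
    d = c_hi - c_lo
    d_in_plane = d - (d @ normal) * normal
    return float(d_in_plane @ ap_axis)


# ---------------------------------------------------------------------------
# benchmark configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Configuration:
    """One of the six benchmark runs: reduction degree x disk state."""

    name: str  # canonical, e.g. "C-H"
    reduction: str  # 'partial' | 'complete'
    disk_state: str  # 'healthy' | 'soft' | 'removed'

    @property
    def label(self) -> str:
        return self.name


def _canonical_name(name: str) -> str:
    s = name.replace("–", "-").replace("—", "-").upper().strip()
    if s not in CONFIGURATION_NAMES:
        raise ValidationError(
            f"unknown configuration {name!r}; expected one of {CONFIGURATION_NAMES}"
        )
    return s


def build_configuration(
    name: str,
    model: SpineModel | None = None,
    junction: str = "L3-L4",
    moved_levels: tuple[str, ...] = ("L2", "L3"),
) -> tuple[Configuration, CorrectionPlan | None, dict[str, str]]:
    """Resolve a configuration label into (configuration, plan, disk states).

    The plan translates the cranial group posteriorly along the caudal
    anteroposterior axis by the measured slip (complete) or half of it
    (partial); the disk at the reduction junction is healthy, soft, or
    removed (with a discectomy registered in the plan).  Without a model
    only the parsed configuration is returned.
    """
    s = _canonical_name(name)
    reduction = "partial" if s[0] == "P" else "complete"
    disk_state = {"H": "healthy", "S": "soft", "D": "removed"}[s[-1]]
    conf = Configuration(name=s, reduction=reduction, disk_state=disk_state)
    if model is None:
        return conf, None, {}

    slip = measure_slip(model, junction)
    amount = slip / 2.0 if reduction == "partial" else slip
    _, _, _, ap_axis = _slip_frame(model, junction, None)
    plan = CorrectionPlan(levels=tuple(model.levels))
    apply_vertebral_transform(plan, list(moved_levels), translation=-amount * ap_axis)
    disk_states = {j.name: "healthy" for j in model.junctions}
    disk_states[junction] = disk_state
    if disk_state == "removed":
        plan.discectomy_levels.append(junction)
    return conf, plan, disk_states
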