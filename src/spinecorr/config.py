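"""Run configuration: YAML-serializable settings for every pipeline stage.

A :class:`RunConfig` gathers the fixture geometry, material overrides,
instrumentation, planning, solver and output settings.  The effective
configuration of a run is echoed into its output directory, which together
with the seed makes every run reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .anatomy import FixtureConfig, VertebraSpec
from .fe.solver import SolverOptions
from .instrumentation import (
    DEFAULT_CAPTURE_FACTOR,
    DEFAULT_SCREW_DIAMETER,
    DEFAULT_SCREW_LENGTH,
    RodSection,
)
from .materials import Elastic, LigamentCurve, MaterialTable

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    fixture: dict = field(default_factory=dict)
    materials: dict = field(default_factory=dict)
    instrumentation: dict = field(default_factory=dict)
    planning: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    output_dir: str = "runs"
    seed: int = 0
    verbosity: str = "info"

    # -- resolved objects --------------------------------------------------
    def fixture_config(self) -> FixtureConfig:
        f = dict(self.fixture)
        specs = {
            lv: VertebraSpec(**sp) for lv, sp in (f.pop("specs", {}) or {}).items()
        }
        defaults = dict(
            levels=("L2", "L3", "L4", "L5"),
            slip_mm={"L3-L4": 14.0},
            coronal_asymmetry_deg=6.0,
            axial_asymmetry_deg=3.0,
        )
        defaults.update(f)
        defaults["levels"] = tuple(defaults["levels"])
        defaults.setdefault("seed", self.seed)
        return FixtureConfig(specs=specs, **defaults)

    def material_table(self) -> MaterialTable:
        m = dict(self.materials)
        kwargs = {}
        for name in (
            "cortical",
            "trabecular",
            "posterior_elements",
            "annulus_ground",
            "annulus_ground_soft",
            "nucleus",
            "rod",
        ):
            if name in m:
                kwargs[name] = Elastic(**m[name])
        for name in ("fiber_modulus", "fiber_modulus_soft"):
            if name in m:
                kwargs[name] = float(m[name])
        curves = {
            g: LigamentCurve(tuple(map(tuple, pts)))
            for g, pts in (m.get("ligament_curves") or {}).items()
        }
        return MaterialTable(ligament_curves=curves, **kwargs)

    def rod_section(self) -> RodSection:
        ins = self.instrumentation
        rod = ins.get("rod", {})
        elastic = Elastic(rod.get("E", 110000.0), rod.get("nu", 0.3))
        return RodSection(diameter=rod.get("diameter", 5.5), elastic=elastic)

    def screw_params(self) -> dict:
        ins = self.instrumentation
        scr = ins.get("screws", {})
        return {
            "length": scr.get("length", DEFAULT_SCREW_LENGTH),
            "diameter": scr.get("diameter", DEFAULT_SCREW_DIAMETER),
            "capture_radius": scr.get(
                "capture_radius", DEFAULT_CAPTURE_FACTOR * scr.get("diameter", DEFAULT_SCREW_DIAMETER)
            ),
        }

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver)

    def rod_elements(self) -> int:
        return int(self.instrumentation.get("rod", {}).get("n_elements", 24))

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
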