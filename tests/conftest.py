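"""Shared fixtures: generated spines and the (expensive) benchmark suite."""

from __future__ import annotations

import numpy as np
import pytest

from spinecorr import anatomy, planning
from spinecorr.config import RunConfig
from spinecorr.workflow import run_one_configuration

ALL_CONFIGURATIONS = ("C-H", "C-S", "C-D", "P-H", "P-S", "P-D")


@pytest.fixture(scope="session")
def test_case_spine():
    """Baseline L2-L5 fixture: 14 mm slip at L3-L4, 6/3 deg asymmetries."""
    return anatomy.generate_spine_fixture(anatomy.test_case_fixture_config())


@pytest.fixture(scope="session")
def symmetric_spine():
    """Bilaterally mirror-symmetric fixture with the same 14 mm slip."""
    return anatomy.generate_spine_fixture(
        anatomy.FixtureConfig(slip_mm={"L3-L4": 14.0})
    )


@pytest.fixture(scope="session")
def default_vertebra():
    return anatomy.generate_vertebra_surface()


@pytest.fixture(scope="session")
def suite_results(test_case_spine):
    """Full three-step simulations of all six benchmark configurations."""
    cfg = RunConfig()
    out = {}
    for name in ALL_CONFIGURATIONS:
        out[name] = run_one_configuration(cfg, name, spine=test_case_spine)
    return out


@pytest.fixture(scope="session")
def symmetric_ch(symmetric_spine):
    """Complete-reduction, healthy-disk run on the symmetric fixture."""
    return run_one_configuration(RunConfig(), "C-H", spine=symmetric_spine)


@pytest.fixture(scope="session")
def cylinder_disk():
    """Reference disk between parallel circular endplates (r=20, gap=10)."""
    from spinecorr import soft_tissue as st

    b, t, tris = st.make_circular_endplates(20.0, 10.0)
    return st.build_disk(b, t, tris, level="cylinder")
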