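import dataclasses

import numpy as np
import pytest

from petpbpk.core_data import (
    CurveKind,
    PhysiologyConstants,
    RegionCurve,
    RegionKind,
    ScanRecord,
)
from petpbpk.pbpk_model import RateConstantSet, ScanGeometry
from petpbpk.synthetic_data import default_frame_schedule, generate_scan, scenario_presets
from petpbpk.tac_preprocess import prepare_scan


@pytest.fixture(scope="session")
def phys() -> PhysiologyConstants:
    return PhysiologyConstants()


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture(scope="session")
def control_truth(presets) -> RateConstantSet:
    return presets["mt107_control_like"].truth


@pytest.fixture(scope="session")
def geometry(presets) -> ScanGeometry:
    scn = presets["mt107_control_like"]
    return ScanGeometry(
        body_weight=scn.bw,
        dose_a0=scn.dose,
        infusion_duration=scn.infusion_duration,
        frame_grid=tuple(scn.frame_schedule),
    )


@pytest.fixture(scope="session")
def clean_scan(presets):
    """Noise-free synthetic control scan plus its ground-truth sidecar."""
    return generate_scan(presets["mt107_control_like"])


@pytest.fixture(scope="session")
def clean_prepared(clean_scan, phys):
    scan, _ = clean_scan
    return prepare_scan(scan, phys)


def random_rate_constants(rng: np.random.Generator) -> RateConstantSet:
    """A strictly positive random parameter set within plausible ranges."""
    draw = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return RateConstantSet(
        k_bh1=draw(0.01, 1.0),
        k_h1b=draw(0.01, 1.0),
        k_h1h2=draw(0.01, 0.5),
        k_h2g=draw(0.01, 0.5),
        k_gh1=draw(0.001, 0.1),
        k_bg=draw(0.001, 0.1),
        k_br1=draw(0.01, 1.0),
        k_r1b=draw(0.01, 1.0),
        k_r1r2=draw(0.01, 0.5),
        k_r2r1=draw(0.01, 0.5),
        k_r1u=draw(0.01, 0.5),
        k_bt=draw(0.01, 1.0),
        k_tb1=draw(0.02, 1.0),
        k_tb2=draw(0.02, 1.0),
        f_bt1=float(rng.uniform(0.1, 0.9)),
        v_tissue=float(rng.uniform(5.0, 25.0)),
    )


def make_scan(curves: dict, n_frames: int = 12, **kwargs) -> ScanRecord:
    """Small helper building a valid ScanRecord around given curves."""
    defaults = dict(
        scan_id="test",
        body_weight=20.0,
        dose_a0=7.1,
        frame_grid=default_frame_schedule()[:n_frames],
    )
    defaults.update(kwargs)
    return ScanRecord(curves=curves, **defaults)


def constant_curves(n: int, value: float = 1.0) -> dict:
    """A full curve set with constant values, for validation-level tests."""
    conc = lambda: RegionCurve(np.full(n, value), CurveKind.CONCENTRATION)
    return {
        RegionKind.BLOOD: conc(),
        RegionKind.LIVER: conc(),
        RegionKind.GI: RegionCurve(np.full(n, value), CurveKind.AMOUNT),
        RegionKind.KIDNEY: conc(),
        RegionKind.TISSUE: conc(),
    }
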