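"""Synthetic scan generation.

Scans are simulated from a ground-truth :class:`RateConstantSet` through
the full observation model (frame-averaged amounts with vascular terms),
converted back to the concentration/amount dialect of the TAC tables, and
perturbed with independent multiplicative lognormal noise per frame and
region.  Ground truth is written to a sidecar file, never into the TAC
table itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .core_data import (
    CurveKind,
    PhysiologyConstants,
    RegionCurve,
    RegionKind,
    ScanRecord,
    ValidationError,
    plasma_volume,
    write_tac_table,
)
from .derived_pk import cl_hepatic, cl_renal, d_tissue
from .pbpk_model import RateConstantSet, ScanGeometry, frame_averaged_observations

__all__ = [
    "SyntheticScenario",
    "default_frame_schedule",
    "generate_scan",
    "write_scenario_files",
    "scenario_presets",
]

#: Deterministic region order for noise draws.
_NOISE_ORDER = (
    RegionKind.BLOOD,
    RegionKind.LIVER,
    RegionKind.GI,
    RegionKind.KIDNEY,
    RegionKind.TISSUE,
    RegionKind.URINE,
)


@dataclass(frozen=True)
class SyntheticScenario:
    truth: RateConstantSet
    bw: float = 20.0  # g
    dose: float = 7.1  # MBq
    infusion_duration: float = 10.0 / 60.0  # min
    frame_schedule: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]
    noise_cv: float | Mapping[RegionKind, float] = 0.0
    seed: int = 0
    group_label: str = ""
    tracer_label: str = "synthetic"
    scan_id: str = "synthetic"
    include_urine: bool = False

    def __post_init__(self) -> None:
        if self.frame_schedule is None:
            object.__setattr__(self, "frame_schedule", default_frame_schedule())
        cvs = (
            [self.noise_cv]
            if np.isscalar(self.noise_cv)
            else list(self.noise_cv.values())
        )
        if any(cv < 0 for cv in cvs):
            raise ValidationError("noise_cv must be non-negative")

    def cv_for(self, region: RegionKind) -> float:
        if np.isscalar(self.noise_cv):
            return float(self.noise_cv)
        return float(self.noise_cv.get(region, 0.0))


def default_frame_schedule(include_first_minute: bool = False) -> tuple[tuple[float, float], ...]:
    """12 frames from 60 s to 3660 s post-injection: six 2-min frames then
    six 8-min frames.  With ``include_first_minute`` two extra early frames
    cover the gap from the end of a 10-s infusion to 60 s (idealized data
    for identifiability studies)."""
    frames: list[tuple[float, float]] = []
    if include_first_minute:
        frames += [(10.0 / 60.0, 0.5), (0.5, 1.0)]
    t = 1.0
    for dur in [2.0] * 6 + [8.0] * 6:
        frames.append((t, t + dur))
        t += dur
    return tuple(frames)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def generate_scan(
    scn: SyntheticScenario,
    phys: PhysiologyConstants | None = None,
) -> tuple[ScanRecord, dict]:
    """Simulate one scan from the scenario's truth.

    Returns the (noisy) :class:`ScanRecord` plus a ground-truth sidecar
    dict holding the rate constants, the derived clearance functionals and
    noise-free end-of-scan amounts (a dissection stand-in).
    """
    phys = phys or PhysiologyConstants()
    k = scn.truth
    geom = ScanGeometry(
        body_weight=scn.bw,
        dose_a0=scn.dose,
        infusion_duration=scn.infusion_duration,
        frame_grid=tuple(scn.frame_schedule),
    )
    obs = frame_averaged_observations(k, geom, phys)
    v_p = plasma_volume(scn.bw, phys)

    clean: dict[RegionKind, tuple[np.ndarray, CurveKind]] = {
        RegionKind.BLOOD: (
            obs[RegionKind.PLASMA] / v_p * (1.0 - phys.hematocrit),
            CurveKind.CONCENTRATION,
        ),
        RegionKind.LIVER: (
            obs[RegionKind.LIVER] / (phys.v_liver * scn.bw),
            CurveKind.CONCENTRATION,
        ),
        RegionKind.GI: (obs[RegionKind.GI], CurveKind.AMOUNT),
        RegionKind.KIDNEY: (
            obs[RegionKind.KIDNEY] / (phys.v_kidney * scn.bw),
            CurveKind.CONCENTRATION,
        ),
        RegionKind.TISSUE: (
            obs[RegionKind.TISSUE] / k.v_tissue,
            CurveKind.CONCENTRATION,
        ),
    }
    if scn.include_urine:
        clean[RegionKind.URINE] = (obs[RegionKind.URINE], CurveKind.AMOUNT)

    rng = np.random.default_rng(scn.seed)
    curves: dict[RegionKind, RegionCurve] = {}
    n = len(scn.frame_schedule)
    for region in _NOISE_ORDER:
        if region not in clean:
            continue
        values, kind = clean[region]
        noisy = values * _lognormal_factors(rng, scn.cv_for(region), n)
        curves[region] = RegionCurve(noisy, kind)

    scan = ScanRecord(
        scan_id=scn.scan_id,
        body_weight=scn.bw,
        dose_a0=scn.dose,
        infusion_duration=scn.infusion_duration,
        frame_grid=tuple(scn.frame_schedule),
        curves=curves,
        group_label=scn.group_label,
        tracer_label=scn.tracer_label,
    )
    truth = {
        "rate_constants": {
            name: float(getattr(k, name))
            for name in (
                "k_bh1", "k_h1b", "k_h1h2", "k_h2g", "k_gh1", "k_bg",
                "k_br1", "k_r1b", "k_r1r2", "k_r2r1", "k_r1u",
                "k_bt", "k_tb1", "k_tb2", "f_bt1", "v_tissue",
            )
        },
        "derived": {
            "cl_h_ul_min": cl_hepatic(k, v_p),
            "cl_r_ul_min": cl_renal(k, v_p),
            "d_tissue": d_tissue(k, v_p),
        },
        "dissection_amounts_kbq": {
            region.value: float(values[-1]) for region, (values, _) in clean.items()
        },
        "seed": scn.seed,
        "noise_cv": scn.noise_cv if np.isscalar(scn.noise_cv) else {
            r.value: v for r, v in scn.noise_cv.items()
        },
    }
    return scan, truth


def write_scenario_files(
    scn: SyntheticScenario,
    out_dir: Path | str,
    phys: PhysiologyConstants | None = None,
) -> dict[str, Path]:
    """Generate a scan and write TAC table, sidecar config and ground
    truth under ``out_dir``.  Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan, truth = generate_scan(scn, phys)
    tac_path = out_dir / f"{scn.scan_id}.csv"
    write_tac_table(scan, tac_path)
    truth_path = out_dir / f"{scn.scan_id}.truth.yaml"
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return {
        "tac": tac_path,
        "config": out_dir / f"{scn.scan_id}.config.yaml",
        "truth": truth_path,
    }


def _hepatic_backflux(k_bh1: float, k_h1h2: float, cl_h_ul: float, v_p: float) -> float:
    """k_h1b that makes cl_hepatic hit the target (µl/min)."""
    frac = cl_h_ul / (k_bh1 * v_p * 1000.0)
    if not 0 < frac < 1:
        raise ValidationError("hepatic target not reachable with this k_bh1")
    return k_h1h2 * (1.0 - frac) / frac


def _renal_urine_rate(
    k_br1: float, k_r1b: float, ratio_r1r2: float, cl_r_ul: float, v_p: float
) -> float:
    """k_r1u that makes cl_renal hit the target given k_r1r2/k_r2r1."""
    frac = cl_r_ul / (k_br1 * v_p * 1000.0)
    if not 0 < frac < 1:
        raise ValidationError("renal target not reachable with this k_br1")
    k_eff = k_r1b * frac / (1.0 - frac)
    return k_eff * (1.0 + ratio_r1r2)


def _tissue_efflux2(
    k_bt: float, f_bt1: float, k_tb1: float, d_target: float, v_p: float, v_t: float
) -> float:
    """k_tb2 that makes d_tissue hit the target."""
    bracket = d_target * v_t / v_p
    rest = bracket - f_bt1 * k_bt / k_tb1
    if rest <= 0:
        raise ValidationError("tissue distribution target not reachable")
    return (1.0 - f_bt1) * k_bt / rest


def scenario_presets(phys: PhysiologyConstants | None = None) -> dict[str, SyntheticScenario]:
    """Named scenarios whose derived clearances sit at the magnitudes of
    the two study arms: a control-like truth (CL_H ~ 35, CL_R ~ 12 µl/min,
    D_tissue ~ 0.10) and a transporter-inhibited truth (CL_H ~ 17,
    CL_R ~ 20 µl/min, D_tissue ~ 0.14) at 20 g body weight, with no
    transintestinal route (k_bg = 0).
    """
    phys = phys or PhysiologyConstants()
    bw = 20.0
    v_p = plasma_volume(bw, phys)

    # truths are solved from the clearance functionals so the targets hold
    # exactly by construction
    v_t_ctrl = 0.74 * bw
    control = RateConstantSet(
        k_bh1=0.2,
        k_h1h2=0.05,
        k_h1b=_hepatic_backflux(0.2, 0.05, 35.2, v_p),
        k_h2g=0.05,
        k_gh1=0.0077,
        k_bg=0.0,
        k_br1=0.1,
        k_r1b=0.3,
        k_r1r2=0.05,
        k_r2r1=0.05,
        k_r1u=_renal_urine_rate(0.1, 0.3, 1.0, 11.9, v_p),
        k_bt=0.2,
        k_tb1=0.3,
        k_tb2=_tissue_efflux2(0.2, 0.5, 0.3, 0.10, v_p, v_t_ctrl),
        f_bt1=0.5,
        v_tissue=v_t_ctrl,
    )

    v_t_csa = 0.79 * bw
    cyclosporine = RateConstantSet(
        k_bh1=0.15,
        k_h1h2=0.03,
        k_h1b=_hepatic_backflux(0.15, 0.03, 17.1, v_p),
        k_h2g=0.04,
        k_gh1=0.008,
        k_bg=0.0,
        k_br1=0.12,
        k_r1b=0.25,
        k_r1r2=0.05,
        k_r2r1=0.05,
        k_r1u=_renal_urine_rate(0.12, 0.25, 1.0, 19.9, v_p),
        k_bt=0.25,
        k_tb1=0.1,
        k_tb2=_tissue_efflux2(0.25, 0.5, 0.1, 0.14, v_p, v_t_csa),
        f_bt1=0.5,
        v_tissue=v_t_csa,
    )

    return {
        "mt107_control_like": SyntheticScenario(
            truth=control,
            bw=bw,
            dose=7.1,
            group_label="control",
            scan_id="mt107_control_like",
        ),
        "mt107_cyclosporine_like": SyntheticScenario(
            truth=cyclosporine,
            bw=bw,
            dose=11.7,
            group_label="cyclosporine",
            scan_id="mt107_cyclosporine_like",
        ),
    }
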