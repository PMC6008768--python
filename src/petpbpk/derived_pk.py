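"""Clearance and distribution functionals of the fitted rate constants,
and between-group statistics.

Hepatobiliary clearance is the plasma-to-liver uptake scaled by the
probability that hepatic tracer proceeds irreversibly rather than
refluxing; renal clearance collapses the two kidney compartments into one
with a mass-ratio correction.  Both are referenced to the plasma volume
and reported in µl/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import PhysiologyConstants, ScanRecord, ValidationError, plasma_volume
from .pbpk_model import RateConstantSet

__all__ = [
    "DerivedPK",
    "GroupComparison",
    "cl_hepatic",
    "cl_renal",
    "d_tissue",
    "derive_all",
    "compare_groups",
]


@dataclass(frozen=True)
class DerivedPK:
    cl_h: float  # µl/min
    cl_r: float  # µl/min
    cl_total: float  # µl/min, cl_h + cl_r (+ cl_ti when k_bg > 0)
    cl_ti: float  # µl/min, transintestinal
    e_h: float  # dimensionless
    cl_r_over_gfr: float
    cl_h_over_cl_r: float
    d_tissue: float


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def cl_hepatic(k: RateConstantSet, v_plasma: float) -> float:
    """Hepatobiliary clearance in µl/min:
    ``k_bh1 * k_h1h2 / (k_h1b + k_h1h2) * v_plasma * 1000``."""
    denom = k.k_h1b + k.k_h1h2
    if denom <= 0:
        if k.k_bh1 == 0:
            return 0.0
        raise ValidationError("k_h1b + k_h1h2 must be positive when k_bh1 > 0")
    return k.k_bh1 * k.k_h1h2 / denom * v_plasma * 1000.0


def cl_renal(k: RateConstantSet, v_plasma: float) -> float:
    """Renal clearance in µl/min, with the two kidney compartments merged:
    ``k_eff = k_r1u / (1 + k_r1r2/k_r2r1)`` and
    ``CL_R = k_br1 * k_eff / (k_r1b + k_eff) * v_plasma * 1000``."""
    if k.k_r1r2 > 0 and k.k_r2r1 == 0:
        raise ValidationError("k_r2r1 must be positive when k_r1r2 > 0 (irreversible trap)")
    k_eff = k.k_r1u / (1.0 + (k.k_r1r2 / k.k_r2r1 if k.k_r1r2 > 0 else 0.0))
    denom = k.k_r1b + k_eff
    if denom <= 0:
        if k.k_br1 == 0:
            return 0.0
        raise ValidationError("k_r1b + effective k_r1u must be positive when k_br1 > 0")
    return k.k_br1 * k_eff / denom * v_plasma * 1000.0


def d_tissue(k: RateConstantSet, v_plasma: float) -> float:
    """Equilibrium tissue-to-plasma distribution coefficient:
    ``[f_bt1*k_bt/k_tb1 + (1-f_bt1)*k_bt/k_tb2] * v_plasma / v_tissue``."""
    total = 0.0
    for frac, k_out in ((k.f_bt1, k.k_tb1), (1.0 - k.f_bt1, k.k_tb2)):
        if frac * k.k_bt == 0.0:
            continue
        if k_out <= 0:
            raise ValidationError("zero tissue efflux with non-zero influx fraction")
        total += frac * k.k_bt / k_out
    return total * v_plasma / k.v_tissue


def derive_all(
    k: RateConstantSet,
    scan: ScanRecord,
    phys: PhysiologyConstants | None = None,
) -> DerivedPK:
    """All derived quantities for one fitted scan."""
    phys = phys or PhysiologyConstants()
    v_p = plasma_volume(scan.body_weight, phys)
    clh = cl_hepatic(k, v_p)
    clr = cl_renal(k, v_p)
    cl_ti = k.k_bg * v_p * 1000.0
    return DerivedPK(
        cl_h=clh,
        cl_r=clr,
        cl_total=clh + clr + cl_ti,
        cl_ti=cl_ti,
        e_h=clh / (phys.q_p_hepatic * 1000.0),
        cl_r_over_gfr=clr / phys.gfr,
        cl_h_over_cl_r=clh / clr if clr > 0 else float("inf"),
        d_tissue=d_tissue(k, v_p),
    )


def compare_groups(values_a, values_b) -> GroupComparison:
    """Homoscedastic (pooled-variance) two-tailed two-sample t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least two values")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    degenerate = False
    if pooled == 0.0:
        degenerate = True
        if np.isclose(a.mean(), b.mean()):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(t_stat), float(p)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p < 0.05),
        degenerate=degenerate,
    )
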