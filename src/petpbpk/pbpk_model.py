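"""Whole-body compartment model: blood plasma (B), liver (H1 reversible,
H2 irreversible), gallbladder+intestine (G), kidneys (R1, R2), peripheral
tissue (T1, T2) and urine (U).

Transfers are first order; tracer enters B as a constant infusion of
duration ``T`` at rate ``dose/T``.  All compartments start at zero.  The
transintestinal route B -> G (``k_bg``) is off by default.

Two solution routes are provided:

* :func:`simulate` — adaptive ODE integration (the general contract,
  relative tolerance <= 1e-8), returning a dense :class:`StateTrajectory`
  with cumulative-flux auxiliary states.
* :func:`frame_averaged_observations` — an exact piecewise
  matrix-exponential propagator for the linear system that returns only
  frame-averaged observed amounts.  It is the fast path used by the fit
  engine and is tested for agreement with :func:`simulate` + :func:`observe`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .core_data import PhysiologyConstants, RegionKind, ScanRecord, ValidationError, plasma_volume

__all__ = [
    "RateConstantSet",
    "StateTrajectory",
    "ExcretionSplit",
    "ScanGeometry",
    "IntegrationError",
    "COMPARTMENTS",
    "transfer_matrix",
    "ode_rhs",
    "simulate",
    "observe",
    "frame_averaged_observations",
    "excretion_split",
]

#: State ordering used everywhere.
COMPARTMENTS = ("B", "H1", "H2", "G", "R1", "R2", "T1", "T2", "U")

_IDX = {name: i for i, name in enumerate(COMPARTMENTS)}


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message echoes the parameters."""


@dataclass(frozen=True)
class ScanGeometry:
    """The scan attributes the simulator needs, without curves.

    :func:`simulate`, :func:`observe` and
    :func:`frame_averaged_observations` accept either a full
    :class:`~petpbpk.core_data.ScanRecord` or this lightweight stand-in.
    """

    body_weight: float  # g
    dose_a0: float  # MBq
    infusion_duration: float  # min
    frame_grid: tuple[tuple[float, float], ...]

    @property
    def n_frames(self) -> int:
        return len(self.frame_grid)

    @property
    def frame_starts(self) -> np.ndarray:
        return np.array([a for a, _ in self.frame_grid])

    @property
    def frame_ends(self) -> np.ndarray:
        return np.array([b for _, b in self.frame_grid])


@dataclass(frozen=True)
class RateConstantSet:
    """First-order mass-transfer rate constants (1/min) plus the tissue
    influx split ``f_bt1`` and the peripheral-tissue volume ``v_tissue``
    (cm^3).  ``k_bt`` is the total plasma-to-tissue rate constant; the
    fraction ``f_bt1`` of it feeds T1 and the rest T2."""

    k_bh1: float = 0.0
    k_h1b: float = 0.0
    k_h1h2: float = 0.0
    k_h2g: float = 0.0
    k_gh1: float = 0.0
    k_bg: float = 0.0
    k_br1: float = 0.0
    k_r1b: float = 0.0
    k_r1r2: float = 0.0
    k_r2r1: float = 0.0
    k_r1u: float = 0.0
    k_bt: float = 0.0
    k_tb1: float = 0.0
    k_tb2: float = 0.0
    f_bt1: float = 0.5
    v_tissue: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("k_") and getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be non-negative")
        if not 0.0 <= self.f_bt1 <= 1.0:
            raise ValidationError("f_bt1 must lie in [0, 1]")
        if self.v_tissue <= 0:
            raise ValidationError("v_tissue must be positive")

    def replace(self, **kwargs) -> "RateConstantSet":
        return replace(self, **kwargs)


def transfer_matrix(k: RateConstantSet) -> np.ndarray:
    """9x9 matrix M with d(state)/dt = M @ state + input."""
    m = np.zeros((9, 9))
    B, H1, H2, G, R1, R2, T1, T2, U = range(9)
    m[B, B] = -(k.k_bh1 + k.k_br1 + k.k_bg + k.k_bt)
    m[B, H1] = k.k_h1b
    m[B, R1] = k.k_r1b
    m[B, T1] = k.k_tb1
    m[B, T2] = k.k_tb2
    m[H1, B] = k.k_bh1
    m[H1, G] = k.k_gh1
    m[H1, H1] = -(k.k_h1b + k.k_h1h2)
    m[H2, H1] = k.k_h1h2
    m[H2, H2] = -k.k_h2g
    m[G, H2] = k.k_h2g
    m[G, B] = k.k_bg
    m[G, G] = -k.k_gh1
    m[R1, B] = k.k_br1
    m[R1, R2] = k.k_r2r1
    m[R1, R1] = -(k.k_r1b + k.k_r1r2 + k.k_r1u)
    m[R2, R1] = k.k_r1r2
    m[R2, R2] = -k.k_r2r1
    m[T1, B] = k.f_bt1 * k.k_bt
    m[T1, T1] = -k.k_tb1
    m[T2, B] = (1.0 - k.f_bt1) * k.k_bt
    m[T2, T2] = -k.k_tb2
    m[U, R1] = k.k_r1u
    return m


def ode_rhs(state: np.ndarray, t: float, k: RateConstantSet, dose: float, T: float) -> np.ndarray:
    """Right-hand side for the 9 compartment amounts at time ``t`` (min).

    ``dose`` and the state share the same activity unit; the infusion
    contributes ``dose/T`` to B for ``0 <= t <= T``.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < -1e-9 * max(1.0, abs(dose))):
        raise IntegrationError("negative compartment amount encountered")
    rhs = transfer_matrix(k) @ state
    if 0.0 <= t <= T:
        rhs[_IDX["B"]] += dose / T
    return rhs


@dataclass(frozen=True)
class StateTrajectory:
    """Dense solution: per-compartment amounts plus cumulative fluxes.

    ``amounts`` has shape (9, n_times) in COMPARTMENTS order.  The three
    cumulative fluxes are the time integrals of k_h2g*H2 (biliary
    secretion into G), k_gh1*G (reabsorption) and k_bg*B (transintestinal
    secretion).
    """

    times: np.ndarray
    amounts: np.ndarray
    cum_biliary: np.ndarray
    cum_reabsorbed: np.ndarray
    cum_transintestinal: np.ndarray
    dose: float  # kBq
    infusion_duration: float  # min

    def compartment(self, name: str) -> np.ndarray:
        return self.amounts[_IDX[name]]

    @property
    def total(self) -> np.ndarray:
        return self.amounts.sum(axis=0)


class ExcretionSplit(NamedTuple):
    hepatobiliary: float  # cumulative H2 -> G flux, kBq
    renal: float  # U at end of scan, kBq
    reabsorbed: float  # cumulative G -> H1 flux, kBq
    transintestinal: float  # cumulative B -> G flux, kBq


def _time_grid(scan: ScanRecord, points_per_frame: int) -> np.ndarray:
    """Dense grid from 0 through the last frame end, splitting at the
    infusion end and containing every frame edge."""
    T = scan.infusion_duration
    pieces = [np.linspace(0.0, T, 5)]
    prev = T
    for a, b in scan.frame_grid:
        if a > prev + 1e-12:
            pieces.append(np.linspace(prev, a, max(2, points_per_frame // 2)))
        pieces.append(np.linspace(a, b, points_per_frame + 1))
        prev = b
    grid = np.unique(np.concatenate(pieces))
    return grid


def simulate(
    k: RateConstantSet,
    scan: ScanRecord,
    phys: PhysiologyConstants | None = None,
    rtol: float = 1e-9,
    points_per_frame: int = 20,
) -> StateTrajectory:
    """Integrate the compartment system over the scan.

    The infusion discontinuity at ``t = T`` is handled by splitting the
    integration; cumulative fluxes ride along as auxiliary states.
    """
    dose_kbq = scan.dose_a0 * 1000.0
    T = scan.infusion_duration
    m = transfer_matrix(k)
    grid = _time_grid(scan, points_per_frame)

    # 9 amounts + 3 cumulative fluxes
    def rhs(t: float, z: np.ndarray) -> np.ndarray:
        y = z[:9]
        dy = m @ y
        if t <= T:
            dy = dy.copy()
            dy[_IDX["B"]] += dose_kbq / T
        flux = np.array(
            [k.k_h2g * y[_IDX["H2"]], k.k_gh1 * y[_IDX["G"]], k.k_bg * y[_IDX["B"]]]
        )
        return np.concatenate([dy, flux])

    atol = max(dose_kbq, 1.0) * 1e-12
    z0 = np.zeros(12)
    out_t: list[np.ndarray] = []
    out_z: list[np.ndarray] = []
    for lo, hi in ((0.0, T), (T, float(grid[-1]))):
        t_eval = grid[(grid >= lo - 1e-12) & (grid <= hi + 1e-12)]
        sol = solve_ivp(
            rhs, (lo, hi), z0, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval, max_step=hi - lo
        )
        if not sol.success:
            raise IntegrationError(f"solver failed ({sol.message}) for parameters {k}")
        out_t.append(sol.t)
        out_z.append(sol.y)
        z0 = sol.y[:, -1]
    times = np.concatenate(out_t)
    z = np.concatenate(out_z, axis=1)
    keep = np.concatenate([[True], np.diff(times) > 1e-12])
    times, z = times[keep], z[:, keep]
    amounts = np.clip(z[:9], 0.0, None)  # solver tolerance can leave tiny negatives
    return StateTrajectory(
        times=times,
        amounts=amounts,
        cum_biliary=z[9],
        cum_reabsorbed=z[10],
        cum_transintestinal=z[11],
        dose=dose_kbq,
        infusion_duration=T,
    )


def _frame_average(times: np.ndarray, values: np.ndarray, a: float, b: float) -> float:
    if a < times[0] - 1e-9 or b > times[-1] + 1e-9:
        raise ValidationError("trajectory grid does not cover the frame")
    mask = (times > a) & (times < b)
    # frame edges enter by interpolation so sparse grids stay unbiased
    t = np.concatenate([[a], times[mask], [b]])
    v = np.concatenate([[np.interp(a, times, values)], values[mask], [np.interp(b, times, values)]])
    return float(np.trapezoid(v, t) / (b - a))


def observe(
    traj: StateTrajectory,
    k: RateConstantSet,
    scan: ScanRecord,
    phys: PhysiologyConstants | None = None,
) -> dict[RegionKind, np.ndarray]:
    """Frame-averaged observed amounts (kBq) per region.

    Vascular activity (``v_blood`` times the organ volume times the blood
    concentration) is added to liver, kidney and peripheral tissue; G and
    U carry no blood term.  Blood concentration derives from B via the
    plasma volume and hematocrit.
    """
    phys = phys or PhysiologyConstants()
    bw = scan.body_weight
    v_p = plasma_volume(bw, phys)
    c_blood = traj.compartment("B") / v_p * (1.0 - phys.hematocrit)

    dense = {
        RegionKind.PLASMA: traj.compartment("B"),
        RegionKind.LIVER: traj.compartment("H1")
        + traj.compartment("H2")
        + phys.v_blood * (phys.v_liver * bw) * c_blood,
        RegionKind.GI: traj.compartment("G"),
        RegionKind.KIDNEY: traj.compartment("R1")
        + traj.compartment("R2")
        + phys.v_blood * (phys.v_kidney * bw) * c_blood,
        RegionKind.TISSUE: traj.compartment("T1")
        + traj.compartment("T2")
        + phys.v_blood * k.v_tissue * c_blood,
        RegionKind.URINE: traj.compartment("U"),
    }
    out: dict[RegionKind, np.ndarray] = {}
    for region, values in dense.items():
        out[region] = np.array(
            [_frame_average(traj.times, values, a, b) for a, b in scan.frame_grid]
        )
    return out


def excretion_split(traj: StateTrajectory) -> ExcretionSplit:
    """End-of-scan excretion bookkeeping from the cumulative fluxes."""
    return ExcretionSplit(
        hepatobiliary=float(traj.cum_biliary[-1]),
        renal=float(traj.compartment("U")[-1]),
        reabsorbed=float(traj.cum_reabsorbed[-1]),
        transintestinal=float(traj.cum_transintestinal[-1]),
    )


# ---------------------------------------------------------------------------
# Exact piecewise propagator (fast path for fitting)
# ---------------------------------------------------------------------------


def _expm_cached(a_aug: np.ndarray, dt: float, cache: dict[float, np.ndarray]) -> np.ndarray:
    key = round(dt, 12)
    if key not in cache:
        cache[key] = expm(a_aug * dt)
    return cache[key]


def frame_averaged_observations(
    k: RateConstantSet,
    scan: ScanRecord,
    phys: PhysiologyConstants | None = None,
) -> dict[RegionKind, np.ndarray]:
    """Frame-averaged observed amounts via exact linear propagation.

    The state is augmented with running integrals of every compartment so
    frame averages are exact; the constant infusion on ``[0, T]`` is
    handled with one extra constant state.  Agrees with
    :func:`simulate` + :func:`observe` to solver tolerance.
    """
    phys = phys or PhysiologyConstants()
    bw = scan.body_weight
    v_p = plasma_volume(bw, phys)
    dose_kbq = scan.dose_a0 * 1000.0
    T = scan.infusion_duration
    m = transfer_matrix(k)

    # infusion phase: z = [y, Y, 1] with dy = M y + u, dY = y
    a_inf = np.zeros((19, 19))
    a_inf[:9, :9] = m
    a_inf[9:18, :9] = np.eye(9)
    a_inf[_IDX["B"], 18] = dose_kbq / T
    z = expm(a_inf * T) @ np.concatenate([np.zeros(18), [1.0]])
    state = z[:18]

    # decay phase: propagate between consecutive breakpoints
    a_free = np.zeros((18, 18))
    a_free[:9, :9] = m
    a_free[9:18, :9] = np.eye(9)
    breakpoints = [T]
    for a, b in scan.frame_grid:
        if a > breakpoints[-1] + 1e-12:
            breakpoints.append(a)
        breakpoints.append(b)
    cache: dict[float, np.ndarray] = {}
    states = {round(breakpoints[0], 10): state.copy()}
    for prev, nxt in zip(breakpoints[:-1], breakpoints[1:]):
        state = _expm_cached(a_free, nxt - prev, cache) @ state
        states[round(nxt, 10)] = state.copy()

    # per-frame compartment averages from integral differences
    avg = np.empty((9, scan.n_frames))
    for j, (a, b) in enumerate(scan.frame_grid):
        ya = states[round(a, 10)][9:18]
        yb = states[round(b, 10)][9:18]
        avg[:, j] = (yb - ya) / (b - a)

    c_blood_avg = avg[_IDX["B"]] / v_p * (1.0 - phys.hematocrit)
    return {
        RegionKind.PLASMA: avg[_IDX["B"]],
        RegionKind.LIVER: avg[_IDX["H1"]]
        + avg[_IDX["H2"]]
        + phys.v_blood * (phys.v_liver * bw) * c_blood_avg,
        RegionKind.GI: avg[_IDX["G"]],
        RegionKind.KIDNEY: avg[_IDX["R1"]]
        + avg[_IDX["R2"]]
        + phys.v_blood * (phys.v_kidney * bw) * c_blood_avg,
        RegionKind.TISSUE: avg[_IDX["T1"]]
        + avg[_IDX["T2"]]
        + phys.v_blood * k.v_tissue * c_blood_avg,
        RegionKind.URINE: avg[_IDX["U"]],
    }
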