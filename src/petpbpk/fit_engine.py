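"""Multistart bounded weighted least-squares fitting of the whole-body
model to prepared amount curves, plus the bounds-refinement step.

The objective is the sum over regions (plasma, liver, gi, kidney, tissue)
and frames of squared weighted residuals; the residuals of the first two
frames of plasma, liver and kidney are multiplied by 5 before squaring.
Urine is never fitted.  Local minimization runs from ``n_starts`` seeded
random bounded starting points and the best optimum is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core_data import PhysiologyConstants, RegionKind, ValidationError, plasma_volume
from .pbpk_model import RateConstantSet, frame_averaged_observations
from .tac_preprocess import PreparedScan

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "FIT_PARAM_NAMES",
    "initial_bounds",
    "objective",
    "multistart_fit",
    "refine_bounds",
]

#: Order of the full parameter vector.
FIT_PARAM_NAMES = (
    "k_bh1",
    "k_h1b",
    "k_h1h2",
    "k_h2g",
    "k_gh1",
    "k_bg",
    "k_br1",
    "k_r1b",
    "k_r1r2",
    "k_r2r1",
    "k_r1u",
    "k_bt",
    "k_tb1",
    "k_tb2",
    "f_bt1",
    "v_tissue",
)

_FITTED_REGIONS = (
    RegionKind.PLASMA,
    RegionKind.LIVER,
    RegionKind.GI,
    RegionKind.KIDNEY,
    RegionKind.TISSUE,
)


class FitError(RuntimeError):
    """Every multistart attempt failed."""


@dataclass(frozen=True)
class FitConfig:
    """Fitting protocol configuration.

    ``n_starts`` defaults to the full 128-start protocol; tests and
    desk-scale runs pass smaller values.  ``lower_bounds``/``upper_bounds``
    override individual entries of the physiological initial bounds (this
    is how refined bounds are applied).
    """

    n_starts: int = 128
    seed: int = 0
    weight_factor: float = 5.0
    weighted_regions: tuple[RegionKind, ...] = (
        RegionKind.PLASMA,
        RegionKind.LIVER,
        RegionKind.KIDNEY,
    )
    weighted_frames: int = 2
    lower_bounds: Mapping[str, float] = field(default_factory=dict)
    upper_bounds: Mapping[str, float] = field(default_factory=dict)
    fit_k_bg: bool = False
    v_tissue_bounds_per_g: tuple[float, float] = (0.2, 1.5)
    default_k_upper: float = 10.0
    rate_floor: float = 1e-4  # lower edge of log-uniform start draws
    max_nfev: int | None = None
    ftol: float = 1e-10
    xtol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValidationError("n_starts must be at least 1")
        if self.weight_factor < 1:
            raise ValidationError("weight_factor must be >= 1")
        for name in set(self.lower_bounds) | set(self.upper_bounds):
            if name not in FIT_PARAM_NAMES:
                raise ValidationError(f"unknown parameter {name!r} in bounds")
        for name in set(self.lower_bounds) & set(self.upper_bounds):
            if self.lower_bounds[name] > self.upper_bounds[name]:
                raise ValidationError(f"lower bound exceeds upper bound for {name!r}")


@dataclass(frozen=True)
class FitResult:
    best_params: RateConstantSet
    objective: float
    per_start_objectives: tuple[float, ...]
    residuals: Mapping[RegionKind, np.ndarray]
    n_starts: int
    seed: int
    n_failed: int
    bounds: Mapping[str, tuple[float, float]]


def initial_bounds(
    phys: PhysiologyConstants, bw: float, cfg: FitConfig
) -> dict[str, tuple[float, float]]:
    """Physiological parameter bounds for one scan.

    Uptake rate constants into liver and kidney are capped by the organ
    plasma flow divided by the plasma volume; other rate constants get a
    configurable generic cap; ``k_bg`` is fixed at zero unless
    ``fit_k_bg`` is set.
    """
    if bw <= 0:
        raise ValidationError("body weight must be positive")
    v_p = plasma_volume(bw, phys)
    bounds: dict[str, tuple[float, float]] = {}
    for name in FIT_PARAM_NAMES:
        if name.startswith("k_"):
            bounds[name] = (0.0, cfg.default_k_upper)
    bounds["k_bh1"] = (0.0, phys.q_p_hepatic / v_p)
    bounds["k_br1"] = (0.0, phys.q_p_renal / v_p)
    if not cfg.fit_k_bg:
        bounds["k_bg"] = (0.0, 0.0)
    bounds["f_bt1"] = (0.0, 1.0)
    lo_vt, hi_vt = cfg.v_tissue_bounds_per_g
    bounds["v_tissue"] = (lo_vt * bw, hi_vt * bw)
    for name, value in cfg.lower_bounds.items():
        bounds[name] = (value, bounds[name][1])
    for name, value in cfg.upper_bounds.items():
        bounds[name] = (bounds[name][0], value)
    for name, (lo, hi) in bounds.items():
        if lo > hi:
            raise ValidationError(f"lower bound exceeds upper bound for {name!r}")
    return bounds


def _weights(prepared: PreparedScan, cfg: FitConfig) -> dict[RegionKind, np.ndarray]:
    n = prepared.scan.n_frames
    weights = {}
    for region in _FITTED_REGIONS:
        w = np.ones(n)
        if region in cfg.weighted_regions:
            w[: cfg.weighted_frames] = cfg.weight_factor
        weights[region] = w
    return weights


def _observed(prepared: PreparedScan, v_tissue: float) -> dict[RegionKind, np.ndarray]:
    return {
        RegionKind.PLASMA: prepared.a_plasma,
        RegionKind.LIVER: prepared.a_liver,
        RegionKind.GI: prepared.a_gi,
        RegionKind.KIDNEY: prepared.a_kidney,
        RegionKind.TISSUE: prepared.tissue_amount(v_tissue),
    }


def _residual_blocks(
    k: RateConstantSet,
    prepared: PreparedScan,
    phys: PhysiologyConstants,
) -> dict[RegionKind, np.ndarray]:
    model = frame_averaged_observations(k, prepared.scan, phys)
    obs = _observed(prepared, k.v_tissue)
    return {region: model[region] - obs[region] for region in _FITTED_REGIONS}


def objective(
    k: RateConstantSet,
    prepared: PreparedScan,
    cfg: FitConfig,
    phys: PhysiologyConstants | None = None,
) -> float:
    """Weighted sum of squared residuals; +inf when simulation fails."""
    phys = phys or PhysiologyConstants()
    try:
        blocks = _residual_blocks(k, prepared, phys)
    except Exception:
        return float("inf")
    weights = _weights(prepared, cfg)
    total = 0.0
    for region, res in blocks.items():
        total += float(np.sum((weights[region] * res) ** 2))
    return total if np.isfinite(total) else float("inf")


def _params_from_vector(x: np.ndarray, free: Sequence[str], fixed: Mapping[str, float]) -> RateConstantSet:
    values = dict(fixed)
    values.update(dict(zip(free, x)))
    return RateConstantSet(**values)


def multistart_fit(
    prepared: PreparedScan,
    cfg: FitConfig,
    phys: PhysiologyConstants | None = None,
    initial_guesses: Sequence[RateConstantSet] = (),
) -> FitResult:
    """Bounded local least squares from ``cfg.n_starts`` seeded random
    starts; rate constants are drawn log-uniformly above ``rate_floor``,
    ``f_bt1`` and ``v_tissue`` uniformly.  Fully reproducible per seed.

    ``initial_guesses`` are run before the random starts (counting toward
    ``n_starts``); refitting under refined bounds passes the previous best
    here so the objective can never get worse.
    """
    phys = phys or PhysiologyConstants()
    bounds = initial_bounds(phys, prepared.scan.body_weight, cfg)
    free = [name for name in FIT_PARAM_NAMES if bounds[name][0] < bounds[name][1]]
    fixed = {name: bounds[name][0] for name in FIT_PARAM_NAMES if name not in free}
    lo = np.array([bounds[n][0] for n in free])
    hi = np.array([bounds[n][1] for n in free])
    weights = _weights(prepared, cfg)
    w_vec = np.concatenate([weights[r] for r in _FITTED_REGIONS])
    big = 1e8

    def residuals(x: np.ndarray) -> np.ndarray:
        k = _params_from_vector(x, free, fixed)
        try:
            blocks = _residual_blocks(k, prepared, phys)
        except Exception:
            return np.full(w_vec.size, big)
        vec = w_vec * np.concatenate([blocks[r] for r in _FITTED_REGIONS])
        return vec if np.all(np.isfinite(vec)) else np.full(w_vec.size, big)

    rng = np.random.default_rng(cfg.seed)
    starting_points: list[np.ndarray] = []
    for guess in initial_guesses[: cfg.n_starts]:
        x0 = np.array([np.clip(getattr(guess, name), bounds[name][0], bounds[name][1]) for name in free])
        starting_points.append(x0)
    for _ in range(cfg.n_starts - len(starting_points)):
        x0 = np.empty(len(free))
        for i, name in enumerate(free):
            a, b = lo[i], hi[i]
            if name.startswith("k_"):
                floor = max(a, cfg.rate_floor)
                x0[i] = np.exp(rng.uniform(np.log(floor), np.log(b))) if b > floor else b
            else:
                x0[i] = rng.uniform(a, b)
        starting_points.append(x0)

    per_start: list[float] = []
    best_x: np.ndarray | None = None
    best_cost = np.inf
    n_failed = 0
    failures: list[str] = []
    for x0 in starting_points:
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=cfg.ftol,
                xtol=cfg.xtol,
                max_nfev=cfg.max_nfev,
            )
            cost = float(2.0 * res.cost)  # least_squares cost is 0.5 * SSR
        except Exception as exc:
            n_failed += 1
            failures.append(str(exc))
            per_start.append(float("inf"))
            continue
        per_start.append(cost)
        if cost < best_cost:
            best_cost = cost
            best_x = res.x
    if best_x is None:
        raise FitError("all multistart attempts failed: " + "; ".join(failures[:3]))
    best_params = _params_from_vector(best_x, free, fixed)
    residual_blocks = _residual_blocks(best_params, prepared, phys)
    return FitResult(
        best_params=best_params,
        objective=best_cost,
        per_start_objectives=tuple(per_start),
        residuals=residual_blocks,
        n_starts=cfg.n_starts,
        seed=cfg.seed,
        n_failed=n_failed,
        bounds=bounds,
    )


def refine_bounds(
    results: Sequence[FitResult], cfg: FitConfig
) -> dict[str, tuple[float, float]]:
    """Per-tracer refined bounds: 0.5x the minimal and 2x the maximal
    best-fit value of each parameter across scans.  Parameters fixed at
    zero stay fixed; ``f_bt1`` is clipped to [0, 1]."""
    if not results:
        raise ValidationError("refine_bounds requires at least one FitResult")
    refined: dict[str, tuple[float, float]] = {}
    for name in FIT_PARAM_NAMES:
        values = [getattr(r.best_params, name) for r in results]
        lo, hi = 0.5 * min(values), 2.0 * max(values)
        if name == "f_bt1":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        refined[name] = (lo, hi)
    return refined
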