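"""End-to-end study orchestration: prepare -> plasma fit -> compartment
fit -> derived PK -> group summaries and t-tests, with optional bounds
refinement and refitting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import PhysiologyConstants, ScanRecord, ValidationError, read_tac_table
from .derived_pk import DerivedPK, compare_groups, derive_all
from .fit_engine import FIT_PARAM_NAMES, FitConfig, FitResult, multistart_fit, refine_bounds
from .plasma_model import fit_plasma, plasma_derived
from .tac_preprocess import prepare_scan

__all__ = ["StudyConfig", "ScanResult", "StudyReport", "run_study", "refine_and_refit"]

logger = logging.getLogger(__name__)

#: Quantities compared between groups, as columns of the per-scan table.
TESTED_QUANTITIES = (
    "lambda_z",
    "v_z",
    "cl_plasma",
    "cl_h",
    "e_h",
    "cl_r",
    "d_tissue",
    "cl_total",
)


@dataclass(frozen=True)
class StudyConfig:
    """Scan list plus fitting configuration for one study."""

    scans: tuple[tuple[Path, Path | None], ...]  # (tac, optional config) pairs
    fit: FitConfig = field(default_factory=FitConfig)
    phys: PhysiologyConstants = field(default_factory=PhysiologyConstants)
    plasma_n_starts: int = 16
    output_dir: Path | None = None
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValidationError("a study needs at least one scan")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        scans = []
        for entry in raw.get("scans", []):
            if isinstance(entry, str):
                entry = {"tac": entry}
            tac = base / entry["tac"]
            cfg = base / entry["config"] if "config" in entry else None
            scans.append((tac, cfg))
        fit_kwargs = dict(raw.get("fit", {}))
        phys_kwargs = dict(raw.get("physiology", {}))
        out = raw.get("output_dir")
        return cls(
            scans=tuple(scans),
            fit=FitConfig(**fit_kwargs),
            phys=PhysiologyConstants(**phys_kwargs),
            plasma_n_starts=int(raw.get("plasma_n_starts", 16)),
            output_dir=base / out if out else None,
            group_labels=tuple(raw.get("groups", [])),
        )


@dataclass(frozen=True)
class ScanResult:
    scan: ScanRecord
    fit: FitResult
    derived: DerivedPK
    plasma_cl: float
    plasma_t_half: float
    lambda_z: float
    v_z: float

    def row(self) -> dict:
        return {
            "scan_id": self.scan.scan_id,
            "group": self.scan.group_label,
            "tracer": self.scan.tracer_label,
            "body_weight_g": self.scan.body_weight,
            "lambda_z": self.lambda_z,
            "v_z": self.v_z,
            "cl_plasma": self.plasma_cl,
            "t_half": self.plasma_t_half,
            "cl_h": self.derived.cl_h,
            "cl_r": self.derived.cl_r,
            "cl_ti": self.derived.cl_ti,
            "cl_total": self.derived.cl_total,
            "e_h": self.derived.e_h,
            "cl_r_over_gfr": self.derived.cl_r_over_gfr,
            "cl_h_over_cl_r": self.derived.cl_h_over_cl_r,
            "d_tissue": self.derived.d_tissue,
            "objective": self.fit.objective,
        }


@dataclass(frozen=True)
class StudyReport:
    per_scan: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    scan_results: tuple[ScanResult, ...]
    failures: tuple[tuple[str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.failures


def _significance_mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _analyse_scan(
    tac: Path,
    config: Path | None,
    cfg: StudyConfig,
    fit_cfg: FitConfig,
    initial_guesses=(),
) -> ScanResult:
    scan = read_tac_table(tac, config)
    prepared = prepare_scan(scan, cfg.phys)
    plasma = fit_plasma(
        prepared.c_plasma, scan, n_starts=cfg.plasma_n_starts, seed=fit_cfg.seed
    )
    pderived = plasma_derived(plasma)
    fit = multistart_fit(prepared, fit_cfg, cfg.phys, initial_guesses=initial_guesses)
    derived = derive_all(fit.best_params, scan, cfg.phys)
    return ScanResult(
        scan=scan,
        fit=fit,
        derived=derived,
        plasma_cl=pderived.cl,
        plasma_t_half=pderived.t_half,
        lambda_z=plasma.lambdaz,
        v_z=plasma.vz,
    )


def _summarize(results: Sequence[ScanResult]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    per_scan = pd.DataFrame([r.row() for r in results])
    numeric = [c for c in per_scan.columns if per_scan[c].dtype.kind == "f"]
    group_summary = per_scan.groupby("group")[numeric].agg(["mean", "std", "count"])

    rows = []
    groups = sorted(per_scan["group"].unique())
    if len(groups) == 2:
        ga = per_scan[per_scan["group"] == groups[0]]
        gb = per_scan[per_scan["group"] == groups[1]]
        for quantity in TESTED_QUANTITIES:
            a, b = ga[quantity].to_numpy(), gb[quantity].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            cmp_result = compare_groups(a, b)
            rows.append(
                {
                    "quantity": quantity,
                    "group_a": groups[0],
                    "group_b": groups[1],
                    "mean_a": cmp_result.mean_a,
                    "sd_a": cmp_result.sd_a,
                    "mean_b": cmp_result.mean_b,
                    "sd_b": cmp_result.sd_b,
                    "t": cmp_result.t_statistic,
                    "p": cmp_result.p_value,
                    "mark": _significance_mark(cmp_result.p_value),
                }
            )
    comparisons = pd.DataFrame(rows)
    return per_scan, group_summary, comparisons


def _write_report(report: StudyReport, cfg: StudyConfig, fit_cfg: FitConfig) -> None:
    out = cfg.output_dir
    if out is None:
        return
    out.mkdir(parents=True, exist_ok=True)
    report.per_scan.to_csv(out / "per_scan.tsv", sep="\t", index=False, float_format="%.10g")
    report.group_summary.to_csv(out / "group_summary.tsv", sep="\t", float_format="%.10g")
    report.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format="%.10g")
    machine = {
        "version": __version__,
        "seed": fit_cfg.seed,
        "n_starts": fit_cfg.n_starts,
        "per_scan": report.per_scan.to_dict(orient="records"),
        "comparisons": report.comparisons.to_dict(orient="records"),
        "failures": list(report.failures),
        "fits": [
            {
                "scan_id": r.scan.scan_id,
                "objective": r.fit.objective,
                "params": {
                    name: float(getattr(r.fit.best_params, name)) for name in FIT_PARAM_NAMES
                },
            }
            for r in report.scan_results
        ],
    }
    (out / "report.json").write_text(json.dumps(machine, indent=2, sort_keys=True))


def run_study(cfg: StudyConfig, fit_cfg: FitConfig | None = None) -> StudyReport:
    """Analyse every scan of the study and build the summary tables.

    Scan failures do not abort the study; they are reported in
    ``StudyReport.failures`` and the caller decides the exit status.
    """
    fit_cfg = fit_cfg or cfg.fit
    results: list[ScanResult] = []
    failures: list[tuple[str, str]] = []
    for tac, config in cfg.scans:
        try:
            results.append(_analyse_scan(tac, config, cfg, fit_cfg))
        except Exception as exc:
            logger.exception("scan %s failed", tac)
            failures.append((str(tac), str(exc)))
    if not results:
        raise ValidationError("every scan failed: " + "; ".join(m for _, m in failures))
    per_scan, group_summary, comparisons = _summarize(results)
    report = StudyReport(
        per_scan=per_scan,
        group_summary=group_summary,
        comparisons=comparisons,
        scan_results=tuple(results),
        failures=tuple(failures),
    )
    _write_report(report, cfg, fit_cfg)
    return report


def refine_and_refit(cfg: StudyConfig, rounds: int = 1) -> tuple[StudyReport, ...]:
    """Initial study run followed by ``rounds`` of per-tracer bounds
    refinement and refitting.  Returns the report of every round
    (``rounds = 0`` reduces to :func:`run_study`)."""
    reports = [run_study(cfg)]
    fit_cfg = cfg.fit
    for _ in range(rounds):
        latest = reports[-1]
        by_tracer: dict[str, list[FitResult]] = {}
        for r in latest.scan_results:
            by_tracer.setdefault(r.scan.tracer_label, []).append(r.fit)
        # refine per tracer, then refit each scan under its tracer's bounds;
        # the previous best seeds the refit so objectives cannot worsen
        previous = {r.scan.scan_id: r.fit.best_params for r in latest.scan_results}
        results: list[ScanResult] = []
        for tac, config in cfg.scans:
            scan = read_tac_table(tac, config)
            refined = refine_bounds(by_tracer[scan.tracer_label], fit_cfg)
            round_cfg = dataclasses.replace(
                fit_cfg,
                lower_bounds={n: lo for n, (lo, _) in refined.items()},
                upper_bounds={n: hi for n, (_, hi) in refined.items()},
            )
            results.append(
                _analyse_scan(
                    tac, config, cfg, round_cfg,
                    initial_guesses=(previous[scan.scan_id],),
                )
            )
        per_scan, group_summary, comparisons = _summarize(results)
        reports.append(
            StudyReport(
                per_scan=per_scan,
                group_summary=group_summary,
                comparisons=comparisons,
                scan_results=tuple(results),
            )
        )
    _write_report(reports[-1], cfg, fit_cfg)
    return tuple(reports)
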