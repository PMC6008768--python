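"""Domain types, physiological constants and TAC table I/O.

Canonical internal units are minutes, millilitres and kBq for amounts
(injected doses are given in MBq and converted on use).  Clearances are
reported in µl/min.  TAC files store frame times in seconds; they are
converted to minutes on read.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PhysiologyConstants",
    "RegionKind",
    "CurveKind",
    "RegionCurve",
    "ScanRecord",
    "ValidationError",
    "FormatError",
    "plasma_volume",
    "read_tac_table",
    "write_tac_table",
]


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


@dataclass(frozen=True)
class PhysiologyConstants:
    """Mouse physiology used throughout the pipeline.

    Attributes
    ----------
    hematocrit : float
        Blood cell volume fraction (dimensionless).
    v_blood : float
        Specific blood volume, ml blood per g body weight.
    v_liver : float
        Liver volume, cm^3 per g body weight.
    v_kidney : float
        Kidney volume, cm^3 per g body weight.
    q_p_hepatic : float
        Hepatic plasma flow, ml plasma/min.
    q_p_renal : float
        Renal plasma flow, ml plasma/min.
    gfr : float
        Glomerular filtration rate, µl/min.
    """

    hematocrit: float = 0.44
    v_blood: float = 0.0585
    v_liver: float = 0.065
    v_kidney: float = 0.0164
    q_p_hepatic: float = 1.0
    q_p_renal: float = 0.73
    gfr: float = 160.0

    def __post_init__(self) -> None:
        for name in ("v_blood", "v_liver", "v_kidney", "q_p_hepatic", "q_p_renal", "gfr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 0 < self.hematocrit < 1:
            raise ValidationError("hematocrit must lie strictly between 0 and 1")


class RegionKind(str, enum.Enum):
    """Regions appearing in a whole-body scan."""

    PLASMA = "plasma"
    BLOOD = "blood"
    LIVER = "liver"
    GI = "gi"  # gallbladder plus intestine, amount only
    KIDNEY = "kidney"
    TISSUE = "tissue"
    URINE = "urine"  # amount only


class CurveKind(str, enum.Enum):
    CONCENTRATION = "conc"  # kBq/ml
    AMOUNT = "amount"  # kBq


#: Regions for which only amounts make sense (no defined volume).
AMOUNT_ONLY_REGIONS = frozenset({RegionKind.GI, RegionKind.URINE})

#: At least one of blood/plasma plus these regions must be present.
MANDATORY_REGIONS = (RegionKind.LIVER, RegionKind.GI, RegionKind.KIDNEY, RegionKind.TISSUE)


@dataclass(frozen=True)
class RegionCurve:
    """Per-frame values for one region, with declared units."""

    values: np.ndarray
    kind: CurveKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValidationError("curve values must be one-dimensional")
        if np.any(self.values < 0):
            bad = int(np.flatnonzero(self.values < 0)[0])
            raise ValidationError(f"negative curve value at row {bad}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("curve values must be finite")


@dataclass(frozen=True)
class ScanRecord:
    """One scan: frame grid, per-region curves and injection metadata.

    Times are minutes post-injection; frames are half-open intervals
    ``[start, end)`` and must not overlap.  The first frame must not
    start before the end of the tracer infusion.
    """

    scan_id: str
    body_weight: float  # g
    dose_a0: float  # MBq
    frame_grid: tuple[tuple[float, float], ...]
    curves: Mapping[RegionKind, RegionCurve]
    infusion_duration: float = 10.0 / 60.0  # min
    group_label: str = ""
    tracer_label: str = ""

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be positive")
        if self.dose_a0 <= 0:
            raise ValidationError("dose_a0 must be positive")
        if self.infusion_duration <= 0:
            raise ValidationError("infusion_duration must be positive")
        grid = tuple((float(a), float(b)) for a, b in self.frame_grid)
        object.__setattr__(self, "frame_grid", grid)
        if not grid:
            raise ValidationError("frame_grid must not be empty")
        for i, (a, b) in enumerate(grid):
            if b <= a:
                raise ValidationError(f"frame {i} has non-positive duration")
            if i and a < grid[i - 1][1] - 1e-12:
                raise ValidationError(f"frames {i - 1} and {i} overlap or are out of order")
        if grid[0][0] < self.infusion_duration - 1e-12:
            raise ValidationError("first frame starts before the end of infusion")
        curves = dict(self.curves)
        if not curves:
            raise ValidationError("at least a blood or plasma curve is required")
        if RegionKind.BLOOD not in curves and RegionKind.PLASMA not in curves:
            raise ValidationError("a blood or plasma curve is required")
        for region, curve in curves.items():
            region = RegionKind(region)
            if len(curve.values) != len(grid):
                raise ValidationError(
                    f"curve {region.value} has {len(curve.values)} values "
                    f"for {len(grid)} frames"
                )
            if region in AMOUNT_ONLY_REGIONS and curve.kind is not CurveKind.AMOUNT:
                raise ValidationError(f"{region.value} curves must be amounts (kBq)")
        object.__setattr__(self, "curves", curves)

    @property
    def n_frames(self) -> int:
        return len(self.frame_grid)

    @property
    def frame_starts(self) -> np.ndarray:
        return np.array([a for a, _ in self.frame_grid])

    @property
    def frame_ends(self) -> np.ndarray:
        return np.array([b for _, b in self.frame_grid])

    @property
    def frame_mids(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)

    def with_curves(self, curves: Mapping[RegionKind, RegionCurve]) -> "ScanRecord":
        return replace(self, curves=curves)


def plasma_volume(bw: float, phys: PhysiologyConstants | None = None) -> float:
    """Plasma volume in ml: ``v_blood * (1 - hematocrit) * bw``."""
    if bw <= 0:
        raise ValidationError("body weight must be positive")
    phys = phys or PhysiologyConstants()
    return phys.v_blood * (1.0 - phys.hematocrit) * bw


# ---------------------------------------------------------------------------
# TAC table dialect
#
# Delimited text (comma or tab), header:
#   frame_start_s, frame_end_s, <region>_conc_kBq_per_ml | <region>_amount_kBq
# Sidecar config (YAML): scan_id, body_weight_g, dose_MBq, infusion_duration_s,
# group, tracer.
# ---------------------------------------------------------------------------

_CONC_SUFFIX = "_conc_kBq_per_ml"
_AMOUNT_SUFFIX = "_amount_kBq"


def _column_name(region: RegionKind, kind: CurveKind) -> str:
    suffix = _CONC_SUFFIX if kind is CurveKind.CONCENTRATION else _AMOUNT_SUFFIX
    return region.value + suffix


def _parse_column(name: str) -> tuple[RegionKind, CurveKind] | None:
    for suffix, kind in ((_CONC_SUFFIX, CurveKind.CONCENTRATION), (_AMOUNT_SUFFIX, CurveKind.AMOUNT)):
        if name.endswith(suffix):
            try:
                return RegionKind(name[: -len(suffix)]), kind
            except ValueError:
                raise FormatError(f"unknown region in column {name!r}") from None
    return None


def default_config_path(tac_path: Path | str) -> Path:
    """Sidecar config path for a TAC table: ``<stem>.config.yaml``."""
    tac_path = Path(tac_path)
    return tac_path.with_name(tac_path.stem + ".config.yaml")


def read_tac_table(path: Path | str, config_path: Path | str | None = None) -> ScanRecord:
    """Read a delimited TAC table plus its sidecar config into a ScanRecord.

    Parameters
    ----------
    path : path to the delimited table (comma or tab separated).
    config_path : optional path to the sidecar config; defaults to
        ``<stem>.config.yaml`` next to the table.
    """
    path = Path(path)
    config_path = Path(config_path) if config_path is not None else default_config_path(path)
    if not config_path.exists():
        raise FormatError(f"missing scan config {config_path}")
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for key in ("body_weight_g", "dose_MBq"):
        if key not in cfg:
            raise FormatError(f"scan config missing key {key!r}")

    table = pd.read_csv(path, sep=None, engine="python")
    for col in ("frame_start_s", "frame_end_s"):
        if col not in table.columns:
            raise FormatError(f"missing mandatory column {col!r}")

    curves: dict[RegionKind, RegionCurve] = {}
    for col in table.columns:
        parsed = _parse_column(col)
        if parsed is None:
            if col in ("frame_start_s", "frame_end_s"):
                continue
            raise FormatError(f"unrecognized column {col!r}")
        region, kind = parsed
        values = table[col].to_numpy(dtype=float)
        neg = np.flatnonzero(values < 0)
        if neg.size:
            raise ValidationError(f"negative value in column {col!r} at row {int(neg[0])}")
        curves[region] = RegionCurve(values, kind)

    if RegionKind.BLOOD not in curves and RegionKind.PLASMA not in curves:
        raise FormatError("missing mandatory column: blood or plasma curve")
    for region in MANDATORY_REGIONS:
        if region not in curves:
            raise FormatError(f"missing mandatory column for region {region.value!r}")

    grid = tuple(
        (s / 60.0, e / 60.0)
        for s, e in zip(table["frame_start_s"].to_numpy(float), table["frame_end_s"].to_numpy(float))
    )
    return ScanRecord(
        scan_id=str(cfg.get("scan_id", path.stem)),
        body_weight=float(cfg["body_weight_g"]),
        dose_a0=float(cfg["dose_MBq"]),
        infusion_duration=float(cfg.get("infusion_duration_s", 10.0)) / 60.0,
        frame_grid=grid,
        curves=curves,
        group_label=str(cfg.get("group", "")),
        tracer_label=str(cfg.get("tracer", "")),
    )


def write_tac_table(
    scan: ScanRecord,
    path: Path | str,
    config_path: Path | str | None = None,
) -> Path:
    """Write a ScanRecord in the dialect :func:`read_tac_table` consumes.

    Emits the TAC table at *path* and the sidecar config next to it.
    Returns the table path.
    """
    path = Path(path)
    config_path = Path(config_path) if config_path is not None else default_config_path(path)

    columns: dict[str, np.ndarray] = {
        "frame_start_s": scan.frame_starts * 60.0,
        "frame_end_s": scan.frame_ends * 60.0,
    }
    for region, curve in scan.curves.items():
        columns[_column_name(RegionKind(region), curve.kind)] = curve.values
    frame = pd.DataFrame(columns)
    buf = io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue())

    cfg = {
        "scan_id": scan.scan_id,
        "body_weight_g": float(scan.body_weight),
        "dose_MBq": float(scan.dose_a0),
        "infusion_duration_s": float(scan.infusion_duration * 60.0),
        "group": scan.group_label,
        "tracer": scan.tracer_label,
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
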