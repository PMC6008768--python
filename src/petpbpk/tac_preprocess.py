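"""Convert image-derived concentration curves to the amount curves the
whole-body model consumes.

Liver and kidney concentrations are scaled by fixed per-body-weight organ
volumes; the peripheral-tissue volume is estimated during fitting, so its
concentration curve is retained alongside a volume hint.  Plasma amounts
come from the blood concentration and the theoretical blood volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import (
    CurveKind,
    PhysiologyConstants,
    RegionKind,
    ScanRecord,
    ValidationError,
    plasma_volume,
)

__all__ = [
    "PreparedScan",
    "blood_to_plasma_conc",
    "total_plasma_amount",
    "suv",
    "prepare_scan",
]

#: Default peripheral-tissue volume hint, cm^3 per g body weight.
DEFAULT_V_TISSUE_PER_G = 0.74


@dataclass(frozen=True)
class PreparedScan:
    """Amount curves A(t) (kBq per frame) ready for model fitting.

    ``c_tissue`` is kept as a concentration when the input was a
    concentration; the tissue amount is then ``c_tissue * v_tissue`` with
    ``v_tissue`` a fit parameter seeded by ``v_tissue_hint``.
    """

    scan: ScanRecord
    a_plasma: np.ndarray
    a_liver: np.ndarray
    a_gi: np.ndarray
    a_kidney: np.ndarray
    c_plasma: np.ndarray
    v_plasma: float
    v_liver_organ: float
    v_kidney_organ: float
    a_tissue: np.ndarray | None = None
    c_tissue: np.ndarray | None = None
    a_urine: np.ndarray | None = None
    v_tissue_hint: float | None = None

    def __post_init__(self) -> None:
        if self.a_tissue is None and self.c_tissue is None:
            raise ValidationError("tissue curve required (amount or concentration)")
        for name in ("a_plasma", "a_liver", "a_gi", "a_kidney"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValidationError(f"{name} contains negative values")

    def tissue_amount(self, v_tissue: float) -> np.ndarray:
        """Tissue amount curve for a candidate tissue volume (cm^3 = ml)."""
        if self.a_tissue is not None:
            return self.a_tissue
        return self.c_tissue * v_tissue


def blood_to_plasma_conc(c_blood, phys: PhysiologyConstants | None = None):
    """Plasma concentration from whole-blood concentration: divide by (1 - hct)."""
    phys = phys or PhysiologyConstants()
    if phys.hematocrit >= 1:
        raise ValidationError("hematocrit must be < 1")
    c_blood = np.asarray(c_blood, dtype=float)
    if np.any(c_blood < 0):
        raise ValidationError("blood concentration must be non-negative")
    return c_blood / (1.0 - phys.hematocrit)


def total_plasma_amount(c_blood, bw: float, phys: PhysiologyConstants | None = None):
    """Total plasma radioactivity (kBq): ``c_blood * v_blood * bw``."""
    phys = phys or PhysiologyConstants()
    if bw <= 0:
        raise ValidationError("body weight must be positive")
    c_blood = np.asarray(c_blood, dtype=float)
    if np.any(c_blood < 0):
        raise ValidationError("blood concentration must be non-negative")
    return c_blood * phys.v_blood * bw


def suv(c, dose: float, bw: float):
    """Standardized uptake value: concentration over injected dose per g.

    ``c`` in kBq/ml, ``dose`` in MBq, ``bw`` in g.
    """
    if dose <= 0:
        raise ValidationError("dose must be positive")
    if bw <= 0:
        raise ValidationError("body weight must be positive")
    return np.asarray(c, dtype=float) / (dose * 1000.0 / bw)


def prepare_scan(
    scan: ScanRecord,
    phys: PhysiologyConstants | None = None,
    v_tissue_hint: float | None = None,
) -> PreparedScan:
    """Build the amount curves used by the objective function.

    Concentration curves for liver and kidney are multiplied by the fixed
    organ volumes; the plasma amount is derived from blood concentration
    and the theoretical blood volume (or directly from a plasma curve when
    present — plasma wins over blood).  Amount-kind inputs pass through.
    """
    phys = phys or PhysiologyConstants()
    bw = scan.body_weight
    v_p = plasma_volume(bw, phys)
    v_liver_organ = phys.v_liver * bw
    v_kidney_organ = phys.v_kidney * bw

    # Plasma: prefer an explicit plasma curve, else derive from blood.
    if RegionKind.PLASMA in scan.curves:
        curve = scan.curves[RegionKind.PLASMA]
        if curve.kind is CurveKind.CONCENTRATION:
            c_plasma = curve.values
            a_plasma = c_plasma * v_p
        else:
            a_plasma = curve.values
            c_plasma = a_plasma / v_p
    else:
        blood = scan.curves[RegionKind.BLOOD]
        if blood.kind is not CurveKind.CONCENTRATION:
            # a blood amount is indistinguishable from a plasma amount here
            a_plasma = blood.values
            c_plasma = a_plasma / v_p
        else:
            c_plasma = blood_to_plasma_conc(blood.values, phys)
            a_plasma = total_plasma_amount(blood.values, bw, phys)

    def organ_amount(region: RegionKind, volume: float) -> np.ndarray:
        curve = scan.curves[region]
        if curve.kind is CurveKind.AMOUNT:
            return curve.values
        return curve.values * volume

    a_liver = organ_amount(RegionKind.LIVER, v_liver_organ)
    a_kidney = organ_amount(RegionKind.KIDNEY, v_kidney_organ)
    a_gi = scan.curves[RegionKind.GI].values

    tissue = scan.curves[RegionKind.TISSUE]
    a_tissue = tissue.values if tissue.kind is CurveKind.AMOUNT else None
    c_tissue = tissue.values if tissue.kind is CurveKind.CONCENTRATION else None

    a_urine = None
    if RegionKind.URINE in scan.curves:
        a_urine = scan.curves[RegionKind.URINE].values

    if v_tissue_hint is None:
        v_tissue_hint = DEFAULT_V_TISSUE_PER_G * bw

    return PreparedScan(
        scan=scan,
        a_plasma=a_plasma,
        a_liver=a_liver,
        a_gi=a_gi,
        a_kidney=a_kidney,
        c_plasma=c_plasma,
        v_plasma=v_p,
        v_liver_organ=v_liver_organ,
        v_kidney_organ=v_kidney_organ,
        a_tissue=a_tissue,
        c_tissue=c_tissue,
        a_urine=a_urine,
        v_tissue_hint=v_tissue_hint,
    )
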