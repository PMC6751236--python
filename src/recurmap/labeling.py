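"""Metabolic tumor volumes and the failure/responder partition of the GTV.

The metabolic tumor volume (MTV) at threshold t% is the set of GTV voxels with
SUV >= t/100 x SUVmax, SUVmax being the single hottest voxel inside the
delineation.  MTV_50 plus a 10 mm metric margin (MTV_50+10) is the classical
candidate volume for dose escalation; total lesion glycolysis (TLG) is mean SUV
inside an MTV times its volume in mL.

After registration, the pre-treatment GTV splits into the part overlapping the
warped recurrent tumor (GTVfailure) and the remainder (GTVresponder).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, Mask, dilate_metric

__all__ = [
    "TumorVolumes",
    "RecurrencePartition",
    "mtv",
    "mtv50_plus10",
    "compute_tumor_volumes",
    "partition_recurrence",
    "coverage",
    "coverage_curve",
]


@dataclass
class TumorVolumes:
    gtv: Mask
    suv_max: float
    mtv50: Mask
    mtv50_plus10: Mask
    mtv50_volume_ml: float
    tlg50: float  # SUV * mL


@dataclass
class RecurrencePartition:
    gtv_failure: Mask
    gtv_responder: Mask
    no_overlap: bool = False  # warning flag: recurrence does not intersect the GTV


def mtv(pet: ImageVolume, gtv: Mask, threshold_pct: float) -> Mask:
    """GTV voxels with SUV >= (threshold_pct/100) x SUVmax (SUVmax inside the GTV)."""
    if gtv.count == 0:
        raise ValueError("MTV undefined for an empty GTV")
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in [0, 100]")
    if not gtv.grid.is_compatible(pet.grid):
        raise ValueError("PET and GTV are on different grids")
    suv_max = float(pet.values[gtv.membership].max())
    cutoff = threshold_pct / 100.0 * suv_max
    member = gtv.membership & (pet.values >= cutoff)
    return Mask(grid=gtv.grid, membership=member, label=f"MTV{threshold_pct:g}")


def mtv50_plus10(pet: ImageVolume, gtv: Mask, margin_mm: float = 10.0) -> Mask:
    """MTV at 50% of SUVmax expanded by a metric margin (default 10 mm)."""
    m = dilate_metric(mtv(pet, gtv, 50.0), margin_mm)
    m.label = f"MTV50+{margin_mm:g}mm"
    return m


def compute_tumor_volumes(pet: ImageVolume, gtv: Mask) -> TumorVolumes:
    m50 = mtv(pet, gtv, 50.0)
    suv_max = float(pet.values[gtv.membership].max())
    vol_ml = m50.volume_ml
    mean_suv = float(pet.values[m50.membership].mean()) if m50.count else 0.0
    return TumorVolumes(
        gtv=gtv,
        suv_max=suv_max,
        mtv50=m50,
        mtv50_plus10=mtv50_plus10(pet, gtv),
        mtv50_volume_ml=vol_ml,
        tlg50=mean_suv * vol_ml,
    )


def partition_recurrence(gtv_pre: Mask, gtv_recur_in_prespace: Mask) -> RecurrencePartition:
    """Split the pre-treatment GTV into failure (overlap with the warped
    recurrent tumor) and responder (no overlap) volumes."""
    if not gtv_pre.grid.is_compatible(gtv_recur_in_prespace.grid):
        raise ValueError("masks must live on the same grid")
    failure = gtv_pre.membership & gtv_recur_in_prespace.membership
    responder = gtv_pre.membership & ~gtv_recur_in_prespace.membership
    return RecurrencePartition(
        gtv_failure=Mask(grid=gtv_pre.grid, membership=failure, label="GTVfailure"),
        gtv_responder=Mask(grid=gtv_pre.grid, membership=responder, label="GTVresponder"),
        no_overlap=not failure.any(),
    )


def coverage(cover: Mask, target: Mask) -> float:
    """Fraction of the target region contained in the covering region."""
    if target.count == 0:
        raise ValueError("coverage undefined for an empty target")
    inter = int(np.logical_and(cover.membership, target.membership).sum())
    return inter / target.count


def coverage_curve(
    pet: ImageVolume, gtv: Mask, target: Mask, thresholds: np.ndarray | None = None
) -> np.ndarray:
    """Coverage of ``target`` by the MTV as the threshold sweeps 0..100% of SUVmax.

    Returns an array of shape (n_thresholds, 2): threshold %, coverage.
    Monotone non-increasing in the threshold by construction.
    """
    if thresholds is None:
        thresholds = np.arange(0, 101, 1, dtype=float)
    if gtv.count == 0:
        raise ValueError("empty GTV")
    suv_max = float(pet.values[gtv.membership].max())
    vals = pet.values[target.membership & gtv.membership]
    n_target = int(target.count)
    out = np.empty((len(thresholds), 2))
    for i, t in enumerate(thresholds):
        out[i, 0] = t
        out[i, 1] = float((vals >= t / 100.0 * suv_max).sum()) / n_target
    return out
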