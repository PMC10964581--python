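"""Detection and segmentation evaluation protocol.

Implements the instance-level evaluation used for the hierarchical
pipeline: Dice per case (mean of case-level Dice) and Dice global (pooled
voxels), instance detection at overlap threshold theta (a predicted
component detects a labeled tumor when their slice-wise Dice exceeds
theta = 0.2 by default), detection sensitivity/precision/F1 at four
granularities —

* ``per_tumor_volume`` — all per-slice tumor instances pooled,
* ``per_tumor_cut``   — per-case instance detection rates, then averaged,
* ``per_slice``       — a tumor-bearing slice counts as detected when at
  least one of its tumors is detected,
* ``per_patient``     — a case counts as detected when at least one of its
  tumors is detected in any slice,

— plus the mean absolute error of the per-case maximum tumor diameter
(MTD MAE, cm) and stratified reporting by reference MTD size bin
(<2, 2-3, 3-5, >5 cm; left-closed boundaries) and tumor count (1, >1).

Dice is the primary overlap coefficient; Jaccard is offered as a secondary
output.  Dice of two empty masks is defined as 1 (affects tumor-free
slices only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .geometry import max_pairwise_distance

THETA_DEFAULT = 0.2
GRANULARITIES = ("per_tumor_volume", "per_tumor_cut", "per_slice",
                 "per_patient")
SIZE_STRATA = ("<2cm", "2-3cm", "3-5cm", ">5cm")
COUNT_STRATA = ("1 tumor", ">1 tumors")


# -- overlap coefficients ----------------------------------------------------

def dice(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if pred_mask.shape != ref_mask.shape:
        raise ValueError(f"mask shapes differ: {pred_mask.shape} vs "
                         f"{ref_mask.shape}")
    a = int(pred_mask.sum())
    b = int(ref_mask.sum())
    if a + b == 0:
        return 1.0
    inter = int(np.count_nonzero(pred_mask & ref_mask))
    return 2.0 * inter / (a + b)


def jaccard(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    d = dice(pred_mask, ref_mask)
    return d / (2.0 - d)


def dice_per_case(cases: list) -> float:
    """Unweighted mean of case-level Dice over (pred, ref) mask pairs."""
    if not cases:
        raise ValueError("need at least one case")
    return float(np.mean([dice(p, r) for p, r in cases]))


def dice_global(cases: list) -> float:
    """Dice on voxel counts pooled across all cases."""
    if not cases:
        raise ValueError("need at least one case")
    inter = tot = 0
    for p, r in cases:
        p = np.asarray(p, dtype=bool)
        r = np.asarray(r, dtype=bool)
        inter += int(np.count_nonzero(p & r))
        tot += int(p.sum()) + int(r.sum())
    if tot == 0:
        return 1.0
    return 2.0 * inter / tot


def f1(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision; 0 when both are 0."""
    if not (0 <= sensitivity <= 1 and 0 <= precision <= 1):
        raise ValueError("sensitivity and precision must lie in [0, 1]")
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


# -- instance matching -------------------------------------------------------

def match_instances(pred_labels: np.ndarray, ref_labels: np.ndarray,
                    theta: float = THETA_DEFAULT) -> list[dict]:
    """Slice-wise instance matching between prediction and reference.

    ``pred_labels`` may be a binary mask (components are labeled here,
    8-connectivity) or an instance labeling; ``ref_labels`` is the
    reference instance labeling.  Within each slice, reference instances
    and predicted components are matched greedily by descending pairwise
    Dice, one-to-one, counting only pairs with Dice > theta.  Matched
    references are true positives, unmatched references false negatives,
    unmatched predicted components false positives.

    Returns one record per slice: ``{"slice", "tp", "fp", "fn", "n_pred",
    "n_ref", "detected_ids"}``.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    pred_labels = np.asarray(pred_labels)
    ref_labels = np.asarray(ref_labels)
    if pred_labels.shape != ref_labels.shape:
        raise ValueError("prediction and reference shapes differ")

    records = []
    for z in range(ref_labels.shape[0]):
        ref_sl = ref_labels[z]
        pred_sl = measure.label(pred_labels[z] > 0, connectivity=2)
        ref_ids = np.unique(ref_sl)
        ref_ids = ref_ids[ref_ids > 0]
        pred_ids = np.unique(pred_sl)
        pred_ids = pred_ids[pred_ids > 0]

        pairs = []
        for ri in ref_ids:
            rmask = ref_sl == ri
            for pi in pred_ids:
                d = dice(pred_sl == pi, rmask)
                if d > theta:
                    pairs.append((d, int(ri), int(pi)))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_ref, used_pred = set(), set()
        for d, ri, pi in pairs:
            if ri in used_ref or pi in used_pred:
                continue
            used_ref.add(ri)
            used_pred.add(pi)
        tp = len(used_ref)
        records.append({
            "slice": z, "tp": tp, "fn": len(ref_ids) - tp,
            "fp": len(pred_ids) - len(used_pred),
            "n_pred": len(pred_ids), "n_ref": len(ref_ids),
            "detected_ids": sorted(used_ref),
        })
    return records


# -- per-case tally ----------------------------------------------------------

@dataclass
class CaseTally:
    """Everything the report needs about one evaluated case."""

    case_id: str
    slices: list                    # output of match_instances
    dice: float
    inter_vox: int
    pred_vox: int
    ref_vox: int
    ref_mtd_cm: float | None        # None when the reference has no tumor
    pred_mtd_cm: float
    n_ref_tumors: int               # 3D instance count in the reference

    @property
    def tp(self):
        return sum(s["tp"] for s in self.slices)

    @property
    def fp(self):
        return sum(s["fp"] for s in self.slices)

    @property
    def fn(self):
        return sum(s["fn"] for s in self.slices)

    @property
    def has_ref(self):
        return self.tp + self.fn > 0

    @property
    def has_pred(self):
        return any(s["n_pred"] > 0 for s in self.slices)

    @property
    def detected(self):
        return self.tp > 0


def case_mtd_cm(labels: np.ndarray, spacing_mm: tuple) -> float:
    """Maximum tumor diameter of a labeling: the largest per-slice longest
    axis over all instances and slices, converted to cm with the in-plane
    spacing.  0.0 for an empty labeling."""
    labels = np.asarray(labels)
    best_px = 0.0
    for z in range(labels.shape[0]):
        sl = labels[z]
        for i in np.unique(sl):
            if i == 0:
                continue
            best_px = max(best_px, max_pairwise_distance(np.argwhere(sl == i)))
    return best_px * spacing_mm[1] / 10.0


def tally_case(pred_mask: np.ndarray, ref_labels: np.ndarray,
               spacing_mm: tuple, theta: float = THETA_DEFAULT,
               case_id: str = "") -> CaseTally:
    """Match one case and collect its voxel counts and MTDs."""
    pred_mask = np.asarray(pred_mask) > 0
    ref_labels = np.asarray(ref_labels)
    slices = match_instances(pred_mask, ref_labels, theta)
    ref_mask = ref_labels > 0
    n_ref = len(np.unique(measure.label(ref_labels > 0, connectivity=3)
                          if ref_labels.max() <= 1 else ref_labels)) - 1
    ref_has = bool(ref_mask.any())
    return CaseTally(
        case_id=case_id, slices=slices,
        dice=dice(pred_mask, ref_mask),
        inter_vox=int(np.count_nonzero(pred_mask & ref_mask)),
        pred_vox=int(pred_mask.sum()), ref_vox=int(ref_mask.sum()),
        ref_mtd_cm=case_mtd_cm(ref_labels, spacing_mm) if ref_has else None,
        pred_mtd_cm=case_mtd_cm(
            measure.label(pred_mask, connectivity=3), spacing_mm),
        n_ref_tumors=int(n_ref))


# -- detection metrics at the four granularities -----------------------------

def _safe_div(num, den):
    return float(num) / den if den else float("nan")


def detection_metrics(tallies: list[CaseTally],
                      granularity: str) -> tuple[float, float, float]:
    """Sensitivity, precision and F1 at one granularity (nan when the
    corresponding denominator is empty)."""
    if granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {granularity!r}")
    if granularity == "per_tumor_volume":
        tp = sum(t.tp for t in tallies)
        fp = sum(t.fp for t in tallies)
        fn = sum(t.fn for t in tallies)
        sens = _safe_div(tp, tp + fn)
        prec = _safe_div(tp, tp + fp)
    elif granularity == "per_tumor_cut":
        sens_list = [_safe_div(t.tp, t.tp + t.fn) for t in tallies
                     if t.tp + t.fn > 0]
        prec_list = [_safe_div(t.tp, t.tp + t.fp) for t in tallies
                     if t.tp + t.fp > 0]
        sens = float(np.mean(sens_list)) if sens_list else float("nan")
        prec = float(np.mean(prec_list)) if prec_list else float("nan")
    elif granularity == "per_slice":
        det = ref = ppos = 0
        for t in tallies:
            for s in t.slices:
                if s["n_ref"] > 0:
                    ref += 1
                    if s["tp"] > 0:
                        det += 1
                if s["n_pred"] > 0:
                    ppos += 1
        sens = _safe_div(det, ref)
        prec = _safe_div(sum(1 for t in tallies for s in t.slices
                             if s["tp"] > 0), ppos)
    else:  # per_patient
        ref_cases = [t for t in tallies if t.has_ref]
        pred_cases = [t for t in tallies if t.has_pred]
        sens = _safe_div(sum(t.detected for t in ref_cases), len(ref_cases))
        prec = _safe_div(sum(t.detected for t in pred_cases), len(pred_cases))
    f = f1(sens, prec) if np.isfinite(sens) and np.isfinite(prec) \
        else float("nan")
    return sens, prec, f


# -- MTD MAE -----------------------------------------------------------------

def mtd_mae(pred_labels, ref_labels, spacing_mm: tuple) -> float:
    """Mean absolute error of the per-case maximum tumor diameter, in cm.

    Accepts single volumes or lists of volumes (one per case).  Every
    reference must contain at least one tumor.
    """
    if isinstance(pred_labels, np.ndarray):
        pred_labels, ref_labels = [pred_labels], [ref_labels]
    errs = []
    for p, r in zip(pred_labels, ref_labels):
        ref_mtd = case_mtd_cm(np.asarray(r), spacing_mm)
        if np.asarray(r).max() == 0:
            raise ValueError("reference case has no tumor; MTD undefined")
        pred = np.asarray(p)
        if pred.max() <= 1:
            pred = measure.label(pred > 0, connectivity=3)
        errs.append(abs(case_mtd_cm(pred, spacing_mm) - ref_mtd))
    return float(np.mean(errs))


# -- report assembly ---------------------------------------------------------

@dataclass
class MetricsReport:
    """Overall and stratified metrics, mirroring the evaluation table."""

    overall: dict
    by_size: dict = field(default_factory=dict)
    by_count: dict = field(default_factory=dict)
    theta: float = THETA_DEFAULT

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, section in [("all", self.overall),
                              *self.by_size.items(), *self.by_count.items()]:
            row = {"stratum": name, "n_cases": section["n_cases"],
                   "dice_per_case": section["dice_per_case"],
                   "dice_global": section["dice_global"],
                   "jaccard_global": section["jaccard_global"],
                   "mtd_mae_cm": section["mtd_mae_cm"]}
            for g in GRANULARITIES:
                s, p, f = section["detection"][g]
                row[f"{g}_sensitivity"] = s
                row[f"{g}_precision"] = p
                row[f"{g}_f1"] = f
            rows.append(row)
        return pd.DataFrame(rows)


def size_stratum_of(mtd_cm: float) -> str:
    """Size bin by reference MTD; boundaries are left-closed ([2,3) etc.)."""
    if mtd_cm < 2.0:
        return SIZE_STRATA[0]
    if mtd_cm < 3.0:
        return SIZE_STRATA[1]
    if mtd_cm < 5.0:
        return SIZE_STRATA[2]
    return SIZE_STRATA[3]


def _section(tallies: list[CaseTally]) -> dict:
    if not tallies:
        return {"n_cases": 0, "dice_per_case": float("nan"),
                "dice_global": float("nan"), "jaccard_global": float("nan"),
                "mtd_mae_cm": float("nan"),
                "detection": {g: (float("nan"),) * 3 for g in GRANULARITIES}}
    dpc = float(np.mean([t.dice for t in tallies]))
    inter = sum(t.inter_vox for t in tallies)
    tot = sum(t.pred_vox + t.ref_vox for t in tallies)
    dg = 2.0 * inter / tot if tot else 1.0
    jg = dg / (2.0 - dg)
    maes = [abs(t.pred_mtd_cm - t.ref_mtd_cm) for t in tallies
            if t.ref_mtd_cm is not None]
    return {
        "n_cases": len(tallies),
        "dice_per_case": dpc,
        "dice_global": dg,
        "jaccard_global": jg,
        "mtd_mae_cm": float(np.mean(maes)) if maes else float("nan"),
        "detection": {g: detection_metrics(tallies, g)
                      for g in GRANULARITIES},
    }


def stratify(tallies: list[CaseTally], by: str = "size_bin") -> dict:
    """Partition tumor-bearing cases into strata and recompute every metric
    within each stratum.  Empty strata are reported with nan metrics (and
    ``n_cases = 0``), not errors."""
    groups: dict[str, list] = {}
    if by == "size_bin":
        keys = SIZE_STRATA
        for t in tallies:
            if t.ref_mtd_cm is not None:
                groups.setdefault(size_stratum_of(t.ref_mtd_cm), []).append(t)
    elif by == "tumor_count":
        keys = COUNT_STRATA
        for t in tallies:
            if t.n_ref_tumors >= 1:
                key = COUNT_STRATA[0] if t.n_ref_tumors == 1 else COUNT_STRATA[1]
                groups.setdefault(key, []).append(t)
    else:
        raise ValueError(f"unknown stratification {by!r}")
    return {k: _section(groups.get(k, [])) for k in keys}


def evaluate_cohort(pred_masks: list, ref_labels: list, spacing_mm: tuple,
                    theta: float = THETA_DEFAULT,
                    case_ids: list | None = None) -> MetricsReport:
    """Full evaluation of a cohort of (prediction, reference) volumes."""
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(pred_masks))]
    tallies = [tally_case(p, r, spacing_mm, theta, cid)
               for p, r, cid in zip(pred_masks, ref_labels, case_ids)]
    return MetricsReport(overall=_section(tallies),
                         by_size=stratify(tallies, "size_bin"),
                         by_count=stratify(tallies, "tumor_count"),
                         theta=theta)
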