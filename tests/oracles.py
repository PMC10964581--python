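"""Independent brute-force reference implementations used to validate the
package's metrics.  Everything here is written with explicit Python loops
and exhaustive enumeration — deliberately naive, sharing no code with
hfsnet.metrics.
"""

from __future__ import annotations

import math

import numpy as np


def dice_bf(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    na = nb = ninter = 0
    for va, vb in zip(a.ravel(), b.ravel()):
        na += bool(va)
        nb += bool(vb)
        ninter += bool(va) and bool(vb)
    if na + nb == 0:
        return 1.0
    return 2.0 * ninter / (na + nb)


def dice_per_case_bf(cases) -> float:
    vals = [dice_bf(p, r) for p, r in cases]
    return sum(vals) / len(vals)


def dice_global_bf(cases) -> float:
    na = nb = ninter = 0
    for p, r in cases:
        p = np.asarray(p).astype(bool)
        r = np.asarray(r).astype(bool)
        for vp, vr in zip(p.ravel(), r.ravel()):
            na += bool(vp)
            nb += bool(vr)
            ninter += bool(vp) and bool(vr)
    if na + nb == 0:
        return 1.0
    return 2.0 * ninter / (na + nb)


def longest_axis_bf(coords) -> float:
    coords = list(coords)
    best = 0.0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = math.dist(coords[i], coords[j])
            best = max(best, d)
    return best


def _components_2d_bf(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling by flood fill."""
    mask = np.asarray(mask).astype(bool)
    lab = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for sy in range(mask.shape[0]):
        for sx in range(mask.shape[1]):
            if mask[sy, sx] and lab[sy, sx] == 0:
                nxt += 1
                stack = [(sy, sx)]
                lab[sy, sx] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < mask.shape[0]
                                    and 0 <= xx < mask.shape[1]
                                    and mask[yy, xx] and lab[yy, xx] == 0):
                                lab[yy, xx] = nxt
                                stack.append((yy, xx))
    return lab


def match_slices_bf(pred_mask: np.ndarray, ref_labels: np.ndarray,
                    theta: float) -> list[dict]:
    """Greedy best-dice one-to-one per-slice matching, counting only pairs
    with dice strictly above theta."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    ref_labels = np.asarray(ref_labels)
    out = []
    for z in range(ref_labels.shape[0]):
        pred_lab = _components_2d_bf(pred_mask[z])
        ref_sl = ref_labels[z]
        ref_ids = sorted(set(ref_sl.ravel().tolist()) - {0})
        pred_ids = sorted(set(pred_lab.ravel().tolist()) - {0})
        pairs = []
        for ri in ref_ids:
            for pi in pred_ids:
                d = dice_bf(pred_lab == pi, ref_sl == ri)
                if d > theta:
                    pairs.append((d, ri, pi))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_r, used_p = set(), set()
        for d, ri, pi in pairs:
            if ri not in used_r and pi not in used_p:
                used_r.add(ri)
                used_p.add(pi)
        out.append({"slice": z, "tp": len(used_r),
                    "fn": len(ref_ids) - len(used_r),
                    "fp": len(pred_ids) - len(used_p),
                    "n_pred": len(pred_ids), "n_ref": len(ref_ids),
                    "detected_ids": sorted(used_r)})
    return out


def granularity_metrics_bf(case_records: list, granularity: str):
    """case_records: list (one per case) of per-slice dicts from
    match_slices_bf.  Returns (sensitivity, precision)."""
    if granularity == "per_tumor_volume":
        tp = sum(s["tp"] for c in case_records for s in c)
        fn = sum(s["fn"] for c in case_records for s in c)
        fp = sum(s["fp"] for c in case_records for s in c)
        return (tp / (tp + fn) if tp + fn else float("nan"),
                tp / (tp + fp) if tp + fp else float("nan"))
    if granularity == "per_tumor_cut":
        sens, prec = [], []
        for c in case_records:
            tp = sum(s["tp"] for s in c)
            fn = sum(s["fn"] for s in c)
            fp = sum(s["fp"] for s in c)
            if tp + fn:
                sens.append(tp / (tp + fn))
            if tp + fp:
                prec.append(tp / (tp + fp))
        return (sum(sens) / len(sens) if sens else float("nan"),
                sum(prec) / len(prec) if prec else float("nan"))
    if granularity == "per_slice":
        det = ref = hit = ppos = 0
        for c in case_records:
            for s in c:
                if s["n_ref"]:
                    ref += 1
                    if s["tp"]:
                        det += 1
                if s["n_pred"]:
                    ppos += 1
                if s["tp"]:
                    hit += 1
        return (det / ref if ref else float("nan"),
                hit / ppos if ppos else float("nan"))
    if granularity == "per_patient":
        det = ref = hit = ppos = 0
        for c in case_records:
            has_ref = any(s["n_ref"] for s in c)
            has_pred = any(s["n_pred"] for s in c)
            has_hit = any(s["tp"] for s in c)
            ref += has_ref
            det += has_ref and has_hit
            ppos += has_pred
            hit += has_pred and has_hit
        return (det / ref if ref else float("nan"),
                hit / ppos if ppos else float("nan"))
    raise ValueError(granularity)


def dice_loss_closed_form(p_const: float, frac_fg_pred_overlap: float = None,
                          n_vox: int = None, n_fg: int = None,
                          smooth: float = 1.0) -> float:
    """Closed-form soft dice loss for a constant foreground probability map
    against a target with n_fg foreground voxels out of n_vox."""
    inter = p_const * n_fg
    denom = p_const * n_vox + n_fg
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)
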