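"""The hierarchical fusion pipeline: staging, routing, training, inference.

Stage I segments the liver (portal-venous slices) and estimates tumor size
(dynamic 3-channel slices).  Stage II routes every per-slice tumor instance
by its longest axis — at most ``m`` pixels to the small-tumor branch
(DenseU-Net on dynamic slices), above ``m`` to the large-tumor branch
(U-Net on portal-venous slices); ``m = 30`` px, about 4.2 cm at 1.4 mm per
pixel.  Stage III stacks the portal-venous image with the four sub-model
probability maps into a 5-channel volume and lets a 3D U-Net produce the
final tumor segmentation.

Also here: the 5:2:3 case-level split, per-sub-model training with early
stopping on validation Dice, and the phase x architecture x loss ablation
harness.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from . import losses, metrics, networks, nn
from .geometry import max_pairwise_distance
from .imaging_io import DynamicCTVolume, normalize_intensity

M_DEMARCATION_PX = 30.0          # small/large demarcation (~4.2 cm)
SUBMODEL_NAMES = ("f_liver", "f_size", "f_large", "f_small", "f_3d")
FUSION_CHANNEL_ORDER = ("portal_venous", "f_liver", "f_size", "f_large",
                        "f_small")

PHASE_CHANNELS = {"portal-venous": ("portal_venous",),
                  "arterial": ("arterial",),
                  "non-contrast": ("non_contrast",),
                  "dynamic": ("non_contrast", "arterial", "portal_venous")}


@dataclass
class PipelineConfig:
    """Every inference-time decision, recorded so runs are auditable."""

    m_px: float = M_DEMARCATION_PX
    threshold: float = 0.5           # binarization of probability maps
    min_component_voxels: int = 3    # speckle suppression
    liver_gate: bool = True          # intersect final mask with liver
    fusion_uses_probs: bool = True   # probabilities (vs binary) as channels
    patch_depth: int = 8             # f_3d Z-patch depth
    share_size_small: bool = False   # reuse f_size weights for f_small

    def fusion_hash(self) -> str:
        payload = json.dumps({"channels": FUSION_CHANNEL_ORDER,
                              "probs": self.fusion_uses_probs},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SubModelSpec:
    """(input phase(s), architecture, loss) triple for one sub-model."""

    name: str
    phase_input: str                 # portal-venous | dynamic | fusion-stack
    arch: networks.NetConfig
    loss: losses.LossSpec

    @property
    def in_channels(self) -> int:
        if self.phase_input == "fusion-stack":
            return 5
        return len(PHASE_CHANNELS[self.phase_input])


def default_submodel_specs(depth: int = 3, base_width: int = 8,
                           growth_rate: int = 8,
                           seed: int = 0) -> dict[str, SubModelSpec]:
    """The five production sub-models:

    ========  =============  =============  ==============
    model     input          architecture   loss
    ========  =============  =============  ==============
    f_liver   portal-venous  2D DenseU-Net  ce + dice
    f_size    dynamic        2D DenseU-Net  focal + dice
    f_large   portal-venous  2D U-Net       ce
    f_small   dynamic        2D DenseU-Net  focal + dice
    f_3d      fusion stack   3D U-Net       focal + dice
    ========  =============  =============  ==============
    """
    def cfg(arch, cin, s):
        return networks.NetConfig(arch=arch, in_channels=cin, out_classes=2,
                                  depth=depth, base_width=base_width,
                                  growth_rate=growth_rate, seed=seed + s)

    return {
        "f_liver": SubModelSpec("f_liver", "portal-venous",
                                cfg("denseunet2d", 1, 1),
                                losses.LossSpec.parse("ce+dice")),
        "f_size": SubModelSpec("f_size", "dynamic",
                               cfg("denseunet2d", 3, 2),
                               losses.LossSpec.parse("focal+dice")),
        "f_large": SubModelSpec("f_large", "portal-venous",
                                cfg("unet2d", 1, 3),
                                losses.LossSpec.parse("ce")),
        "f_small": SubModelSpec("f_small", "dynamic",
                                cfg("denseunet2d", 3, 4),
                                losses.LossSpec.parse("focal+dice")),
        "f_3d": SubModelSpec("f_3d", "fusion-stack",
                             cfg("unet3d", 5, 5),
                             losses.LossSpec.parse("focal+dice")),
    }


# -- routing -----------------------------------------------------------------

def longest_axis_px(component_pixels) -> float:
    """Longest axis of one per-slice component: the maximum pairwise
    Euclidean distance between its pixel centers, in pixels."""
    coords = np.asarray(sorted(component_pixels)
                        if isinstance(component_pixels, set)
                        else component_pixels, dtype=np.float64)
    if coords.size == 0:
        raise ValueError("empty component has no axis")
    return max_pairwise_distance(coords.reshape(-1, 2))


@dataclass
class RoutingPlan:
    """Per-slice, per-instance branch assignment from Stage-I estimates."""

    entries: list = field(default_factory=list)  # dicts: slice, comp, axis, branch
    m_px: float = M_DEMARCATION_PX

    @property
    def slices_for_small(self) -> set:
        return {e["slice"] for e in self.entries if e["branch"] == "small"}

    @property
    def slices_for_large(self) -> set:
        return {e["slice"] for e in self.entries if e["branch"] == "large"}


def route(size_prob: np.ndarray, m: float = M_DEMARCATION_PX,
          threshold: float = 0.5, min_component_px: int = 3) -> RoutingPlan:
    """Assign every per-slice component of the Stage-I tumor map to a branch.

    A component goes to the small branch iff its longest axis is <= m pixels
    (the tie at exactly m is small), otherwise to the large branch.  A slice
    belongs to a branch's slice set when it holds at least one component of
    that branch; a slice holding both kinds is fed to both branches.
    """
    binary = np.asarray(size_prob) >= threshold
    plan = RoutingPlan(m_px=m)
    for z in range(binary.shape[0]):
        lab = measure.label(binary[z], connectivity=2)
        for comp in np.unique(lab):
            if comp == 0:
                continue
            coords = np.argwhere(lab == comp)
            if len(coords) < min_component_px:
                continue
            axis = max_pairwise_distance(coords)
            plan.entries.append({
                "slice": int(z), "component": int(comp),
                "axis_px": float(axis),
                "branch": "small" if axis <= m else "large"})
    return plan


# -- slice-wise inference ----------------------------------------------------

def _phase_stack(volume: DynamicCTVolume, phase_input: str,
                 z_indices) -> np.ndarray:
    """(n, C, H, W) batch of normalized slices for a 2D sub-model."""
    chans = PHASE_CHANNELS[phase_input]
    norm = {c: normalize_intensity(volume.phase(c)) for c in chans}
    return np.stack([np.stack([norm[c][z] for c in chans])
                     for z in z_indices])


def _infer_slices(model, batch_x: np.ndarray, chunk: int = 8) -> np.ndarray:
    """Foreground probability maps, chunked to bound memory."""
    outs = []
    for i in range(0, len(batch_x), chunk):
        outs.append(networks.predict_probs(model, batch_x[i:i + chunk])[:, 1])
    return np.concatenate(outs) if outs else np.zeros((0,) + batch_x.shape[2:])


def segment_liver(model, volume: DynamicCTVolume) -> np.ndarray:
    """Stage-I liver probability volume (2D inference on portal-venous
    slices, restacked)."""
    x = _phase_stack(volume, "portal-venous", range(volume.shape[0]))
    return _infer_slices(model, x)


def segment_size(model, volume: DynamicCTVolume) -> np.ndarray:
    """Stage-I tumor probability volume used for size estimation and
    routing (2D inference on dynamic 3-channel slices)."""
    x = _phase_stack(volume, "dynamic", range(volume.shape[0]))
    return _infer_slices(model, x)


def run_branch(model, volume: DynamicCTVolume, plan: RoutingPlan,
               branch: str) -> np.ndarray:
    """Stage-II branch probabilities on the branch's routed slices, zeros
    elsewhere.  The small branch consumes 3 dynamic channels, the large
    branch the single portal-venous channel."""
    if branch not in ("small", "large"):
        raise ValueError("branch must be 'small' or 'large'")
    zs = sorted(plan.slices_for_small if branch == "small"
                else plan.slices_for_large)
    out = np.zeros(volume.shape)
    if not zs:
        return out
    phase_input = "dynamic" if branch == "small" else "portal-venous"
    x = _phase_stack(volume, phase_input, zs)
    probs = _infer_slices(model, x)
    for i, z in enumerate(zs):
        out[z] = probs[i]
    return out


# -- fusion ------------------------------------------------------------------

def assemble_fusion_input(volume: DynamicCTVolume, liver_prob, size_prob,
                          large_prob, small_prob,
                          config: PipelineConfig | None = None) -> np.ndarray:
    """5-channel fusion volume in the fixed order (portal-venous image,
    liver, size, large, small)."""
    config = config or PipelineConfig()
    pv = normalize_intensity(volume.portal_venous)
    parts = {"portal_venous": pv, "f_liver": liver_prob, "f_size": size_prob,
             "f_large": large_prob, "f_small": small_prob}
    shapes = {np.asarray(p).shape for p in parts.values()}
    if len(shapes) != 1:
        raise ValueError(f"fusion inputs disagree in shape: {shapes}")
    stack = []
    for name in FUSION_CHANNEL_ORDER:
        arr = np.asarray(parts[name], dtype=np.float64)
        if name != "portal_venous" and not config.fusion_uses_probs:
            arr = (arr >= config.threshold).astype(np.float64)
        stack.append(arr)
    return np.stack(stack)


def fuse_3d(model, fusion_input: np.ndarray,
            patch_depth: int = 8) -> np.ndarray:
    """Stage-III volumetric inference on overlapping Z patches, blended
    with triangular weights."""
    nz = fusion_input.shape[1]
    pd_ = min(patch_depth, nz)
    stride = max(pd_ // 2, 1)
    starts = sorted({min(s, nz - pd_) for s in range(0, nz, stride)})
    acc = np.zeros(fusion_input.shape[1:])
    wacc = np.zeros(nz)
    w = np.minimum(np.arange(1, pd_ + 1), np.arange(pd_, 0, -1)).astype(float)
    for s in starts:
        patch = fusion_input[None, :, s:s + pd_]
        prob = networks.predict_probs(model, patch)[0, 1]
        acc[s:s + pd_] += prob * w[:, None, None]
        wacc[s:s + pd_] += w
    return acc / wacc[:, None, None]


# -- full pipeline -----------------------------------------------------------

@dataclass
class CaseResult:
    """All intermediate probability volumes plus the final masks."""

    liver_prob: np.ndarray
    size_prob: np.ndarray
    large_prob: np.ndarray
    small_prob: np.ndarray
    final_prob: np.ndarray
    final_mask: np.ndarray
    final_liver: np.ndarray
    routing: RoutingPlan
    mode: str


def _clean_mask(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    lab = measure.label(mask, connectivity=3)
    out = np.zeros_like(mask, dtype=bool)
    for comp in np.unique(lab):
        if comp == 0:
            continue
        where = lab == comp
        if where.sum() >= min_voxels:
            out |= where
    return out


class HFSNet:
    """The trained ensemble: five sub-models plus the inference config."""

    def __init__(self, models: dict, config: PipelineConfig | None = None):
        self.models = dict(models)
        self.config = config or PipelineConfig()
        if self.config.share_size_small and "f_size" in self.models:
            self.models.setdefault("f_small", self.models["f_size"])

    def _need(self, *names):
        missing = [n for n in names if n not in self.models]
        if missing:
            raise RuntimeError(f"missing trained sub-model(s): {missing}")

    def run_case(self, volume: DynamicCTVolume, mode: str = "3d") -> CaseResult:
        """Run the hierarchy.  ``mode='2d'`` stops after Stage II (union of
        the routed branch outputs); ``mode='3d'`` adds the fusion stage."""
        if mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        need = ["f_liver", "f_size", "f_large", "f_small"]
        if mode == "3d":
            need.append("f_3d")
        self._need(*need)
        cfg = self.config

        liver_prob = segment_liver(self.models["f_liver"], volume)
        size_prob = segment_size(self.models["f_size"], volume)
        plan = route(size_prob, cfg.m_px, cfg.threshold,
                     cfg.min_component_voxels)
        large_prob = run_branch(self.models["f_large"], volume, plan, "large")
        small_prob = run_branch(self.models["f_small"], volume, plan, "small")

        if mode == "2d":
            final_prob = np.maximum(large_prob, small_prob)
        else:
            fusion = assemble_fusion_input(volume, liver_prob, size_prob,
                                           large_prob, small_prob, cfg)
            final_prob = fuse_3d(self.models["f_3d"], fusion, cfg.patch_depth)

        final_liver = liver_prob >= cfg.threshold
        mask = final_prob >= cfg.threshold
        if cfg.liver_gate:
            mask = mask & final_liver
        mask = _clean_mask(mask, cfg.min_component_voxels)
        return CaseResult(liver_prob, size_prob, large_prob, small_prob,
                          final_prob, mask, final_liver, plan, mode)

    # -- persistence ----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, model in self.models.items():
            networks.save_checkpoint(model, directory / f"{name}.npz")
        (directory / "pipeline.json").write_text(
            json.dumps({**self.config.__dict__,
                        "fusion_hash": self.config.fusion_hash()}, indent=1))

    @classmethod
    def load(cls, directory) -> "HFSNet":
        directory = Path(directory)
        cfg_d = json.loads((directory / "pipeline.json").read_text())
        cfg_d.pop("fusion_hash", None)
        models = {p.stem: networks.load_checkpoint(p)
                  for p in sorted(directory.glob("*.npz"))}
        return cls(models, PipelineConfig(**cfg_d))


# -- dataset preparation -----------------------------------------------------

def split_cases(cases: list, ratio=(5, 2, 3), seed: int = 0) -> tuple:
    """Seeded case-level shuffle into train/validation/test; rounding
    remainders go to the training set."""
    if not cases:
        raise ValueError("no cases to split")
    n = len(cases)
    idx = np.random.default_rng(seed).permutation(n)
    total = sum(ratio)
    n_val = n * ratio[1] // total
    n_test = n * ratio[2] // total
    n_train = n - n_val - n_test
    order = [cases[i] for i in idx]
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


def _case_target(case, submodel: str) -> np.ndarray:
    if submodel == "f_liver":
        return case.liver_mask.astype(np.int32)
    return (case.tumor_labels.labels > 0).astype(np.int32)


def _gt_slice_routing(case, m: float = M_DEMARCATION_PX) -> dict:
    """Ground-truth per-slice branch membership used to pick training
    slices for the Stage-II branches."""
    labels = case.tumor_labels.labels
    small, large = set(), set()
    for z in range(labels.shape[0]):
        sl = labels[z]
        for i in np.unique(sl):
            if i == 0:
                continue
            axis = max_pairwise_distance(np.argwhere(sl == i))
            (small if axis <= m else large).add(z)
    return {"small": small, "large": large}


@dataclass
class TrainConfig:
    """Optimization settings shared by all sub-models."""

    epochs: int = 20
    batch_size: int = 8
    steps_per_epoch: int = 20
    lr: float = 3e-3
    patience: int = 5                # early stopping on validation dice
    augment_flips: bool = True
    neg_slice_fraction: float = 0.3  # share of background slices per epoch
    patch_tumor_fraction: float = 0.65  # tumor-centered share of 3D patches
    seed: int = 0


# epoch budget per sub-model for the desk-scale study: the prior-initialized
# focal/dice learners converge within a few epochs, while the plain
# cross-entropy large branch needs most of the schedule for its
# class-imbalance breakthrough
DESK_EPOCHS = {"f_liver": 4, "f_size": 6, "f_small": 6, "f_large": 12,
               "f_3d": 12}


def _training_slices(cases: list, submodel: str, m: float) -> list:
    """(case_index, z) pairs: positive slices for the sub-model's task plus
    every slice as negative-candidate pool."""
    pos, neg = [], []
    for ci, case in enumerate(cases):
        target = _case_target(case, submodel)
        if submodel in ("f_small", "f_large"):
            branch = "small" if submodel == "f_small" else "large"
            zs = _gt_slice_routing(case, m)[branch]
        else:
            zs = {z for z in range(target.shape[0]) if target[z].any()}
        for z in range(target.shape[0]):
            (pos if z in zs else neg).append((ci, z))
    return pos, neg


def train_submodel(cases: list, spec: SubModelSpec,
                   train_config: TrainConfig | None = None,
                   val_cases: list | None = None,
                   m: float = M_DEMARCATION_PX,
                   fusion_volumes: dict | None = None) -> tuple:
    """Train one sub-model on phantom/clinical cases; returns
    ``(model, history)`` with best-validation weight selection.

    For ``f_3d`` pass ``fusion_volumes``: ``{case_id: (5ch volume, target)}``
    covering train and validation cases (built with
    :func:`assemble_fusion_input` from the trained Stage I/II models).
    """
    cfg = train_config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    model = networks.build(replace(spec.arch, seed=spec.arch.seed))
    loss_fn = losses.combine(spec.loss)
    opt = nn.Adam(model.params, lr=cfg.lr)
    if val_cases is None:
        val_cases = cases[-max(1, len(cases) // 5):]

    is_3d = spec.phase_input == "fusion-stack"
    if is_3d:
        if fusion_volumes is None:
            raise ValueError("f_3d training requires fusion_volumes")
        data = [fusion_volumes[c.case_id] for c in cases]
        val_data = [fusion_volumes[c.case_id] for c in val_cases]
    else:
        pos, neg = _training_slices(cases, spec.name, m)
        if not pos:
            raise RuntimeError(f"no positive training slices for {spec.name}")
        inputs = [_phase_stack(c.volume, spec.phase_input,
                               range(c.volume.shape[0])) for c in cases]
        targets = [_case_target(c, spec.name) for c in cases]
        # branch models are validated on their own routed slices only;
        # whole-volume models on a stride-2 slice subsample (for speed)
        val_inputs, val_targets = [], []
        for c in val_cases:
            if spec.name in ("f_small", "f_large"):
                branch = "small" if spec.name == "f_small" else "large"
                zs = sorted(_gt_slice_routing(c, m)[branch])
            else:
                zs = list(range(0, c.volume.shape[0], 2))
            if not zs:
                continue
            val_inputs.append(_phase_stack(c.volume, spec.phase_input, zs))
            val_targets.append(_case_target(c, spec.name)[zs])

    history, best = [], {"dice": -1.0, "state": None, "epoch": -1}
    for epoch in range(cfg.epochs):
        ep_losses = []
        for _ in range(cfg.steps_per_epoch):
            if is_3d:
                xb, yb = _sample_patch_batch(data, cfg, rng)
            else:
                xb, yb = _sample_slice_batch(inputs, targets, pos, neg,
                                             cfg, rng)
            probs = model.forward_t(nn.Tensor(xb))
            loss = loss_fn(probs, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"{spec.name}: loss diverged (non-finite) at epoch "
                    f"{epoch}; last finite losses: {ep_losses[-3:]}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        if is_3d:
            vd = _validation_dice_3d(model, val_data, cfg)
        else:
            vd = _validation_dice_2d(model, val_inputs, val_targets)
        history.append({"epoch": epoch, "train_loss": float(np.mean(ep_losses)),
                        "val_dice": vd})
        if vd > best["dice"]:
            best = {"dice": vd, "epoch": epoch,
                    "state": copy.deepcopy(model.state_dict())}
        elif epoch - best["epoch"] >= cfg.patience:
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return model, history


def _augment(xb, yb, rng):
    for ax_x, ax_y in ((-1, -1), (-2, -2)):  # horizontal / vertical flips
        if rng.uniform() < 0.5:
            xb = np.flip(xb, axis=ax_x)
            yb = np.flip(yb, axis=ax_y)
    return np.ascontiguousarray(xb), np.ascontiguousarray(yb)


def _sample_slice_batch(inputs, targets, pos, neg, cfg, rng):
    n_neg = int(round(cfg.batch_size * cfg.neg_slice_fraction))
    n_pos = cfg.batch_size - n_neg
    picks = [pos[i] for i in rng.integers(len(pos), size=n_pos)]
    if neg:
        picks += [neg[i] for i in rng.integers(len(neg), size=n_neg)]
    xb = np.stack([inputs[ci][z] for ci, z in picks])
    yb = np.stack([targets[ci][z] for ci, z in picks])
    if cfg.augment_flips:
        xb, yb = _augment(xb, yb, rng)
    return xb, yb


def _sample_patch_batch(data, cfg, rng, n_patches: int = 2):
    pd_ = None
    xs, ys = [], []
    for _ in range(n_patches):
        vol, tgt = data[rng.integers(len(data))]
        nz = vol.shape[1]
        pd_ = min(8, nz)
        tumor_z = np.nonzero(tgt.reshape(tgt.shape[0], -1).any(axis=1))[0]
        if len(tumor_z) and rng.uniform() < cfg.patch_tumor_fraction:
            zc = int(rng.choice(tumor_z))
            s = int(np.clip(zc - pd_ // 2, 0, nz - pd_))
        else:
            s = int(rng.integers(0, max(nz - pd_, 0) + 1))
        xs.append(vol[:, s:s + pd_])
        ys.append(tgt[s:s + pd_])
    xb, yb = np.stack(xs), np.stack(ys)
    if cfg.augment_flips:
        xb, yb = _augment(xb, yb, rng)
    return xb, yb


def _validation_dice_2d(model, val_inputs, val_targets) -> float:
    pairs = []
    for x, t in zip(val_inputs, val_targets):
        prob = _infer_slices(model, x)
        pairs.append((prob >= 0.5, t > 0))
    return metrics.dice_global(pairs)


def _validation_dice_3d(model, val_data, cfg,
                        patch_depth: int = 8) -> float:
    pairs = []
    for vol, tgt in val_data:
        prob = fuse_3d(model, vol, patch_depth)
        pairs.append((prob >= 0.5, tgt > 0))
    return metrics.dice_global(pairs)


# -- end-to-end training -----------------------------------------------------

def build_fusion_volumes(models: dict, cases: list,
                         config: PipelineConfig | None = None) -> dict:
    """Run Stages I-II on each case and assemble the f_3d training input."""
    config = config or PipelineConfig()
    out = {}
    for case in cases:
        liver = segment_liver(models["f_liver"], case.volume)
        size = segment_size(models["f_size"], case.volume)
        plan = route(size, config.m_px, config.threshold,
                     config.min_component_voxels)
        large = run_branch(models["f_large"], case.volume, plan, "large")
        small = run_branch(models["f_small"], case.volume, plan, "small")
        fusion = assemble_fusion_input(case.volume, liver, size, large,
                                       small, config)
        out[case.case_id] = (fusion, (case.tumor_labels.labels > 0)
                             .astype(np.int32))
    return out


def train_hfsnet(train_cases: list, val_cases: list,
                 specs: dict | None = None,
                 train_config: TrainConfig | None = None,
                 config: PipelineConfig | None = None,
                 epochs_per_model: dict | None = None) -> tuple:
    """Train all five sub-models in dependency order; returns
    ``(HFSNet, {name: history})``.

    ``epochs_per_model`` overrides the epoch budget per sub-model (see
    :data:`DESK_EPOCHS` for the desk-scale schedule).
    """
    specs = specs or default_submodel_specs()
    cfg = config or PipelineConfig()
    tc = train_config or TrainConfig()
    epochs_per_model = epochs_per_model or {}

    def tc_for(name):
        if name in epochs_per_model:
            return replace(tc, epochs=epochs_per_model[name])
        return tc

    models, histories = {}, {}
    for name in ("f_liver", "f_size", "f_large", "f_small"):
        if name == "f_small" and cfg.share_size_small:
            models[name] = models["f_size"]
            histories[name] = histories["f_size"]
            continue
        models[name], histories[name] = train_submodel(
            train_cases, specs[name], tc_for(name), val_cases, cfg.m_px)
    fusion_volumes = build_fusion_volumes(
        models, list(train_cases) + list(val_cases), cfg)
    models["f_3d"], histories["f_3d"] = train_submodel(
        train_cases, specs["f_3d"], tc_for("f_3d"), val_cases, cfg.m_px,
        fusion_volumes=fusion_volumes)
    return HFSNet(models, cfg), histories


# -- ablation harness --------------------------------------------------------

PX_BINS = ((0, 10), (10, 30), (30, 50), (50, np.inf))
PX_BIN_NAMES = ("<=10px", "10-30px", "30-50px", ">50px")


def per_instance_detection(pred_mask: np.ndarray, ref_labels: np.ndarray,
                           theta: float = metrics.THETA_DEFAULT) -> list:
    """(axis_px, detected) for every per-slice reference instance."""
    recs = metrics.match_instances(pred_mask, ref_labels, theta)
    out = []
    for rec in recs:
        z = rec["slice"]
        sl = np.asarray(ref_labels)[z]
        for i in np.unique(sl):
            if i == 0:
                continue
            axis = max_pairwise_distance(np.argwhere(sl == i))
            out.append((float(axis), int(i) in rec["detected_ids"]))
    return out


def detection_rate_by_px_bin(instances: list) -> dict:
    """Detected fraction of per-slice instances within each axis bin."""
    rates = {}
    for (lo, hi), name in zip(PX_BINS, PX_BIN_NAMES):
        hits = [det for axis, det in instances if lo < axis <= hi]
        rates[name] = float(np.mean(hits)) if hits else float("nan")
    return rates


def ablation_grid(train_cases: list, val_cases: list, test_cases: list,
                  phases: list, archs: list, loss_specs: list,
                  train_config: TrainConfig | None = None,
                  depth: int = 3, base_width: int = 8,
                  growth_rate: int = 8) -> pd.DataFrame:
    """Train one single-strategy tumor segmenter per (phase, arch, loss)
    combination and evaluate it on the test cases, stratified by per-slice
    axis bins.  Returns one row per combination."""
    tc = train_config or TrainConfig()
    rows = []
    for phase in phases:
        if phase not in PHASE_CHANNELS:
            raise ValueError(f"unknown phase {phase!r}")
        for arch in archs:
            if arch not in ("unet2d", "denseunet2d"):
                raise ValueError(f"unsupported ablation architecture {arch!r}")
            for loss_name in loss_specs:
                spec = SubModelSpec(
                    "f_size", phase,
                    networks.NetConfig(arch=arch,
                                       in_channels=len(PHASE_CHANNELS[phase]),
                                       depth=depth, base_width=base_width,
                                       growth_rate=growth_rate, seed=tc.seed),
                    losses.LossSpec.parse(loss_name))
                model, _ = train_submodel(train_cases, spec, tc, val_cases)
                pairs, instances = [], []
                for case in test_cases:
                    x = _phase_stack(case.volume, phase,
                                     range(case.volume.shape[0]))
                    prob = _infer_slices(model, x)
                    pred = prob >= 0.5
                    ref = case.tumor_labels.labels
                    pairs.append((pred, ref > 0))
                    instances += per_instance_detection(pred, ref)
                row = {"phase": phase, "arch": arch, "loss": loss_name,
                       "dice_per_case": metrics.dice_per_case(pairs),
                       "dice_global": metrics.dice_global(pairs)}
                for name, rate in detection_rate_by_px_bin(instances).items():
                    row[f"detection_{name}"] = rate
                rows.append(row)
    return pd.DataFrame(rows)
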