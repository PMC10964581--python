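"""Segmentation loss functions and their compounds.

The sub-models of the hierarchical pipeline train with different loss
combinations — cross entropy + dice for the liver model, focal + dice for
the size/small-tumor/fusion models, plain cross entropy for the large-tumor
branch — and the experiment harness additionally supports median-frequency-
balanced (MFB) class weighting.  Compound specs are written as strings such
as ``"ce+dice"`` or ``"focal+dice"`` in configuration files.

All losses accept either plain numpy arrays (returning a float) or autodiff
tensors from :mod:`hfsnet.nn` (returning a scalar tensor through which
gradients flow).  Probabilities are expected to be softmax-normalized over
the class axis (axis 1); targets are integer label maps of the same spatial
shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

# probabilities are clamped to this range before any logarithm
EPS = 1e-7
# additive smoothing in the soft-dice numerator and denominator
DICE_SMOOTH = 1.0

KNOWN_TERMS = ("ce", "dice", "focal", "mfb_focal")


@dataclass
class LossSpec:
    """A weighted sum of loss terms.

    ``terms`` are drawn from ``ce`` (cross entropy), ``dice`` (soft dice),
    ``focal`` (focal loss, exponent ``focal_gamma``) and ``mfb_focal``
    (focal loss with median-frequency-balance class weights).  Weights
    default to 1 for every term, matching the convention of writing
    compound losses as plain sums.
    """

    terms: tuple = ("ce",)
    weights: tuple | None = None
    focal_gamma: float = 2.0
    class_weights: np.ndarray | None = None

    def __post_init__(self):
        self.terms = tuple(self.terms)
        if not self.terms:
            raise ValueError("LossSpec needs at least one term")
        for t in self.terms:
            if t not in KNOWN_TERMS:
                raise ValueError(f"unknown loss term {t!r}")
        if self.weights is None:
            self.weights = (1.0,) * len(self.terms)
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != len(self.terms):
            raise ValueError("one weight per term required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("term weights must be positive")

    @classmethod
    def parse(cls, text: str, **kwargs) -> "LossSpec":
        """Parse a compound spec string such as ``"focal+dice"``."""
        return cls(terms=tuple(t.strip() for t in text.split("+")), **kwargs)

    def name(self) -> str:
        return "+".join(self.terms)


# -- helpers -----------------------------------------------------------------

def _as_tensor(probs) -> tuple[nn.Tensor, bool]:
    if isinstance(probs, nn.Tensor):
        return probs, True
    return nn.Tensor(np.asarray(probs, dtype=np.float64)), False


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, *spatial) integer labels -> (N, C, *spatial) one-hot floats."""
    target = np.asarray(target)
    if target.ndim >= 2 and target.shape[1] == n_classes and \
            np.issubdtype(target.dtype, np.floating):
        return target  # already one-hot / soft
    eye = np.eye(n_classes, dtype=np.float64)
    oh = eye[target.astype(np.intp)]  # (N, *spatial, C)
    return np.moveaxis(oh, -1, 1)


def _ret(loss: nn.Tensor, was_tensor: bool):
    return loss if was_tensor else float(loss.data)


def _check_shapes(probs_data: np.ndarray, onehot: np.ndarray) -> None:
    if probs_data.shape != onehot.shape:
        raise ValueError(f"probability map {probs_data.shape} does not match "
                         f"target {onehot.shape}")


# -- individual losses -------------------------------------------------------

def cross_entropy(probs, target, class_weights=None):
    """Mean per-voxel negative log-likelihood of the true class.

    Probabilities at the true class are clamped to ``[EPS, 1-EPS]`` so a
    confident wrong prediction yields a large finite loss rather than inf.
    """
    p, was_tensor = _as_tensor(probs)
    oh = _one_hot(target, p.shape[1])
    _check_shapes(p.data, oh)
    pt = (p * oh).sum(axis=1).clip(EPS, 1.0 - EPS)
    nll = -pt.log()
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float64)
        wmap = w[np.argmax(oh, axis=1)]  # (N, *spatial)
        nll = nll * nn.Tensor(wmap)
    return _ret(nll.mean(), was_tensor)


def dice_loss(probs, target, fg_class: int = 1):
    """1 - soft dice of the designated foreground class, in [0, 1]."""
    p, was_tensor = _as_tensor(probs)
    oh = _one_hot(target, p.shape[1])
    _check_shapes(p.data, oh)
    pf = p[:, fg_class]
    tf = nn.Tensor(oh[:, fg_class])
    inter = (pf * tf).sum()
    denom = pf.sum() + tf.sum()
    soft_dice = (2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)
    return _ret(1.0 - soft_dice, was_tensor)


def focal_loss(probs, target, gamma: float = 2.0, class_weights=None):
    """Mean of ``-w_c (1 - p_t)^gamma log(p_t)``.

    At ``gamma = 0`` this is exactly (weighted) cross entropy; larger gamma
    down-weights well-classified voxels, concentrating the gradient on hard
    ones — the property that favors small-lesion segmentation.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p, was_tensor = _as_tensor(probs)
    oh = _one_hot(target, p.shape[1])
    _check_shapes(p.data, oh)
    pt = (p * oh).sum(axis=1).clip(EPS, 1.0 - EPS)
    loss = -((1.0 - pt) ** gamma) * pt.log()
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float64)
        wmap = w[np.argmax(oh, axis=1)]
        loss = loss * nn.Tensor(wmap)
    return _ret(loss.mean(), was_tensor)


def mfb_weights(class_frequencies) -> np.ndarray:
    """Median-frequency-balance weights: ``median(freq) / freq_c``.

    Rare classes receive weights above 1, dominant classes below 1; with
    uniform frequencies every weight is exactly 1.
    """
    f = np.asarray(class_frequencies, dtype=np.float64)
    if np.any(f <= 0):
        raise ValueError("every class must occur in the training set "
                         "(zero frequency encountered)")
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("class frequencies must sum to 1")
    return np.median(f) / f


# -- compounds ---------------------------------------------------------------

def combine(spec: LossSpec):
    """Return a callable computing the weighted sum of the spec's terms."""

    def loss_fn(probs, target):
        p, was_tensor = _as_tensor(probs)
        total = None
        for term, w in zip(spec.terms, spec.weights):
            if term == "ce":
                part = cross_entropy(p, target, class_weights=spec.class_weights)
            elif term == "dice":
                part = dice_loss(p, target)
            elif term == "focal":
                part = focal_loss(p, target, gamma=spec.focal_gamma,
                                  class_weights=spec.class_weights)
            elif term == "mfb_focal":
                if spec.class_weights is None:
                    raise ValueError("mfb_focal requires class_weights "
                                     "(see mfb_weights)")
                part = focal_loss(p, target, gamma=spec.focal_gamma,
                                  class_weights=spec.class_weights)
            part = part * w
            total = part if total is None else total + part
        return _ret(total, was_tensor)

    return loss_fn
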