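"""Joint training objective: focal classification loss + cosine contrastive term.

The contrastive term pulls the two branch embeddings of the *same* sample
together: each 48×7×7 map is min-max rescaled to [-1, 1], flattened, and the
cosine of the pair is turned into a loss ``L_con = 1 - sim``.  The total is
``L = L_cls + λ·L_con`` with λ small (default 0.01) so classification stays
the dominant task.  Only positive pairs enter the contrastive term.

Public functions operate on NumPy arrays; the ``*_t`` variants build autodiff
graphs for training and share the same definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, log_softmax

_EPS = 1e-12

#: Per-class weights printed for the weighted-CE ablation on the composite
#: corpus (Negative, Positive, Surprise).  Kept as an opaque preset — they are
#: not derivable from the per-class sample counts.
MEGC_WCE_WEIGHTS = np.array([0.2857, 0.1329, 0.1695])


class UndefinedSimilarityError(ValueError):
    """Raised when a feature map is constant, making min-max scaling undefined."""


@dataclass
class LossConfig:
    """Joint-loss hyperparameters.

    lam: weight λ of the contrastive term (0 disables it);
    focal_gamma: focusing exponent γ (0 reduces focal to cross-entropy);
    focal_alpha: per-class weight vector, or None for uniform 1;
    loss: classification-term selector, ``focal`` | ``ce`` | ``weighted-ce``.
    """

    lam: float = 0.01
    focal_gamma: float = 2.0
    focal_alpha: np.ndarray | None = None
    class_count: int = 3
    loss: str = "focal"

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.focal_gamma < 0:
            raise ValueError("focal gamma must be non-negative")
        if self.loss not in ("focal", "ce", "weighted-ce"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def effective(self) -> tuple[float, np.ndarray]:
        """(gamma, alpha) after applying the loss selector."""
        if self.loss == "focal":
            alpha = self.focal_alpha if self.focal_alpha is not None else np.ones(self.class_count)
            return self.focal_gamma, np.asarray(alpha, dtype=float)
        if self.loss == "ce":
            return 0.0, np.ones(self.class_count)
        if self.focal_alpha is None:
            raise ValueError("weighted-ce requires explicit per-class weights")
        return 0.0, np.asarray(self.focal_alpha, dtype=float)


# ---------------------------------------------------------------------------
# similarity / contrastive term
# ---------------------------------------------------------------------------

def _scale_minmax(x: np.ndarray) -> np.ndarray:
    mn, mx = x.min(), x.max()
    if mx - mn <= 0:
        raise UndefinedSimilarityError("constant feature map: min-max scaling undefined")
    return 2.0 * (x - mn) / (mx - mn) - 1.0


def cosine_similarity(ve: np.ndarray, vp: np.ndarray) -> float:
    """Cosine of the two feature maps after per-map min-max scaling to [-1, 1].

    1 means a perfect match, 0 orthogonal, -1 a complete mismatch.
    """
    ve = np.asarray(ve, dtype=float)
    vp = np.asarray(vp, dtype=float)
    if ve.shape != vp.shape:
        raise ValueError(f"shape mismatch: {ve.shape} vs {vp.shape}")
    a = _scale_minmax(ve).ravel()
    b = _scale_minmax(vp).ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def contrastive_loss(ve: np.ndarray, vp: np.ndarray) -> float:
    """1 - cosine similarity; 0 for identical maps, up to 2 for opposite ones."""
    return 1.0 - cosine_similarity(ve, vp)


# ---------------------------------------------------------------------------
# classification term
# ---------------------------------------------------------------------------

def focal_loss(probs: np.ndarray, label, config: LossConfig | None = None) -> float:
    """Focal loss −α_y (1−p_y)^γ log p_y, averaged over the batch.

    ``probs`` is one probability vector or a (N, C) batch; ``label`` the
    matching class index/indices.  Probabilities are clamped at 1e-12 before
    the log.
    """
    config = config or LossConfig()
    gamma, alpha = config.effective()
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.atleast_1d(np.asarray(label, dtype=int))
    if p.shape[0] != y.shape[0]:
        raise ValueError("batch sizes of probs and labels differ")
    py = np.clip(p[np.arange(len(y)), y], _EPS, 1.0)
    focal = (1.0 - py) ** gamma if gamma > 0 else 1.0
    return float(np.mean(-alpha[y] * focal * np.log(py)))


def joint_loss(probs: np.ndarray, label, ve: np.ndarray, vp: np.ndarray,
               config: LossConfig | None = None) -> tuple[float, dict]:
    """L = L_cls + λ·L_con; returns the total and both components."""
    config = config or LossConfig()
    l_cls = focal_loss(probs, label, config)
    l_con = contrastive_loss(ve, vp)
    total = l_cls + config.lam * l_con
    return total, {"cls": l_cls, "con": l_con, "total": total}


# ---------------------------------------------------------------------------
# autodiff (training) variants
# ---------------------------------------------------------------------------

def batch_cosine_t(ve: Tensor, vp: Tensor, eps: float = 1e-8) -> Tensor:
    """Per-sample min-max-scaled cosine similarity, averaged over the batch.

    The eps guard keeps the scaling finite if a map collapses to a constant
    during training (the strict NumPy op raises instead).
    """
    def scaled(x: Tensor) -> Tensor:
        n = x.shape[0]
        flat = x.reshape(n, -1)
        mn = flat.min(axis=1, keepdims=True)
        mx = flat.max(axis=1, keepdims=True)
        return (flat - mn) * ((mx - mn + eps).pow(-1.0)) * 2.0 - 1.0

    a, b = scaled(ve), scaled(vp)
    dot = (a * b).sum(axis=1)
    norms = ((a * a).sum(axis=1) + eps).pow(0.5) * ((b * b).sum(axis=1) + eps).pow(0.5)
    return (dot / norms).mean()


def contrastive_loss_t(ve: Tensor, vp: Tensor) -> Tensor:
    return 1.0 - batch_cosine_t(ve, vp)


def focal_loss_t(logits: Tensor, labels: np.ndarray, config: LossConfig) -> Tensor:
    """Focal loss on logits (batched), as an autodiff graph."""
    gamma, alpha = config.effective()
    y = np.asarray(labels, dtype=int)
    onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
    onehot[np.arange(len(y)), y] = 1.0
    logp = log_softmax(logits, axis=1)
    logpy = (logp * Tensor(onehot)).sum(axis=1)
    weight = Tensor(alpha[y].astype(logits.data.dtype))
    if gamma > 0:
        py = logpy.exp()
        modulator = ((1.0 - py) + _EPS).pow(gamma)
        return (-(weight * modulator * logpy)).mean()
    return (-(weight * logpy)).mean()


def joint_loss_t(logits: Tensor, labels: np.ndarray, ve: Tensor, vp: Tensor,
                 config: LossConfig) -> tuple[Tensor, dict]:
    """Training objective; returns (scalar graph node, float components)."""
    l_cls = focal_loss_t(logits, labels, config)
    if config.lam > 0:
        l_con = contrastive_loss_t(ve, vp)
        total = l_cls + config.lam * l_con
        comps = {"cls": float(l_cls.data), "con": float(l_con.data), "total": float(total.data)}
    else:
        total = l_cls
        comps = {"cls": float(l_cls.data), "con": 0.0, "total": float(total.data)}
    return total, comps
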