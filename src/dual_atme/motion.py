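"""Optical flow and optical strain features between onset and apex frames.

One micro-expression instance is reduced to a single onset→apex displacement
field.  Dense TV-L1 flow gives (u, v); optical strain — the magnitude of the
symmetric part of the flow gradient — adds a deformation-intensity channel
that is insensitive to rigid translation.  The three channels are resized to
the network resolution and max-abs normalised per channel to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.registration import optical_flow_tvl1
from skimage.transform import resize


@dataclass
class TVL1Config:
    """Parameters of the duality-based TV-L1 dense flow solver.

    attachment: data-attachment weight (lower = smoother flow);
    tightness: coupling between the auxiliary and flow fields;
    num_warp: image warps per pyramid level; num_iter: fixed-point
    iterations per warp.
    """

    attachment: float = 15.0
    tightness: float = 0.3
    num_warp: int = 5
    num_iter: int = 10
    prefilter: bool = True

    @property
    def name(self) -> str:
        return "tvl1-skimage"


@dataclass
class FlowField:
    """Dense per-pixel displacement, pixels per onset→apex step."""

    u: np.ndarray
    v: np.ndarray
    estimator: str = "tvl1-skimage"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("flow components must be finite")


@dataclass
class FlowFeature:
    """(u, v, strain) stack at network resolution, channels-first, in [-1, 1]."""

    channels: np.ndarray                 # (3, H, W)
    role: str                            # "entire" | "puzzled"
    scale: np.ndarray = None             # per-channel max-abs used for normalisation

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) channels, got {self.channels.shape}")
        if self.role not in ("entire", "puzzled"):
            raise ValueError(f"role must be 'entire' or 'puzzled', got {self.role!r}")


def estimate_flow(onset: np.ndarray, apex: np.ndarray,
                  config: TVL1Config | None = None) -> FlowField:
    """Dense onset→apex optical flow under brightness constancy.

    Returns per-pixel (u, v) in pixels, x right / y down, such that
    ``apex(y, x) ≈ onset(y - v, x - u)``.
    """
    config = config or TVL1Config()
    onset = np.asarray(onset, dtype=float)
    apex = np.asarray(apex, dtype=float)
    if onset.shape != apex.shape:
        raise ValueError(f"onset/apex shape mismatch: {onset.shape} vs {apex.shape}")
    if onset.ndim != 2:
        raise ValueError("flow estimation expects single-channel images")
    # skimage returns (row, col) displacement; row -> v, col -> u
    v, u = optical_flow_tvl1(
        onset, apex,
        attachment=config.attachment, tightness=config.tightness,
        num_warp=config.num_warp, num_iter=config.num_iter,
        prefilter=config.prefilter,
    )
    return FlowField(u=u, v=v, estimator=config.name, params=asdict(config))


def optical_strain(flow: FlowField) -> np.ndarray:
    """Magnitude of the symmetric flow-gradient (strain) tensor.

    ε = ½(∇Of + ∇Ofᵀ) with Of = (u, v); the scalar map returned is the
    Frobenius norm √(ε_xx² + ε_yy² + 2·ε_xy²), zero for any rigid
    translation or rotation.  Gradients use central differences with
    one-sided stencils at the borders.
    """
    # axis 0 is y (rows), axis 1 is x (cols)
    du_dy, du_dx = np.gradient(flow.u)
    dv_dy, dv_dx = np.gradient(flow.v)
    e_xx = du_dx
    e_yy = dv_dy
    e_xy = 0.5 * (du_dy + dv_dx)
    return np.sqrt(e_xx ** 2 + e_yy ** 2 + 2.0 * e_xy ** 2)


def _maxabs_normalise(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = np.abs(stack).max(axis=(1, 2))
    safe = np.where(scale > 0, scale, 1.0)
    return stack / safe[:, None, None], scale


def build_feature(onset: np.ndarray, apex: np.ndarray,
                  resize_to: tuple[int, int] = (28, 28), role: str = "entire",
                  config: TVL1Config | None = None) -> FlowFeature:
    """Full motion-feature pipeline for one cropped (or puzzled) image pair.

    Flow is estimated at the native crop resolution, strain derived from it,
    and each of the three channels is bilinearly resized to ``resize_to``
    (height, width follow the (W, H) tuple order used for sizes) and scaled
    by its own max absolute value into [-1, 1].
    """
    flow = estimate_flow(onset, apex, config)
    strain = optical_strain(flow)
    h, w = int(resize_to[1]), int(resize_to[0])
    chans = np.stack([
        resize(c, (h, w), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
        for c in (flow.u, flow.v, strain)
    ])
    chans, scale = _maxabs_normalise(chans)
    return FlowFeature(channels=chans, role=role, scale=scale)


def flip_feature(feature: FlowFeature) -> FlowFeature:
    """Horizontal mirror of a flow feature.

    Mirroring the underlying face reverses horizontal motion, so the u
    channel is both spatially mirrored and negated; v and strain are only
    mirrored.  For the puzzled role the full-width mirror also exchanges the
    two eyebrow tiles, matching the puzzle of the mirrored face.
    """
    c = feature.channels[:, :, ::-1].copy()
    c[0] = -c[0]
    return FlowFeature(channels=c, role=feature.role, scale=feature.scale)
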