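"""View construction: windows -> per-view feature images -> depth-major tensors.

Each view is a deterministic per-channel feature map applied column-wise to
an ``L x C`` window, giving an ``M_i x C`` feature image (one column per
electrode, one row per feature value).  Before entering the network the
image is rearranged into a depth-major ``M_i x C x 1`` tensor (depth, width,
height): a 20-sample, 10-channel window under a 20-coefficient feature op
becomes a ``20 x 10 x 1`` input.

View indices are fixed: v1 = DWPTC, v2 = DWTC, v3 = Phin_FS1.  The "two
view" configuration uses {1, 2}.  Raw feature values are used directly (no
per-image rescaling); the network's input batch normalization takes care of
scale.  An optional min-max rescaling per image is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (PHIN_FS1_LENGTH, WaveletConfig, dwpt_coeffs,
                       dwt_coeffs, phin_fs1)
from .signals import WindowSet

__all__ = [
    "ViewConfig",
    "ViewImage",
    "ViewTensor",
    "MultiViewBatch",
    "build_view_image",
    "to_depth_layout",
    "from_depth_layout",
    "construct_views",
]

ALL_VIEWS = (1, 2, 3)
TWO_VIEWS = (1, 2)


@dataclass(frozen=True)
class ViewConfig:
    """Settings shared by all view-construction functions."""

    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    ar_order: int = 4
    minmax_scale: bool = False


@dataclass
class ViewImage:
    """An ``M_i x C`` feature image; column c is channel c's feature vector."""

    pixels: np.ndarray
    view_id: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D (M_i, C) matrix")
        if not np.isfinite(self.pixels).all():
            raise ValueError("feature image contains non-finite entries")


@dataclass
class ViewTensor:
    """Depth-major ``M_i x C x 1`` layout of a view image."""

    data: np.ndarray
    view_id: int

    @property
    def depth(self) -> int:
        return self.data.shape[0]


def _phin_image(window: np.ndarray, cfg: ViewConfig) -> np.ndarray:
    cols = [phin_fs1(window[:, c], m=cfg.sampen_m,
                     r_factor=cfg.sampen_r_factor, ar_order=cfg.ar_order)
            for c in range(window.shape[1])]
    return np.stack(cols, axis=1)


def build_view_image(window: np.ndarray, view_id: int,
                     cfg: ViewConfig = ViewConfig()) -> ViewImage:
    """Apply view ``view_id``'s feature op channel-wise to an ``L x C`` window."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2:
        raise ValueError("window must be an (L, C) segment")
    if not np.isfinite(window).all():
        raise ValueError("window contains non-finite samples")
    if view_id == 1:
        img = dwpt_coeffs(window.T, cfg.wavelet).T
    elif view_id == 2:
        img = dwt_coeffs(window.T, cfg.wavelet).T
    elif view_id == 3:
        img = _phin_image(window, cfg)
    else:
        raise ValueError(f"unknown view id {view_id}; views are 1, 2, 3")
    if cfg.minmax_scale:
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo)
    return ViewImage(img, view_id)


def to_depth_layout(img: ViewImage) -> ViewTensor:
    """Rearrange an ``M_i x C`` image into the ``M_i x C x 1`` input tensor."""
    return ViewTensor(img.pixels[:, :, None].copy(), img.view_id)


def from_depth_layout(t: ViewTensor) -> ViewImage:
    """Inverse of :func:`to_depth_layout`."""
    if t.data.ndim != 3 or t.data.shape[2] != 1:
        raise ValueError("expected an (M_i, C, 1) depth-major tensor")
    return ViewImage(t.data[:, :, 0].copy(), t.view_id)


@dataclass
class MultiViewBatch:
    """Per-view stacked tensors for a whole window set.

    ``arrays[j]`` has shape ``(n, M_j, C)`` (the singleton height axis is
    implicit) and is aligned with the window ordering of the source set.
    """

    arrays: list[np.ndarray]
    view_ids: tuple[int, ...]

    @property
    def view_dims(self) -> tuple[int, ...]:
        return tuple(a.shape[1] for a in self.arrays)

    @property
    def n_windows(self) -> int:
        return self.arrays[0].shape[0]

    def __len__(self) -> int:
        return self.n_windows

    def window(self, i: int) -> list[ViewTensor]:
        """The depth-major tensors of window ``i``, one per view."""
        return [ViewTensor(a[i][:, :, None].copy(), vid)
                for a, vid in zip(self.arrays, self.view_ids)]

    def subset(self, idx: np.ndarray) -> "MultiViewBatch":
        return MultiViewBatch([a[idx] for a in self.arrays], self.view_ids)


def construct_views(ws: WindowSet, view_ids: tuple[int, ...] = ALL_VIEWS,
                    cfg: ViewConfig = ViewConfig()) -> MultiViewBatch:
    """Build the selected views for every window of a set.

    Wavelet views are computed in one vectorised transform over the whole
    batch; the Phin_FS1 view is computed per channel.  The result holds
    ``|ws| * |view_ids|`` tensors, aligned with the window ordering, and
    records each view's feature dimension ``M_i`` for model construction.
    """
    if not view_ids:
        raise ValueError("view_ids must be a nonempty subset of {1, 2, 3}")
    if any(v not in ALL_VIEWS for v in view_ids):
        raise ValueError(f"unknown view id in {view_ids}; views are 1, 2, 3")
    w = ws.windows  # (n, L, C)
    n, L, C = w.shape
    wt = np.ascontiguousarray(np.swapaxes(w, 1, 2))  # (n, C, L)
    arrays: list[np.ndarray] = []
    for vid in view_ids:
        if vid == 1:
            feat = dwpt_coeffs(wt, cfg.wavelet)  # (n, C, M1)
            arr = np.swapaxes(feat, 1, 2)
        elif vid == 2:
            feat = dwt_coeffs(wt, cfg.wavelet)
            arr = np.swapaxes(feat, 1, 2)
        else:
            arr = np.empty((n, PHIN_FS1_LENGTH, C))
            for i in range(n):
                arr[i] = _phin_image(w[i], cfg)
        if cfg.minmax_scale:
            lo = arr.min(axis=(1, 2), keepdims=True)
            hi = arr.max(axis=(1, 2), keepdims=True)
            rng = np.where(hi > lo, hi - lo, 1.0)
            arr = (arr - lo) / rng
        arrays.append(np.ascontiguousarray(arr))
    return MultiViewBatch(arrays, tuple(view_ids))
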