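"""Sparse local-context feature.

A pixel is described by mean-filtered gray values sampled along eight
directions at 45-degree intervals, at radii that widen away from the pixel
(default {1, 3, 5, 9, 13, 17, 23, 29}), plus the pixel itself: 8 x 8 + 1 =
65 values with the defaults.  Each sample is the mean of a small window
(default 3x3) around the sampling position, which suppresses speckle; the
sparse geometry keeps the descriptor cheap while still encoding the fixed
spatial arrangement of cardiac tissue around the mitral annulus.

Feature values are raw mean gray levels in [0, 255] — nonnegative, as the
intersection kernel requires.  Layout is frozen: center value first, then
for each direction (in the order of ``DIRECTIONS``) the radii in ascending
order.  Borders are handled by replicate-edge padding, for both the mean
window and out-of-range sampling offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS",
    "DEFAULT_RADII",
    "SamplingPattern",
    "mean_sample",
    "extract_feature",
    "extract_features_batch",
]

#: (row, col) unit offsets at 45-degree intervals; row grows downward.
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)

DEFAULT_RADII: tuple[int, ...] = (1, 3, 5, 9, 13, 17, 23, 29)


@dataclass(frozen=True)
class SamplingPattern:
    """Geometry of the local-context feature."""

    radii: tuple[int, ...] = DEFAULT_RADII
    directions: tuple[tuple[int, int], ...] = DIRECTIONS
    include_center: bool = True
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        radii = tuple(int(r) for r in self.radii)
        if not radii or any(r < 1 for r in radii):
            raise ValueError("radii must be positive integers")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(
            self, "directions", tuple((int(dr), int(dc)) for dr, dc in self.directions)
        )

    @property
    def n_features(self) -> int:
        return len(self.directions) * len(self.radii) + int(self.include_center)

    @property
    def margin(self) -> int:
        """Border margin (pixels) inside which all samples stay in-image."""
        return max(self.radii) + self.smoothing_window // 2

    def offsets(self) -> np.ndarray:
        """(n_features, 2) array of (row, col) offsets in the frozen layout."""
        offs = []
        if self.include_center:
            offs.append((0, 0))
        for dr, dc in self.directions:
            for r in self.radii:
                offs.append((dr * r, dc * r))
        return np.asarray(offs, dtype=np.int64)

    def fingerprint(self) -> dict:
        """Layout descriptor stored with trained models to prevent drift."""
        return {
            "radii": list(self.radii),
            "directions": [list(d) for d in self.directions],
            "include_center": self.include_center,
            "smoothing_window": self.smoothing_window,
        }


def mean_sample(frame, point, window: int = 3) -> float:
    """Mean gray value of the ``window`` x ``window`` neighborhood of ``point``.

    Replicate-edge padding: out-of-image neighbors take the nearest edge
    pixel's value.  ``point`` itself must lie inside the image.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    img = _pixels(frame)
    h, w = img.shape
    r, c = int(point[0]), int(point[1])
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"sampling point {(r, c)} outside image {img.shape}")
    half = window // 2
    rows = np.clip(np.arange(r - half, r + half + 1), 0, h - 1)
    cols = np.clip(np.arange(c - half, c + half + 1), 0, w - 1)
    return float(img[np.ix_(rows, cols)].mean())


def _pixels(frame) -> np.ndarray:
    return np.asarray(getattr(frame, "pixels", frame), dtype=np.float64)


def _smoothed(frame, window: int) -> np.ndarray:
    img = _pixels(frame)
    if window == 1:
        return img
    # mode="nearest" is replicate-edge padding
    return ndimage.uniform_filter(img, size=window, mode="nearest")


def extract_features_batch(
    frame,
    points,
    pattern: SamplingPattern | None = None,
    on_border: str = "replicate",
) -> np.ndarray:
    """Local-context features at several pixels; one row per point.

    Parameters
    ----------
    points : (n, 2) array-like of (row, col)
        Query pixels; must lie inside the image.
    on_border : {"replicate", "raise"}
        With "replicate" (default), samples falling outside the image take
        the nearest edge value; with "raise", points closer than
        ``pattern.margin`` to the border are a coordinate error.
    """
    if pattern is None:
        pattern = SamplingPattern()
    img = _pixels(frame)
    h, w = img.shape
    pts = np.atleast_2d(np.asarray(points, dtype=np.int64))
    if pts.size == 0:
        return np.empty((0, pattern.n_features), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (row, col)")
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    )
    if not inside.all():
        bad = int(np.flatnonzero(~inside)[0])
        raise IndexError(f"point index {bad} {tuple(pts[bad])} outside image")
    if on_border == "raise":
        m = pattern.margin
        ok = (
            (pts[:, 0] >= m) & (pts[:, 0] < h - m)
            & (pts[:, 1] >= m) & (pts[:, 1] < w - m)
        )
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise IndexError(
                f"point index {bad} {tuple(pts[bad])} within margin {m} of border"
            )
    elif on_border != "replicate":
        raise ValueError("on_border must be 'replicate' or 'raise'")

    smoothed = _smoothed(img, pattern.smoothing_window)
    offs = pattern.offsets()
    rows = np.clip(pts[:, 0, None] + offs[None, :, 0], 0, h - 1)
    cols = np.clip(pts[:, 1, None] + offs[None, :, 1], 0, w - 1)
    return smoothed[rows, cols]


def extract_feature(
    frame,
    point,
    pattern: SamplingPattern | None = None,
    on_border: str = "replicate",
) -> np.ndarray:
    """Local-context feature vector at one pixel (see module docstring)."""
    return extract_features_batch(frame, [point], pattern, on_border)[0]
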