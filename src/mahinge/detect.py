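"""Pixel scanning and training-set assembly.

The first two layers of the classification flow: extract the local-context
feature at every pixel of a region of interest and classify it with the
trained SVM; positively classified pixels form the candidate set handed to
the refinement stage.  This module also assembles (features, labels) pairs
from annotated frames: positives are pixels near a ground-truth hinge
point, negatives are seeded uniform samples far from both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import SamplingPattern, extract_features_batch
from .iksvm import IKSVMModel, IntersectionKernelSVC, decide_naive

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSpec",
    "CandidateSet",
    "build_training_set",
    "scan_frame",
    "default_roi",
    "annulus_band_roi",
]


@dataclass(frozen=True)
class TrainingSpec:
    """How to turn annotated frames into an SVM training set.

    positive_radius : pixels; all pixels within this Euclidean distance of
        a truth point are labelled +1 (0 keeps only the truth pixels).
    negative_min_distance : pixels; negatives are sampled at least this far
        (Euclidean) from both truth points.  Must exceed positive_radius,
        and should stay *below* half the valve-gap width so the classifier
        sees near-miss pixels inside the gap as negatives.
    negatives_per_frame : uniform seeded samples per frame.
    stride : pixels; grid step used when sampling negatives.
    seed : reproducibility of the negative sampling.
    """

    positive_radius: int = 2
    negative_min_distance: int = 6
    negatives_per_frame: int = 150
    stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positive_radius < 0 or self.negatives_per_frame < 0:
            raise ValueError("radius and counts must be nonnegative")
        if not self.positive_radius < self.negative_min_distance:
            raise ValueError("positive_radius must be < negative_min_distance")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class CandidateSet:
    """Pixels classified positive in one frame, with their decision values."""

    frame_id: str
    points: np.ndarray          # (k, 2) int (row, col), unique
    decision_values: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)
        self.decision_values = np.asarray(
            self.decision_values, dtype=np.float64
        ).ravel()
        if self.points.shape[0] != self.decision_values.shape[0]:
            raise ValueError("points and decision_values must align")

    def __len__(self) -> int:
        return self.points.shape[0]


def default_roi(shape, pattern: SamplingPattern):
    """Full image minus the feature margin: (top, bottom, left, right), half-open."""
    h, w = shape
    m = pattern.margin
    return (m, h - m, m, w - m)


def annulus_band_roi(frame, pattern: SamplingPattern, band: int = 12):
    """Horizontal band around the annotated annulus row (phantom convenience)."""
    if frame.truth is None:
        raise ValueError("annulus_band_roi requires an annotated frame")
    rows = [p[0] for p in frame.truth]
    t0, b0, l0, r0 = default_roi(frame.shape, pattern)
    top = max(t0, min(rows) - band)
    bottom = min(b0, max(rows) + band + 1)
    return (top, bottom, l0, r0)


def build_training_set(
    frames,
    pattern: SamplingPattern | None = None,
    spec: TrainingSpec | None = None,
    return_points: bool = False,
):
    """Assemble (features, labels) from annotated frames.

    Positives: every pixel within ``positive_radius`` of either truth point.
    Negatives: ``negatives_per_frame`` pixels drawn uniformly (seeded) from
    the default ROI grid, at Euclidean distance >= ``negative_min_distance``
    from both truth points.  Labels are +1 / -1.
    """
    if pattern is None:
        pattern = SamplingPattern()
    if spec is None:
        spec = TrainingSpec()
    X_parts, y_parts, recs = [], [], []
    children = np.random.SeedSequence(spec.seed).spawn(max(len(frames), 1))
    for frame, child in zip(frames, children):
        if frame.truth is None:
            raise ValueError(f"frame {frame.frame_id!r} has no truth annotation")
        rng = np.random.default_rng(child)
        h, w = frame.shape
        truth = np.asarray(frame.truth, dtype=np.float64)

        # positives: disk of positive_radius around each truth point
        pr = spec.positive_radius
        pos = set()
        for tr, tc in frame.truth:
            for dr in range(-pr, pr + 1):
                for dc in range(-pr, pr + 1):
                    if dr * dr + dc * dc <= pr * pr:
                        r, c = tr + dr, tc + dc
                        if 0 <= r < h and 0 <= c < w:
                            pos.add((r, c))
        pos_pts = np.asarray(sorted(pos), dtype=np.int64)

        # negatives: rejection-sample the stride grid of the default ROI
        top, bottom, left, right = default_roi(frame.shape, pattern)
        neg_pts = np.empty((0, 2), dtype=np.int64)
        if spec.negatives_per_frame > 0:
            if bottom <= top or right <= left:
                raise ValueError("image too small for the feature margin")
            grid_r = np.arange(top, bottom, spec.stride)
            grid_c = np.arange(left, right, spec.stride)
            need, chunks = spec.negatives_per_frame, []
            got = 0
            while got < need:
                k = max(4 * (need - got), 16)
                rr = rng.choice(grid_r, size=k)
                cc = rng.choice(grid_c, size=k)
                cand = np.stack([rr, cc], axis=1).astype(np.float64)
                d = np.linalg.norm(cand[:, None, :] - truth[None, :, :], axis=2)
                keep = cand[(d >= spec.negative_min_distance).all(axis=1)]
                chunks.append(keep.astype(np.int64))
                got += keep.shape[0]
            neg_pts = np.concatenate(chunks)[:need]

        pts = np.concatenate([pos_pts, neg_pts]) if len(neg_pts) else pos_pts
        X_parts.append(extract_features_batch(frame, pts, pattern))
        y_parts.append(
            np.concatenate([np.ones(len(pos_pts)), -np.ones(len(neg_pts))])
        )
        if return_points:
            recs.extend(
                (frame.frame_id, int(r), int(c))
                for r, c in pts
            )
    X = np.concatenate(X_parts) if X_parts else np.empty((0, pattern.n_features))
    y = np.concatenate(y_parts) if y_parts else np.empty((0,))
    return (X, y.astype(np.float64), recs) if return_points else (X, y.astype(np.float64))


def scan_frame(
    frame,
    model,
    pattern: SamplingPattern | None = None,
    stride: int = 1,
    roi=None,
) -> CandidateSet:
    """Classify every stride-grid pixel of the ROI; return the positives.

    ``model`` may be a fitted :class:`IntersectionKernelSVC` (fast tables
    used automatically) or a bare :class:`IKSVMModel` (direct expansion).
    An ROI that is empty after the feature margin yields an empty candidate
    set (logged), not an error.
    """
    if pattern is None:
        pattern = SamplingPattern()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = frame.shape
    if roi is None:
        roi = default_roi(frame.shape, pattern)
    top, bottom, left, right = roi
    if not (0 <= top and bottom <= h and 0 <= left and right <= w):
        raise ValueError(f"roi {roi} outside image {frame.shape}")
    if bottom <= top or right <= left:
        logger.warning("empty ROI %s for frame %s", roi, frame.frame_id)
        return CandidateSet(frame.frame_id, np.empty((0, 2)), np.empty(0))

    rr, cc = np.meshgrid(
        np.arange(top, bottom, stride), np.arange(left, right, stride),
        indexing="ij",
    )
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    X = extract_features_batch(frame, pts, pattern)
    if isinstance(model, IntersectionKernelSVC):
        h_vals = model.decision_function(X)
    elif isinstance(model, IKSVMModel):
        h_vals = decide_naive(model, X)
    else:
        raise TypeError("model must be IntersectionKernelSVC or IKSVMModel")
    positive = h_vals >= 0  # 0 counts as positive, matching classify()
    return CandidateSet(frame.frame_id, pts[positive], h_vals[positive])
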