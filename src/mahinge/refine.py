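"""Candidate refinement: density field, adaptive threshold, K-means.

The SVM scan produces a cloud of candidate pixels: dense clumps at the two
true hinge points plus scattered misclassifications.  Density separates
them.  Each candidate stamps a diamond-shaped weight template onto a field,

    F(A) = sum over candidates y with D_block(y, A) < R of (R - D_block(y, A)),

where D_block is the Manhattan (block) distance and R the template radius
(default 10, so an isolated candidate contributes weight 10 at its own
pixel).  True clusters become bright blobs, stray candidates stay dim.  A
threshold H is then searched between the smallest and largest field values
until the pixels with F > H form *exactly two* connected components; their
coordinate centroids seed a 2-means pass over all candidates within a
fixed scale of either centroid, and the final cluster means (rounded to
pixels) are the hinge points.  The left (smaller-column) point is labelled
septal by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage import measure

from .detect import CandidateSet, scan_frame
from .features import SamplingPattern

logger = logging.getLogger(__name__)

__all__ = [
    "RefineConfig",
    "DensityField",
    "HingeResult",
    "RefinementError",
    "block_distance",
    "weight_template",
    "density_field",
    "adaptive_threshold",
    "component_centroids",
    "kmeans_refine",
    "localize",
]


class RefinementError(RuntimeError):
    """Raised when no hinge points can be recovered from the candidates."""


@dataclass(frozen=True)
class RefineConfig:
    """Knobs of the refinement stage.

    template_radius : R of the weight template (pixels).
    template : "diamond" (support D_block < R) or "box" (square window of
        half-width R // 2 with the same R - D_block weights).
    connectivity : 4 or 8, for the connected-component count.
    kmeans_scale : block-distance gate around each initial centre for the
        K-means pass; None means 2 * R.
    """

    template_radius: int = 10
    template: str = "diamond"
    connectivity: int = 8
    kmeans_scale: int | None = None
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.template_radius < 1:
            raise ValueError("template_radius must be >= 1")
        if self.template not in ("diamond", "box"):
            raise ValueError("template must be 'diamond' or 'box'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def scale(self) -> int:
        return 2 * self.template_radius if self.kmeans_scale is None else self.kmeans_scale


@dataclass
class DensityField:
    values: np.ndarray       # (h, w) nonnegative
    template_radius: int = 10
    template: str = "diamond"


@dataclass
class HingeResult:
    """Final hinge points plus the intermediates that produced them."""

    detected: bool
    septal: tuple[int, int] | None = None
    lateral: tuple[int, int] | None = None
    threshold: float | None = None
    component_centroids: tuple | None = None
    cluster_members: tuple | None = None
    field: DensityField | None = None
    candidates: CandidateSet | None = None
    flags: list = dc_field(default_factory=list)
    frame_id: str = ""


def block_distance(p, q) -> int:
    """Manhattan (block) distance between two pixel coordinates."""
    return abs(int(p[0]) - int(q[0])) + abs(int(p[1]) - int(q[1]))


def weight_template(R: int, kind: str = "diamond") -> np.ndarray:
    """The stamped weight patch: (R - D_block) clipped at zero.

    "diamond": full support D_block < R, a diamond of width 2R - 1.
    "box": the same weights restricted to a square window of half-width
    R // 2 (the window reading of the template's neighborhood).
    """
    if kind == "diamond":
        half = R - 1
    elif kind == "box":
        half = R // 2
    else:
        raise ValueError("template kind must be 'diamond' or 'box'")
    d = np.arange(-half, half + 1)
    dist = np.abs(d)[:, None] + np.abs(d)[None, :]
    return np.maximum(R - dist, 0).astype(np.float64)


def density_field(
    candidates: CandidateSet,
    shape,
    R: int = 10,
    template: str = "diamond",
) -> DensityField:
    """Weighted candidate density: stamp the template at every candidate."""
    if R < 1:
        raise ValueError("template radius must be >= 1")
    h, w = shape
    pts = candidates.points
    if pts.size and (
        pts[:, 0].min() < 0 or pts[:, 0].max() >= h
        or pts[:, 1].min() < 0 or pts[:, 1].max() >= w
    ):
        raise ValueError("candidate outside field shape")
    tmpl = weight_template(R, template)
    half = tmpl.shape[0] // 2
    F = np.zeros((h, w), dtype=np.float64)
    for r, c in pts:
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        F[r0:r1, c0:c1] += tmpl[
            r0 - (r - half) : r1 - (r - half), c0 - (c - half) : c1 - (c - half)
        ]
    return DensityField(values=F, template_radius=R, template=template)


def _label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    return measure.label(mask, connectivity=1 if connectivity == 4 else 2)


def _components(field: np.ndarray, H: float, connectivity: int):
    lab = _label(field > H, connectivity)
    return [
        np.argwhere(lab == k) for k in range(1, lab.max() + 1)
    ]


def _split_two(points: np.ndarray, max_iter: int = 100):
    """Deterministic 2-means split of one pixel set (degenerate fallback)."""
    order = np.lexsort((points[:, 0], points[:, 1]))  # by column, then row
    c1 = points[order[0]].astype(np.float64)
    c2 = points[order[-1]].astype(np.float64)
    pts = points.astype(np.float64)
    assign = None
    for _ in range(max_iter):
        d1 = ((pts - c1) ** 2).sum(1)
        d2 = ((pts - c2) ** 2).sum(1)
        new = d2 < d1
        if assign is not None and np.array_equal(new, assign):
            break
        assign = new
        if (~assign).any():
            c1 = pts[~assign].mean(0)
        if assign.any():
            c2 = pts[assign].mean(0)
    return [points[~assign], points[assign]]


def adaptive_threshold(field: DensityField, connectivity: int = 8):
    """Search a threshold H at which the field splits into exactly two blobs.

    Discrete binary search over the sorted distinct positive field values:
    fewer than two components means H is too high (decrease), more than two
    means too low (increase); the first probe with exactly two wins.  If the
    search interval collapses, fall back: among probes with >= 2 components
    take the max-count probe (smallest H on ties) and keep the two
    components with the largest summed field weight (flag ``best_probe``);
    if every probe had a single component, split it by 2-means on its pixels
    (flag ``single_component``).

    Returns ``(threshold, (component_1, component_2), flags)`` with each
    component an (k, 2) array of pixel coordinates.
    """
    F = field.values
    vals = np.unique(F[F > 0])
    if vals.size == 0:
        raise RefinementError("density field has no positive values")
    lo, hi = 0, vals.size - 1
    probes = []
    while lo <= hi:
        mid = (lo + hi) // 2
        H = float(vals[mid])
        comps = _components(F, H, connectivity)
        probes.append((H, comps))
        if len(comps) == 2:
            return H, (comps[0], comps[1]), []
        if len(comps) < 2:
            hi = mid - 1  # threshold too high: decrease H
        else:
            lo = mid + 1  # too many blobs: increase H
    multi = [(H, comps) for H, comps in probes if len(comps) >= 2]
    if multi:
        best_n = max(len(c) for _, c in multi)
        H, comps = min(
            ((H, c) for H, c in multi if len(c) == best_n), key=lambda t: t[0]
        )
        weights = [F[c[:, 0], c[:, 1]].sum() for c in comps]
        top2 = np.argsort(weights)[-2:][::-1]
        logger.info("adaptive threshold fallback best_probe at H=%g", H)
        return H, (comps[top2[0]], comps[top2[1]]), ["best_probe"]
    # single connected blob at every probe: take the lowest threshold and split
    H = float(vals[0])
    comps = _components(F, H, connectivity)
    if not comps:  # only one distinct positive value: strict > empties the mask
        H = 0.0
        comps = _components(F, H, connectivity)
    if len(comps) == 1:
        parts = _split_two(comps[0])
    else:
        parts = comps[:2]
    logger.info("adaptive threshold fallback single_component at H=%g", H)
    return H, (parts[0], parts[1]), ["single_component"]


def component_centroids(components):
    """Coordinate means of the two components, as float (row, col) pairs."""
    cents = []
    for comp in components:
        comp = np.asarray(comp, dtype=np.float64)
        if comp.size == 0:
            raise RefinementError("empty component has no centroid")
        cents.append(tuple(comp.mean(axis=0)))
    return tuple(cents)


def kmeans_refine(
    candidates: CandidateSet,
    centers,
    scale: int,
    max_iter: int = 100,
    **context,
) -> HingeResult:
    """2-means over candidates near the initial centres; means become hinges.

    Candidates within block distance <= ``scale`` of either centre are
    assigned to the nearer centre (Euclidean), centres move to cluster
    means, until assignments stabilize or ``max_iter``.  A cluster that
    empties is re-seeded at its initial centre and flagged.  Final means,
    rounded to the nearest pixel, are labelled septal/lateral by column
    order (row order breaks ties).
    """
    c_init = [np.asarray(c, dtype=np.float64) for c in centers]
    if len(c_init) != 2 or np.allclose(c_init[0], c_init[1]):
        raise RefinementError("two distinct initial centers required")
    if scale <= 0:
        raise ValueError("scale must be positive")
    pts = candidates.points.astype(np.float64)
    flags = list(context.pop("flags", []))
    if len(pts):
        bd = np.abs(pts[:, None, :] - np.rint(np.stack(c_init))[None, :, :]).sum(2)
        pts = pts[(bd <= scale).any(axis=1)]
    if len(pts) == 0:
        raise RefinementError("no candidates within scale of the initial centers")

    centers_now = [c.copy() for c in c_init]
    assign = None
    for _ in range(max_iter):
        d = np.stack(
            [((pts - c) ** 2).sum(axis=1) for c in centers_now], axis=1
        )
        new = d.argmin(axis=1)
        if assign is not None and np.array_equal(new, assign):
            break
        assign = new
        for k in range(2):
            members = pts[assign == k]
            if len(members):
                centers_now[k] = members.mean(axis=0)
            else:
                centers_now[k] = c_init[k].copy()
                if "empty_cluster" not in flags:
                    flags.append("empty_cluster")
    members = (pts[assign == 0], pts[assign == 1])
    if not (len(members[0]) or len(members[1])):
        raise RefinementError("both clusters empty")
    final = [tuple(int(v) for v in np.rint(c)) for c in centers_now]
    order = sorted(range(2), key=lambda k: (final[k][1], final[k][0]))
    septal, lateral = final[order[0]], final[order[1]]
    return HingeResult(
        detected=True,
        septal=septal,
        lateral=lateral,
        threshold=context.pop("threshold", None),
        component_centroids=context.pop("component_centroids", None),
        cluster_members=(members[order[0]], members[order[1]]),
        field=context.pop("field", None),
        candidates=candidates,
        flags=flags,
        frame_id=candidates.frame_id,
    )


def localize(
    frame,
    model,
    pattern: SamplingPattern | None = None,
    config: RefineConfig | None = None,
    stride: int = 1,
    roi=None,
) -> HingeResult:
    """Full three-layer flow: scan -> density -> threshold -> 2-means.

    An empty candidate set, or candidates too scattered to refine, yields a
    ``detected=False`` result rather than an exception; genuine contract
    violations (bad ROI, dimension mismatch) still raise.
    """
    if pattern is None:
        pattern = SamplingPattern()
    if config is None:
        config = RefineConfig()
    candidates = scan_frame(frame, model, pattern, stride=stride, roi=roi)
    if len(candidates) == 0:
        return HingeResult(
            detected=False, candidates=candidates,
            flags=["no_candidates"], frame_id=frame.frame_id,
        )
    field = density_field(
        candidates, frame.shape, R=config.template_radius, template=config.template
    )
    try:
        H, comps, flags = adaptive_threshold(field, config.connectivity)
        cents = component_centroids(comps)
        if np.allclose(cents[0], cents[1]):
            raise RefinementError("coincident component centroids")
        return kmeans_refine(
            candidates, cents, scale=config.scale, max_iter=config.max_iter,
            threshold=H, component_centroids=cents, field=field, flags=flags,
        )
    except RefinementError as exc:
        logger.warning("refinement failed for %s: %s", frame.frame_id, exc)
        return HingeResult(
            detected=False, field=field, candidates=candidates,
            flags=["refinement_failed"], frame_id=frame.frame_id,
        )
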