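"""Error statistics against manual / ground-truth hinge annotations.

Per landmark (septal, lateral) and axis (x = image column, y = image row)
the table reports the mean absolute error and the population variance of
the absolute errors, in millimetres; frames with no detection are counted
as failures and excluded from the statistics.  A combined Euclidean error
is reported as a convenience.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ErrorTable", "landmark_errors", "summary_report", "parse_report"]

LANDMARKS = ("septal", "lateral")
AXES = ("x", "y")  # x = column, y = row


@dataclass
class ErrorTable:
    """Per-landmark, per-axis absolute-error statistics in mm."""

    mean_mm: dict          # {landmark: {axis: float}}
    variance_mm2: dict     # {landmark: {axis: float}}
    mean_euclidean_mm: float
    n_frames: int
    n_failures: int
    config: dict = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ErrorTable):
            return NotImplemented
        return (
            self.n_frames == other.n_frames
            and self.n_failures == other.n_failures
            and self.mean_euclidean_mm == other.mean_euclidean_mm
            and self.mean_mm == other.mean_mm
            and self.variance_mm2 == other.variance_mm2
        )


def _sorted_truth(truth):
    """Order the annotated pair by column (septal = smaller column)."""
    return tuple(sorted(truth, key=lambda p: (p[1], p[0])))


def landmark_errors(predicted, frames, pixel_spacing_mm: float | None = None) -> ErrorTable:
    """Compare one prediction per annotated frame with its ground truth.

    ``predicted`` is a list of HingeResult (or objects with ``detected``,
    ``septal``, ``lateral``), aligned with ``frames``.  ``pixel_spacing_mm``
    defaults to the frames' own spacing (which must then agree across
    frames).
    """
    if len(predicted) != len(frames):
        raise ValueError("one prediction per frame required")
    if pixel_spacing_mm is None:
        spacings = {float(f.pixel_spacing_mm) for f in frames}
        if len(spacings) != 1:
            raise ValueError("frames disagree on pixel spacing; pass it explicitly")
        pixel_spacing_mm = spacings.pop()
    if not pixel_spacing_mm > 0:
        raise ValueError("pixel_spacing_mm must be positive")

    errs = {lm: {ax: [] for ax in AXES} for lm in LANDMARKS}
    euclid = []
    n_failures = 0
    for res, frame in zip(predicted, frames):
        if frame.truth is None:
            raise ValueError(f"frame {frame.frame_id!r} has no truth annotation")
        if not getattr(res, "detected", False):
            n_failures += 1
            continue
        truth = dict(zip(LANDMARKS, _sorted_truth(frame.truth)))
        pred = {"septal": res.septal, "lateral": res.lateral}
        for lm in LANDMARKS:
            dr = (pred[lm][0] - truth[lm][0]) * pixel_spacing_mm
            dc = (pred[lm][1] - truth[lm][1]) * pixel_spacing_mm
            errs[lm]["x"].append(abs(dc))
            errs[lm]["y"].append(abs(dr))
            euclid.append(float(np.hypot(dr, dc)))

    def _stats(v):
        a = np.asarray(v, dtype=np.float64)
        if a.size == 0:
            return float("nan"), float("nan")
        return float(a.mean()), float(a.var(ddof=0))  # population variance

    mean_mm = {lm: {} for lm in LANDMARKS}
    var_mm2 = {lm: {} for lm in LANDMARKS}
    for lm in LANDMARKS:
        for ax in AXES:
            m, v = _stats(errs[lm][ax])
            mean_mm[lm][ax] = m
            var_mm2[lm][ax] = v
    mean_eu = float(np.mean(euclid)) if euclid else float("nan")
    return ErrorTable(
        mean_mm=mean_mm,
        variance_mm2=var_mm2,
        mean_euclidean_mm=mean_eu,
        n_frames=len(frames),
        n_failures=n_failures,
    )


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def summary_report(table: ErrorTable, config: dict | None = None, fmt: str = "json") -> str:
    """Render the error table (plus optional config snapshot) to text.

    Formats: "json", "csv" (one row per landmark/axis, mirroring the
    conventional mean/variance layout), "text" (aligned columns).  All
    formats carry full float precision and parse back losslessly via
    :func:`parse_report`.
    """
    cfg = config if config is not None else table.config
    if fmt == "json":
        payload = {
            "schema": "mahinge-error-table",
            "mean_mm": table.mean_mm,
            "variance_mm2": table.variance_mm2,
            "mean_euclidean_mm": table.mean_euclidean_mm,
            "n_frames": table.n_frames,
            "n_failures": table.n_failures,
            "config": cfg,
        }
        return json.dumps(payload, sort_keys=True, indent=1)
    if fmt == "csv":
        rows = [
            {
                "landmark": lm,
                "axis": ax,
                "mean_mm": _fmt(table.mean_mm[lm][ax]),
                "variance_mm2": _fmt(table.variance_mm2[lm][ax]),
            }
            for lm in LANDMARKS
            for ax in AXES
        ]
        df = pd.DataFrame(rows)
        buf = _io.StringIO()
        buf.write(f"# n_frames={table.n_frames} n_failures={table.n_failures} "
                  f"mean_euclidean_mm={_fmt(table.mean_euclidean_mm)}\n")
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "text":
        lines = [
            "Hinge-point localization error vs. manual annotation (mm)",
            f"frames: {table.n_frames}   failures: {table.n_failures}   "
            f"mean Euclidean: {_fmt(table.mean_euclidean_mm)}",
            f"{'landmark':<10}{'axis':<6}{'mean_mm':<26}{'variance_mm2':<26}",
        ]
        for lm in LANDMARKS:
            for ax in AXES:
                lines.append(
                    f"{lm:<10}{ax:<6}{_fmt(table.mean_mm[lm][ax]):<26}"
                    f"{_fmt(table.variance_mm2[lm][ax]):<26}"
                )
        if cfg:
            lines.append("config: " + json.dumps(cfg, sort_keys=True))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def parse_report(text: str, fmt: str = "json") -> ErrorTable:
    """Inverse of :func:`summary_report` for every supported format."""
    if fmt == "json":
        d = json.loads(text)
        if d.get("schema") != "mahinge-error-table":
            raise ValueError("not a mahinge error-table report")
        return ErrorTable(
            mean_mm=d["mean_mm"],
            variance_mm2=d["variance_mm2"],
            mean_euclidean_mm=d["mean_euclidean_mm"],
            n_frames=d["n_frames"],
            n_failures=d["n_failures"],
            config=d.get("config") or {},
        )
    if fmt == "csv":
        lines = text.splitlines()
        header = dict(
            item.split("=", 1) for item in lines[0].lstrip("# ").split()
        )
        # dtype=str + float() keeps full precision (pandas' fast float
        # parser can be one ulp off)
        df = pd.read_csv(_io.StringIO("\n".join(lines[1:])), dtype=str)
        mean_mm = {lm: {} for lm in LANDMARKS}
        var_mm2 = {lm: {} for lm in LANDMARKS}
        for _, row in df.iterrows():
            mean_mm[row["landmark"]][row["axis"]] = float(row["mean_mm"])
            var_mm2[row["landmark"]][row["axis"]] = float(row["variance_mm2"])
        return ErrorTable(
            mean_mm=mean_mm,
            variance_mm2=var_mm2,
            mean_euclidean_mm=float(header["mean_euclidean_mm"]),
            n_frames=int(header["n_frames"]),
            n_failures=int(header["n_failures"]),
        )
    if fmt == "text":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        meta = lines[1].replace("frames:", "").replace("failures:", "|").replace(
            "mean Euclidean:", "|"
        )
        n_frames_s, n_failures_s, eu_s = [p.strip() for p in meta.split("|")]
        mean_mm = {lm: {} for lm in LANDMARKS}
        var_mm2 = {lm: {} for lm in LANDMARKS}
        for ln in lines[3:]:
            if ln.startswith("config:"):
                continue
            lm, ax, m, v = ln.split()
            mean_mm[lm][ax] = float(m)
            var_mm2[lm][ax] = float(v)
        return ErrorTable(
            mean_mm=mean_mm,
            variance_mm2=var_mm2,
            mean_euclidean_mm=float(eu_s),
            n_frames=int(n_frames_s),
            n_failures=int(n_failures_s),
        )
    raise ValueError(f"unknown report format {fmt!r}")
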