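"""File formats: frames (PNG/TIFF), annotations (CSV), models (JSON).

All artifacts are plain text or standard images so runs are inspectable
and diffable; trained models store support vectors, signed coefficients,
bias and a feature-layout fingerprint, and the fast tables are rebuilt on
load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .detect import CandidateSet
from .iksvm import IKSVMModel
from .phantom import GrayFrame

__all__ = [
    "save_frame",
    "load_frame",
    "write_truth_csv",
    "read_truth_csv",
    "write_manifest",
    "read_manifest",
    "save_model",
    "load_model",
    "write_candidates_csv",
    "read_candidates_csv",
    "save_overlay",
    "save_dataset",
    "load_dataset",
]


def save_frame(frame: GrayFrame, path) -> None:
    """Write the frame as an 8-bit grayscale PNG or TIFF (by extension)."""
    img = np.clip(np.rint(frame.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(str(path))


def load_frame(path, pixel_spacing_mm: float = 1.0,
               truth=None, frame_id: str | None = None) -> GrayFrame:
    img = np.asarray(Image.open(str(path)).convert("L"), dtype=np.float64)
    return GrayFrame(
        pixels=img,
        pixel_spacing_mm=pixel_spacing_mm,
        truth=truth,
        frame_id=frame_id or Path(path).stem,
    )


def write_truth_csv(frames, path) -> None:
    """Hinge annotations: frame_id, point_label in {septal, lateral}, row, col."""
    rows = []
    for f in frames:
        if f.truth is None:
            continue
        pts = sorted(f.truth, key=lambda p: (p[1], p[0]))
        for label, (r, c) in zip(("septal", "lateral"), pts):
            rows.append(
                {"frame_id": f.frame_id, "point_label": label, "row": r, "col": c}
            )
    pd.DataFrame(rows, columns=["frame_id", "point_label", "row", "col"]).to_csv(
        path, index=False
    )


def read_truth_csv(path) -> dict:
    """{frame_id: ((row, col) septal, (row, col) lateral)}."""
    df = pd.read_csv(path)
    out = {}
    for fid, grp in df.groupby("frame_id", sort=False):
        by_label = {
            row.point_label: (int(row.row), int(row.col))
            for row in grp.itertuples()
        }
        out[str(fid)] = (by_label["septal"], by_label["lateral"])
    return out


def write_manifest(path, *, pixel_spacing_mm: float, seed: int, frame_ids,
                   extra: dict | None = None) -> None:
    payload = {
        "schema": "mahinge-dataset",
        "pixel_spacing_mm": pixel_spacing_mm,
        "seed": seed,
        "frames": list(frame_ids),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_manifest(path) -> dict:
    d = json.loads(Path(path).read_text())
    if d.get("schema") != "mahinge-dataset":
        raise ValueError("not a mahinge dataset manifest")
    return d


def save_dataset(frames, outdir, seed: int = 0, fmt: str = "png") -> None:
    """Frames as images + truth.csv + manifest.json in one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = frames[0].pixel_spacing_mm if frames else 1.0
    for f in frames:
        save_frame(f, outdir / f"{f.frame_id}.{fmt}")
    write_truth_csv(frames, outdir / "truth.csv")
    write_manifest(
        outdir / "manifest.json",
        pixel_spacing_mm=spacing,
        seed=seed,
        frame_ids=[f.frame_id for f in frames],
    )


def load_dataset(indir) -> list[GrayFrame]:
    indir = Path(indir)
    manifest = read_manifest(indir / "manifest.json")
    truth_path = indir / "truth.csv"
    truth = read_truth_csv(truth_path) if truth_path.exists() else {}
    frames = []
    for fid in manifest["frames"]:
        matches = sorted(indir.glob(f"{fid}.*"))
        img_path = next(p for p in matches if p.suffix in (".png", ".tif", ".tiff"))
        frames.append(
            load_frame(
                img_path,
                pixel_spacing_mm=manifest["pixel_spacing_mm"],
                truth=truth.get(fid),
                frame_id=fid,
            )
        )
    return frames


def save_model(model: IKSVMModel, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path) -> IKSVMModel:
    return IKSVMModel.from_json(Path(path).read_text())


def write_candidates_csv(candidates: CandidateSet, path) -> None:
    pd.DataFrame(
        {
            "frame_id": candidates.frame_id,
            "row": candidates.points[:, 0],
            "col": candidates.points[:, 1],
            "decision_value": candidates.decision_values,
        }
    ).to_csv(path, index=False)


def read_candidates_csv(path) -> list[CandidateSet]:
    df = pd.read_csv(path)
    out = []
    for fid, grp in df.groupby("frame_id", sort=False):
        out.append(
            CandidateSet(
                frame_id=str(fid),
                points=grp[["row", "col"]].to_numpy(),
                decision_values=grp["decision_value"].to_numpy(),
            )
        )
    return out


def save_overlay(frame: GrayFrame, candidates: CandidateSet, path,
                 result=None) -> None:
    """Frame with candidates painted red (and hinge points green) as PNG."""
    gray = np.clip(np.rint(frame.pixels), 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for r, c in candidates.points:
        rgb[r, c] = (255, 0, 0)
    if result is not None and getattr(result, "detected", False):
        for r, c in (result.septal, result.lateral):
            rgb[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2] = (0, 255, 0)
    Image.fromarray(rgb, mode="RGB").save(str(path))
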