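"""End-to-end detector: phantom/annotated frames in, hinge points out.

:class:`HingePointDetector` is a scikit-learn-style estimator: ``fit`` on a
list of annotated frames builds the training set and trains the
intersection-kernel SVM; ``predict`` runs the three-layer flow (pixel scan,
density field, adaptive threshold + 2-means) on each frame and returns one
:class:`~mahinge.refine.HingeResult` per frame.  ``run_demo`` wires the
whole pipeline over generated phantoms and writes the evaluation report —
the same path the command-line ``mahinge demo`` takes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import io as mio
from .detect import TrainingSpec, build_training_set
from .evaluation import ErrorTable, landmark_errors, summary_report
from .features import SamplingPattern
from .iksvm import IntersectionKernelSVC
from .phantom import PhantomParams, generate_dataset
from .refine import RefineConfig, localize

__all__ = ["HingePointDetector", "RunConfig", "run_demo"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run (logged with every output)."""

    phantom: PhantomParams = PhantomParams()
    pattern: SamplingPattern = SamplingPattern()
    training: TrainingSpec = TrainingSpec()
    refine: RefineConfig = RefineConfig()
    C: float = 1.0
    kernel: str = "intersection"
    gamma: str | float = "scale"
    tol: float = 1e-6
    stride: int = 1
    n_train: int = 10
    n_test: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pattern"]["directions"] = [list(x) for x in self.pattern.directions]
        d["pattern"]["radii"] = list(self.pattern.radii)
        return d


class HingePointDetector(BaseEstimator):
    """Mitral-annulus hinge-point detector over grayscale frames.

    Parameters mirror the stage modules: the sampling pattern of the
    local-context feature, the SVM (C, kernel, tol), the training-set
    recipe, the scan stride, and the refinement stage (template radius,
    connectivity, K-means scale).

    ``fit(frames)`` expects frames carrying ``truth`` annotations;
    ``predict(frames)`` returns a list of HingeResult; ``score(frames)``
    is the negative median Euclidean pixel error (failures count as +inf),
    so larger is better as scikit-learn expects.
    """

    def __init__(
        self,
        pattern: SamplingPattern | None = None,
        training: TrainingSpec | None = None,
        refine: RefineConfig | None = None,
        C: float = 1.0,
        kernel: str = "intersection",
        gamma="scale",
        tol: float = 1e-6,
        stride: int = 1,
        roi=None,
    ):
        self.pattern = pattern
        self.training = training
        self.refine = refine
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.tol = tol
        self.stride = stride
        self.roi = roi

    def _resolved(self):
        return (
            self.pattern or SamplingPattern(),
            self.training or TrainingSpec(),
            self.refine or RefineConfig(),
        )

    def fit(self, frames, y=None):
        pattern, training, _ = self._resolved()
        X, labels = build_training_set(frames, pattern, training)
        self.svc_ = IntersectionKernelSVC(
            C=self.C, kernel=self.kernel, gamma=self.gamma, tol=self.tol
        ).fit(X, labels)
        self.pattern_ = pattern
        self.n_training_samples_ = X.shape[0]
        return self

    def predict(self, frames):
        check_is_fitted(self, "svc_")
        _, _, refine_cfg = self._resolved()
        return [
            localize(
                f, self.svc_, self.pattern_, refine_cfg,
                stride=self.stride, roi=self.roi,
            )
            for f in frames
        ]

    def score(self, frames, y=None) -> float:
        results = self.predict(frames)
        errs = []
        for res, frame in zip(results, frames):
            errs.append(localization_error_px(res, frame))
        return -float(np.median(errs)) if errs else float("nan")


def localization_error_px(result, frame) -> float:
    """Mean Euclidean pixel error of the two hinges; inf when undetected."""
    if not getattr(result, "detected", False) or frame.truth is None:
        return float("inf")
    truth = sorted(frame.truth, key=lambda p: (p[1], p[0]))
    pred = (result.septal, result.lateral)
    d = [
        float(np.hypot(p[0] - t[0], p[1] - t[1])) for p, t in zip(pred, truth)
    ]
    return float(np.mean(d))


def run_demo(config: RunConfig | None = None, outdir=None) -> ErrorTable:
    """Simulate, train, detect and evaluate on a small phantom set.

    All randomness flows from ``config.seed``; identical configs produce
    byte-identical reports.  Writes report.{json,csv,txt} (and the model)
    into ``outdir`` when given.
    """
    cfg = config or RunConfig()
    phantom = dataclasses.replace(cfg.phantom)
    train_frames = generate_dataset(cfg.n_train, phantom, seed=cfg.seed)
    test_frames = generate_dataset(cfg.n_test, phantom, seed=cfg.seed + 1)
    training = dataclasses.replace(cfg.training, seed=cfg.seed + 2)

    det = HingePointDetector(
        pattern=cfg.pattern, training=training, refine=cfg.refine,
        C=cfg.C, kernel=cfg.kernel, gamma=cfg.gamma, tol=cfg.tol,
        stride=cfg.stride,
    ).fit(train_frames)
    results = det.predict(test_frames)
    table = landmark_errors(results, test_frames)
    table.config = cfg.to_dict()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fmt, name in (("json", "report.json"), ("csv", "report.csv"),
                          ("text", "report.txt")):
            (outdir / name).write_text(summary_report(table, cfg.to_dict(), fmt))
        mio.save_model(det.svc_.model_, outdir / "model.json")
        (outdir / "config.json").write_text(
            json.dumps(cfg.to_dict(), sort_keys=True, indent=1)
        )
    return table
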