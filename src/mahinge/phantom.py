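"""Synthetic four-chamber echo phantom with known hinge-point ground truth.

The phantom is a deliberately simple stand-in for an apical four-chamber
echocardiographic view: four dark chambers separated by a bright vertical
septum and a bright horizontal atrioventricular (annulus) line, with the
annulus line interrupted by a gap that plays the role of the open mitral
valve.  The two wall pixels flanking the gap are recorded as ground-truth
hinge points, so every downstream stage (feature extraction, SVM training,
candidate refinement, evaluation) can be exercised without clinical data.

Speckle is modelled as multiplicative unit-mean Gamma noise, the standard
first-order model for fully developed ultrasound speckle; ``speckle_shape``
is the Gamma shape parameter (larger = cleaner, ``inf`` = noiseless).
Geometry jitter is drawn *before* the speckle field, so two frames built
from the same seed share identical geometry (and truth) even when their
``speckle_shape`` differs — convenient for noise-level sweeps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhantomParams",
    "GrayFrame",
    "generate_frame",
    "generate_dataset",
    "wall_chamber_masks",
]


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the synthetic four-chamber phantom.

    Attributes
    ----------
    height, width : int
        Image size in pixels; at least 64 x 64.
    wall_intensity, chamber_intensity : float
        Mean gray levels (0-255) of myocardial walls and blood pool;
        walls must be brighter than chambers.
    wall_thickness : int
        Thickness in pixels of the septum, the outer walls and the
        annulus line.
    annulus_gap : int
        Width in pixels of the valve opening interrupting the annulus
        line; its two flanking wall pixels are the ground-truth hinge
        points.
    speckle_shape : float
        Shape parameter of the unit-mean multiplicative Gamma speckle;
        relative noise std is ``1/sqrt(speckle_shape)``.  ``np.inf``
        disables noise.
    jitter_px : int
        Half-range (pixels) of the uniform per-frame perturbation of the
        annulus row and of the gap centre column.
    pixel_spacing_mm : float
        Physical pixel size, mm/pixel.
    seed : int
        Fully determines the frame (geometry jitter and speckle).
    """

    height: int = 128
    width: int = 192
    wall_intensity: float = 200.0
    chamber_intensity: float = 30.0
    wall_thickness: int = 5
    annulus_gap: int = 16
    speckle_shape: float = 8.0
    jitter_px: int = 5
    pixel_spacing_mm: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("phantom image must be at least 64x64 pixels")
        if not self.wall_intensity > self.chamber_intensity:
            raise ValueError("wall_intensity must exceed chamber_intensity")
        if not (0 <= self.chamber_intensity and self.wall_intensity <= 255):
            raise ValueError("intensities must lie in [0, 255]")
        if self.wall_thickness < 1 or self.annulus_gap < 2:
            raise ValueError("wall_thickness >= 1 and annulus_gap >= 2 required")
        if not self.speckle_shape > 0:
            raise ValueError("speckle_shape must be positive")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")


@dataclass
class GrayFrame:
    """One 2D grayscale frame with physical spacing and optional truth.

    ``truth`` is a pair of (row, col) hinge coordinates ordered by column
    (smaller column first); coordinates are 0-based image indices.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = 1.0
    truth: tuple[tuple[int, int], tuple[int, int]] | None = None
    frame_id: str = "frame"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValueError("pixel values must lie in [0, 255]")
        if self.truth is not None:
            h, w = self.pixels.shape
            for r, c in self.truth:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError("truth point outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _layout(params: PhantomParams, rng: np.random.Generator):
    """Render the noiseless geometry; returns (clean, wall_mask, truth).

    Jitter is drawn here, before any speckle sampling, so the geometry is a
    function of the seed alone.
    """
    h, w, wt = params.height, params.width, params.wall_thickness
    j = params.jitter_px
    jr = int(rng.integers(-j, j + 1))
    jc = int(rng.integers(-j, j + 1))

    clean = np.full((h, w), params.chamber_intensity, dtype=np.float64)
    wall = np.zeros((h, w), dtype=bool)
    # outer walls
    wall[:wt, :] = wall[-wt:, :] = True
    wall[:, :wt] = wall[:, -wt:] = True
    # septum (vertical, fixed)
    s0 = w // 2 - wt // 2
    wall[:, s0 : s0 + wt] = True
    # annulus line (horizontal, jittered row)
    a0 = h // 2 - wt // 2 + jr
    wall[a0 : a0 + wt, :] = True
    # valve gap in the left half of the annulus line
    gc = (wt + s0) // 2 + jc
    g0 = gc - params.annulus_gap // 2
    g1 = g0 + params.annulus_gap
    wall[a0 : a0 + wt, g0:g1] = False

    clean[wall] = params.wall_intensity
    a_mid = a0 + wt // 2
    truth = ((a_mid, g0 - 1), (a_mid, g1))  # ordered by column
    return clean, wall, truth


def generate_frame(params: PhantomParams) -> GrayFrame:
    """Generate one phantom frame; bit-reproducible from ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    clean, _, truth = _layout(params, rng)
    if np.isfinite(params.speckle_shape):
        k = params.speckle_shape
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=clean.shape)
        pixels = np.clip(clean * speckle, 0.0, 255.0)
    else:
        pixels = clean
    return GrayFrame(
        pixels=pixels,
        pixel_spacing_mm=params.pixel_spacing_mm,
        truth=truth,
        frame_id=f"phantom_s{params.seed}",
    )


def wall_chamber_masks(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (wall, chamber) masks of the geometry encoded by ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    _, wall, _ = _layout(params, rng)
    return wall, ~wall


def generate_dataset(
    n_frames: int, params: PhantomParams, seed: int
) -> list[GrayFrame]:
    """Generate ``n_frames`` phantoms with independently jittered geometry.

    Per-frame seeds are spawned from ``seed`` via ``numpy.random.SeedSequence``,
    so the dataset is reproducible and frames are statistically independent.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    params.validate()
    children = np.random.SeedSequence(seed).spawn(n_frames)
    frames = []
    for i, child in enumerate(children):
        fseed = int(child.generate_state(1)[0] % (2**31))
        frame = generate_frame(dataclasses.replace(params, seed=fseed))
        frame.frame_id = f"frame_{i:04d}"
        frames.append(frame)
    return frames
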