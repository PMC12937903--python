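"""Segment-colored attractor images (chaotic-dynamics maps) and augmentation.

A cardiac cycle's delay embedding is projected onto its first two
coordinates (x_i, x_{i+tau}) and drawn as a connected polyline on a
white canvas, each line segment colored by the cardiac-cycle segment of
its starting sample.  Rasterization uses Bresenham lines on a numpy
buffer so identical inputs produce bit-identical pixels.

Four augmentation families (rotation +-10 deg, translation +-5%,
Gaussian pixel noise, contrast-brightness) expand a rendered dataset by
exactly one output per family per source image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import line as _bresenham_line
from skimage.transform import rotate as _sk_rotate

from .phase_space import EmbeddedTrajectory
from .preprocess import SEGMENTS, CardiacCycle

__all__ = [
    "DEFAULT_PALETTE",
    "BACKGROUND",
    "AUGMENT_FAMILIES",
    "MCDMImage",
    "render_mcdm",
    "augment_image",
    "augment_dataset",
    "save_png",
    "load_png",
    "write_manifest",
    "read_manifest",
]

#: Segment -> RGB color.  One entry per canonical cardiac segment:
#: red pre-P, green P, blue post-P(-to-pre-QRS), black QRS, pink ST,
#: yellow T, cyan post-T.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "pre-P": (255, 0, 0),
    "P": (0, 200, 0),
    "post-P": (0, 0, 255),
    "QRS": (0, 0, 0),
    "ST": (255, 105, 180),
    "T": (255, 215, 0),
    "post-T": (0, 255, 255),
}

BACKGROUND: tuple[int, int, int] = (255, 255, 255)

AUGMENT_FAMILIES: tuple[str, ...] = ("rotate", "translate", "noise", "contrast")


@dataclass(frozen=True)
class MCDMImage:
    """Rasterized segment-colored attractor projection.

    ``pixels`` is an H x W x 3 uint8 buffer; ``provenance`` records the
    source subject, cycle index, class label and the transform applied
    (``{"family": "none"}`` for originals).
    """

    pixels: np.ndarray
    palette: Mapping[str, tuple[int, int, int]]
    subject_id: str = ""
    cycle_index: int = 0
    class_label: str | None = None
    transform: Mapping[str, object] = field(default_factory=lambda: {"family": "none"})

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.dtype != np.uint8:
            raise ValueError("pixels must be an H x W x 3 uint8 array")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "transform", dict(self.transform))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def render_mcdm(
    traj: EmbeddedTrajectory,
    cycle: CardiacCycle,
    image_size: tuple[int, int] = (256, 256),
    palette: Mapping[str, tuple[int, int, int]] | None = None,
    class_label: str | None = None,
) -> MCDMImage:
    """Render the 2-D projection (x_i, x_{i+tau}) of a cycle's embedding.

    The polyline is drawn on a white background with each line segment
    colored by the segment label of its starting sample.  Axis limits
    are the data range expanded by a 5% margin with a single scale for
    both axes; rasterization is deterministic.
    """
    palette = dict(palette or DEFAULT_PALETTE)
    missing = set(SEGMENTS) - set(palette)
    if missing:
        raise ValueError(f"palette missing segment colors: {sorted(missing)}")
    h, w = image_size
    if h < 64 or w < 64:
        raise ValueError("image_size must be at least 64 x 64")
    if traj.m < 2:
        raise ValueError("trajectory must have at least two embedding coordinates")
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least two points")
    if traj.source_length != len(cycle):
        raise ValueError(
            f"trajectory derives from {traj.source_length} samples but cycle "
            f"has {len(cycle)}"
        )

    x = traj.points[:, 0]
    y = traj.points[:, 1]
    span = max(x.max() - x.min(), y.max() - y.min()) * 1.05
    if span == 0:
        span = 1.0
    cx, cy = (x.max() + x.min()) / 2.0, (y.max() + y.min()) / 2.0
    cols = np.clip(np.round((x - (cx - span / 2)) / span * (w - 1)), 0, w - 1).astype(int)
    rows = np.clip((h - 1) - np.round((y - (cy - span / 2)) / span * (h - 1)), 0, h - 1).astype(int)

    canvas = np.full((h, w, 3), BACKGROUND, dtype=np.uint8)
    labels = cycle.segment_labels
    for i in range(len(traj) - 1):
        rr, cc = _bresenham_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        canvas[rr, cc] = palette[str(labels[i])]
    return MCDMImage(
        pixels=canvas,
        palette=palette,
        subject_id=cycle.subject_id,
        cycle_index=cycle.cycle_index,
        class_label=class_label,
        transform={"family": "none"},
    )


def _clip_u8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def augment_image(
    image: MCDMImage,
    family: str,
    seed: int = 0,
    *,
    angle: float | None = None,
    shift: tuple[float, float] | None = None,
    gain: float | None = None,
    offset: float | None = None,
) -> MCDMImage:
    """Apply one augmentation family with randomized parameters.

    rotate: angle ~ U(-10, +10) degrees about the image center;
    translate: shifts ~ U(+-5% of H and W); noise: additive Gaussian
    with SD = 2% of the intensity range, clipped to 0-255; contrast:
    gain ~ U(0.8, 1.2) and offset ~ U(-25, +25) levels, clipped.  The
    keyword overrides pin individual parameters (useful for identity
    checks).  Output dimensions are unchanged and the transform is
    recorded in the provenance.
    """
    rng = np.random.default_rng(seed)
    pixels = image.pixels
    h, w = image.shape
    if family == "rotate":
        if angle is None:
            angle = float(rng.uniform(-10.0, 10.0))
        if angle == 0.0:
            out = pixels.copy()
        else:
            rotated = _sk_rotate(pixels.astype(float), angle, resize=False,
                                 order=1, mode="constant", cval=255.0,
                                 preserve_range=True)
            out = _clip_u8(rotated)
        params: dict[str, object] = {"family": "rotate", "angle_deg": angle}
    elif family == "translate":
        if shift is None:
            shift = (float(rng.uniform(-0.05, 0.05) * h),
                     float(rng.uniform(-0.05, 0.05) * w))
        if shift == (0.0, 0.0):
            out = pixels.copy()
        else:
            shifted = ndimage.shift(pixels.astype(float), (shift[0], shift[1], 0.0),
                                    order=1, mode="constant", cval=255.0)
            out = _clip_u8(shifted)
        params = {"family": "translate", "shift_px": tuple(shift)}
    elif family == "noise":
        sd = 0.02 * 255.0
        out = _clip_u8(pixels.astype(float) + rng.normal(0.0, sd, pixels.shape))
        params = {"family": "noise", "sd": sd}
    elif family == "contrast":
        if gain is None:
            gain = float(rng.uniform(0.8, 1.2))
        if offset is None:
            offset = float(rng.uniform(-25.0, 25.0))
        out = _clip_u8(gain * pixels.astype(float) + offset)
        params = {"family": "contrast", "gain": gain, "offset": offset}
    else:
        raise ValueError(f"unknown augmentation family {family!r}")
    return MCDMImage(
        pixels=out,
        palette=image.palette,
        subject_id=image.subject_id,
        cycle_index=image.cycle_index,
        class_label=image.class_label,
        transform=params,
    )


def augment_dataset(
    images: Sequence[MCDMImage],
    expansion_factor: int = 4,
    seed: int = 0,
    families: Sequence[str] = AUGMENT_FAMILIES,
) -> list[MCDMImage]:
    """Balanced expansion: one output per transform family per source image.

    Originals are not duplicated into the output, so the result has
    exactly ``len(images) * expansion_factor`` elements with class
    balance preserved.  Per-image, per-family seeds derive
    deterministically from the master seed.
    """
    if not images:
        raise ValueError("empty input list")
    if expansion_factor != len(families):
        raise ValueError(
            f"expansion_factor={expansion_factor} must equal the number of "
            f"transform families ({len(families)})"
        )
    out: list[MCDMImage] = []
    for i, image in enumerate(images):
        for f, family in enumerate(families):
            child_seed = int(np.random.SeedSequence([int(seed), i, f]).generate_state(1)[0])
            out.append(augment_image(image, family, seed=child_seed))
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_png(image: MCDMImage, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")
    return path


def load_png(path: str | Path, **provenance) -> MCDMImage:
    pixels = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
    return MCDMImage(pixels=pixels, palette=DEFAULT_PALETTE, **provenance)


def write_manifest(records: Iterable[Mapping[str, object]], path: str | Path) -> Path:
    """Write a dataset manifest as JSON lines (one record per image)."""
    path = Path(path)
    with open(path, "w") as fh:
        for record in records:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
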