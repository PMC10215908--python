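"""Ground-truthed synthetic scenes: bright shapes of known physical area on a
darker wall, rendered at a given camera distance.

The render transform is deliberately simple. A scale factor converts
millimetres on the wall plane to pixels:

* ``pinhole_inverse_square``: scale = focal_constant / distance_cm, so the
  pixel count of a shape falls off as 1/distance^2 (the physically standard
  behaviour, and what measured calibration tables show);
* ``paper_linear``: pixel count proportional to area / distance, i.e.
  scale = sqrt(focal_constant / distance_cm).

``focal_constant`` is an arbitrary render scale (pixels per mm at 1 cm for
the pinhole model), not a physical focal length.

Shapes are axis-aligned and must not overlap, so ground-truth areas add. The
rasterization rule is pixel-center-inside. The truth mask is the exact
rasterized footprint before any degradation; noise touches only the image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import SceneError
from .image_ops import BinaryMask

__all__ = [
    "Shape",
    "SceneSpec",
    "RenderedScene",
    "rectangle",
    "disk",
    "mm_to_px_scale",
    "project_pixels",
    "render",
    "degrade",
    "load_scene_spec",
    "save_scene_spec",
]

SCALE_MODELS = ("pinhole_inverse_square", "paper_linear")


@dataclass(frozen=True)
class Shape:
    """An axis-aligned bright region on the wall plane.

    Positions are the shape centre in mm, relative to the optical axis
    (x to the right, y downward). ``color`` is the rendered RGB value.
    """

    kind: str                      # "rectangle" | "disk"
    x_mm: float = 0.0
    y_mm: float = 0.0
    width_mm: float | None = None   # rectangle
    height_mm: float | None = None  # rectangle
    radius_mm: float | None = None  # disk
    color: tuple[int, int, int] = (230, 40, 40)

    def __post_init__(self):
        if self.kind == "rectangle":
            if not (self.width_mm and self.height_mm and self.width_mm > 0 and self.height_mm > 0):
                raise ValueError("rectangle needs positive width_mm and height_mm")
        elif self.kind == "disk":
            if not (self.radius_mm and self.radius_mm > 0):
                raise ValueError("disk needs a positive radius_mm")
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")

    @property
    def area_mm2(self) -> float:
        if self.kind == "rectangle":
            return self.width_mm * self.height_mm
        return math.pi * self.radius_mm ** 2


def rectangle(width_mm: float, height_mm: float, x_mm: float = 0.0, y_mm: float = 0.0,
              color: tuple[int, int, int] = (230, 40, 40)) -> Shape:
    return Shape(kind="rectangle", width_mm=width_mm, height_mm=height_mm,
                 x_mm=x_mm, y_mm=y_mm, color=color)


def disk(radius_mm: float, x_mm: float = 0.0, y_mm: float = 0.0,
         color: tuple[int, int, int] = (230, 40, 40)) -> Shape:
    return Shape(kind="disk", radius_mm=radius_mm, x_mm=x_mm, y_mm=y_mm, color=color)


@dataclass(frozen=True)
class SceneSpec:
    """Declarative scene: physical shapes + camera distance + degradations."""

    shapes: tuple[Shape, ...]
    distance_cm: float
    scale_model: str = "pinhole_inverse_square"
    focal_constant: float = 100.0
    width_px: int = 256
    height_px: int = 256
    wall_color: tuple[int, int, int] = (96, 96, 96)
    cast: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gradient_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        if self.scale_model not in SCALE_MODELS:
            raise ValueError(
                f"unknown scale_model {self.scale_model!r}; expected one of {SCALE_MODELS}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")


@dataclass(frozen=True)
class RenderedScene:
    image: np.ndarray        # (H, W, 3) uint8
    truth_mask: BinaryMask   # exact rasterized footprint, pre-noise
    truth_area: float        # mm^2, sum of shape areas
    truth_pixels: int        # white count of truth_mask


def mm_to_px_scale(distance_cm: float, focal_constant: float, scale_model: str) -> float:
    """Linear scale in pixels per mm on the wall plane at the given distance."""
    if distance_cm <= 0 or focal_constant <= 0:
        raise ValueError("distance and focal_constant must be positive")
    if scale_model == "pinhole_inverse_square":
        return focal_constant / distance_cm
    if scale_model == "paper_linear":
        return math.sqrt(focal_constant / distance_cm)
    raise ValueError(f"unknown scale_model {scale_model!r}; expected one of {SCALE_MODELS}")


def project_pixels(area_mm2: float, distance_cm: float, focal_constant: float,
                   scale_model: str) -> float:
    """Expected pixel count of a region of the given physical area."""
    if area_mm2 < 0:
        raise ValueError("area must be non-negative")
    s = mm_to_px_scale(distance_cm, focal_constant, scale_model)
    return area_mm2 * s * s


def _pixel_centers_mm(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    s = mm_to_px_scale(spec.distance_cm, spec.focal_constant, spec.scale_model)
    xs = (np.arange(spec.width_px) - (spec.width_px - 1) / 2.0) / s
    ys = (np.arange(spec.height_px) - (spec.height_px - 1) / 2.0) / s
    return np.meshgrid(xs, ys)


def _shape_mask(shape: Shape, xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    if shape.kind == "rectangle":
        return ((np.abs(xg - shape.x_mm) <= shape.width_mm / 2.0)
                & (np.abs(yg - shape.y_mm) <= shape.height_mm / 2.0))
    return (xg - shape.x_mm) ** 2 + (yg - shape.y_mm) ** 2 <= shape.radius_mm ** 2


def _shape_extent_mm(shape: Shape) -> tuple[float, float, float, float]:
    if shape.kind == "rectangle":
        hw, hh = shape.width_mm / 2.0, shape.height_mm / 2.0
    else:
        hw = hh = shape.radius_mm
    return (shape.x_mm - hw, shape.x_mm + hw, shape.y_mm - hh, shape.y_mm + hh)


def render(spec: SceneSpec) -> RenderedScene:
    """Rasterize a scene; deterministic for a fixed spec (seed drives noise only)."""
    xg, yg = _pixel_centers_mm(spec)
    half_w = abs(xg[0, 0])
    half_h = abs(yg[0, 0])

    image = np.empty((spec.height_px, spec.width_px, 3), dtype=np.uint8)
    image[:] = np.asarray(spec.wall_color, dtype=np.uint8)
    truth = np.zeros((spec.height_px, spec.width_px), dtype=bool)

    for i, shape in enumerate(spec.shapes):
        x0, x1, y0, y1 = _shape_extent_mm(shape)
        if x0 < -half_w or x1 > half_w or y0 < -half_h or y1 > half_h:
            raise SceneError(
                f"shape {i} ({shape.kind}) projects outside the frame at "
                f"{spec.distance_cm} cm")
        m = _shape_mask(shape, xg, yg)
        if (truth & m).any():
            raise SceneError(f"shape {i} ({shape.kind}) overlaps an earlier shape")
        truth |= m
        image[m] = np.asarray(shape.color, dtype=np.uint8)

    image = degrade(image, cast=spec.cast, gradient_amplitude=spec.gradient_amplitude,
                    noise_sigma=spec.noise_sigma, seed=spec.seed)

    mask = BinaryMask(pixels=np.where(truth, 255, 0).astype(np.uint8), threshold_used=0)
    return RenderedScene(
        image=image,
        truth_mask=mask,
        truth_area=float(sum(s.area_mm2 for s in spec.shapes)),
        truth_pixels=int(truth.sum()),
    )


def degrade(img: np.ndarray, cast: tuple[float, float, float] = (1.0, 1.0, 1.0),
            gradient_amplitude: float = 0.0, noise_sigma: float = 0.0,
            seed: int = 0) -> np.ndarray:
    """Apply, in order: per-channel multiplicative cast, a zero-mean horizontal
    illumination ramp, and additive Gaussian noise; clamp to [0, 255].

    All-default arguments return the input unchanged (bit-for-bit).
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    if any(c <= 0 for c in cast):
        raise ValueError(f"cast multipliers must be positive, got {cast}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")

    if cast == (1.0, 1.0, 1.0) and gradient_amplitude == 0.0 and noise_sigma == 0.0:
        return img.copy()

    out = img.astype(np.float64)
    out *= np.asarray(cast, dtype=np.float64)

    if gradient_amplitude != 0.0:
        w = img.shape[1]
        ramp = np.zeros(w) if w == 1 else gradient_amplitude * (2.0 * np.arange(w) / (w - 1) - 1.0)
        out += ramp[np.newaxis, :, np.newaxis]

    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        out += rng.normal(0.0, noise_sigma, size=out.shape)

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# --- JSON (de)serialization of scene specs ---------------------------------

def save_scene_spec(spec: SceneSpec, path: str | Path) -> None:
    payload = {
        "distance_cm": spec.distance_cm,
        "scale_model": spec.scale_model,
        "focal_constant": spec.focal_constant,
        "width_px": spec.width_px,
        "height_px": spec.height_px,
        "wall_color": list(spec.wall_color),
        "cast": list(spec.cast),
        "gradient_amplitude": spec.gradient_amplitude,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "shapes": [
            {k: v for k, v in {
                "kind": s.kind, "x_mm": s.x_mm, "y_mm": s.y_mm,
                "width_mm": s.width_mm, "height_mm": s.height_mm,
                "radius_mm": s.radius_mm, "color": list(s.color),
            }.items() if v is not None}
            for s in spec.shapes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_scene_spec(path: str | Path, **overrides) -> SceneSpec:
    """Load a SceneSpec from JSON; keyword overrides replace stored fields."""
    payload = json.loads(Path(path).read_text())
    shapes = tuple(
        Shape(kind=s["kind"], x_mm=s.get("x_mm", 0.0), y_mm=s.get("y_mm", 0.0),
              width_mm=s.get("width_mm"), height_mm=s.get("height_mm"),
              radius_mm=s.get("radius_mm"), color=tuple(s.get("color", (230, 40, 40))))
        for s in payload["shapes"]
    )
    spec = SceneSpec(
        shapes=shapes,
        distance_cm=payload["distance_cm"],
        scale_model=payload.get("scale_model", "pinhole_inverse_square"),
        focal_constant=payload.get("focal_constant", 100.0),
        width_px=payload.get("width_px", 256),
        height_px=payload.get("height_px", 256),
        wall_color=tuple(payload.get("wall_color", (96, 96, 96))),
        cast=tuple(payload.get("cast", (1.0, 1.0, 1.0))),
        gradient_amplitude=payload.get("gradient_amplitude", 0.0),
        noise_sigma=payload.get("noise_sigma", 0.0),
        seed=payload.get("seed", 0),
    )
    return replace(spec, **overrides) if overrides else spec
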