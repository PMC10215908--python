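"""Convert white-pixel fractions plus a photography distance into mm^2.

Two calibration routes are provided and must be selected explicitly:

* single-reference ``lambda``: one photograph of an object of known area at a
  known distance fixes a constant ``lam = ref_area / (d * ref_ratio)``; any
  later measurement is ``lam * d * ratio``;
* distance-indexed ``curves``: per-distance ordinary least squares of area
  (mm^2, response) on white-pixel count (predictor), with linear blending of
  the two bracketing curves for distances in between.

Distances are centimetres, areas square millimetres throughout; no unit
inference is attempted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CalibrationRangeError, FitError, TableParseError

__all__ = [
    "LambdaCalibration",
    "CalibrationPoint",
    "DistanceCurve",
    "CalibrationSet",
    "Measurement",
    "fit_lambda",
    "area_from_lambda",
    "fit_distance_curve",
    "predict_area",
    "interpolate_area",
    "load_calibration_table",
    "fit_calibration_set",
]


@dataclass(frozen=True)
class LambdaCalibration:
    """Single-reference calibration constant with its provenance."""

    lam: float            # mm^2 per (cm * ratio)
    ref_area: float       # mm^2
    ref_distance: float   # cm
    ref_ratio: float      # dimensionless white/total


@dataclass(frozen=True)
class CalibrationPoint:
    """One (physical area, white-pixel count) pair at a fixed distance."""

    area: float    # mm^2
    pixels: float  # white-pixel count


@dataclass(frozen=True)
class DistanceCurve:
    """Per-distance linear map pixels -> mm^2: area = a0 + a1 * pixels."""

    distance: float  # cm
    a0: float        # intercept, mm^2
    a1: float        # slope, mm^2 per pixel
    r2: float
    n: int


@dataclass(frozen=True)
class CalibrationSet:
    """Distance curves sorted by strictly increasing distance."""

    curves: tuple[DistanceCurve, ...]
    total_pixels: int | None = None  # image pixel count the curves were built against

    def __post_init__(self):
        if not self.curves:
            raise ValueError("calibration set needs at least one curve")
        ds = [c.distance for c in self.curves]
        if any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError("curve distances must be strictly increasing")

    @property
    def distances(self) -> tuple[float, ...]:
        return tuple(c.distance for c in self.curves)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total_pixels": self.total_pixels,
            "curves": [
                {"distance_cm": c.distance, "a0": c.a0, "a1": c.a1, "r2": c.r2, "n": c.n}
                for c in self.curves
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationSet":
        payload = json.loads(Path(path).read_text())
        curves = tuple(
            DistanceCurve(distance=c["distance_cm"], a0=c["a0"], a1=c["a1"],
                          r2=c["r2"], n=c["n"])
            for c in payload["curves"]
        )
        return cls(curves=curves, total_pixels=payload.get("total_pixels"))


@dataclass(frozen=True)
class Measurement:
    """An area estimate together with how it was obtained."""

    distance: float            # cm
    estimated_area: float      # mm^2
    method: str                # one of {"lambda", "curve", "interpolated"}
    ratio: float | None = None
    pixels: float | None = None
    warnings: tuple[str, ...] = field(default=())


def fit_lambda(ref_area: float, d: float, ref_ratio: float) -> LambdaCalibration:
    """Calibrate lam = ref_area / (d * ref_ratio) from one reference photo."""
    for name, v in (("ref_area", ref_area), ("d", d), ("ref_ratio", ref_ratio)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return LambdaCalibration(lam=ref_area / (d * ref_ratio),
                             ref_area=ref_area, ref_distance=d, ref_ratio=ref_ratio)


def area_from_lambda(cal: LambdaCalibration, d: float, ratio: float) -> Measurement:
    """Estimated area = lam * d * ratio (mm^2)."""
    if not d > 0:
        raise ValueError(f"distance must be positive, got {d}")
    if not 0 <= ratio <= 1:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    return Measurement(distance=d, estimated_area=cal.lam * d * ratio,
                       method="lambda", ratio=ratio)


def fit_distance_curve(points: list[CalibrationPoint], distance: float) -> DistanceCurve:
    """Ordinary least squares of area (response) on pixel count (predictor).

    Uses the closed-form centered normal equations; r^2 = 1 - SSresid/SStot.
    Requires >= 2 points with non-identical pixel counts.
    """
    if len(points) < 2:
        raise FitError(f"distance {distance}: need >= 2 points, got {len(points)}")
    x = np.array([p.pixels for p in points], dtype=np.float64)
    y = np.array([p.area for p in points], dtype=np.float64)
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise FitError(f"distance {distance}: zero variance in pixel counts")
    a1 = float(((x - x.mean()) * (y - y.mean())).sum()) / sxx
    a0 = float(y.mean() - a1 * x.mean())
    resid = y - (a0 + a1 * x)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sstot == 0.0 else 1.0 - float((resid ** 2).sum()) / sstot
    return DistanceCurve(distance=float(distance), a0=a0, a1=a1, r2=r2, n=len(points))


def predict_area(curve: DistanceCurve, pixels: float) -> float:
    """Evaluate area = a0 + a1 * pixels; negatives are returned as-is."""
    if pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return curve.a0 + curve.a1 * pixels


def interpolate_area(cal: CalibrationSet, d: float, pixels: float,
                     allow_extrapolation: bool = False) -> Measurement:
    """Predict area at distance d by blending the two bracketing curves.

    With curves at d_lo <= d <= d_hi:

        area = f_lo(pixels) + (d - d_lo)/(d_hi - d_lo) * (f_hi(pixels) - f_lo(pixels))

    At a calibrated distance this reduces to that curve's own prediction
    (``method == "curve"``). Distances outside the calibrated range raise
    unless ``allow_extrapolation``, in which case the nearest curve pair (or
    the single curve) extends the blend linearly.
    """
    if not d > 0:
        raise ValueError(f"distance must be positive, got {d}")
    ds = cal.distances
    warnings: list[str] = []

    for c in cal.curves:
        if c.distance == d:
            area = predict_area(c, pixels)
            if area < 0:
                warnings.append("predicted area is negative (pixel count below intercept)")
            return Measurement(distance=d, estimated_area=area, method="curve",
                               pixels=pixels, warnings=tuple(warnings))

    if d < ds[0] or d > ds[-1]:
        if not allow_extrapolation:
            raise CalibrationRangeError(
                f"distance {d} cm outside calibrated range [{ds[0]}, {ds[-1]}] cm")
        warnings.append(f"extrapolating outside calibrated range [{ds[0]}, {ds[-1]}] cm")
        if len(cal.curves) == 1:
            area = predict_area(cal.curves[0], pixels)
            if area < 0:
                warnings.append("predicted area is negative (pixel count below intercept)")
            return Measurement(distance=d, estimated_area=area, method="interpolated",
                               pixels=pixels, warnings=tuple(warnings))
        lo, hi = (cal.curves[0], cal.curves[1]) if d < ds[0] else (cal.curves[-2], cal.curves[-1])
    else:
        idx = int(np.searchsorted(np.asarray(ds), d)) - 1
        lo, hi = cal.curves[idx], cal.curves[idx + 1]

    t = (d - lo.distance) / (hi.distance - lo.distance)
    f_lo = predict_area(lo, pixels)
    f_hi = predict_area(hi, pixels)
    area = f_lo + t * (f_hi - f_lo)
    if area < 0:
        warnings.append("predicted area is negative (pixel count below intercept)")
    return Measurement(distance=d, estimated_area=area, method="interpolated",
                       pixels=pixels, warnings=tuple(warnings))


def _parse_number(text: str, what: str, row: int) -> float:
    # tolerate thousands separators as printed in calibration tables ("10,547")
    cleaned = text.strip().replace(",", "")
    if not cleaned:
        raise TableParseError(f"empty {what} field", row=row)
    try:
        return float(cleaned)
    except ValueError:
        raise TableParseError(f"cannot parse {what} value {text!r}", row=row) from None


def load_calibration_table(path: str | Path) -> list[tuple[float, list[CalibrationPoint]]]:
    """Read a CSV with header ``distance_cm,area_mm2,pixels``.

    Returns [(distance, [CalibrationPoint, ...]), ...] grouped by distance in
    ascending order; duplicated distance blocks are merged. Thousands
    separators inside quoted fields are tolerated.
    """
    path = Path(path)
    groups: dict[float, list[CalibrationPoint]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableParseError(f"{path}: empty file")
        required = {"distance_cm", "area_mm2", "pixels"}
        have = {name.strip() for name in reader.fieldnames}
        if not required <= have:
            raise TableParseError(
                f"{path}: header must contain {sorted(required)}, got {reader.fieldnames}")
        n_rows = 0
        for i, rec in enumerate(reader, start=2):  # data starts on file line 2
            d = _parse_number(rec["distance_cm"], "distance_cm", i)
            area = _parse_number(rec["area_mm2"], "area_mm2", i)
            pixels = _parse_number(rec["pixels"], "pixels", i)
            if d <= 0 or area <= 0 or pixels <= 0:
                raise TableParseError("all values must be positive", row=i)
            groups.setdefault(d, []).append(CalibrationPoint(area=area, pixels=pixels))
            n_rows += 1
    if n_rows == 0:
        raise TableParseError(f"{path}: no data rows")
    return [(d, groups[d]) for d in sorted(groups)]


def fit_calibration_set(table: list[tuple[float, list[CalibrationPoint]]],
                        total_pixels: int | None = None) -> CalibrationSet:
    """Fit one DistanceCurve per distance group of a loaded table."""
    curves = tuple(fit_distance_curve(points, distance=d) for d, points in table)
    return CalibrationSet(curves=curves, total_pixels=total_pixels)
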