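"""Propagation of distance mis-measurement into area error.

Two sweep backends:

* :func:`distance_sweep` pushes a fixed white-pixel count through a
  :class:`~fluoarea.calibration.CalibrationSet` at a range of assumed
  distances;
* :func:`area_table_sweep` reads measured (distance, area) pairs directly
  from a table, linearly interpolating between listed distances.

Relative error is one-sided: ``100 * |estimated - true| / true``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import CalibrationSet, interpolate_area
from .errors import CalibrationRangeError, TableParseError

__all__ = [
    "SensitivityRow",
    "relative_error",
    "distance_sweep",
    "area_table_sweep",
    "load_area_by_distance",
    "step_change_pct",
]


@dataclass(frozen=True)
class SensitivityRow:
    assumed_distance: float        # cm
    estimated_area: float          # mm^2
    relative_error_pct: float | None  # None when no true area was supplied


def relative_error(estimated: float, true: float) -> float:
    """One-sided relative error in percent: 100 * |estimated - true| / true."""
    if not true > 0:
        raise ValueError(f"true area must be positive, got {true}")
    return 100.0 * abs(estimated - true) / true


def distance_sweep(cal: CalibrationSet, pixels: float, center_d: float,
                   offsets: list[float], true_area: float | None = None,
                   allow_extrapolation: bool = False) -> list[SensitivityRow]:
    """Estimate area at ``center_d + offset`` for each offset, fixed pixel count."""
    rows = []
    for off in offsets:
        d = center_d + off
        try:
            m = interpolate_area(cal, d, pixels, allow_extrapolation=allow_extrapolation)
        except CalibrationRangeError as exc:
            raise CalibrationRangeError(
                f"offset {off:+g} cm puts distance at {d} cm: {exc}") from None
        err = relative_error(m.estimated_area, true_area) if true_area is not None else None
        rows.append(SensitivityRow(assumed_distance=d, estimated_area=m.estimated_area,
                                   relative_error_pct=err))
    return rows


def load_area_by_distance(path: str | Path) -> list[tuple[float, float]]:
    """Read a CSV with header ``distance_cm,area_mm2`` into sorted pairs."""
    path = Path(path)
    pairs: list[tuple[float, float]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableParseError(f"{path}: empty file")
        have = {name.strip() for name in reader.fieldnames}
        if not {"distance_cm", "area_mm2"} <= have:
            raise TableParseError(
                f"{path}: header must contain ['area_mm2', 'distance_cm'], got {reader.fieldnames}")
        for i, rec in enumerate(reader, start=2):
            try:
                d = float(rec["distance_cm"].strip().replace(",", ""))
                a = float(rec["area_mm2"].strip().replace(",", ""))
            except (ValueError, AttributeError):
                raise TableParseError(f"cannot parse row {rec!r}", row=i) from None
            if d <= 0 or a <= 0:
                raise TableParseError("values must be positive", row=i)
            pairs.append((d, a))
    if not pairs:
        raise TableParseError(f"{path}: no data rows")
    pairs.sort()
    ds = [d for d, _ in pairs]
    if len(set(ds)) != len(ds):
        raise TableParseError(f"{path}: duplicate distances")
    return pairs


def _table_area(pairs: list[tuple[float, float]], d: float) -> float:
    ds = np.array([p[0] for p in pairs])
    areas = np.array([p[1] for p in pairs])
    if d < ds[0] or d > ds[-1]:
        raise CalibrationRangeError(
            f"distance {d} cm outside table range [{ds[0]}, {ds[-1]}] cm")
    return float(np.interp(d, ds, areas))


def area_table_sweep(pairs: list[tuple[float, float]], center_d: float,
                     offsets: list[float],
                     true_area: float | None = None) -> list[SensitivityRow]:
    """Sweep over a measured (distance, area) table instead of a calibration."""
    rows = []
    for off in offsets:
        d = center_d + off
        try:
            area = _table_area(pairs, d)
        except CalibrationRangeError as exc:
            raise CalibrationRangeError(
                f"offset {off:+g} cm puts distance at {d} cm: {exc}") from None
        err = relative_error(area, true_area) if true_area is not None else None
        rows.append(SensitivityRow(assumed_distance=d, estimated_area=area,
                                   relative_error_pct=err))
    return rows


def step_change_pct(pairs: list[tuple[float, float]], d_from: float, d_to: float) -> float:
    """Percent change of tabulated area between two distances, relative to d_from."""
    a_from = _table_area(pairs, d_from)
    a_to = _table_area(pairs, d_to)
    return 100.0 * (a_to - a_from) / a_from
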