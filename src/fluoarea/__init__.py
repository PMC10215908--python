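"""fluoarea: physical-area quantification of bright (fluorescent-dye) regions
from orthogonal photographs, via Otsu binarization and distance calibration.
"""

from importlib import resources as _resources
from pathlib import Path

from .calibration import (
    CalibrationPoint,
    CalibrationSet,
    DistanceCurve,
    LambdaCalibration,
    Measurement,
    area_from_lambda,
    fit_calibration_set,
    fit_distance_curve,
    fit_lambda,
    interpolate_area,
    load_calibration_table,
    predict_area,
)
from .image_ops import (
    BT601_WEIGHTS,
    AreaRatio,
    BinaryMask,
    OtsuResult,
    binarize,
    gray_histogram,
    load_image,
    otsu_threshold,
    rgb_to_gray,
    save_mask,
    white_ratio,
)
from .sensitivity import (
    SensitivityRow,
    area_table_sweep,
    distance_sweep,
    load_area_by_distance,
    relative_error,
    step_change_pct,
)
from .synthetic import (
    RenderedScene,
    SceneSpec,
    Shape,
    degrade,
    disk,
    load_scene_spec,
    mm_to_px_scale,
    project_pixels,
    rectangle,
    render,
    save_scene_spec,
)

__version__ = "0.1.0"


def fixture_path(name: str) -> Path:
    """Absolute path of a shipped data fixture (e.g. ``table1.csv``)."""
    path = _resources.files("fluoarea").joinpath("data", name)
    return Path(str(path))
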