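"""Reading, writing and frame conversion for respiratory tracking-log bundles.

A treatment fraction of a robotic radiosurgery tracking system produces five
plain-text log streams:

* ``Markers.log``      — raw chest-LED surrogate positions (camera stream)
* ``ModelPoints.log``  — sparse radiographic fiducial-centroid localizations,
  the concurrent LED positions and the correlation-model residual at each
  localization; the data from which the internal/external correlation model
  is built
* ``Modeler.log``      — the correlation model's continuous target estimate
* ``Predictor.log``    — the latency-compensation predictor output (~200 ms
  lookahead) and its residual
* ``ERsiData.log``     — robot position / commanded offset in the robot world
  frame plus the per-record robotic (targeting) residual

Vendor logs are proprietary; this module defines an open, diffable dialect:
``# key=value`` header lines followed by comma-separated numeric rows, all
positions in mm.  Two concentric coordinate frames exist — the patient frame
(axes superior–inferior, left–right, anterior–posterior at the imaging
isocenter) and the robot world frame.  Files may be written in either frame
(``frame=`` header); parsing normalizes every patient-frame quantity via the
fixed linear transform in :func:`robot_to_patient`.  The robot position and
commanded offset of ``ERsiData.log`` stay in the robot frame by definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AXES",
    "TUMOR_SITES",
    "Vector3",
    "RobotVector3",
    "ModelPointRecord",
    "PredictorRecord",
    "ERsiRecord",
    "MarkerStream",
    "ModelPointStream",
    "ModelerStream",
    "PredictorStream",
    "ERsiStream",
    "FractionLogBundle",
    "LogIOError",
    "LogParseError",
    "MissingStreamError",
    "LogValidationError",
    "robot_to_patient",
    "patient_to_robot",
    "parse_bundle",
    "write_bundle",
    "bundles_allclose",
]

#: Fixed axis order used everywhere: superior–inferior, left–right,
#: anterior–posterior.
AXES = ("SI", "LR", "AP")

#: Controlled tumor-site vocabulary of the cohort.
TUMOR_SITES = (
    "Lung apex left",
    "Lung hilum",
    "Lung hilum left",
    "Lung hilum right",
    "Lung LLL",
    "Lung LUL",
    "Lung RLL",
    "Lung RML",
    "Lung RUL",
    "Liver",
    "Pancreas",
    "Retroperitoneum",
    "Chest wall",
    "Internal mammary nodes",
)

# Printed transform coefficients between the robot world frame and the
# patient frame.  The matrix is only approximately a 45-degree rotation
# (0.7081 vs 0.7061); the printed coefficients are used verbatim.
_A = 0.7081
_B = 0.7061
_ROB_TO_PAT = np.array([[_A, _B, 0.0], [-_A, _B, 0.0], [0.0, 0.0, 1.0]])
_PAT_TO_ROB = np.linalg.inv(_ROB_TO_PAT)


class LogIOError(Exception):
    """Base class for log-bundle I/O failures."""


class LogParseError(LogIOError):
    """A malformed row or header; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


class MissingStreamError(LogIOError):
    """One of the five required log files is absent."""


class LogValidationError(LogIOError):
    """Parsed content violates a stream invariant (e.g. timestamps)."""


@dataclass(frozen=True)
class Vector3:
    """A patient-frame vector in mm: (S–I, L–R, A–P)."""

    si: float
    lr: float
    ap: float

    def __post_init__(self):
        if not all(math.isfinite(c) for c in (self.si, self.lr, self.ap)):
            raise ValueError(f"non-finite component in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.si, self.lr, self.ap], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Vector3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class RobotVector3:
    """A robot-world-frame vector in mm."""

    x_rob: float
    y_rob: float
    z_rob: float

    def __post_init__(self):
        if not all(math.isfinite(c) for c in (self.x_rob, self.y_rob, self.z_rob)):
            raise ValueError(f"non-finite component in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_rob, self.y_rob, self.z_rob], dtype=float)

    @classmethod
    def from_array(cls, a) -> "RobotVector3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


def robot_to_patient(v: RobotVector3 | np.ndarray) -> Vector3:
    """Map a robot-world-frame vector to the patient frame.

    The transform is linear with the printed coefficients::

        si = 0.7081 * x_rob + 0.7061 * y_rob
        lr = -0.7081 * x_rob + 0.7061 * y_rob
        ap = z_rob
    """
    a = v.as_array() if isinstance(v, RobotVector3) else np.asarray(v, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite component in robot-frame vector")
    return Vector3.from_array(_ROB_TO_PAT @ a)


def patient_to_robot(v: Vector3 | np.ndarray) -> RobotVector3:
    """Inverse of :func:`robot_to_patient` (exact linear inverse)."""
    a = v.as_array() if isinstance(v, Vector3) else np.asarray(v, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite component in patient-frame vector")
    return RobotVector3.from_array(_PAT_TO_ROB @ a)


def _rob_to_pat_rows(x: np.ndarray) -> np.ndarray:
    """Vectorized robot->patient transform on an (n, 3) array."""
    return x @ _ROB_TO_PAT.T


def _pat_to_rob_rows(x: np.ndarray) -> np.ndarray:
    return x @ _PAT_TO_ROB.T


# ---------------------------------------------------------------------------
# Streams: columnar containers (numpy-backed) with record-style access.
# ---------------------------------------------------------------------------


def _check_timestamps(t: np.ndarray, name: str) -> None:
    if t.size and not np.all(np.diff(t) > 0):
        raise LogValidationError(f"{name}: timestamps not strictly increasing")


@dataclass
class MarkerStream:
    """Raw LED surrogate stream: timestamps (s) and 3 LED positions (mm)."""

    t: np.ndarray  # (n,)
    leds: np.ndarray  # (n, 3, 3) — LED index, then (SI, LR, AP)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.leds = np.asarray(self.leds, dtype=float)
        if self.leds.ndim != 3 or self.leds.shape[1:] != (3, 3):
            raise LogValidationError("MarkerStream: leds must have shape (n, 3, 3)")
        _check_timestamps(self.t, "Markers")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class ModelPointRecord:
    timestamp: float
    fiducial_centroid: Vector3
    led_positions: tuple[Vector3, Vector3, Vector3]
    correlation_error: Vector3


@dataclass
class ModelPointStream:
    """Sparse radiographic localizations used to build the correlation model.

    ``fiducial`` is the imaged fiducial-centroid (tumor) position,
    ``correlation_error`` the correlation-model residual at that instant.
    """

    t: np.ndarray  # (n,)
    fiducial: np.ndarray  # (n, 3) mm
    leds: np.ndarray  # (n, 3, 3) mm
    correlation_error: np.ndarray  # (n, 3) mm

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.fiducial = np.asarray(self.fiducial, dtype=float)
        self.leds = np.asarray(self.leds, dtype=float)
        self.correlation_error = np.asarray(self.correlation_error, dtype=float)
        if self.leds.ndim != 3 or self.leds.shape[1:] != (3, 3):
            raise LogValidationError("ModelPoints: exactly 3 LED triplets per row")
        _check_timestamps(self.t, "ModelPoints")

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> ModelPointRecord:
        return ModelPointRecord(
            float(self.t[i]),
            Vector3.from_array(self.fiducial[i]),
            tuple(Vector3.from_array(self.leds[i, j]) for j in range(3)),
            Vector3.from_array(self.correlation_error[i]),
        )


@dataclass
class ModelerStream:
    """Continuous correlation-model target estimate (mm, patient frame)."""

    t: np.ndarray
    estimate: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        _check_timestamps(self.t, "Modeler")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class PredictorRecord:
    timestamp: float
    predicted_position: Vector3
    prediction_error: Vector3


@dataclass
class PredictorStream:
    """Latency-compensation predictor output and residual (mm)."""

    t: np.ndarray
    predicted: np.ndarray  # (n, 3)
    prediction_error: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.prediction_error = np.asarray(self.prediction_error, dtype=float)
        _check_timestamps(self.t, "Predictor")

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> PredictorRecord:
        return PredictorRecord(
            float(self.t[i]),
            Vector3.from_array(self.predicted[i]),
            Vector3.from_array(self.prediction_error[i]),
        )


@dataclass(frozen=True)
class ERsiRecord:
    timestamp: float
    robot_position: RobotVector3
    commanded_offset: RobotVector3
    robotic_error: Vector3


@dataclass
class ERsiStream:
    """Robot world-frame position/offsets plus patient-frame robotic residual."""

    t: np.ndarray
    robot_position: np.ndarray  # (n, 3), robot frame, mm
    commanded_offset: np.ndarray  # (n, 3), robot frame, mm
    robotic_error: np.ndarray  # (n, 3), patient frame, mm

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.robot_position = np.asarray(self.robot_position, dtype=float)
        self.commanded_offset = np.asarray(self.commanded_offset, dtype=float)
        self.robotic_error = np.asarray(self.robotic_error, dtype=float)
        _check_timestamps(self.t, "ERsiData")

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> ERsiRecord:
        return ERsiRecord(
            float(self.t[i]),
            RobotVector3.from_array(self.robot_position[i]),
            RobotVector3.from_array(self.commanded_offset[i]),
            Vector3.from_array(self.robotic_error[i]),
        )


@dataclass
class FractionLogBundle:
    """One treatment fraction's five parsed log streams (patient frame, mm)."""

    patient_id: str
    tumor_site: str
    fraction_index: int
    modelpoints: ModelPointStream
    predictor: PredictorStream
    ersidata: ERsiStream
    markers: MarkerStream
    modeler: ModelerStream

    def __post_init__(self):
        if self.tumor_site not in TUMOR_SITES:
            raise LogValidationError(
                f"unknown tumor site {self.tumor_site!r}; "
                f"expected one of {TUMOR_SITES}"
            )
        if self.fraction_index < 1:
            raise LogValidationError("fraction_index must be a positive integer")


# ---------------------------------------------------------------------------
# File dialect
# ---------------------------------------------------------------------------

_STREAM_FILES = {
    "markers": "Markers.log",
    "modelpoints": "ModelPoints.log",
    "modeler": "Modeler.log",
    "predictor": "Predictor.log",
    "ersidata": "ERsiData.log",
}

_STREAM_NCOLS = {
    "markers": 10,
    "modelpoints": 16,
    "modeler": 4,
    "predictor": 7,
    "ersidata": 10,
}

_COLUMNS = {
    "markers": "t,led1_si,led1_lr,led1_ap,led2_si,led2_lr,led2_ap,led3_si,led3_lr,led3_ap",
    "modelpoints": (
        "t,fid_si,fid_lr,fid_ap,led1_si,led1_lr,led1_ap,led2_si,led2_lr,led2_ap,"
        "led3_si,led3_lr,led3_ap,cerr_si,cerr_lr,cerr_ap"
    ),
    "modeler": "t,est_si,est_lr,est_ap",
    "predictor": "t,pred_si,pred_lr,pred_ap,perr_si,perr_lr,perr_ap",
    "ersidata": "t,rob_x,rob_y,rob_z,off_x,off_y,off_z,rerr_si,rerr_lr,rerr_ap",
}

_FMT = "%.6f"


def _parse_file(path: Path) -> tuple[dict, np.ndarray]:
    """Read one dialect file: header mapping and a (n, ncols) float array."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    ncols = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split(",")
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise LogParseError(path, lineno, f"non-numeric field: {exc}") from None
            if ncols is None:
                ncols = len(row)
            elif len(row) != ncols:
                raise LogParseError(
                    path, lineno, f"expected {ncols} fields, found {len(row)}"
                )
            rows.append(row)
    stream = meta.get("stream")
    expected = _STREAM_NCOLS.get(stream) if stream else None
    if expected is not None and rows and len(rows[0]) != expected:
        raise LogParseError(
            path, 1, f"stream {stream!r} requires {expected} columns, found {len(rows[0])}"
        )
    data = np.array(rows, dtype=float) if rows else np.empty((0, expected or 0))
    if not np.all(np.isfinite(data)):
        raise LogValidationError(f"{path}: non-finite value in data rows")
    return meta, data


def _require(meta: dict, key: str, path: Path) -> str:
    if key not in meta:
        raise LogParseError(path, 1, f"missing required header key {key!r}")
    return meta[key]


def parse_bundle(directory) -> FractionLogBundle:
    """Parse one fraction's five log files from *directory*.

    Positions are normalized to the patient frame: if a file declares
    ``frame=robot``, every patient-frame vector column is mapped through the
    world-to-patient transform.  The robot position and commanded offset in
    ``ERsiData.log`` are robot-frame quantities and are stored as recorded.
    """
    directory = Path(directory)
    raw: dict[str, tuple[dict, np.ndarray]] = {}
    for stream, fname in _STREAM_FILES.items():
        path = directory / fname
        if not path.exists():
            raise MissingStreamError(f"missing log stream {fname} in {directory}")
        raw[stream] = _parse_file(path)

    meta0, _ = raw["modelpoints"]
    patient_id = _require(meta0, "patient_id", directory / "ModelPoints.log")
    tumor_site = _require(meta0, "tumor_site", directory / "ModelPoints.log")
    fraction_index = int(_require(meta0, "fraction_index", directory / "ModelPoints.log"))

    def vec_cols(stream: str, data: np.ndarray, start: int) -> np.ndarray:
        block = data[:, start : start + 3]
        if raw[stream][0].get("frame", "patient") == "robot":
            block = _rob_to_pat_rows(block)
        return block

    m_meta, m = raw["markers"]
    markers = MarkerStream(
        t=m[:, 0] if m.size else np.empty(0),
        leds=np.stack(
            [vec_cols("markers", m, 1 + 3 * j) for j in range(3)], axis=1
        )
        if m.size
        else np.empty((0, 3, 3)),
    )

    _, mp = raw["modelpoints"]
    if mp.size == 0:
        raise LogValidationError(f"{directory}/ModelPoints.log: no data rows")
    modelpoints = ModelPointStream(
        t=mp[:, 0],
        fiducial=vec_cols("modelpoints", mp, 1),
        leds=np.stack([vec_cols("modelpoints", mp, 4 + 3 * j) for j in range(3)], axis=1),
        correlation_error=vec_cols("modelpoints", mp, 13),
    )

    _, md = raw["modeler"]
    modeler = ModelerStream(
        t=md[:, 0] if md.size else np.empty(0),
        estimate=vec_cols("modeler", md, 1) if md.size else np.empty((0, 3)),
    )

    _, pr = raw["predictor"]
    predictor = PredictorStream(
        t=pr[:, 0] if pr.size else np.empty(0),
        predicted=vec_cols("predictor", pr, 1) if pr.size else np.empty((0, 3)),
        prediction_error=vec_cols("predictor", pr, 4) if pr.size else np.empty((0, 3)),
    )

    _, er = raw["ersidata"]
    ersidata = ERsiStream(
        t=er[:, 0] if er.size else np.empty(0),
        robot_position=er[:, 1:4] if er.size else np.empty((0, 3)),
        commanded_offset=er[:, 4:7] if er.size else np.empty((0, 3)),
        robotic_error=vec_cols("ersidata", er, 7) if er.size else np.empty((0, 3)),
    )

    return FractionLogBundle(
        patient_id=patient_id,
        tumor_site=tumor_site,
        fraction_index=fraction_index,
        modelpoints=modelpoints,
        predictor=predictor,
        ersidata=ersidata,
        markers=markers,
        modeler=modeler,
    )


def _write_file(path: Path, meta: Mapping[str, object], data: np.ndarray) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        for row in data:
            fh.write(",".join(_FMT % v for v in row) + "\n")


def write_bundle(bundle: FractionLogBundle, directory) -> dict[str, Path]:
    """Write a bundle's five log files (patient frame) into *directory*.

    Values are printed at 6 decimal places; the round trip
    ``parse_bundle(write_bundle(b))`` is lossless at that precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base_meta = {
        "patient_id": bundle.patient_id,
        "tumor_site": bundle.tumor_site,
        "fraction_index": bundle.fraction_index,
        "frame": "patient",
    }
    paths: dict[str, Path] = {}

    def out(stream: str, data: np.ndarray) -> None:
        path = directory / _STREAM_FILES[stream]
        meta = dict(base_meta, stream=stream, columns=_COLUMNS[stream])
        _write_file(path, meta, data)
        paths[stream] = path

    mk = bundle.markers
    out("markers", np.column_stack([mk.t, mk.leds.reshape(len(mk), 9)]) if len(mk) else np.empty((0, 10)))
    mp = bundle.modelpoints
    out(
        "modelpoints",
        np.column_stack(
            [mp.t, mp.fiducial, mp.leds.reshape(len(mp), 9), mp.correlation_error]
        ),
    )
    md = bundle.modeler
    out("modeler", np.column_stack([md.t, md.estimate]) if len(md) else np.empty((0, 4)))
    pr = bundle.predictor
    out(
        "predictor",
        np.column_stack([pr.t, pr.predicted, pr.prediction_error]) if len(pr) else np.empty((0, 7)),
    )
    er = bundle.ersidata
    out(
        "ersidata",
        np.column_stack([er.t, er.robot_position, er.commanded_offset, er.robotic_error])
        if len(er)
        else np.empty((0, 10)),
    )
    return paths


def bundles_allclose(a: FractionLogBundle, b: FractionLogBundle, atol: float = 1e-6) -> bool:
    """True if two bundles agree in metadata and numerically within *atol*."""
    if (a.patient_id, a.tumor_site, a.fraction_index) != (
        b.patient_id,
        b.tumor_site,
        b.fraction_index,
    ):
        return False
    pairs = [
        (a.markers.t, b.markers.t),
        (a.markers.leds, b.markers.leds),
        (a.modelpoints.t, b.modelpoints.t),
        (a.modelpoints.fiducial, b.modelpoints.fiducial),
        (a.modelpoints.leds, b.modelpoints.leds),
        (a.modelpoints.correlation_error, b.modelpoints.correlation_error),
        (a.modeler.t, b.modeler.t),
        (a.modeler.estimate, b.modeler.estimate),
        (a.predictor.t, b.predictor.t),
        (a.predictor.predicted, b.predictor.predicted),
        (a.predictor.prediction_error, b.predictor.prediction_error),
        (a.ersidata.t, b.ersidata.t),
        (a.ersidata.robot_position, b.ersidata.robot_position),
        (a.ersidata.commanded_offset, b.ersidata.commanded_offset),
        (a.ersidata.robotic_error, b.ersidata.robotic_error),
    ]
    return all(
        x.shape == y.shape and np.allclose(x, y, atol=atol, rtol=0.0) for x, y in pairs
    )
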