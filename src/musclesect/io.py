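"""Imaging, landmark and cohort-table I/O with geometric validation.

All imagery moves through NIfTI-1 (via :mod:`nibabel`); landmarks through a
small JSON schema; tabular data through CSV.  The loaders are strict: a CT
volume and its muscle label map must live on the identical voxel lattice
(shape, spacing, world transform), label codes must be drawn from the declared
code map, and landmark geometry must actually define a plane.  Anything that
fails validation raises an :class:`ExamValidationError` subclass rather than
propagating downstream as a silent geometric inconsistency.

World coordinates are patient-based millimetres in the frame declared by the
landmark file (default RAS: +x right, +y anterior, +z superior).  The NIfTI
affine is honoured as given; "medial" is always resolved from the
``medial_reference`` landmark, never from an axis sign, so left and right
shoulders are handled identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "MUSCLE_CODES",
    "COVARIATE_COLUMNS",
    "ExamValidationError",
    "LatticeMismatchError",
    "LabelCodeError",
    "LandmarkGeometryError",
    "CohortError",
    "ImageVolume",
    "MuscleLabelMap",
    "LandmarkSet",
    "ExamRecord",
    "CovariateRecord",
    "load_exam",
    "save_exam",
    "load_landmarks",
    "load_cohort",
    "load_covariates",
    "encode_covariates",
    "write_measurement_table",
    "read_measurement_table",
]

#: The four serial examination timepoints: preoperative and 1, 6, 12 months
#: after surgery.
TIMEPOINTS = ("pre", "1mo", "6mo", "12mo")

#: Label codes of the two muscle groups of the transverse force couple.
MUSCLE_CODES = {1: "Ssc", 2: "Isp+TM"}

#: Accepted world frames.  Both have +z superior, which is all the pipeline
#: relies on (the inferior cut-off direction); medial/lateral is resolved
#: per-exam from the medial_reference landmark.
_SUPPORTED_FRAMES = ("RAS", "LPS")


class ExamValidationError(ValueError):
    """An exam triple failed geometric or semantic validation."""


class LatticeMismatchError(ExamValidationError):
    """CT volume and label map do not share a voxel lattice."""


class LabelCodeError(ExamValidationError):
    """Label map contains codes outside the declared code map."""


class LandmarkGeometryError(ExamValidationError):
    """Landmarks do not define a usable plane geometry."""


class CohortError(ValueError):
    """Manifest or covariate table violates the cohort contract."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A 3D CT scalar field (Hounsfield units) on a rigid voxel lattice.

    Parameters
    ----------
    data:
        3D array of HU values.
    affine:
        4x4 voxel-index -> world-mm transform (NIfTI convention).  The
        rotational part must be orthogonal up to per-axis scaling by the
        voxel spacing.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ExamValidationError(f"expected 3D data, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ExamValidationError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def direction(self) -> np.ndarray:
        """Direction-cosine matrix (columns are unit voxel axes in world)."""
        return self.affine[:3, :3] / self.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def validate(self) -> None:
        sp = self.spacing
        if not np.all(sp > 0):
            raise ExamValidationError(f"non-positive voxel spacing {sp}")
        det = np.linalg.det(self.direction)
        if abs(abs(det) - 1.0) > 1e-6:
            raise ExamValidationError(
                f"direction cosines not orthonormal (|det|={abs(det):.8f})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ExamValidationError("HU field contains non-finite values")


@dataclass
class MuscleLabelMap:
    """Integer segmentation on the same lattice as its :class:`ImageVolume`.

    Codes: 0 background, 1 subscapularis (Ssc), 2 infraspinatus + teres
    minor (Isp+TM).  An alternative ``code_map`` may be supplied when
    ingesting label maps produced with different conventions.
    """

    labels: np.ndarray
    affine: np.ndarray
    code_map: dict = field(default_factory=lambda: dict(MUSCLE_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ExamValidationError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            rounded = np.rint(lab)
            if not np.allclose(lab, rounded):
                raise LabelCodeError("label map values are not integers")
            self.labels = rounded.astype(np.int16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def validate(self, require_nonempty: bool = True) -> None:
        present = np.unique(self.labels)
        allowed = set(self.code_map) | {0}
        extra = set(present.tolist()) - allowed
        if extra:
            raise LabelCodeError(f"unknown label codes {sorted(extra)}")
        if require_nonempty:
            for code, name in sorted(self.code_map.items()):
                if code == 0:
                    continue
                if not np.any(self.labels == code):
                    raise LabelCodeError(f"label {code} ({name}) is empty")

    def support(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class LandmarkSet:
    """World-mm landmarks anchoring the sectional geometry of one exam.

    ``y_plane_points`` are three non-collinear points on the scapular Y-view
    plane; ``medial_reference`` disambiguates which side of that plane is
    medial; ``labrum_inferior`` marks the lower end of the glenoid labrum,
    from which the inferior cut-off plane is offset.
    """

    y_plane_points: np.ndarray
    medial_reference: np.ndarray
    labrum_inferior: np.ndarray
    frame: str = "RAS"

    def __post_init__(self) -> None:
        self.y_plane_points = np.asarray(self.y_plane_points, dtype=float)
        self.medial_reference = np.asarray(self.medial_reference, dtype=float)
        self.labrum_inferior = np.asarray(self.labrum_inferior, dtype=float)
        if self.y_plane_points.shape != (3, 3):
            raise LandmarkGeometryError("y_plane_points must be three 3-vectors")
        for name in ("medial_reference", "labrum_inferior"):
            if getattr(self, name).shape != (3,):
                raise LandmarkGeometryError(f"{name} must be a 3-vector")
        if self.frame not in _SUPPORTED_FRAMES:
            raise LandmarkGeometryError(
                f"frame {self.frame!r} not supported (use one of {_SUPPORTED_FRAMES})"
            )

    def validate(self) -> None:
        p1, p2, p3 = self.y_plane_points
        cross = np.cross(p2 - p1, p3 - p1)
        area = 0.5 * np.linalg.norm(cross)
        if area <= 1.0:  # mm^2
            raise LandmarkGeometryError(
                f"y_plane_points nearly collinear (triangle area {area:.3g} mm^2)"
            )
        normal = cross / np.linalg.norm(cross)
        dist = abs(float(np.dot(normal, self.medial_reference - p1)))
        if dist <= 1.0:  # mm
            raise LandmarkGeometryError(
                f"medial_reference lies on the Y-view plane (distance {dist:.3g} mm)"
            )

    def to_json(self, path) -> None:
        payload = {
            "frame": self.frame,
            "y_plane_points": self.y_plane_points.tolist(),
            "medial_reference": self.medial_reference.tolist(),
            "labrum_inferior": self.labrum_inferior.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        payload = json.loads(Path(path).read_text())
        try:
            return cls(
                y_plane_points=payload["y_plane_points"],
                medial_reference=payload["medial_reference"],
                labrum_inferior=payload["labrum_inferior"],
                frame=payload.get("frame", "RAS"),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise LandmarkGeometryError(f"landmark file missing key {exc}") from exc


@dataclass
class ExamRecord:
    """One examination of one subject at one timepoint (optionally one rater)."""

    subject_id: str
    timepoint: str
    rater_id: Optional[str]
    ct_path: Path
    label_path: Path
    landmark_path: Path

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise CohortError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        self.ct_path = Path(self.ct_path)
        self.label_path = Path(self.label_path)
        self.landmark_path = Path(self.landmark_path)

    def load(self):
        return load_exam(self.ct_path, self.label_path, self.landmark_path)


# fields used as regression covariates, in the canonical reporting order
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "side",
    "symptom_duration",
    "activity_level",
    "bankart",
    "hill_sachs",
    "load_shift",
    "sulcus",
    "rom_flexion",
    "rom_abduction",
    "rom_external",
)

_CATEGORY_CODES = {
    "sex": {"male": 1, "female": 0},
    "side": {"right": 1, "left": 0},
    "activity_level": {"high": 1, "low": 0},
    "bankart": {"bone": 1, "soft_tissue": 0},
    "hill_sachs": {"none": 0, "shallow": 1, "deep": 2},
}


@dataclass
class CovariateRecord:
    """Clinical/demographic covariates of one subject.

    Categorical fields keep their string levels; :func:`encode_covariates`
    maps them to the numeric coding used by the regression module
    (male=1, right=1, high activity=1, bony Bankart=1, Hill-Sachs
    none/shallow/deep = 0/1/2, ordinal grades as-is).
    """

    subject_id: str
    age: float
    sex: str
    side: str
    symptom_duration: float
    activity_level: str
    load_shift: int
    sulcus: int
    hill_sachs: str
    bankart: str
    rom_flexion: float
    rom_abduction: float
    rom_external: float

    def validate(self) -> None:
        for name in ("sex", "side", "activity_level", "bankart", "hill_sachs"):
            value = getattr(self, name)
            if value not in _CATEGORY_CODES[name]:
                raise CohortError(
                    f"subject {self.subject_id}: {name}={value!r} not in "
                    f"{sorted(_CATEGORY_CODES[name])}"
                )
        for name in ("load_shift", "sulcus"):
            grade = getattr(self, name)
            if not (0 <= int(grade) <= 3):
                raise CohortError(
                    f"subject {self.subject_id}: {name} grade {grade} outside 0-3"
                )
        for name in ("rom_flexion", "rom_abduction", "rom_external"):
            rom = float(getattr(self, name))
            if not (0.0 <= rom <= 200.0):
                raise CohortError(
                    f"subject {self.subject_id}: {name}={rom} outside [0, 200] degrees"
                )


# ---------------------------------------------------------------------------
# exam loading / saving
# ---------------------------------------------------------------------------


def _lattice_matches(vol: ImageVolume, labels: MuscleLabelMap, rtol: float = 1e-4) -> bool:
    if vol.shape != labels.shape:
        return False
    scale = max(1.0, float(np.abs(vol.affine).max()))
    return bool(np.allclose(vol.affine, labels.affine, rtol=rtol, atol=rtol * scale))


def load_landmarks(path) -> LandmarkSet:
    """Read and validate a landmark JSON file."""
    lm = LandmarkSet.from_json(path)
    lm.validate()
    return lm


def load_exam(volume_path, label_path, landmark_path):
    """Load and cross-validate one exam triple.

    Returns ``(ImageVolume, MuscleLabelMap, LandmarkSet)``.  Raises
    :class:`LatticeMismatchError` when the CT and label lattices disagree
    beyond 1e-4 relative, :class:`LabelCodeError` for unknown or empty label
    codes and :class:`LandmarkGeometryError` for degenerate landmarks.
    """
    for p in (volume_path, label_path, landmark_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    vol_img = nib.load(str(volume_path))
    lab_img = nib.load(str(label_path))
    volume = ImageVolume(np.asarray(vol_img.dataobj, dtype=np.float32), vol_img.affine)
    labels = MuscleLabelMap(
        np.asarray(np.rint(np.asarray(lab_img.dataobj)), dtype=np.int16),
        lab_img.affine,
    )
    volume.validate()
    labels.validate()
    if not _lattice_matches(volume, labels):
        raise LatticeMismatchError(
            f"CT {volume.shape} and label map {labels.shape} lattices differ "
            f"(shape/spacing/transform)"
        )
    landmarks = load_landmarks(landmark_path)
    return volume, labels, landmarks


def save_exam(volume: ImageVolume, labels: MuscleLabelMap, landmarks: LandmarkSet,
              volume_path, label_path, landmark_path) -> None:
    """Write an exam triple (NIfTI + NIfTI + landmark JSON)."""
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine),
             str(volume_path))
    nib.save(nib.Nifti1Image(np.asarray(labels.labels, dtype=np.uint8), labels.affine),
             str(label_path))
    landmarks.to_json(landmark_path)


# ---------------------------------------------------------------------------
# cohort loading
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("subject_id", "timepoint", "rater_id",
                     "ct_path", "label_path", "landmark_path")


def load_covariates(covariate_path) -> pd.DataFrame:
    """Read a covariate CSV (one row per subject) and validate each record."""
    cov = pd.read_csv(covariate_path, dtype={"subject_id": str})
    missing = {"subject_id", *COVARIATE_COLUMNS} - set(cov.columns)
    if missing:
        raise CohortError(f"covariate table missing columns {sorted(missing)}")
    if cov["subject_id"].duplicated().any():
        dup = cov.loc[cov["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortError(f"duplicate covariate rows for subjects {dup}")
    for row in cov.itertuples(index=False):
        CovariateRecord(**{k: getattr(row, k) for k in
                           ("subject_id", *COVARIATE_COLUMNS)}).validate()
    return cov.set_index("subject_id", drop=False)


def load_cohort(manifest_path, covariate_path):
    """Load a cohort manifest and its covariate table, joined by subject.

    Returns ``(exam_records, covariates)`` where ``exam_records`` is a list of
    :class:`ExamRecord` (files are not opened here) and ``covariates`` a
    subject-indexed DataFrame.  Rejects unknown timepoints, duplicate
    (subject, timepoint, rater) rows and manifest subjects without covariates.
    """
    manifest = pd.read_csv(manifest_path, dtype=str)
    missing = set(_MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise CohortError(f"manifest missing columns {sorted(missing)}")
    bad_tp = sorted(set(manifest["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise CohortError(f"unknown timepoints {bad_tp}; expected {TIMEPOINTS}")
    keys = manifest[["subject_id", "timepoint", "rater_id"]].fillna("")
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].to_dict("records")
        raise CohortError(f"duplicate (subject, timepoint, rater) rows: {dup}")
    covariates = load_covariates(covariate_path)
    orphans = sorted(set(manifest["subject_id"]) - set(covariates.index))
    if orphans:
        raise CohortError(f"manifest subjects missing from covariates: {orphans}")
    base = Path(manifest_path).parent
    records = []
    for row in manifest.itertuples(index=False):
        rater = row.rater_id if isinstance(row.rater_id, str) and row.rater_id else None
        records.append(ExamRecord(
            subject_id=row.subject_id,
            timepoint=row.timepoint,
            rater_id=rater,
            ct_path=base / row.ct_path,
            label_path=base / row.label_path,
            landmark_path=base / row.landmark_path,
        ))
    return records, covariates


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns for the 12 regression covariates.

    Coding: sex male=1/female=0; side right=1/left=0; activity high=1/low=0;
    Bankart bone=1/soft_tissue=0; Hill-Sachs none/shallow/deep = 0/1/2;
    load-shift and sulcus as ordinal grades; age, symptom duration and the
    three range-of-motion measures untransformed.
    """
    out = {}
    for name in COVARIATE_COLUMNS:
        col = covariates[name]
        if name in _CATEGORY_CODES:
            out[name] = col.map(_CATEGORY_CODES[name]).astype(float)
            if out[name].isna().any():
                bad = col[out[name].isna()].unique().tolist()
                raise CohortError(f"cannot code {name} levels {bad}")
        else:
            out[name] = pd.to_numeric(col).astype(float)
    return pd.DataFrame(out, index=covariates.index)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

_MEASUREMENT_COLUMNS = ("subject_id", "timepoint", "rater_id", "muscle",
                        "section", "voxel_count", "volume_cm3", "mean_hu")


def write_measurement_table(rows: Iterable, path) -> pd.DataFrame:
    """Write sectional measurements to CSV, one row per
    (subject, timepoint, rater, muscle, section).

    ``rows`` may be measurement dataclasses, dicts or a DataFrame.  Floats are
    written at full precision so a read-back round-trips within 1e-9.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        dicts = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                 for r in rows]
        if not dicts:
            raise ValueError("no measurement rows to write")
        df = pd.DataFrame(dicts)
    if df.empty:
        raise ValueError("no measurement rows to write")
    missing = set(_MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement rows missing fields {sorted(missing)}")
    df = df.loc[:, [c for c in df.columns if c in _MEASUREMENT_COLUMNS]]
    df = df[list(_MEASUREMENT_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_measurement_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "rater_id": str})
    missing = set(_MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    return df
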