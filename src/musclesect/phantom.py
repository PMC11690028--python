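"""Synthetic exams and cohorts with analytically known ground truth.

Patient CT cannot be redistributed, so every pipeline stage is exercised
against synthetic data built from primitives whose sectional volumes have
closed forms:

* **Ellipsoid phantoms** stand in for segmented muscles.  An ellipsoid cut by
  a plane has an exact slab volume (see :func:`ellipsoid_halfspace_volume`),
  so voxelized sectional measurements can be checked against analytic truth
  at any spacing.  Realism is a non-goal; verifiability is the goal.
* **Longitudinal trajectories** emulate the perioperative course reported for
  shoulder muscles: an early (1-month) drop in volume and CT density by a
  per-subject fraction delta, near-complete recovery by 6 months and partial
  recovery (rho ~ 0.8 * delta) by 12 months.  Because the 12-month recovery
  amount grows with the drop, the generated ``Dif.pre.1mo`` and
  ``Dif.1.12mo`` differences are negatively correlated by construction —
  the qualitative signature the statistics module must detect.
* **Rater noise** is i.i.d. additive error on a latent per-subject truth, so
  the expected ICC(2,1) equals var(truth) / (var(truth) + sigma_e^2).

All randomness flows through a single seed; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    MUSCLE_CODES,
    TIMEPOINTS,
    ImageVolume,
    LandmarkSet,
    MuscleLabelMap,
    save_exam,
)

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "PhantomExam",
    "TrajectorySpec",
    "ellipsoid_halfspace_volume",
    "make_phantom_exam",
    "default_phantom_spec",
    "simulate_covariates",
    "simulate_cohort",
    "simulate_imaging_cohort",
    "write_imaging_cohort",
    "simulate_raters",
]


# ---------------------------------------------------------------------------
# analytic ellipsoid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    """A world-space ellipsoid: center (mm), semi-axes (mm), rotation matrix.

    ``rotation`` columns are the world directions of the local a/b/c axes.
    """

    center: tuple
    semi_axes: tuple
    rotation: Optional[tuple] = None  # 3x3, row-major; None = axis-aligned

    def _rot(self) -> np.ndarray:
        if self.rotation is None:
            return np.eye(3)
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("ellipsoid rotation must be orthonormal")
        return r

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def half_width(self, direction) -> float:
        """Support half-width: extent of the ellipsoid along a unit direction."""
        n = np.asarray(direction, dtype=float)
        t = (self._rot() * np.asarray(self.semi_axes)).T @ n  # diag scaling
        return float(np.linalg.norm(t))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside-test for an (..., 3) array of world points."""
        pts = np.asarray(points, dtype=float)
        local = (pts - np.asarray(self.center)) @ self._rot()
        u = local / np.asarray(self.semi_axes, dtype=float)
        return np.einsum("...i,...i->...", u, u) <= 1.0


def ellipsoid_halfspace_volume(ellipsoid: Ellipsoid, normal, plane_offset: float) -> float:
    """Exact volume (mm^3) of an ellipsoid within the half-space n.x <= offset.

    For the unit ball cut at signed height t the cap-complement volume is
    pi * (2/3 + t - t^3/3); a general ellipsoid is its linear image, so the
    same expression applies with t = d / a_n where d is the plane's signed
    distance from the center and a_n the support half-width along the normal.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = float(plane_offset - n @ np.asarray(ellipsoid.center, dtype=float))
    a_n = ellipsoid.half_width(n)
    t = np.clip(d / a_n, -1.0, 1.0)
    a, b, c = ellipsoid.semi_axes
    return float(a * b * c * np.pi * (2.0 / 3.0 + t - t ** 3 / 3.0))


# ---------------------------------------------------------------------------
# single-exam phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic exam.

    The world frame is RAS with the grid centered on the origin; +x is the
    medial direction by construction (the medial-reference landmark is placed
    at large +x).  Voxel centers sit at half-spacing offsets from the origin,
    so a plane through x=0 never coincides with a layer of voxel centers.

    ``labrum_z`` defaults to auto-placement making the inferior cut-off plane
    tangent to the bottom of the lowest muscle, which keeps every sectional
    ground-truth volume a pure ellipsoid-slab closed form.
    """

    muscles: dict  # label code -> Ellipsoid
    hu: dict = field(default_factory=lambda: {1: (59.0, 6.0), 2: (62.0, 6.0)})
    background_hu: tuple = (-40.0, 15.0)
    spacing: tuple = (1.0, 1.0, 2.0)
    fov_mm: tuple = (150.0, 150.0, 90.0)
    y_plane_x: float = 0.0
    #: Y-view plane normal (medial side positive; x component must dominate).
    #: A tilted normal avoids the grid-aligned special case in which the cut
    #: quantizes to voxel columns and voxelization error stops shrinking.
    y_plane_normal: tuple = (1.0, 0.0, 0.0)
    labrum_z: Optional[float] = None
    inferior_offset_mm: float = 30.0
    offsets_mm: tuple = (0.0, 25.0, 50.0)
    seed: int = 0


@dataclass
class PhantomExam:
    volume: ImageVolume
    labels: MuscleLabelMap
    landmarks: LandmarkSet
    ground_truth: dict


def _grid(spec: PhantomSpec):
    spacing = np.asarray(spec.spacing, dtype=float)
    fov = np.asarray(spec.fov_mm, dtype=float)
    shape = np.maximum(2, (np.round(fov / spacing / 2) * 2).astype(int))  # even
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = (0.5 - shape / 2.0) * spacing  # centers at half-offsets
    return shape, affine


def _cutoff_z(spec: PhantomSpec) -> float:
    if spec.labrum_z is not None:
        return spec.labrum_z - spec.inferior_offset_mm
    z_axis = np.array([0.0, 0.0, 1.0])
    bottoms = [e.center[2] - e.half_width(z_axis) for e in spec.muscles.values()]
    return float(min(bottoms))  # tangent to the lowest muscle


def _section_names(offsets):
    from .geometry import section_name

    return [section_name(o) for o in offsets]


def make_phantom_exam(spec: PhantomSpec) -> PhantomExam:
    """Voxelize a phantom spec into a full exam triple plus ground truth.

    Labels are assigned by the voxel-center inside-test; where ellipsoids
    overlap, Isp+TM (code 2) takes precedence and Ssc is excised.  HU values
    are drawn per voxel from each region's normal distribution (seeded); with
    all standard deviations zero the field is deterministic constants.

    ``ground_truth`` maps ``(muscle_name, section)`` to the analytic slab
    volume in cm^3, and carries full-muscle volumes, the HU means, and the
    count of overlap voxels excised from Ssc (zero for valid specs).
    """
    shape, affine = _grid(spec)
    spacing = np.asarray(spec.spacing, dtype=float)
    half_fov = shape * spacing / 2.0
    for code, ell in spec.muscles.items():
        for ax in range(3):
            n = np.zeros(3)
            n[ax] = 1.0
            lo = ell.center[ax] - ell.half_width(n)
            hi = ell.center[ax] + ell.half_width(n)
            if lo < -half_fov[ax] or hi > half_fov[ax]:
                raise ValueError(
                    f"muscle {code} ellipsoid exceeds the field of view on axis {ax}"
                )

    ni, nj, nk = (int(s) for s in shape)
    xs = (np.arange(ni) + 0.5 - ni / 2.0) * spacing[0]
    ys = (np.arange(nj) + 0.5 - nj / 2.0) * spacing[1]
    zs = (np.arange(nk) + 0.5 - nk / 2.0) * spacing[2]

    rng = np.random.default_rng(spec.seed)
    bg_mean, bg_sd = spec.background_hu
    noiseless = bg_sd == 0 and all(sd == 0 for _, sd in spec.hu.values())

    labels = np.zeros((ni, nj, nk), dtype=np.int16)
    data = np.empty((ni, nj, nk), dtype=np.float32)
    overlap_voxels = 0
    # slice-by-slice to keep peak memory independent of grid size
    plane_pts = np.empty((ni, nj, 3))
    plane_pts[:, :, 0] = xs[:, None]
    plane_pts[:, :, 1] = ys[None, :]
    codes = sorted(spec.muscles)
    for k in range(nk):
        plane_pts[:, :, 2] = zs[k]
        inside = {c: spec.muscles[c].contains(plane_pts) for c in codes}
        lab_k = np.zeros((ni, nj), dtype=np.int16)
        if 1 in inside:
            lab_k[inside[1]] = 1
        if 2 in inside:
            if 1 in inside:
                overlap_voxels += int(np.count_nonzero(inside[1] & inside[2]))
            lab_k[inside[2]] = 2  # Isp+TM precedence in overlaps
        labels[:, :, k] = lab_k
        if noiseless:
            hu_k = np.full((ni, nj), bg_mean, dtype=np.float32)
            for c in codes:
                hu_k[lab_k == c] = spec.hu[c][0]
        else:
            hu_k = rng.normal(bg_mean, bg_sd, size=(ni, nj)).astype(np.float32)
            for c in codes:
                sel = lab_k == c
                mu, sd = spec.hu[c]
                hu_k[sel] = rng.normal(mu, sd, size=int(sel.sum())).astype(np.float32)
        data[:, :, k] = hu_k

    cutoff_z = _cutoff_z(spec)
    labrum_z = (spec.labrum_z if spec.labrum_z is not None
                else cutoff_z + spec.inferior_offset_mm)
    medial = np.asarray(spec.y_plane_normal, dtype=float)
    medial = medial / np.linalg.norm(medial)
    if medial[0] <= 0.1:
        raise ValueError("y_plane_normal must point predominantly medial (+x)")
    p0 = np.array([spec.y_plane_x, 0.0, 0.0])
    u = np.cross(medial, [0.0, 0.0, 1.0])
    u /= np.linalg.norm(u)
    v = np.cross(medial, u)
    landmarks = LandmarkSet(
        y_plane_points=np.array([p0, p0 + 35.0 * u, p0 + 25.0 * v]),
        medial_reference=p0 + 60.0 * medial,
        labrum_inferior=np.array([0.0, 0.0, labrum_z]),
        frame="RAS",
    )
    truth: dict = {"sections_cm3": {}, "full_cm3": {}, "hu_mean": {},
                   "overlap_voxels": overlap_voxels, "cutoff_z": cutoff_z}
    for c in codes:
        name = MUSCLE_CODES.get(c, str(c))
        ell = spec.muscles[c]
        bottom = ell.center[2] - ell.half_width(np.array([0.0, 0.0, 1.0]))
        if bottom < cutoff_z - 1e-9:
            raise ValueError(
                f"muscle {c} extends below the inferior cut-off; analytic "
                f"ground truth requires a tangent-or-lower cut-off"
            )
        truth["full_cm3"][name] = ell.volume_mm3 / 1000.0
        truth["hu_mean"][name] = spec.hu[c][0]
        base_level = float(medial @ p0)
        for off, sec in zip(spec.offsets_mm, _section_names(spec.offsets_mm)):
            vol = ellipsoid_halfspace_volume(ell, medial, base_level + off)
            truth["sections_cm3"][(name, sec)] = vol / 1000.0

    return PhantomExam(
        volume=ImageVolume(data, affine),
        labels=MuscleLabelMap(labels, affine),
        landmarks=landmarks,
        ground_truth=truth,
    )


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """A two-muscle phantom with magnitudes loosely echoing shoulder CT:
    full-muscle volumes ~110 and ~95 cm^3, HU means in the high 50s/low 60s,
    2 mm slices on a 15 x 15 x 9 cm field of view."""
    return PhantomSpec(
        muscles={
            1: Ellipsoid(center=(-5.0, -25.0, 4.0), semi_axes=(55.0, 20.0, 24.0)),
            2: Ellipsoid(center=(-5.0, 25.0, 4.0), semi_axes=(52.0, 19.0, 23.0)),
        },
        hu={1: (59.0, 6.0), 2: (62.0, 6.0)},
        y_plane_x=-30.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# longitudinal cohort simulation
# ---------------------------------------------------------------------------

# Baseline (preoperative) distribution of each measurement, keyed by
# (muscle, section, metric): mean and sd across subjects.  Magnitudes echo a
# small adult surgical cohort; the Y+2.5 entries are interpolated.
DEFAULT_BASELINES = {
    ("Ssc", "Y", "volume"): (33.5, 9.5),
    ("Ssc", "Y+2.5", "volume"): (70.0, 14.0),
    ("Ssc", "Y+5", "volume"): (109.2, 18.2),
    ("Isp+TM", "Y", "volume"): (33.9, 11.0),
    ("Isp+TM", "Y+2.5", "volume"): (64.0, 15.0),
    ("Isp+TM", "Y+5", "volume"): (96.0, 18.3),
    ("Ssc", "Y", "mean_hu"): (59.2, 6.1),
    ("Ssc", "Y+2.5", "mean_hu"): (59.1, 5.0),
    ("Ssc", "Y+5", "mean_hu"): (59.1, 4.5),
    ("Isp+TM", "Y", "mean_hu"): (59.0, 6.1),
    ("Isp+TM", "Y+2.5", "mean_hu"): (62.0, 5.5),
    ("Isp+TM", "Y+5", "mean_hu"): (64.8, 5.1),
}


@dataclass(frozen=True)
class TrajectorySpec:
    """Generative parameters of the perioperative drop-and-recover course.

    Per subject, a volume-drop fraction ``delta ~ N(drop_mean, drop_sd)``
    (clipped to [0, drop_max]) takes every volume from V_pre to
    ``V_pre * (1 - delta)`` at 1 month.  Recovery returns
    ``rho6 = six_month_gain * delta`` of baseline by 6 months and
    ``rho = recover_gain * delta`` by 12 months (each plus small noise).
    Because rho grows with delta, Dif.pre.1mo (= -delta * V_pre) and
    Dif.1.12mo (= rho * V_pre) are negatively correlated by construction.
    CT density follows the same mechanism with its own (smaller) drop.

    ``covariate_effects`` maps covariate names to linear effects (in cm^3 per
    coded unit) added to every post-operative volume, i.e. to Dif.pre.1mo and
    Dif.pre.12mo of the volume metrics.  ``obs_noise_frac`` is i.i.d.
    multiplicative observation noise per (subject, timepoint, key).
    """

    drop_mean: float = 0.11
    drop_sd: float = 0.06
    drop_max: float = 0.5
    recover_gain: float = 0.8
    recover_sd: float = 0.03
    six_month_gain: float = 0.95
    six_month_sd: float = 0.02
    hu_drop_mean: float = 0.06
    hu_drop_sd: float = 0.04
    hu_recover_gain: float = 0.95
    obs_noise_frac: float = 0.04
    covariate_effects: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))

    def validate(self) -> None:
        for name in ("drop_sd", "recover_sd", "six_month_sd", "hu_drop_sd",
                     "obs_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.drop_mean <= self.drop_max <= 0.95):
            raise ValueError("need 0 <= drop_mean <= drop_max <= 0.95")


def simulate_covariates(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate table with marginals resembling a young surgical ASI cohort
    (mostly male, high activity, shallow/deep Hill-Sachs, bony Bankart)."""
    age = np.clip(np.round(rng.normal(23.4, 8.7, n_subjects), 1), 15.0, 60.0)
    duration = np.clip(np.round(rng.gamma(0.61, 118.0, n_subjects), 1), 1.0, 400.0)
    df = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n_subjects)],
        "age": age,
        "sex": rng.choice(["male", "female"], n_subjects, p=[0.79, 0.21]),
        "side": rng.choice(["right", "left"], n_subjects, p=[0.42, 0.58]),
        "symptom_duration": duration,
        "activity_level": rng.choice(["high", "low"], n_subjects, p=[0.71, 0.29]),
        "load_shift": np.clip(np.rint(rng.normal(1.8, 0.8, n_subjects)), 0, 3
                              ).astype(int),
        "sulcus": np.clip(np.rint(rng.normal(1.0, 0.8, n_subjects)), 0, 3
                          ).astype(int),
        "hill_sachs": rng.choice(["none", "shallow", "deep"], n_subjects,
                                 p=[1 / 24, 15 / 24, 8 / 24]),
        "bankart": rng.choice(["soft_tissue", "bone"], n_subjects,
                              p=[4 / 24, 20 / 24]),
        "rom_flexion": np.clip(np.round(rng.normal(159.8, 26.8, n_subjects), 0),
                               0.0, 200.0),
        "rom_abduction": np.clip(np.round(rng.normal(155.9, 27.9, n_subjects), 0),
                                 0.0, 200.0),
        "rom_external": np.clip(np.round(rng.normal(54.1, 16.4, n_subjects), 0),
                                0.0, 200.0),
    })
    return df.set_index("subject_id", drop=False)


def _subject_course(traj: TrajectorySpec, rng, n):
    delta = np.clip(rng.normal(traj.drop_mean, traj.drop_sd, n), 0.0, traj.drop_max)
    rho = np.clip(traj.recover_gain * delta + rng.normal(0, traj.recover_sd, n)
                  if traj.recover_sd > 0 else traj.recover_gain * delta, 0.0, None)
    rho6 = np.clip(traj.six_month_gain * delta
                   + (rng.normal(0, traj.six_month_sd, n)
                      if traj.six_month_sd > 0 else 0.0), 0.0, None)
    delta_h = np.clip(rng.normal(traj.hu_drop_mean, traj.hu_drop_sd, n), 0.0, 0.5)
    rho_h = np.clip(traj.hu_recover_gain * delta_h
                    + (rng.normal(0, traj.recover_sd, n)
                       if traj.recover_sd > 0 else 0.0), 0.0, None)
    return delta, rho, rho6, delta_h, rho_h


def _timepoint_factor(metric, tp, delta, rho, rho6, delta_h, rho_h):
    if metric == "volume":
        d, r12, r6 = delta, rho, rho6
    else:
        d, r12, r6 = delta_h, rho_h, np.clip(delta_h, 0.0, None)  # HU: full by 6mo
    return {"pre": np.ones_like(d), "1mo": 1.0 - d,
            "6mo": 1.0 - d + r6, "12mo": 1.0 - d + r12}[tp]


def simulate_cohort(n_subjects: int, traj: TrajectorySpec = TrajectorySpec(),
                    seed: int = 0):
    """Value-level longitudinal cohort (no imaging).

    Returns ``(cohort, covariates, truth)``: a long cohort table with
    volume/mean_hu rows for both muscles and three sections plus vr/ct_dr
    ratio rows, a covariate table, and the generating parameters
    (per-subject delta/rho vectors and the covariate effect vector).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    traj.validate()
    rng = np.random.default_rng(seed)
    covariates = simulate_covariates(n_subjects, rng)
    from .io import encode_covariates

    coded = encode_covariates(covariates)
    effect = np.zeros(n_subjects)
    for name, beta in traj.covariate_effects.items():
        if name not in coded.columns:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        effect += beta * coded[name].to_numpy()

    delta, rho, rho6, delta_h, rho_h = _subject_course(traj, rng, n_subjects)
    subjects = covariates["subject_id"].to_numpy()

    keys = sorted(traj.baselines)
    values: dict = {}
    for (muscle, section, metric) in keys:
        mean, sd = traj.baselines[(muscle, section, metric)]
        base = np.clip(rng.normal(mean, sd, n_subjects), 0.2 * mean, None)
        for tp in TIMEPOINTS:
            f = _timepoint_factor(metric, tp, delta, rho, rho6, delta_h, rho_h)
            v = base * f
            if metric == "volume" and tp != "pre":
                v = v + effect
            if traj.obs_noise_frac > 0:
                v = v * (1.0 + rng.normal(0, traj.obs_noise_frac, n_subjects))
            values[(muscle, section, metric, tp)] = v

    rows = []
    for (muscle, section, metric, tp), v in values.items():
        for i, s in enumerate(subjects):
            rows.append({"subject_id": s, "timepoint": tp, "rater_id": None,
                         "muscle": muscle, "section": section, "metric": metric,
                         "value": float(v[i])})
    sections = sorted({k[1] for k in keys})
    for section in sections:
        for tp in TIMEPOINTS:
            v_ssc = values[("Ssc", section, "volume", tp)]
            v_isp = values[("Isp+TM", section, "volume", tp)]
            h_ssc = values[("Ssc", section, "mean_hu", tp)]
            h_isp = values[("Isp+TM", section, "mean_hu", tp)]
            for i, s in enumerate(subjects):
                rows.append({"subject_id": s, "timepoint": tp, "rater_id": None,
                             "muscle": "Ssc/Isp+TM", "section": section,
                             "metric": "vr", "value": float(v_ssc[i] / v_isp[i])})
                rows.append({"subject_id": s, "timepoint": tp, "rater_id": None,
                             "muscle": "Ssc/Isp+TM", "section": section,
                             "metric": "ct_dr", "value": float(h_ssc[i] / h_isp[i])})
    cohort = pd.DataFrame(rows)
    truth = {"delta": delta, "rho": rho, "rho6": rho6,
             "delta_hu": delta_h, "rho_hu": rho_h,
             "covariate_effects": dict(traj.covariate_effects),
             "subject_effect": effect}
    return cohort, covariates, truth


# ---------------------------------------------------------------------------
# image-level cohort: phantom exam per subject x timepoint
# ---------------------------------------------------------------------------


# volumes at any timepoint are capped at this multiple of baseline, so one
# fixed inferior cut-off per subject stays tangent-or-below all timepoints
_GROWTH_CAP = 1.25


def simulate_imaging_cohort(n_subjects: int,
                            traj: TrajectorySpec = TrajectorySpec(),
                            seed: int = 0,
                            spacing: tuple = (1.5, 1.5, 2.0)):
    """Synthesize one phantom exam per subject x timepoint.

    Each subject gets the default two-ellipsoid anatomy scaled by a random
    overall size; per timepoint the ellipsoid axes shrink/regrow so the
    full-muscle volume follows the subject's drop-and-recover course, and the
    muscle HU means follow the density course.  Landmarks are fixed per
    subject (identical across timepoints), with the inferior cut-off tangent
    to the preoperative (largest) muscles.

    Returns ``(exams, covariates, truth)`` where ``exams`` is a list of dicts
    with keys subject_id/timepoint/volume/labels/landmarks/ground_truth.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    traj.validate()
    rng = np.random.default_rng(seed)
    covariates = simulate_covariates(n_subjects, rng)
    from .io import encode_covariates

    coded = encode_covariates(covariates)
    effect = np.zeros(n_subjects)
    for name, beta in traj.covariate_effects.items():
        effect += beta * coded[name].to_numpy()

    delta, rho, rho6, delta_h, rho_h = _subject_course(traj, rng, n_subjects)
    size_scale = np.clip(rng.normal(1.0, 0.10, n_subjects), 0.7, 1.3)
    hu_base = {1: rng.normal(59.0, 4.0, n_subjects),
               2: rng.normal(62.0, 4.0, n_subjects)}

    base_spec = default_phantom_spec()
    exams = []
    for i, subject in enumerate(covariates["subject_id"]):
        pre_axes = {c: tuple(np.asarray(e.semi_axes) * size_scale[i] ** (1 / 3))
                    for c, e in base_spec.muscles.items()}
        pre_muscles = {c: replace(base_spec.muscles[c], semi_axes=pre_axes[c])
                       for c in pre_axes}
        # cut-off fixed for all of the subject's timepoints, placed below the
        # largest anatomy any timepoint can reach (growth capped at +25%)
        roomy = {c: replace(pre_muscles[c],
                            semi_axes=tuple(np.asarray(pre_axes[c])
                                            * _GROWTH_CAP ** (1 / 3)))
                 for c in pre_muscles}
        labrum_z = (_cutoff_z(replace(base_spec, muscles=roomy))
                    + base_spec.inferior_offset_mm)
        for tp in TIMEPOINTS:
            f_vol = float(_timepoint_factor("volume", tp, delta[i:i + 1],
                                            rho[i:i + 1], rho6[i:i + 1],
                                            delta_h[i:i + 1], rho_h[i:i + 1])[0])
            f_hu = float(_timepoint_factor("mean_hu", tp, delta[i:i + 1],
                                           rho[i:i + 1], rho6[i:i + 1],
                                           delta_h[i:i + 1], rho_h[i:i + 1])[0])
            muscles = {}
            for c in pre_muscles:
                full_pre = pre_muscles[c].volume_mm3 / 1000.0
                target = full_pre * f_vol
                if tp != "pre":
                    target = target + effect[i]
                target = float(np.clip(target, 0.1 * full_pre,
                                       _GROWTH_CAP * full_pre))
                axis_scale = (target / full_pre) ** (1 / 3)
                muscles[c] = replace(
                    pre_muscles[c],
                    semi_axes=tuple(np.asarray(pre_muscles[c].semi_axes)
                                    * axis_scale))
            hu = {c: (float(hu_base[c][i] * f_hu), 6.0) for c in muscles}
            spec = replace(base_spec, muscles=muscles, hu=hu, spacing=spacing,
                           labrum_z=labrum_z,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
            exam = make_phantom_exam(spec)
            exams.append({"subject_id": subject, "timepoint": tp,
                          "volume": exam.volume, "labels": exam.labels,
                          "landmarks": exam.landmarks,
                          "ground_truth": exam.ground_truth})
    truth = {"delta": delta, "rho": rho, "rho6": rho6,
             "delta_hu": delta_h, "rho_hu": rho_h,
             "size_scale": size_scale,
             "covariate_effects": dict(traj.covariate_effects)}
    return exams, covariates, truth


def write_imaging_cohort(out_dir, n_subjects: int,
                         traj: TrajectorySpec = TrajectorySpec(),
                         seed: int = 0,
                         spacing: tuple = (1.5, 1.5, 2.0)):
    """Write a full imaging cohort to disk: per-exam NIfTI pairs + landmark
    JSONs, a manifest CSV, a covariate CSV and a ground-truth JSON.

    Returns ``(manifest_path, covariate_path)`` for direct consumption by the
    measurement pipeline.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exams, covariates, truth = simulate_imaging_cohort(
        n_subjects, traj=traj, seed=seed, spacing=spacing)
    manifest_rows = []
    gt = {}
    for e in exams:
        stem = f"{e['subject_id']}_{e['timepoint']}"
        ct = f"{stem}_ct.nii.gz"
        lab = f"{stem}_labels.nii.gz"
        lmk = f"{stem}_landmarks.json"
        save_exam(e["volume"], e["labels"], e["landmarks"],
                  out / ct, out / lab, out / lmk)
        manifest_rows.append({"subject_id": e["subject_id"],
                              "timepoint": e["timepoint"], "rater_id": "",
                              "ct_path": ct, "label_path": lab,
                              "landmark_path": lmk})
        gt[stem] = {f"{m}|{s}": v
                    for (m, s), v in e["ground_truth"]["sections_cm3"].items()}
    manifest_path = out / "manifest.csv"
    covariate_path = out / "covariates.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    covariates.to_csv(covariate_path, index=False)
    (out / "ground_truth.json").write_text(json.dumps(
        {"sections_cm3": gt,
         "covariate_effects": truth["covariate_effects"]}, indent=1))
    return manifest_path, covariate_path


# ---------------------------------------------------------------------------
# rater simulation
# ---------------------------------------------------------------------------


def simulate_raters(truth_values, sigma_error: float, k: int = 2, seed: int = 0,
                    rater_bias=None) -> np.ndarray:
    """Subjects x raters matrix: latent truth plus i.i.d. N(0, sigma_error^2)
    per cell (plus optional fixed per-rater bias).

    With subject variance sigma_s^2 in ``truth_values`` and no bias, the
    expected ICC(2,1) is sigma_s^2 / (sigma_s^2 + sigma_error^2).
    """
    truth = np.asarray(truth_values, dtype=float)
    if truth.ndim != 1:
        raise ValueError("truth_values must be 1-D (one latent value per subject)")
    if k < 2:
        raise ValueError("need at least 2 raters")
    if sigma_error < 0:
        raise ValueError("sigma_error must be non-negative")
    rng = np.random.default_rng(seed)
    mat = truth[:, None] + rng.normal(0.0, sigma_error, size=(truth.size, k))
    if rater_bias is not None:
        bias = np.asarray(rater_bias, dtype=float)
        if bias.shape != (k,):
            raise ValueError("rater_bias must have one entry per rater")
        mat = mat + bias[None, :]
    return mat
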