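"""Sectional volumes, mean CT densities and force-couple ratios.

Volume is voxel counting: ``volume_cm3 = voxel_count * voxel_volume_mm3 /
1000``.  CT density is the plain arithmetic mean of the HU values over the
sectional mask — no trimming, windowing or weighting (a configurable HU clamp
exists for robustness studies but defaults off).  The transverse-force-couple
balance of one exam is summarised per section by the volume ratio
``VR = volume(Ssc) / volume(Isp+TM)`` and the CT-density ratio
``CT-DR = mean_hu(Ssc) / mean_hu(Isp+TM)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import SectionMask, SectionPlaneSet, build_plane_set, section_mask
from .io import ImageVolume, LandmarkSet, MuscleLabelMap

__all__ = [
    "MeasureConfig",
    "SectionalMeasurement",
    "RatioSet",
    "measure_section",
    "measure_exam",
    "compute_ratios",
    "measurements_to_frame",
    "ratios_to_frame",
]


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable geometry/measurement parameters of the sectional pipeline.

    ``offsets_mm`` are the medial plane offsets defining the cumulative
    sections (0 = Y-view itself); ``inferior_offset_mm`` places the inferior
    cut-off below the labrum landmark; ``hu_clamp`` optionally clips HU values
    to a window before averaging (off by default, matching the raw-mean
    definition of CT density).
    """

    offsets_mm: tuple = (0.0, 25.0, 50.0)
    inferior_offset_mm: float = 30.0
    hu_clamp: Optional[tuple] = None


@dataclass
class SectionalMeasurement:
    """Volume/density of one muscle within one cumulative section."""

    muscle: str
    section: str
    voxel_count: int
    volume_cm3: float
    mean_hu: float  # NaN when the section is empty
    subject_id: Optional[str] = None
    timepoint: Optional[str] = None
    rater_id: Optional[str] = None

    @property
    def hu_defined(self) -> bool:
        return self.voxel_count > 0 and np.isfinite(self.mean_hu)


@dataclass
class RatioSet:
    """Per-section transverse-force-couple ratios Ssc / Isp+TM.

    ``vr``/``ct_dr`` are NaN (flagged missing, never an exception) when the
    Isp+TM denominator is zero or undefined.
    """

    section: str
    vr: float
    ct_dr: float
    subject_id: Optional[str] = None
    timepoint: Optional[str] = None
    rater_id: Optional[str] = None


def measure_section(volume: ImageVolume, mask: SectionMask,
                    hu_clamp: Optional[tuple] = None) -> SectionalMeasurement:
    """Voxel count, volume (cm^3) and mean HU of one sectional mask."""
    if mask.mask.shape != volume.shape:
        raise ValueError(
            f"mask lattice {mask.mask.shape} != volume lattice {volume.shape}"
        )
    count = int(np.count_nonzero(mask.mask))
    vol_cm3 = count * volume.voxel_volume_mm3 / 1000.0
    if count == 0:
        mean_hu = float("nan")
    else:
        hu = np.asarray(volume.data, dtype=np.float64)[mask.mask]
        if hu_clamp is not None:
            hu = np.clip(hu, hu_clamp[0], hu_clamp[1])
        mean_hu = float(hu.mean())
    return SectionalMeasurement(
        muscle=mask.muscle, section=mask.section,
        voxel_count=count, volume_cm3=vol_cm3, mean_hu=mean_hu,
    )


def measure_exam(
    volume: ImageVolume,
    labels: MuscleLabelMap,
    landmarks: LandmarkSet,
    config: MeasureConfig = MeasureConfig(),
    subject_id: Optional[str] = None,
    timepoint: Optional[str] = None,
    rater_id: Optional[str] = None,
) -> list:
    """All sectional measurements of one exam (2 muscles x sections).

    With the default three offsets this yields the six sectional muscle
    models (Y, Y+2.5, Y+5 for each of Ssc and Isp+TM).  Raises when either
    muscle label is absent from the label map.
    """
    volume.validate()
    labels.validate()
    if volume.shape != labels.shape or not np.allclose(
        volume.affine, labels.affine, rtol=1e-4,
        atol=1e-4 * max(1.0, float(np.abs(volume.affine).max())),
    ):
        raise ValueError("volume and label map are not on the same lattice")
    planes = build_plane_set(landmarks, offsets_mm=config.offsets_mm,
                             inferior_offset_mm=config.inferior_offset_mm)
    out = []
    for code in sorted(c for c in labels.code_map if c != 0):
        for section in planes.section_names:
            m = section_mask(labels, code, planes, section)
            rec = measure_section(volume, m, hu_clamp=config.hu_clamp)
            rec.subject_id = subject_id
            rec.timepoint = timepoint
            rec.rater_id = rater_id
            out.append(rec)
    return out


def compute_ratios(measurements: Sequence[SectionalMeasurement]) -> list:
    """Per-section VR and CT-DR from one exam's sectional measurements.

    Expects exactly one Ssc and one Isp+TM record per section.  Zero or
    undefined Isp+TM denominators yield NaN ratios (flagged missing).
    """
    by_section: dict = {}
    for m in measurements:
        by_section.setdefault(m.section, {})[m.muscle] = m
    out = []
    for section, pair in by_section.items():
        if set(pair) != {"Ssc", "Isp+TM"}:
            raise ValueError(
                f"section {section}: need one Ssc and one Isp+TM record, "
                f"got {sorted(pair)}"
            )
        ssc, isp = pair["Ssc"], pair["Isp+TM"]
        vr = ssc.volume_cm3 / isp.volume_cm3 if isp.volume_cm3 > 0 else float("nan")
        if isp.hu_defined and ssc.hu_defined and isp.mean_hu != 0:
            ct_dr = ssc.mean_hu / isp.mean_hu
        else:
            ct_dr = float("nan")
        out.append(RatioSet(
            section=section, vr=vr, ct_dr=ct_dr,
            subject_id=ssc.subject_id, timepoint=ssc.timepoint,
            rater_id=ssc.rater_id,
        ))
    return out


def measurements_to_frame(measurements: Sequence[SectionalMeasurement]) -> pd.DataFrame:
    rows = [{
        "subject_id": m.subject_id, "timepoint": m.timepoint, "rater_id": m.rater_id,
        "muscle": m.muscle, "section": m.section,
        "voxel_count": m.voxel_count, "volume_cm3": m.volume_cm3,
        "mean_hu": m.mean_hu,
    } for m in measurements]
    return pd.DataFrame(rows)


def ratios_to_frame(ratios: Sequence[RatioSet]) -> pd.DataFrame:
    rows = [{
        "subject_id": r.subject_id, "timepoint": r.timepoint, "rater_id": r.rater_id,
        "section": r.section, "vr": r.vr, "ct_dr": r.ct_dr,
    } for r in ratios]
    return pd.DataFrame(rows)
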