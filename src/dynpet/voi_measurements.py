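"""Volume-of-interest measurements and lesion-to-background ratios.

VOIs are spheres of nominal volume (the reference-tissue volumes follow the
reading protocol: aortic-arch blood 1 cm3, L5 bone 2 cm3, cerebellum 2 cm3,
subcutaneous fat 2 cm3, liver 3 cm3, lung 3 cm3, gluteal muscle 2 cm3,
spleen 2 cm3).  Lesion values are maxima over the VOI; liver references are
means; the lesion-to-background ratio (LBR) is lesion max over liver mean.
Voxel coordinates are 0-based in x/y/z order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics_sim import CohortSample
from .patlak_core import PatlakDesign, fit_patlak_many, patlak_design

__all__ = [
    "VOI",
    "TISSUE_VOI_VOLUMES_CM3",
    "realize_voi",
    "voi_stats",
    "lesion_to_background",
    "measure_cohort",
    "measure_tac_cohort",
]

#: nominal sphere volumes (cm^3) per reference tissue
TISSUE_VOI_VOLUMES_CM3: dict[str, float] = {
    "blood": 1.0,
    "bone": 2.0,
    "brain": 2.0,
    "fat": 2.0,
    "liver": 3.0,
    "lung": 3.0,
    "muscle": 2.0,
    "spleen": 2.0,
    "lesion": 1.0,
}

_TAGS = frozenset(TISSUE_VOI_VOLUMES_CM3)


@dataclass(frozen=True)
class VOI:
    """Spherical volume of interest at a voxel-coordinate centre."""

    center: tuple[float, float, float]  # 0-based voxel coordinates, x/y/z
    nominal_volume_cm3: float
    tissue_tag: str = "lesion"

    def __post_init__(self) -> None:
        if self.nominal_volume_cm3 <= 0:
            raise ValueError("nominal volume must be positive")
        if self.tissue_tag not in _TAGS:
            raise ValueError(f"unknown tissue tag {self.tissue_tag!r}")

    @property
    def radius_mm(self) -> float:
        return float((3.0 * self.nominal_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def realize_voi(
    voi: VOI,
    voxel_size: float | tuple[float, float, float],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Voxel index set (N, 3) of the sphere: all voxels whose centres lie
    within the nominal radius; the centre voxel is always included."""
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    center = np.asarray(voi.center, dtype=float)
    cidx = np.rint(center).astype(int)
    if np.any(cidx < 0) or np.any(cidx >= np.asarray(shape)):
        raise ValueError("VOI outside volume bounds")
    r = voi.radius_mm
    half = np.ceil(r / vs).astype(int) + 1
    ranges = [
        np.arange(max(0, cidx[d] - half[d]), min(shape[d], cidx[d] + half[d] + 1))
        for d in range(3)
    ]
    ix, iy, iz = np.meshgrid(*ranges, indexing="ij")
    d2 = (((ix - center[0]) * vs[0]) ** 2
          + ((iy - center[1]) * vs[1]) ** 2
          + ((iz - center[2]) * vs[2]) ** 2)
    mask = d2 <= r**2 + 1e-9
    idx = np.column_stack([ix[mask], iy[mask], iz[mask]])
    if idx.size == 0:
        idx = cidx[None, :]
    return idx


def voi_stats(volume: np.ndarray, voxels: np.ndarray) -> tuple[float, float]:
    """Exact (max, mean) of a 3-D map over a realized voxel set."""
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        raise ValueError("empty voxel set")
    vals = volume[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    return float(vals.max()), float(vals.mean())


def lesion_to_background(lesion_max: float, liver_mean: float) -> float:
    """LBR: lesion maximum divided by the mean in normal liver."""
    if liver_mean <= 0:
        raise ValueError("invalid reference: liver mean must be positive")
    return float(lesion_max) / float(liver_mean)


def measure_cohort(
    ki_map: np.ndarray,
    vd_map: np.ndarray,
    suv_volume: np.ndarray,
    lesion_vois: Sequence[VOI] | Mapping[str, VOI],
    liver_voi: VOI | None,
    voxel_size: float | tuple[float, float, float],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One record per lesion: SUV_max, Ki_max, Vd_max and the three
    liver-normalized LBRs.  Deterministic; requires a liver reference."""
    if liver_voi is None:
        raise ValueError("missing liver reference")
    if isinstance(lesion_vois, Mapping):
        ids = list(lesion_vois.keys())
        vois = list(lesion_vois.values())
    else:
        vois = list(lesion_vois)
        ids = [str(i + 1) for i in range(len(vois))]
    shape = ki_map.shape
    liver_idx = realize_voi(liver_voi, voxel_size, shape)
    _, liver_ki_mean = voi_stats(ki_map, liver_idx)
    _, liver_vd_mean = voi_stats(vd_map, liver_idx)
    _, liver_suv_mean = voi_stats(suv_volume, liver_idx)
    rows = []
    for i, (lid, voi) in enumerate(zip(ids, vois)):
        idx = realize_voi(voi, voxel_size, shape)
        ki_max, _ = voi_stats(ki_map, idx)
        vd_max, _ = voi_stats(vd_map, idx)
        suv_max, _ = voi_stats(suv_volume, idx)
        rows.append({
            "lesion_id": lid,
            "group": groups[i] if groups is not None else "lesion",
            "SUV_max": suv_max,
            "Ki_max": ki_max,
            "Vd_max": vd_max,
            "LBR_suv": lesion_to_background(suv_max, liver_suv_mean),
            "LBR_ki": lesion_to_background(ki_max, liver_ki_mean),
            "LBR_vd": lesion_to_background(vd_max, liver_vd_mean),
            "liver_ki_mean": liver_ki_mean,
            "liver_vd_mean": liver_vd_mean,
            "liver_suv_mean": liver_suv_mean,
        })
    return pd.DataFrame(rows)


def measure_tac_cohort(
    cohort: CohortSample,
    t_star: float = 20.0,
    design: PatlakDesign | None = None,
) -> pd.DataFrame:
    """Lesion records from per-lesion TACs (the cohort path).

    Each lesion TAC and its paired liver TAC are Patlak-fitted against the
    cohort's input function; SUVs come from the static-window concentrations.
    Per-lesion TACs represent the lesion's peak voxel, so the fitted values
    stand in for the VOI maxima; the paired liver fit is the mean reference.
    """
    if design is None:
        design = patlak_design(cohort.cp, cohort.schedule, t_star=t_star)
    idx = design.frame_indices
    les_ki, les_vd, les_r2 = fit_patlak_many(cohort.lesion_tacs[:, idx], design)
    liv_ki, liv_vd, _ = fit_patlak_many(cohort.liver_tacs[:, idx], design)
    spec = cohort.spec
    suv_factor = spec.weight_kg / spec.dose_mbq
    les_suv = cohort.lesion_static * suv_factor
    liv_suv = cohort.liver_static * suv_factor
    records = cohort.records.copy()
    records["SUV_max"] = les_suv
    records["Ki_max"] = les_ki
    records["Vd_max"] = les_vd
    records["r_squared"] = les_r2
    records["liver_suv_mean"] = liv_suv
    records["liver_ki_mean"] = liv_ki
    records["liver_vd_mean"] = liv_vd
    records["LBR_suv"] = [
        lesion_to_background(a, b) for a, b in zip(les_suv, liv_suv)
    ]
    records["LBR_ki"] = [
        lesion_to_background(a, b) for a, b in zip(les_ki, liv_ki)
    ]
    records["LBR_vd"] = [
        lesion_to_background(a, b) for a, b in zip(les_vd, liv_vd)
    ]
    return records
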