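"""File formats, run configuration, and the end-to-end pipeline.

Artifacts: 4D activity and 3D label volumes as NIfTI-1 with a sidecar JSON
carrying the schedule, ground-truth kinetics, and generator parameters;
curves and tables as CSV with units embedded in the headers; configs and
manifests as JSON.  A run is reproducible from its config alone: every
random stream derives from the single config seed, and the manifest echoes
every parameter plus per-stage status and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import cohort_stats, input_function, kinetics_sim, patlak_core, voi_measurements
from .kinetics_sim import (
    AORTA_LABEL,
    DEFAULT_LIVER_KINETICS,
    FIRST_LESION_LABEL,
    LIVER_LABEL,
    CohortSpec,
    DynamicPhantom,
    FrameSchedule,
    InputFunctionParams,
    PartitionModel,
    TissueKinetics,
)

__all__ = [
    "RunConfig",
    "save_phantom",
    "load_phantom",
    "write_input_function",
    "read_input_function",
    "write_lesion_records",
    "read_lesion_records",
    "run_pipeline",
]

# CSV headers carry units to avoid the x1e-2 scale ambiguity of reported Ki
_RECORD_UNITS = {
    "Ki_max": "Ki_max_mL_per_min_per_mL",
    "Vd_max": "Vd_max_mL_per_mL",
    "SUV_max": "SUV_max_g_per_mL",
    "liver_ki_mean": "liver_ki_mean_mL_per_min_per_mL",
    "liver_vd_mean": "liver_vd_mean_mL_per_mL",
    "liver_suv_mean": "liver_suv_mean_g_per_mL",
    "true_ki": "true_ki_mL_per_min_per_mL",
    "true_vd": "true_vd_mL_per_mL",
    "liver_true_ki": "liver_true_ki_mL_per_min_per_mL",
    "liver_true_vd": "liver_true_vd_mL_per_mL",
}


# ---------------------------------------------------------------------------
# NIfTI + sidecar round trip
# ---------------------------------------------------------------------------


def _kinetics_to_dict(kin: TissueKinetics) -> dict:
    return dataclasses.asdict(kin)


def _kinetics_from_dict(d: dict) -> TissueKinetics:
    return TissueKinetics(**d)


def save_phantom(phantom: DynamicPhantom, out_dir: str | Path) -> dict:
    """Write activity + label NIfTI volumes and the sidecar JSON; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.voxel_size) + [1.0])
    act_path = out / "phantom_activity.nii"
    lab_path = out / "phantom_labels.nii"
    side_path = out / "phantom_sidecar.json"
    nib.save(nib.Nifti1Image(phantom.activity, affine), act_path)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), affine), lab_path)
    sidecar = {
        "schedule": {
            "frame_start": phantom.schedule.frame_start.tolist(),
            "frame_duration": phantom.schedule.frame_duration.tolist(),
            "bed_label": list(phantom.schedule.bed_label) if phantom.schedule.bed_label else None,
        },
        "voxel_size_mm": list(phantom.voxel_size),
        "truth": {str(k): _kinetics_to_dict(v) for k, v in phantom.truth.items()},
        "if_params": dataclasses.asdict(phantom.if_params) if phantom.if_params else None,
        "partition": dataclasses.asdict(phantom.partition) if phantom.partition else None,
        "noise_scale": phantom.noise_scale,
        "seed": phantom.seed,
    }
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {"activity": act_path, "labels": lab_path, "sidecar": side_path}


def load_phantom(
    activity_path: str | Path,
    labels_path: str | Path,
    sidecar_path: str | Path,
) -> DynamicPhantom:
    """Reload a phantom; voxel values round-trip bit-exactly (float64 NIfTI)."""
    act_img = nib.load(str(activity_path))
    lab_img = nib.load(str(labels_path))
    side = json.loads(Path(sidecar_path).read_text())
    schedule = FrameSchedule(
        frame_start=np.asarray(side["schedule"]["frame_start"]),
        frame_duration=np.asarray(side["schedule"]["frame_duration"]),
        bed_label=tuple(side["schedule"]["bed_label"]) if side["schedule"]["bed_label"] else None,
    )
    activity = np.asarray(act_img.dataobj, dtype=np.float64)
    if activity.ndim != 4 or activity.shape[3] != schedule.n_frames:
        raise ValueError("volume frame count does not match the sidecar schedule")
    ifp = side.get("if_params")
    part = side.get("partition")
    phantom = DynamicPhantom(
        activity=activity,
        labels=np.asarray(lab_img.dataobj).astype(np.int16),
        truth={int(k): _kinetics_from_dict(v) for k, v in side["truth"].items()},
        schedule=schedule,
        voxel_size=tuple(side["voxel_size_mm"]),
        if_params=InputFunctionParams(**ifp) if ifp else None,
        partition=PartitionModel(**part) if part else None,
        noise_scale=side.get("noise_scale", 0.0),
        seed=side.get("seed"),
    )
    return phantom


def write_input_function(cp: kinetics_sim.PlasmaInputFunction, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "idif.csv"
    pd.DataFrame({"t_min": cp.grid, "Cp_kBq_per_mL": cp.values}).to_csv(csv_path, index=False)
    tail_path = out / "idif_tail_params.json"
    if cp.tail_params is not None:
        a1, l1, a2, l2 = cp.tail_params
        tail_path.write_text(json.dumps(
            {"A1_kBq_per_mL": a1, "lambda1_per_min": l1,
             "A2_kBq_per_mL": a2, "lambda2_per_min": l2}, indent=1))
    return {"csv": csv_path, "tail": tail_path}


def read_input_function(csv_path: str | Path) -> kinetics_sim.PlasmaInputFunction:
    df = pd.read_csv(csv_path)
    return kinetics_sim.PlasmaInputFunction(
        grid=df["t_min"].to_numpy(), values=df["Cp_kBq_per_mL"].to_numpy()
    )


def write_lesion_records(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records.rename(columns=_RECORD_UNITS).to_csv(path, index=False)
    return path


def read_lesion_records(path: str | Path) -> pd.DataFrame:
    inverse = {v: k for k, v in _RECORD_UNITS.items()}
    return pd.read_csv(path).rename(columns=inverse)


def _write_maps(maps: patlak_core.ParametricMaps, suv: patlak_core.SuvImage,
                voxel_size: tuple, out_dir: Path) -> dict:
    affine = np.diag(list(voxel_size) + [1.0])
    paths = {}
    for name, vol, unit in (
        ("ki_map", maps.Ki_map, "mL/min/mL"),
        ("vd_map", maps.Vd_map, "mL/mL"),
        ("qc_map", maps.qc_map, "r_squared"),
        ("suv", suv.volume, "g/mL"),
    ):
        img = nib.Nifti1Image(vol, affine)
        img.header["descrip"] = unit.encode()
        p = out_dir / f"{name}.nii"
        nib.save(img, p)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully serializable description of one reproducible run."""

    seed: int = 0
    out_dir: str = "dynpet_run"
    phantom_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 4.0
    phantom_noise_scale: float = 0.05
    n_early_60s: int = 5
    n_passes: int = 11
    n_beds: int = 5
    sec_per_bed: float = 35.0
    t_star: float = 20.0
    switch_time: float = 10.0
    suv_window: tuple[float, float] | None = None  # default: last 10 min of the scan
    if_params: InputFunctionParams = field(default_factory=InputFunctionParams)
    partition: PartitionModel = field(default_factory=PartitionModel)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "if_params" in kwargs and isinstance(kwargs["if_params"], dict):
            kwargs["if_params"] = InputFunctionParams(**kwargs["if_params"])
        if "partition" in kwargs and isinstance(kwargs["partition"], dict):
            kwargs["partition"] = PartitionModel(**kwargs["partition"])
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            c = dict(kwargs["cohort"])
            if "suv_window" in c and c["suv_window"] is not None:
                c["suv_window"] = tuple(c["suv_window"])
            kwargs["cohort"] = CohortSpec(**c)
        if "phantom_shape" in kwargs:
            kwargs["phantom_shape"] = tuple(kwargs["phantom_shape"])
        if kwargs.get("suv_window") is not None:
            kwargs["suv_window"] = tuple(kwargs["suv_window"])
        return cls(**kwargs)


def _default_truth() -> dict[int, TissueKinetics]:
    return {
        AORTA_LABEL: TissueKinetics.macro(Ki=0.0, Vd=1.0),  # whole-blood pool
        LIVER_LABEL: DEFAULT_LIVER_KINETICS,
        FIRST_LESION_LABEL: TissueKinetics.macro(Ki=0.030, Vd=0.9),
        FIRST_LESION_LABEL + 1: TissueKinetics.macro(Ki=0.020, Vd=0.7),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, write_volumes: bool = True) -> dict:
    """Simulate -> IDIF -> Patlak fit -> measure -> compare, with a manifest.

    Deterministic for a fixed config; the cohort's seed is derived from the
    run seed.  Any stage error is recorded in the manifest (stage name and
    message) and re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    phantom_seed, cohort_seed = (int(s) for s in ss.generate_state(2) % (2**31 - 1))
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }
    results: dict = {}
    stage = "simulate"
    try:
        t0 = time.time()
        schedule = kinetics_sim.make_study_schedule(
            config.n_early_60s, config.n_passes, config.n_beds, config.sec_per_bed
        )
        truth = _default_truth()
        phantom = kinetics_sim.build_phantom(
            config.phantom_shape, config.voxel_size_mm, truth, config.if_params,
            schedule, noise_scale=config.phantom_noise_scale, seed=phantom_seed,
            partition=config.partition,
        )
        cohort_spec = dataclasses.replace(config.cohort, seed=cohort_seed)
        cohort = kinetics_sim.generate_cohort(cohort_spec, if_params=config.if_params)
        results["phantom"] = phantom
        results["cohort"] = cohort
        if write_volumes:
            paths = save_phantom(phantom, out)
            manifest["outputs"].update({k: str(v) for k, v in paths.items()})
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 3)}

        stage = "idif"
        t0 = time.time()
        cp_est, toi = input_function.estimate_input_function(
            phantom, partition=config.partition, switch_time=config.switch_time
        )
        results["cp_est"] = cp_est
        results["toi"] = toi
        paths = write_input_function(cp_est, out)
        manifest["outputs"].update({"idif_csv": str(paths["csv"]), "idif_tail": str(paths["tail"])})
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 3),
                                     "toi_voxels": toi.n_voxels}

        stage = "fit"
        t0 = time.time()
        maps = patlak_core.fit_patlak_map(phantom, cp_est, t_star=config.t_star)
        scan_end = schedule.end_times[-1]
        suv_window = config.suv_window or (max(scan_end - 10.0, 0.0), scan_end)
        suv = patlak_core.static_suv_image(
            phantom, suv_window, dose_mbq=config.cohort.dose_mbq,
            weight_kg=config.cohort.weight_kg,
        )
        results["maps"] = maps
        results["suv"] = suv
        if write_volumes:
            paths = _write_maps(maps, suv, phantom.voxel_size, out)
            manifest["outputs"].update({k: str(v) for k, v in paths.items()})
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 3)}

        stage = "measure"
        t0 = time.time()
        records = voi_measurements.measure_tac_cohort(cohort, t_star=config.t_star)
        results["records"] = records
        rec_path = write_lesion_records(records, out / "lesion_records.csv")
        manifest["outputs"]["lesion_records"] = str(rec_path)
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 3)}

        stage = "compare"
        t0 = time.time()
        summary = cohort_stats.summarize_cohort(records)
        roc = cohort_stats.roc_youden(
            records["Ki_max"].to_numpy(), records["group"].to_numpy() == "cancer"
        )
        summary["roc_ki_max"] = {
            "cutoff": roc.youden_cutoff,
            "sensitivity": roc.sensitivity_at_cutoff,
            "specificity": roc.specificity_at_cutoff,
            "auc": roc.auc,
        }
        results["summary"] = summary
        results["roc"] = roc
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        pd.DataFrame({
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivities,
            "specificity": roc.specificities,
        }).to_csv(out / "roc_ki_max.csv", index=False)
        manifest["outputs"]["summary"] = str(out / "summary.json")
        manifest["outputs"]["roc_csv"] = str(out / "roc_ki_max.csv")
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 3)}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "error", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    manifest["hashes"] = {
        name: _sha256(Path(p))
        for name, p in manifest["outputs"].items()
        if Path(p).suffix in (".csv", ".json")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
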