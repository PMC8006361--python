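"""Disk round-trips: NIfTI volumes, CSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from cmrperf.imagedata import DynamicSeries
from cmrperf.synthetic import SyntheticStudy

__all__ = [
    "write_series_nifti",
    "read_series_nifti",
    "write_rendered_patient",
    "write_ground_truth",
]


def write_series_nifti(series: DynamicSeries, path: str | Path) -> None:
    """One 4D NIfTI per plane (x, y, 1, t) plus a JSON timing sidecar."""
    path = Path(path)
    vol = np.transpose(series.data, (2, 1, 0))[:, :, None, :]  # x, y, z=1, t
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
    sidecar = {
        "frame_times_s": series.frame_times.tolist(),
        "pixel_spacing_mm": series.pixel_spacing,
        "plane_role": series.plane_role,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_series_nifti(path: str | Path) -> DynamicSeries:
    path = Path(path)
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    data = np.transpose(vol[:, :, 0, :], (2, 1, 0)).astype(float)
    return DynamicSeries(
        data,
        np.asarray(meta["frame_times_s"]),
        float(meta["pixel_spacing_mm"]),
        meta.get("plane_role", "myocardium"),
    )


def write_rendered_patient(rendered: dict, out_dir: str | Path) -> None:
    """Rendered planes as NIfTI, geometry and ROIs as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, series in rendered["planes"].items():
        write_series_nifti(series, out / f"{name}.nii")
    sidecar = {
        "phase": rendered["phase"],
        "lv_center_mm": list(rendered["lv_center"]),
        "rois": {
            loc: {"center_mm": list(r.center), "diameter_mm": r.diameter}
            for loc, r in rendered["rois"].items()
        },
        "contours": {
            level: {
                "endo": c.endo.tolist(),
                "epi": c.epi.tolist(),
                "rv_insertion": c.rv_insertion.tolist(),
            }
            for level, c in rendered["contours"].items()
        },
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=1))


def write_ground_truth(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Ground-truth segment table (CSV) and the study configuration (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.ground_truth.to_csv(out / "ground_truth_segments.csv", index=False)
    cfg = study.config
    (out / "study_config.json").write_text(
        json.dumps(
            {
                "n_patients": cfg.n_patients,
                "segments_per_patient": cfg.segments_per_patient,
                "abnormal_prevalence": cfg.abnormal_prevalence,
                "seed": cfg.seed,
                "rr_interval_s": cfg.rr_interval_s,
                "n_frames": cfg.n_frames,
            },
            indent=1,
        )
    )
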