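"""Disk formats: NIfTI beta volumes, CSV manifests, trait tables.

A cohort is written either as one 4D NIfTI per subject (volumes ordered
run-major: run 1 conditions 1..10, run 2 conditions 1..10, ...) with a
JSON sidecar manifest, or as a single compressed array with a CSV
manifest. Voxel patterns are laid out on a caller-supplied 3D grid shape.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import VoxelPatternSet


def save_pattern_set_nifti(
    patterns: VoxelPatternSet,
    grid_shape: tuple[int, int, int],
    out_dir: str | Path,
    voxel_size: float = 2.0,
) -> Path:
    """Write a subject's betas as a 4D NIfTI plus a JSON sidecar manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_vox = int(np.prod(grid_shape))
    if patterns.n_voxels != n_vox:
        raise ValueError("grid shape does not match the voxel count")
    n_runs, n_cond, _ = patterns.betas.shape
    vols = patterns.betas.reshape(n_runs * n_cond, *grid_shape)
    img = nib.Nifti1Image(
        np.moveaxis(vols, 0, -1).astype(np.float32), np.diag([voxel_size] * 3 + [1.0])
    )
    base = out_dir / f"{patterns.subject}_betas"
    nib.save(img, str(base.with_suffix(".nii")))
    manifest = {
        "subject": patterns.subject,
        "group": patterns.group,
        "conditions": list(patterns.conditions),
        "n_runs": n_runs,
        "grid_shape": list(grid_shape),
        "volume_order": "run-major",
        "voxel_size_mm": voxel_size,
    }
    base.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return base.with_suffix(".nii")


def load_pattern_set_nifti(nifti_path: str | Path) -> VoxelPatternSet:
    """Read a subject written by :func:`save_pattern_set_nifti`."""
    nifti_path = Path(nifti_path)
    manifest = json.loads(nifti_path.with_suffix(".json").read_text())
    data = np.asarray(nib.load(str(nifti_path)).dataobj, dtype=float)
    vols = np.moveaxis(data, -1, 0)
    n_runs = manifest["n_runs"]
    n_cond = len(manifest["conditions"])
    betas = vols.reshape(n_runs, n_cond, -1)
    return VoxelPatternSet(
        subject=manifest["subject"],
        group=manifest["group"],
        betas=betas,
        conditions=tuple(manifest["conditions"]),
    )


def save_cohort_array(
    cohort: list[VoxelPatternSet], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a whole cohort as one .npz plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr_path = out_dir / "betas.npz"
    np.savez_compressed(
        arr_path, **{p.subject: p.betas for p in cohort}
    )
    manifest = pd.DataFrame(
        {
            "subject": [p.subject for p in cohort],
            "group": [p.group for p in cohort],
            "n_runs": [p.n_runs for p in cohort],
            "n_voxels": [p.n_voxels for p in cohort],
            "conditions": ["|".join(p.conditions) for p in cohort],
        }
    )
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return arr_path, manifest_path


def load_cohort_array(out_dir: str | Path) -> list[VoxelPatternSet]:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    with np.load(out_dir / "betas.npz") as arrs:
        return [
            VoxelPatternSet(
                subject=row.subject,
                group=row.group,
                betas=arrs[row.subject],
                conditions=tuple(row.conditions.split("|")),
            )
            for row in manifest.itertuples()
        ]
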