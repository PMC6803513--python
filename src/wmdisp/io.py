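"""Readers and writers: score CSVs, NIfTI volumes, study folders."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import LabelVolume, read_label_volume
from .voxelwise import SkeletonDataset, SkeletonMask, make_mask

logger = logging.getLogger(__name__)

METRICS = ("FA", "MD")


def read_scores(path) -> pd.DataFrame:
    """Read a score table CSV; requires participant_id and age columns."""
    df = pd.read_csv(path)
    for col in ("participant_id", "age"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["participant_id"] = df["participant_id"].astype(str)
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"{path}: duplicate participant ids {dupes}")
    age = df["age"].to_numpy(dtype=float)
    if not np.all(np.isfinite(age)) or np.any(age <= 0):
        raise ValueError(f"{path}: ages must be finite and positive")
    return df


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def _check_geometry(path, data, affine, ref_shape, ref_affine) -> None:
    if data.shape != ref_shape:
        raise ValueError(
            f"{path}: shape {data.shape} does not match reference {ref_shape}"
        )
    if not np.allclose(affine, ref_affine):
        raise ValueError(f"{path}: affine does not match the reference volume")


def read_study(
    study_dir,
    metrics: tuple[str, ...] = METRICS,
    fa_threshold: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, SkeletonDataset], LabelVolume, SkeletonMask]:
    """Load a study folder: scores, skeleton datasets per metric, atlas, mask.

    Expects ``scores.csv``, ``mean_fa.nii.gz``, ``atlas.nii.gz`` +
    ``atlas_labels.csv`` and ``subjects/<participant_id>_<METRIC>.nii.gz``.
    Subjects present in the score table but missing any metric volume are
    dropped with a logged count; zero matched subjects is an error.  All
    volumes must share the mean-FA shape and affine exactly.
    """
    study = Path(study_dir)
    scores = read_scores(study / "scores.csv")
    mean_fa, affine = load_volume(study / "mean_fa.nii.gz")
    mask = make_mask(mean_fa, threshold=fa_threshold, affine=affine)
    atlas = read_label_volume(study / "atlas.nii.gz", study / "atlas_labels.csv")
    _check_geometry("atlas.nii.gz", atlas.data, atlas.affine, mean_fa.shape, affine)

    subj_dir = study / "subjects"
    matched, dropped = [], []
    for sid in scores["participant_id"]:
        if all((subj_dir / f"{sid}_{m}.nii.gz").exists() for m in metrics):
            matched.append(sid)
        else:
            dropped.append(sid)
    if dropped:
        logger.warning(
            "dropped %d subject(s) without complete imaging: %s",
            len(dropped), dropped,
        )
    if not matched:
        raise ValueError(f"{study}: no subjects with complete imaging data")
    scores = scores[scores["participant_id"].isin(matched)].reset_index(drop=True)

    datasets: dict[str, SkeletonDataset] = {}
    for metric in metrics:
        rows = np.empty((len(matched), mask.n_voxels))
        for i, sid in enumerate(matched):
            path = subj_dir / f"{sid}_{metric}.nii.gz"
            data, aff = load_volume(path)
            _check_geometry(path.name, data, aff, mean_fa.shape, affine)
            rows[i] = data[mask.data]
        datasets[metric] = SkeletonDataset(metric, rows, mask, list(matched))
    return scores, datasets, atlas, mask
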