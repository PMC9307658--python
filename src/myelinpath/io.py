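"""Standard-format I/O for trial tables, skeleton data, and results.

Trial tables are tab-separated with a fixed mandatory header (subject,
trial_type, condition, rt_ms, correct, mep_mv, precontraction_mv); unknown
columns are preserved on read and ignored by the analysis. Skeleton data can
be written either as one 4-D NIfTI per modality plus a binary mask defining
the voxel index, or as a packed ``.npz`` container with a JSON sidecar naming
modalities and voxel coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .config import MODALITIES, GeneratorConfig, PipelineConfig
from .datasets import SkeletonDataset

logger = logging.getLogger("myelinpath")

MANDATORY_COLUMNS = (
    "subject",
    "trial_type",
    "condition",
    "rt_ms",
    "correct",
    "mep_mv",
    "precontraction_mv",
)

NUMERIC_COLUMNS = ("rt_ms", "mep_mv", "precontraction_mv")


class TrialTableError(ValueError):
    pass


def write_trial_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial-table TSV, validating header and numeric fields."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    extra = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path.name, extra)
    for col in NUMERIC_COLUMNS:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TrialTableError(
                f"{path.name}: non-numeric value {raw[bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = parsed
    df["correct"] = df["correct"].astype(str).str.lower().isin(["true", "1", "1.0", "yes"])
    return df


def write_cohort_tables(trial_tables: dict[str, pd.DataFrame], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        write_trial_table(table, directory / f"{sid}_trials.tsv")
        for sid, table in trial_tables.items()
    ]


def read_cohort_tables(directory) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    tables = {}
    for path in sorted(directory.glob("*_trials.tsv")):
        df = read_trial_table(path)
        tables[str(df["subject"].iloc[0])] = df
    if not tables:
        raise FileNotFoundError(f"no *_trials.tsv files under {directory}")
    return tables


# ---------------------------------------------------------------- skeleton

def write_skeleton_npz(skeleton: SkeletonDataset, path) -> Path:
    """Packed array container + JSON sidecar naming modalities and voxels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, values=skeleton.values)
    sidecar = {
        "modality_names": list(skeleton.modality_names),
        "subject_ids": list(skeleton.subject_ids),
        "voxel_index": np.asarray(skeleton.voxel_index).tolist(),
        "voxel_coords": (
            np.asarray(skeleton.voxel_coords).tolist()
            if skeleton.voxel_coords is not None
            else None
        ),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_skeleton_npz(path) -> SkeletonDataset:
    path = Path(path)
    with np.load(path) as npz:
        values = npz["values"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    coords = sidecar.get("voxel_coords")
    return SkeletonDataset(
        values=values,
        modality_names=tuple(sidecar["modality_names"]),
        subject_ids=list(sidecar["subject_ids"]),
        voxel_index=np.asarray(sidecar["voxel_index"]),
        voxel_coords=np.asarray(coords) if coords is not None else None,
    )


def _grid_shape(coords: np.ndarray) -> tuple[int, int, int]:
    return tuple(int(m) + 1 for m in coords.max(axis=0))


def write_skeleton_nifti(skeleton: SkeletonDataset, directory) -> dict[str, Path]:
    """One 4-D NIfTI per modality (x, y, z, subject) plus a binary mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coords = np.asarray(skeleton.voxel_coords)
    if coords is None or coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("skeleton needs 3-D voxel coordinates for NIfTI export")
    shape = _grid_shape(coords)
    affine = np.eye(4)
    paths: dict[str, Path] = {}
    mask = np.zeros(shape, dtype=np.uint8)
    mask[tuple(coords.T)] = 1
    mask_path = directory / "skeleton_mask.nii.gz"
    nib.save(nib.Nifti1Image(mask, affine), mask_path)
    paths["mask"] = mask_path
    for k, name in enumerate(skeleton.modality_names):
        vol = np.zeros(shape + (skeleton.n_subjects,), dtype=np.float32)
        vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = skeleton.values[:, :, k].T
        p = directory / f"{name}_skeletonised.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), p)
        paths[name] = p
    (directory / "subjects.json").write_text(
        json.dumps(list(skeleton.subject_ids), indent=1)
    )
    return paths


def read_skeleton_nifti(directory, modality_names=MODALITIES) -> SkeletonDataset:
    directory = Path(directory)
    mask = np.asarray(
        nib.load(directory / "skeleton_mask.nii.gz").dataobj, dtype=np.uint8
    )
    coords = np.column_stack(np.nonzero(mask))
    # fixed voxel order: lexicographic in (x, y, z), matching write order
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    coords = coords[order]
    mats = []
    for name in modality_names:
        vol = np.asarray(
            nib.load(directory / f"{name}_skeletonised.nii.gz").dataobj, dtype=float
        )
        mats.append(vol[coords[:, 0], coords[:, 1], coords[:, 2], :].T)
    values = np.stack(mats, axis=2)
    subjects_file = directory / "subjects.json"
    subject_ids = (
        json.loads(subjects_file.read_text()) if subjects_file.exists() else None
    )
    return SkeletonDataset(
        values=values,
        modality_names=tuple(modality_names),
        subject_ids=subject_ids,
        voxel_coords=coords,
    )


def write_stat_map(values: np.ndarray, coords: np.ndarray, path) -> Path:
    """Write a per-voxel statistic back onto the input grid as NIfTI."""
    coords = np.asarray(coords)
    vol = np.zeros(_grid_shape(coords), dtype=np.float32)
    vol[tuple(coords.T)] = values
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), path)
    return path


# ------------------------------------------------------------------ misc

def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n")
    return path


def write_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)
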