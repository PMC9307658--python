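"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MODALITIES


@dataclass
class SkeletonDataset:
    """Skeletonized voxel data: ``values[subject, voxel, modality]``.

    ``voxel_index`` holds integer voxel ids; ``voxel_coords`` optionally embeds
    the same voxels on a 3-D grid (used when writing volumetric files).
    """

    values: np.ndarray
    modality_names: tuple[str, ...] = MODALITIES
    voxel_index: np.ndarray | None = None
    subject_ids: list[str] | None = None
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be (n_subjects, n_voxels, n_modalities), got shape {self.values.shape}"
            )
        n, v, k = self.values.shape
        if k != len(self.modality_names):
            raise ValueError(
                f"values has {k} modalities but {len(self.modality_names)} names were given"
            )
        if self.voxel_index is None:
            self.voxel_index = np.arange(v)
        else:
            self.voxel_index = np.asarray(self.voxel_index)
            if len(self.voxel_index) != v:
                raise ValueError("voxel_index length does not match n_voxels")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
        elif len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match n_subjects")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def n_modalities(self) -> int:
        return self.values.shape[2]


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort, kept for validation of the pipeline.

    ``structural`` holds the latent-scale mediation variables (columns
    pp_sp, m1_inhibition, rt_cost before the positive-ratio link);
    ``true_subject_ratios`` the noiseless observable ratios; ``trial_flags``
    the contamination kind drawn for every trial ('clean' otherwise).
    """

    latent_myelin: np.ndarray
    signal_mask: np.ndarray
    true_paths: dict[str, float]
    structural: pd.DataFrame
    true_subject_ratios: pd.DataFrame
    trial_flags: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Cohort:
    """A complete simulated dataset: trial tables, skeleton maps and truth."""

    trial_tables: dict[str, pd.DataFrame]
    skeleton: SkeletonDataset
    truth: GroundTruth
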