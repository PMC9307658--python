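"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a latent
per-subject myelin factor expressed in a contiguous block of skeleton voxels
across four myelin-sensitive modalities (MT, R1, R2*, FA), and paired-pulse
TMS physiology and behaviour generated under a serial two-mediator structural
model (myelin -> switch PP/SP ratio -> switch M1 inhibition -> switch RT
cost, plus a direct path). Trial-level MEP amplitudes are lognormal around
the subject's condition median so that median-based ratio metrics recover the
subject-level truth; reaction times are Gaussian around the condition mean.

Contamination kinds (premature, slow, incorrect response; precontraction;
out-of-range MEP amplitude) are assigned disjointly by a single categorical
draw per trial and recorded in the ground truth, so filter recall and
precision can be measured exactly. Trials drawn as clean have their MEPs and
reaction times truncated into the acceptance windows, which leaves condition
medians untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CONTAMINATION_KINDS, MODALITIES, GeneratorConfig
from .datasets import Cohort, GroundTruth, SkeletonDataset

TRIAL_COLUMNS = (
    "subject",
    "trial_type",
    "condition",
    "rt_ms",
    "correct",
    "mep_mv",
    "precontraction_mv",
)

_METRIC_NAMES = ("pp_sp", "m1_inhibition", "rt_cost")


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def implied_covariance(config: GeneratorConfig) -> np.ndarray:
    """Closed-form covariance of (latent myelin, m1, m2, y) under the model.

    The structural equations are linear with independent Gaussian residuals,
    so the covariance follows directly from the path coefficients and
    residual variances.
    """
    a, d21, b2, c = (
        config.path_a,
        config.path_d21,
        config.path_b2,
        config.path_c_direct,
    )
    s1, s2, s3 = config.structural_noise_sd
    cov = np.zeros((4, 4))
    cov[0, 0] = 1.0                                   # var(x)
    cov[1, 1] = a**2 + s1**2                          # var(m1)
    cov[0, 1] = a
    cov[2, 2] = d21**2 * cov[1, 1] + s2**2            # var(m2)
    cov[0, 2] = d21 * cov[0, 1]
    cov[1, 2] = d21 * cov[1, 1]
    cov[3, 3] = (
        b2**2 * cov[2, 2] + c**2 + 2 * b2 * c * cov[0, 2] + s3**2
    )                                                 # var(y)
    cov[0, 3] = b2 * cov[0, 2] + c
    cov[1, 3] = b2 * cov[1, 2] + c * cov[0, 1]
    cov[2, 3] = b2 * cov[2, 2] + c * cov[0, 2]
    cov += np.triu(cov, 1).T
    return cov


def implied_correlation(config: GeneratorConfig) -> np.ndarray:
    cov = implied_covariance(config)
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


def _structural_sample(config: GeneratorConfig, rng: np.random.Generator):
    """Draw latent myelin and the three latent-scale metric variables."""
    n = config.n_subjects
    s1, s2, s3 = config.structural_noise_sd
    x = rng.standard_normal(n)
    m1 = config.path_a * x + s1 * rng.standard_normal(n)
    m2 = config.path_d21 * m1 + s2 * rng.standard_normal(n)
    y = (
        config.path_b2 * m2
        + config.path_c_direct * x
        + s3 * rng.standard_normal(n)
    )
    return x, np.column_stack([m1, m2, y])


def _ratios_from_structural(config: GeneratorConfig, structural: np.ndarray) -> np.ndarray:
    """Map latent metric variables to strictly positive observable ratios."""
    cov = implied_covariance(config)
    sd = np.sqrt(np.diag(cov))[1:]
    z = structural / sd
    bases = np.asarray(config.ratio_bases)
    scales = np.asarray(config.ratio_scales)
    return bases * np.exp(scales * z)


def generate_skeleton_maps(latent_myelin, config: GeneratorConfig, seed=None) -> SkeletonDataset:
    """Simulate skeletonized voxel maps for the four myelin markers.

    In signal voxels (a contiguous block at the start of the voxel index) the
    value is ``loading_k * latent_myelin + noise``; elsewhere pure noise.
    """
    latent_myelin = np.asarray(latent_myelin, dtype=float)
    if latent_myelin.ndim != 1 or len(latent_myelin) != config.n_subjects:
        raise ValueError(
            f"latent_myelin must have length n_subjects={config.n_subjects}, "
            f"got shape {latent_myelin.shape}"
        )
    rng = np.random.default_rng(_as_seed_sequence(config.seed if seed is None else seed))
    n, v, k = config.n_subjects, config.n_voxels, len(MODALITIES)
    n_signal = int(round(config.signal_fraction * v))
    loadings = np.asarray(config.modality_loadings)
    noise_sd = np.asarray(config.modality_noise_sd)

    values = rng.standard_normal((n, v, k)) * noise_sd
    values[:, :n_signal, :] += latent_myelin[:, None, None] * loadings

    # compact 3-D embedding: voxels filled into the smallest enclosing cube
    side = int(np.ceil(v ** (1.0 / 3.0)))
    coords = np.column_stack(np.unravel_index(np.arange(v), (side, side, side)))
    return SkeletonDataset(values=values, modality_names=MODALITIES, voxel_coords=coords)


def signal_mask(config: GeneratorConfig) -> np.ndarray:
    mask = np.zeros(config.n_voxels, dtype=bool)
    mask[: int(round(config.signal_fraction * config.n_voxels))] = True
    return mask


def generate_trial_table(subject_truth, config: GeneratorConfig, seed=None):
    """Simulate one subject's stimulated-trial table.

    ``subject_truth`` is a mapping with keys ``subject`` and the three ratios
    ``pp_sp``, ``m1_inhibition``, ``rt_cost`` (one row of
    ``GroundTruth.true_subject_ratios``). Returns ``(table, flags)`` where
    ``flags`` records the contamination kind per trial ('clean' otherwise).
    """
    if config.trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    rng = np.random.default_rng(_as_seed_sequence(config.seed if seed is None else seed))
    t = config.trials_per_condition
    subject = subject_truth["subject"]

    # condition medians implied by the subject's true ratios
    sp_stay = config.mep_base_mv
    sp_switch = sp_stay * subject_truth["m1_inhibition"]
    pp_switch = sp_switch * subject_truth["pp_sp"]
    pp_stay = sp_stay * config.pp_stay_ratio
    mep_median = {
        ("stay", "SP"): sp_stay,
        ("switch", "SP"): sp_switch,
        ("stay", "PP"): pp_stay,
        ("switch", "PP"): pp_switch,
    }
    rt_mean = {
        "stay": config.stay_rt_ms,
        "switch": config.stay_rt_ms * subject_truth["rt_cost"],
    }

    conditions = [("stay", "SP"), ("switch", "SP"), ("stay", "PP"), ("switch", "PP")]
    trial_type = np.repeat([c[0] for c in conditions], t)
    condition = np.repeat([c[1] for c in conditions], t)
    n_trials = 4 * t

    medians = np.array([mep_median[(tt, c)] for tt, c in zip(trial_type, condition)])
    means = np.array([rt_mean[tt] for tt in trial_type])

    # clean draws, truncated into the acceptance windows (medians unchanged)
    mep = medians * np.exp(config.mep_noise * rng.standard_normal(n_trials))
    mep = np.clip(mep, 0.25, 8.5)
    rt = means + config.rt_noise_ms * rng.standard_normal(n_trials)
    rt = np.clip(rt, 160.0, 790.0)
    correct = np.ones(n_trials, dtype=bool)
    precontraction = rng.uniform(0.0, 0.2, n_trials)

    # disjoint contamination: one categorical draw per trial
    rates = [config.contamination_rates[k] for k in CONTAMINATION_KINDS]
    probs = np.array([1.0 - sum(rates)] + rates)
    draw = rng.choice(len(probs), size=n_trials, p=probs)
    flags = np.array(["clean"] + list(CONTAMINATION_KINDS), dtype=object)[draw]

    premature = flags == "premature"
    rt[premature] = rng.uniform(50.0, 140.0, premature.sum())
    slow = flags == "slow"
    rt[slow] = rng.uniform(810.0, 1500.0, slow.sum())
    correct[flags == "incorrect"] = False
    pre = flags == "precontraction"
    precontraction[pre] = rng.uniform(0.45, 1.2, pre.sum())
    extreme = flags == "extreme_amplitude"
    n_ex = extreme.sum()
    small = rng.random(n_ex) < 0.5
    ex_vals = np.where(
        small, rng.uniform(0.01, 0.15, n_ex), rng.uniform(9.5, 12.0, n_ex)
    )
    mep[extreme] = ex_vals

    order = rng.permutation(n_trials)
    table = pd.DataFrame(
        {
            "subject": subject,
            "trial_type": trial_type,
            "condition": condition,
            "rt_ms": np.round(rt, 3),
            "correct": correct,
            "mep_mv": np.round(mep, 5),
            "precontraction_mv": np.round(precontraction, 5),
        }
    ).iloc[order].reset_index(drop=True)
    return table, np.asarray(flags[order], dtype=object)


def generate_cohort(config: GeneratorConfig, seed=None, with_trials: bool = True) -> Cohort:
    """Generate a full synthetic cohort: trial tables, skeleton maps, truth.

    ``with_trials=False`` skips the per-subject trial tables (subject-level
    structural variables, ratios and skeleton maps only), which is much
    faster for large-n calibration checks.
    """
    ss = _as_seed_sequence(config.seed if seed is None else seed)
    s_struct, s_skel, s_trials = ss.spawn(3)
    rng = np.random.default_rng(s_struct)

    latent, structural = _structural_sample(config, rng)
    ratios = _ratios_from_structural(config, structural)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(config.n_subjects)]
    truth_ratios = pd.DataFrame(
        ratios, columns=["pp_sp", "m1_inhibition", "rt_cost"], index=subject_ids
    )
    truth_ratios.insert(0, "subject", subject_ids)

    skeleton = generate_skeleton_maps(latent, config, seed=s_skel)
    skeleton.subject_ids = subject_ids

    trial_tables: dict[str, pd.DataFrame] = {}
    trial_flags: dict[str, np.ndarray] = {}
    if with_trials:
        for sid, child in zip(subject_ids, s_trials.spawn(config.n_subjects)):
            table, flags = generate_trial_table(truth_ratios.loc[sid], config, seed=child)
            trial_tables[sid] = table
            trial_flags[sid] = flags

    truth = GroundTruth(
        latent_myelin=latent,
        signal_mask=signal_mask(config),
        true_paths={
            "a": config.path_a,
            "d21": config.path_d21,
            "b2": config.path_b2,
            "c_direct": config.path_c_direct,
        },
        structural=pd.DataFrame(structural, columns=_METRIC_NAMES, index=subject_ids),
        true_subject_ratios=truth_ratios,
        trial_flags=trial_flags,
    )
    return Cohort(trial_tables=trial_tables, skeleton=skeleton, truth=truth)
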