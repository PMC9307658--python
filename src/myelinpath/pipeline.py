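"""End-to-end orchestration: preprocess -> joint inference -> composite -> mediation.

Stage order follows the analysis logic: trial-level filtering and subject
metrics first; voxelwise joint inference with the switch PP/SP ratio as
regressor; PCA composite over the significant voxels; serial two-mediator
mediation (composite -> PP/SP ratio -> M1 inhibition -> RT cost). One master
seed deterministically spawns per-stage seeds, all recorded in the run
report, so a report's configuration reproduces every output byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composite import extract_composite
from .config import PipelineConfig
from .datasets import Cohort, SkeletonDataset
from .inference import (
    JointInference,
    compare_dependent_correlations,
    significant_clusters,
    spearman_correlation,
)
from .io import (
    write_cohort_tables,
    write_config,
    write_json,
    write_skeleton_npz,
    write_stat_map,
)
from .mediation import SerialMediation, path_diagram
from .mep import cohort_physiology, physiology_frame, wilcoxon_switch_vs_stay
from .simulate import generate_cohort

logger = logging.getLogger("myelinpath")


class AlignmentError(ValueError):
    pass


class NoIncludedSubjectsError(ValueError):
    pass


def _stage_seeds(master_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(4)
    names = ("simulate", "inference", "mediation", "reserved")
    return {name: int(s) for name, s in zip(names, state)}


def align_subjects(skeleton: SkeletonDataset, physiology: pd.DataFrame):
    """Subset skeleton and physiology to included subjects, aligned by ID."""
    phys = physiology.loc[physiology["included"]].set_index("subject")
    skel_ids = list(skeleton.subject_ids)
    missing_in_skel = [s for s in phys.index if s not in skel_ids]
    if missing_in_skel:
        raise AlignmentError(
            f"subjects present in trial data but absent from skeleton data: {missing_in_skel}"
        )
    if len(phys) == 0:
        raise NoIncludedSubjectsError(
            "zero included subjects after the fewer-than-nine-MEPs exclusion"
        )
    keep = [i for i, s in enumerate(skel_ids) if s in phys.index]
    ordered_ids = [skel_ids[i] for i in keep]
    sub = SkeletonDataset(
        values=skeleton.values[keep],
        modality_names=skeleton.modality_names,
        subject_ids=ordered_ids,
        voxel_index=skeleton.voxel_index,
        voxel_coords=skeleton.voxel_coords,
    )
    return sub, phys.loc[ordered_ids].reset_index()


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    output_dir=None,
    write_nifti: bool = False,
) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    seeds = _stage_seeds(config.seed)
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        cohort = generate_cohort(config.generator, seed=seeds["simulate"])
    report: dict = {
        "software": {"name": "myelinpath", "version": __version__},
        "config": config.to_dict(),
        "seeds": seeds,
    }

    # ---- stage 1: trial filtering and subject metrics
    phys_list, filter_reports = cohort_physiology(
        cohort.trial_tables,
        thresholds=config.thresholds,
        grubbs_alpha=config.grubbs_alpha,
        min_count=config.min_meps_per_condition,
    )
    physiology = physiology_frame(phys_list)
    n_included = int(physiology["included"].sum())
    if n_included == 0:
        raise NoIncludedSubjectsError(
            "every subject was excluded during preprocessing; "
            "check trial counts and filter thresholds"
        )
    logger.info(
        "preprocess: %d subjects in, %d included", len(physiology), n_included
    )
    report["preprocess"] = {
        "n_subjects": len(physiology),
        "n_included": n_included,
        "filter_counts_total": {
            k: int(sum(r.counts.get(k, 0) for r in filter_reports.values()))
            for k in next(iter(filter_reports.values())).counts
        },
        "metrics_summary": {
            col: {
                "mean": float(physiology.loc[physiology["included"], col].mean()),
                "sd": float(physiology.loc[physiology["included"], col].std()),
            }
            for col in (
                "switch_pp_sp_ratio",
                "switch_m1_inhibition",
                "switch_rt_cost",
            )
        },
    }
    physiology.to_csv(out / "physiology.tsv", sep="\t", index=False)
    write_json({k: r.to_dict() for k, r in filter_reports.items()}, out / "filter_reports.json")

    est, ci, pval = wilcoxon_switch_vs_stay(phys_list)
    report["wilcoxon_switch_vs_stay"] = {
        "median_difference": est,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p": pval,
    }

    # ---- stage 2: voxelwise joint inference (regressor = switch PP/SP ratio)
    skel, phys = align_subjects(cohort.skeleton, physiology)
    regressor = phys["switch_pp_sp_ratio"].to_numpy(dtype=float)
    ji = JointInference(
        n_permutations=config.n_permutations,
        direction=config.direction,
        alpha=config.alpha,
        transform_voxels=config.transform_voxels,
        random_state=seeds["inference"],
    ).fit(skel, regressor)
    clusters = significant_clusters(ji.significant_mask_)
    peak = int(np.argmax(ji.fisher_stat_))
    logger.info(
        "inference: %d/%d voxels significant (peak FWE p = %.4g)",
        int(ji.significant_mask_.sum()),
        skel.n_voxels,
        float(ji.fwe_p_[peak]),
    )
    report["inference"] = {
        "n_subjects": skel.n_subjects,
        "n_voxels": skel.n_voxels,
        "n_permutations": config.n_permutations,
        "direction": config.direction,
        "peak_fisher_stat": float(ji.fisher_stat_[peak]),
        "peak_fwe_p": float(ji.fwe_p_[peak]),
        "n_significant_voxels": int(ji.significant_mask_.sum()),
        "n_clusters": len(clusters),
        "seed": seeds["inference"],
    }
    np.savez_compressed(
        out / "inference_maps.npz",
        fisher_stat=ji.fisher_stat_,
        fwe_p=ji.fwe_p_,
        combined_p=ji.combined_p_,
        modality_p=ji.modality_p_,
        significant_mask=ji.significant_mask_,
    )
    if write_nifti and skel.voxel_coords is not None:
        write_stat_map(ji.fwe_p_, skel.voxel_coords, out / "fwe_p.nii.gz")
        write_stat_map(
            ji.significant_mask_.astype(float), skel.voxel_coords, out / "significant_mask.nii.gz"
        )

    if not ji.significant_mask_.any():
        report["composite"] = None
        report["mediation"] = None
        report["status"] = "no-significant-mask"
        write_json(report, out / "report.json")
        logger.warning("empty significant mask; mediation skipped")
        return report

    # ---- stage 3: composite + correlations
    comp = extract_composite(skel, ji.significant_mask_)
    m1 = phys["switch_pp_sp_ratio"].to_numpy(dtype=float)
    m2 = phys["switch_m1_inhibition"].to_numpy(dtype=float)
    y = phys["switch_rt_cost"].to_numpy(dtype=float)
    x = comp.scores
    rho_x_m1, p_x_m1 = spearman_correlation(x, m1)
    rho_m1_m2, p_m1_m2 = spearman_correlation(m1, m2)
    rho_m2_y, p_m2_y = spearman_correlation(m2, y)
    n = len(x)

    def _r(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    cmp_m1_m2 = compare_dependent_correlations(_r(x, m1), _r(x, m2), _r(m1, m2), n)
    cmp_m1_y = compare_dependent_correlations(_r(x, m1), _r(x, y), _r(m1, y), n)
    report["composite"] = {
        "variance_explained": comp.variance_explained,
        "loadings": {
            name: float(l) for name, l in zip(comp.modality_names, comp.loadings)
        },
        "mask_size": comp.mask_size,
        "spearman": {
            "composite_vs_pp_sp": {"rho": rho_x_m1, "p": p_x_m1},
            "pp_sp_vs_m1_inhibition": {"rho": rho_m1_m2, "p": p_m1_m2},
            "m1_inhibition_vs_rt_cost": {"rho": rho_m2_y, "p": p_m2_y},
        },
        "correlation_comparisons": {
            "pp_sp_vs_m1_inhibition": {"z": cmp_m1_m2.z, "p": cmp_m1_m2.p},
            "pp_sp_vs_rt_cost": {"z": cmp_m1_y.z, "p": cmp_m1_y.p},
        },
    }

    # ---- stage 4: serial mediation
    med = (
        SerialMediation(
            standardize=config.standardize,
            n_boot=config.n_boot,
            ci_method=config.ci_method,
            random_state=seeds["mediation"],
        )
        .fit(np.column_stack([x, m1, m2]), y)
        .result()
    )
    report["mediation"] = med.to_dict()
    (out / "path_diagram.txt").write_text(path_diagram(med) + "\n")
    report["status"] = "complete"
    write_json(report, out / "report.json")
    write_config(config, out / "config.yaml")
    return report


def simulate_to_disk(config: PipelineConfig, output_dir, write_nifti: bool = False) -> Cohort:
    """Generate a cohort and write trial tables, skeleton and ground truth."""
    seeds = _stage_seeds(config.seed)
    cohort = generate_cohort(config.generator, seed=seeds["simulate"])
    out = Path(output_dir)
    write_cohort_tables(cohort.trial_tables, out / "trials")
    write_skeleton_npz(cohort.skeleton, out / "skeleton.npz")
    if write_nifti:
        from .io import write_skeleton_nifti

        write_skeleton_nifti(cohort.skeleton, out / "nifti")
    write_json(
        {
            "latent_myelin": cohort.truth.latent_myelin,
            "signal_mask": cohort.truth.signal_mask,
            "true_paths": cohort.truth.true_paths,
            "true_subject_ratios": cohort.truth.true_subject_ratios.drop(
                columns="subject"
            ).to_dict(orient="index"),
        },
        out / "ground_truth.json",
    )
    return cohort
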