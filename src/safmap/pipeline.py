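"""End-to-end pipeline: simulate -> parcellate -> track -> assign -> connect -> stats.

The default configuration is the package's validation study: a synthetic
folded cortex with three area bands, per-hemisphere planted U-fibre
tractograms dominated by retinotopic connections, isotropic null
tractography (10 repeats per hemisphere) restricted to the white-matter
mask, and element-wise Poisson and paired t-tests of the planted counts
against the per-hemisphere null means.  Every stage is also usable on its
own; ``tractogram_source='odf'`` replaces the planted tractograms with
probabilistic ODF tractography of a field carrying the planted bundles.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import io as sio
from .assignment import CorticalRibbon, assign_tractogram
from .connectivity import (
    AREA_PAIRS,
    block_percent_contributions,
    build_count_matrix,
    closeness_matrix,
    group_average,
    inter_area_block,
    overall_retinotopic_ratio,
    percent_matrix,
    retinotopic_ratio,
)
from .retinotopy import (
    AREA_NAMES,
    segment_subareas,
    smooth_phase_map,
)
from .significance import (
    block_pattern,
    inter_area_pattern,
    null_mean_matrix,
    paired_t_test,
    poisson_test,
    sensitivity_specificity,
    significance_mask,
)
from .synthetic import (
    cortical_seed_mask,
    make_area_labels,
    make_mesh,
    make_odf_field,
    make_planted_tractogram,
    make_retinotopy,
)
from .tracking import TrackingParams, track_null, track_odf

__all__ = ["PipelineConfig", "run_pipeline"]


def _derive_seed(*keys: int) -> int:
    """Deterministic child seed (< 2**31) from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """All tunable parameters of the validation pipeline.

    Defaults follow the analysis conventions: SNR threshold 5, 4 smoothing
    iterations, 0.2 mm steps with a 30 degree curvature threshold, amplitude
    threshold 0.1, retained lengths 3-120 mm, 4x4x4 seeds per voxel, the
    80 % intracortical filter, 10 null repeats per hemisphere and alpha 0.05.
    """

    seed: int = 0
    n_hemispheres: int = 6
    # synthetic cortex
    n_rows: int = 24
    n_cols: int = 45
    fold_amplitude: float = 2.5
    spacing: float = 1.0
    fold_wavelength: float = 10.0
    thickness: float = 2.0
    # retinotopy
    noise_sd: float = 2.0
    low_snr_fraction: float = 0.1
    snr_threshold: float = 5.0
    smoothing_iterations: int = 4
    # planted tractogram (per hemisphere)
    n_retinotopic: int = 600
    n_nonretinotopic: int = 6
    n_intra: int = 10
    tractogram_source: str = "planted"  # or 'odf'
    # tracking / null tractography
    voxel_size: float = 1.0
    step_size: float = 0.2
    max_angle: float = 30.0
    amplitude_threshold: float = 0.1
    min_length: float = 3.0
    max_length: float = 120.0
    seeds_per_voxel_axis: int = 4
    null_repeats: int = 10
    null_seed_max_voxels: int = 24
    odf_seed_max_voxels: int = 40
    # assignment
    endpoint_tolerance: float = 2.0
    max_intracortical: float = 0.8
    # statistics
    alpha: float = 0.05

    def tracking_params(self, rng_seed: int) -> TrackingParams:
        return TrackingParams(
            step_size=self.step_size,
            max_angle=self.max_angle,
            amplitude_threshold=self.amplitude_threshold,
            min_length=self.min_length,
            max_length=self.max_length,
            seeds_per_voxel_axis=self.seeds_per_voxel_axis,
            rng_seed=rng_seed,
        )


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full pipeline and return the result bundle.

    The bundle holds the synthetic inputs, per-hemisphere count/percent/
    closeness matrices, null mean matrices, planted-truth recovery, the
    group-averaged matrices with per-block retinotopic ratios, and the
    Poisson/t-test significance results.  When ``out_dir`` is given, all
    artefacts (mesh, maps, parcellation, per-hemisphere matrices, group
    matrices, statistics, provenance) are written there.
    """
    t0 = time.time()
    timings: dict[str, float] = {}

    # --- simulate geometry and retinotopy -------------------------------
    mesh = make_mesh(
        config.n_rows,
        config.n_cols,
        config.fold_amplitude,
        _derive_seed(config.seed, 1),
        spacing=config.spacing,
        fold_wavelength=config.fold_wavelength,
    )
    labels = make_area_labels(mesh)
    retinotopy = make_retinotopy(
        mesh,
        labels,
        config.noise_sd,
        config.low_snr_fraction,
        _derive_seed(config.seed, 2),
        snr_threshold=config.snr_threshold,
    )
    timings["simulate"] = time.time() - t0

    # --- parcellate ------------------------------------------------------
    t1 = time.time()
    ecc_s = smooth_phase_map(
        mesh,
        retinotopy.eccentricity,
        retinotopy.snr,
        snr_threshold=config.snr_threshold,
        iterations=config.smoothing_iterations,
        circular=False,
    )
    pol_s = smooth_phase_map(
        mesh,
        retinotopy.polar_angle,
        retinotopy.snr,
        snr_threshold=config.snr_threshold,
        iterations=config.smoothing_iterations,
        circular=True,
    )
    smoothed = type(retinotopy)(
        eccentricity=np.maximum(ecc_s, 0.0), polar_angle=pol_s, snr=retinotopy.snr
    )
    parcellation = segment_subareas(
        mesh, labels, smoothed, snr_threshold=config.snr_threshold
    )
    ribbon = CorticalRibbon(inner=mesh, thickness=config.thickness)
    timings["parcellate"] = time.time() - t1

    # --- ODF field and masks (shared across hemispheres) -----------------
    t2 = time.time()
    bundles = [(6 * a + k, 6 * b + k) for a, b in AREA_PAIRS for k in range(6)]
    field = make_odf_field(
        mesh,
        bundles,
        config.voxel_size,
        _derive_seed(config.seed, 3),
        parcellation=parcellation,
        thickness=config.thickness,
        amplitude_threshold=config.amplitude_threshold,
    )
    null_seed_mask = cortical_seed_mask(
        field,
        mesh,
        thickness=config.thickness,
        max_voxels=config.null_seed_max_voxels,
        seed=_derive_seed(config.seed, 4),
    )
    timings["odf_field"] = time.time() - t2

    # --- per-hemisphere tracking, assignment, counting -------------------
    t3 = time.time()
    hemispheres = []
    for h in range(config.n_hemispheres):
        if config.tractogram_source == "planted":
            tractogram, truth = make_planted_tractogram(
                parcellation,
                mesh,
                config.n_retinotopic,
                config.n_nonretinotopic,
                config.n_intra,
                _derive_seed(config.seed, 10, h),
                thickness=config.thickness,
                step=config.step_size,
            )
        elif config.tractogram_source == "odf":
            odf_seed_mask = cortical_seed_mask(
                field,
                mesh,
                thickness=config.thickness,
                max_voxels=config.odf_seed_max_voxels,
                seed=_derive_seed(config.seed, 11, h),
            )
            tractogram = track_odf(
                field, odf_seed_mask, config.tracking_params(_derive_seed(config.seed, 12, h))
            )
            truth = None
        else:
            raise ValueError(f"unknown tractogram_source {config.tractogram_source!r}")

        assignments = assign_tractogram(
            tractogram,
            ribbon,
            parcellation,
            tolerance=config.endpoint_tolerance,
            max_intracortical=config.max_intracortical,
        )
        if len(assignments) != len(tractogram):
            raise RuntimeError("streamline conservation violated in assignment")
        counts = build_count_matrix(assignments)
        percent = percent_matrix(counts)
        closeness = closeness_matrix(assignments)

        nulls = track_null(
            field.wm_mask,
            field.affine,
            null_seed_mask,
            config.tracking_params(_derive_seed(config.seed, 13, h)),
            repeats=config.null_repeats,
        )
        null_counts = []
        for tg in nulls:
            null_assignments = assign_tractogram(
                tg,
                ribbon,
                parcellation,
                tolerance=config.endpoint_tolerance,
                max_intracortical=config.max_intracortical,
            )
            null_counts.append(build_count_matrix(null_assignments))
        null_mean = null_mean_matrix(null_counts)

        recovery = None
        if truth is not None:
            ok = sum(
                1
                for a, p in zip(assignments, truth.pairs)
                if a.accepted and tuple(a.subarea_pair) == tuple(p)
            )
            recovery = ok / len(truth.pairs) if truth.pairs else 1.0

        hemispheres.append(
            {
                "counts": counts,
                "percent": percent,
                "closeness": closeness,
                "null_mean": null_mean,
                "assignments": assignments,
                "truth": truth,
                "recovery": recovery,
                "n_streamlines": len(tractogram),
            }
        )
    timings["track_assign_connect"] = time.time() - t3

    # --- group averaging and retinotopic order ---------------------------
    t4 = time.time()
    group_percent = group_average([h["percent"] for h in hemispheres])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        group_closeness = np.nanmean(
            np.stack([h["closeness"] for h in hemispheres]), axis=0
        )
    ratios = {}
    for a, b in AREA_PAIRS:
        ret, nonret, ratio = retinotopic_ratio(inter_area_block(group_percent, a, b))
        ratios[f"{AREA_NAMES[a]}-{AREA_NAMES[b]}"] = {
            "retinotopic_percent": ret,
            "nonretinotopic_percent": nonret,
            "ratio": ratio,
        }
    o_ret, o_nonret, o_ratio = overall_retinotopic_ratio(group_percent)
    ratios["overall"] = {
        "retinotopic_percent": o_ret,
        "nonretinotopic_percent": o_nonret,
        "ratio": o_ratio,
    }
    contributions = block_percent_contributions(group_percent)
    timings["group"] = time.time() - t4

    # --- significance -----------------------------------------------------
    t5 = time.time()
    counts_list = [h["counts"] for h in hemispheres]
    nulls_list = [h["null_mean"] for h in hemispheres]
    p_poisson = poisson_test(counts_list, nulls_list)
    mask_poisson = significance_mask(p_poisson, config.alpha)
    stats: dict = {"poisson": {"p": p_poisson, "mask": mask_poisson}}
    if config.n_hemispheres >= 2:
        p_t = paired_t_test(counts_list, nulls_list)
        stats["ttest"] = {"p": p_t, "mask": significance_mask(p_t, config.alpha)}
    for name, entry in stats.items():
        sens, spec = sensitivity_specificity(entry["mask"], inter_area_pattern())
        entry["sensitivity"] = sens
        entry["specificity"] = spec
        entry["blocks"] = {}
        for a, b in AREA_PAIRS:
            bsens, bspec = sensitivity_specificity(
                inter_area_block(entry["mask"], a, b), block_pattern()
            )
            entry["blocks"][f"{AREA_NAMES[a]}-{AREA_NAMES[b]}"] = {
                "sensitivity": bsens,
                "specificity": bspec,
            }
    timings["stats"] = time.time() - t5
    timings["total"] = time.time() - t0

    result = {
        "config": asdict(config),
        "mesh": mesh,
        "labels": labels,
        "retinotopy": retinotopy,
        "smoothed": smoothed,
        "parcellation": parcellation,
        "field": field,
        "hemispheres": hemispheres,
        "group_percent": group_percent,
        "group_closeness": group_closeness,
        "ratios": ratios,
        "contributions": contributions,
        "stats": stats,
        "recovery": (
            float(np.mean([h["recovery"] for h in hemispheres]))
            if hemispheres and hemispheres[0]["recovery"] is not None
            else None
        ),
        "timings": timings,
    }
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _summary_dict(result: dict) -> dict:
    """JSON-serialisable summary of a pipeline result bundle."""
    out = {
        "config": result["config"],
        "ratios": result["ratios"],
        "contributions": result["contributions"],
        "recovery": result["recovery"],
        "timings": result["timings"],
        "group_percent_uppertriangle_sum": float(
            np.triu(result["group_percent"], k=1).sum()
        ),
        "stats": {},
    }
    for name, entry in result["stats"].items():
        out["stats"][name] = {
            "sensitivity": entry["sensitivity"],
            "specificity": entry["specificity"],
            "blocks": entry["blocks"],
        }
    return out


def _write_bundle(result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.write_mesh_ply(result["mesh"], out_dir / "mesh.ply")
    sio.write_area_labels(result["labels"], out_dir / "labels.csv")
    r = result["retinotopy"]
    sio.write_vertex_scalars(r.eccentricity, out_dir / "eccentricity.csv", "eccentricity_deg")
    sio.write_vertex_scalars(r.polar_angle, out_dir / "polar_angle.csv", "polar_angle_deg")
    sio.write_vertex_scalars(r.snr, out_dir / "snr.csv", "snr")
    sio.write_parcellation(
        result["parcellation"], out_dir / "parcellation.csv", out_dir / "parcellation.json"
    )
    sio.write_volume(result["field"].wm_mask, result["field"].affine, out_dir / "wm_mask.nii.gz")
    for h, hemi in enumerate(result["hemispheres"]):
        sio.write_matrix(hemi["counts"], out_dir / f"counts_h{h:02d}.csv")
        sio.write_matrix(hemi["null_mean"], out_dir / f"null_mean_h{h:02d}.csv")
    sio.write_matrix(result["group_percent"], out_dir / "group_percent.csv")
    sio.write_matrix(result["group_closeness"], out_dir / "group_closeness.csv")
    for name, entry in result["stats"].items():
        sio.write_matrix(entry["p"], out_dir / f"p_{name}.csv")
        sio.write_matrix(entry["mask"].astype(int), out_dir / f"mask_{name}.csv")
    sio.write_json(_summary_dict(result), out_dir / "summary.json")
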