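"""End-to-end orchestration: preprocess -> JIERP -> statistics ->
cross-correlation -> starNNMF -> population clustering.

:func:`run_pipeline` executes the stages in the canonical order on either
supplied recordings or freshly simulated subjects, writes each stage's
container plus a JSON provenance record (package and library versions,
seeds, parameters, exclusion counts) into an output directory, and returns
the in-memory results bundle. Every randomized stage derives its seed from
the config seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, clustering, core, factorization, io, preprocess, simulate
from .config import PipelineConfig
from .similarity import crosscorr_spearman, fdr_offdiagonal
from .stats import bin_ttest

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    jierps: list
    z_jierps: list
    grand: core.JierpTensor
    grand_z: core.ZJierp
    statmap: object
    crosscorr: object
    population_nmf: factorization.StarNMF
    subject_factorizations: list
    pooled: clustering.PooledFactors | None
    cluster_solution: clustering.ClusterSolution | None
    representatives: dict | None
    provenance: dict = field(default_factory=dict)


def _simulate_subjects(cfg: PipelineConfig) -> list:
    recs = []
    template = simulate.erp_template()
    for s in range(cfg.n_subjects):
        train = simulate.generate_train(
            cfg.n_events,
            interval_range_ms=cfg.interval_range_ms,
            distribution=cfg.interval_distribution,
            seed=cfg.seed * 1000 + s,
            finger=cfg.finger,
        )
        recs.append(
            simulate.synthesize_recording(
                train,
                template=template,
                spec=cfg.preset,
                n_channels=cfg.n_channels,
                noise_sd=cfg.noise_sd_uv,
                seed=cfg.seed * 1000 + 500 + s,
            )
        )
    return recs


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all stages; see the module docstring."""
    if cfg.input_paths:
        recordings = [
            io.read_recording(p, e)
            for p, e in zip(
                cfg.input_paths,
                cfg.events_paths or [None] * len(cfg.input_paths),
            )
        ]
    else:
        recordings = _simulate_subjects(cfg)

    filters = (
        (
            preprocess.FilterSpec(0.1, 75.0),
            preprocess.FilterSpec(cfg.filter_low_hz, cfg.filter_high_hz),
        )
        if cfg.two_stage_filter
        else (preprocess.FilterSpec(cfg.filter_low_hz, cfg.filter_high_hz),)
    )
    grid = core.BinGrid(tuple(cfg.edges_s))
    jierps, z_jierps, counts = [], [], []
    for rec in recordings:
        epochs = preprocess.preprocess_pipeline(
            rec,
            filters=filters,
            epoch_window_ms=tuple(cfg.epoch_window_ms),
            reject_uv=cfg.reject_uv,
            baseline_ms=tuple(cfg.baseline_ms),
            apply_filter=cfg.apply_filter,
        )
        channel = preprocess.select_channel(
            epochs,
            latency_window_ms=tuple(cfg.select_window_ms),
            roi=list(cfg.roi) if cfg.roi else None,
            criterion=cfg.select_criterion,
        )
        triads = core.compute_triads(rec.events)
        jierp = core.build_jierp(
            epochs, triads, grid, min_trials=cfg.min_trials, channel=channel
        )
        jierps.append(jierp)
        z_jierps.append(core.zscore_latencywise(jierp))
        counts.append(jierp.meta)

    grand = core.grand_average(jierps, min_subject_fraction=cfg.min_subject_fraction)
    grand_z = core.zscore_latencywise(grand, source="grand-average")

    statmap = bin_ttest(z_jierps, alpha=cfg.alpha, method=cfg.fdr_method)

    # Cross-correlation and NNMF consider post-stimulus latencies only.
    post = _post_stimulus(grand_z)
    ccm = fdr_offdiagonal(
        crosscorr_spearman(post),
        alpha=cfg.alpha,
        band_halfwidth_ms=cfg.band_halfwidth_ms,
    )

    pop_matrix = factorization.magnitude_transform(grand)
    pop_nmf = factorization.StarNMF(
        rank="cv",
        rank_range=tuple(cfg.rank_range),
        n_reps=cfg.n_reps,
        random_state=cfg.seed + 17,
    ).fit(pop_matrix.M)

    subject_facts, bin_lists = [], []
    for s, jierp in enumerate(jierps):
        mat = factorization.magnitude_transform(jierp)
        est = factorization.StarNMF(
            rank=pop_nmf.rank_,
            n_reps=cfg.n_reps,
            random_state=cfg.seed + 100 + s,
        ).fit(mat.M)
        subject_facts.append(est.factorization_)
        bin_lists.append(mat.bins)

    pooled = solution = reps = None
    n_points = sum(f.rank for f in subject_facts)
    if n_points > cfg.k_range[0]:
        pooled = clustering.pool_factors(subject_facts, bin_lists=bin_lists)
        try:
            solution = clustering.cluster_metatimes(
                pooled.meta_times,
                k_range=tuple(cfg.k_range),
                n_restarts=cfg.n_restarts,
                seed=cfg.seed + 23,
            )
            reps = clustering.cluster_representatives(solution, pooled)
        except ValueError as exc:
            logger.warning("population clustering skipped: %s", exc)

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "n_subjects": len(recordings),
        "per_subject_counts": [
            {k: v for k, v in m.items() if isinstance(v, (int, str))} for m in counts
        ],
        "population_rank": int(pop_nmf.rank_),
        "population_stability": pop_nmf.stability_score_,
        "n_significant_cells": int(statmap.fdr_mask.sum()),
        "selected_k": None if solution is None else int(solution.k),
    }
    result = PipelineResult(
        config=cfg,
        jierps=jierps,
        z_jierps=z_jierps,
        grand=grand,
        grand_z=grand_z,
        statmap=statmap,
        crosscorr=ccm,
        population_nmf=pop_nmf,
        subject_factorizations=subject_facts,
        pooled=pooled,
        cluster_solution=solution,
        representatives=reps,
        provenance=provenance,
    )
    if cfg.out_dir:
        _write_bundle(result, Path(cfg.out_dir))
    return result


def _post_stimulus(zj: core.ZJierp) -> core.ZJierp:
    tmask = zj.time_ms >= 1
    return core.ZJierp(
        z=zj.z[:, :, tmask],
        valid=zj.valid,
        time_ms=zj.time_ms[tmask],
        source=zj.source,
        degenerate_latencies=zj.degenerate_latencies[tmask],
        meta=zj.meta,
    )


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    import h5py

    out_dir.mkdir(parents=True, exist_ok=True)
    h = result.config.config_hash
    for s, jierp in enumerate(result.jierps):
        io.write_jierp(jierp, out_dir / f"jierp_sub{s:02d}.h5", config_hash=h)
    io.write_jierp(result.grand, out_dir / "jierp_grand.h5", config_hash=h)
    with h5py.File(out_dir / "stats.h5", "w") as f:
        f.create_dataset("stats/t", data=result.statmap.t)
        f.create_dataset("stats/p", data=result.statmap.p)
        f.create_dataset("stats/fdr_mask", data=result.statmap.fdr_mask)
        f.create_dataset("xcorr/rho", data=result.crosscorr.rho)
        f.create_dataset("xcorr/p", data=result.crosscorr.p)
        f.create_dataset("xcorr/fdr_mask", data=result.crosscorr.fdr_mask)
        f.attrs["config_hash"] = h
    with h5py.File(out_dir / "nnmf.h5", "w") as f:
        f.create_dataset("nnmf/W", data=result.population_nmf.basis_)
        f.create_dataset("nnmf/H", data=result.population_nmf.components_)
        f.create_dataset("nnmf/rank", data=result.population_nmf.rank_)
        sel = result.population_nmf.rank_selection_
        if sel is not None:
            f.create_dataset("nnmf/error_curve", data=sel.cv_error)
            f.create_dataset("nnmf/ranks", data=sel.ranks)
        if result.population_nmf.stability_score_ is not None:
            f.create_dataset(
                "nnmf/stability", data=result.population_nmf.stability_score_
            )
        f.attrs["config_hash"] = h
    if result.cluster_solution is not None:
        with h5py.File(out_dir / "clusters.h5", "w") as f:
            f.create_dataset(
                "clusters/assignments", data=result.cluster_solution.assignments
            )
            f.create_dataset(
                "clusters/silhouette", data=result.cluster_solution.silhouette_values
            )
            for c, rep in result.representatives.items():
                f.create_dataset(
                    f"clusters/representatives/{c}/meta_time", data=rep["meta_time"]
                )
                f.create_dataset(
                    f"clusters/representatives/{c}/meta_jierp", data=rep["meta_jierp"]
                )
            f.attrs["config_hash"] = h
    with open(out_dir / "provenance.json", "w") as f:
        json.dump(result.provenance, f, indent=2, default=str)
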