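"""End-to-end experiment orchestrators on synthetic recipes.

`run_experiment1` mirrors the resting-state/MMN workflow: identify
microstates on eyes-open rest at the group level, back-fit them to all
conditions, and run the condition contrasts, alpha-change correlation,
parcel permutation test and event-locked statistics.  `run_experiment2`
mirrors the simultaneous EEG-MEG workflow: identify microstates per
modality, then test label co-occurrence and GEV correlations.

Every run is fully determined by its seed; each bundle carries the seed and
configuration used.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import cluster, crossmodal, fit, stats_evoked, stats_rest, synth
from .io import PipelineConfig

__all__ = ["run_experiment1", "run_experiment2"]


def _fit_metrics(rec, group_ms, cfg):
    seg = fit.backfit(rec, group_ms, cfg.threshold)
    seg = fit.smooth_labels(seg, rec, group_ms, cfg.half_window, cfg.besag_lambda)
    return seg, fit.temporal_metrics(seg)


def run_experiment1(
    config: PipelineConfig | None = None,
    n_subjects: int = 5,
    n_channels: int = 32,
    K: int = 6,
    duration_s: float = 60.0,
    snr: float = 10.0,
    include_rce: bool = True,
    n_std: int = 120,
    n_dev: int = 12,
    k_grid=None,
    n_restarts: int = 10,
    n_perm_parcel: int | None = None,
    seed: int = 0,
) -> dict:
    """Synthetic-recipe version of the resting-state + MMN experiment.

    Returns a results bundle (dict) with the group microstate set, temporal
    metrics per condition, coverage contrasts, alpha/coverage correlations,
    the parcel permutation grid, and event-locked statistics.  Missing RCE
    (``include_rce=False``) skips the contrasts and flags them.
    """
    cfg = config or PipelineConfig()
    rng_seed = int(seed)
    layout = synth.make_layout(n_channels, seed=rng_seed)
    maps = synth.make_topographies(K, layout, cfg.mode, seed=rng_seed + 1)
    k_grid = list(k_grid) if k_grid is not None else [k for k in cfg.k_grid]

    roe, rce, mmn_data = [], [], []
    for s in range(n_subjects):
        rec, gt = synth.simulate_resting(
            layout, maps, duration_s, cfg.target_fs, snr=snr,
            mode=cfg.mode, seed=rng_seed + 10 + s, condition="ROE",
        )
        roe.append((rec, gt))
        if include_rce:
            w = np.full(K, 1.0)
            w[: min(2, K)] = 2.0  # eyes-closed prevalence shift toward states 1-2
            rec_c, gt_c = synth.simulate_resting(
                layout, maps, duration_s, cfg.target_fs, snr=snr,
                coverage_weights=w, mode=cfg.mode,
                seed=rng_seed + 200 + s, condition="RCE",
            )
            rce.append((rec_c, gt_c))
        ev = synth.simulate_evoked(
            layout, maps, n_std=n_std, n_dev=n_dev, deviant_state=min(6, K),
            fs=cfg.target_fs, snr=snr, mode=cfg.mode, seed=rng_seed + 400 + s,
        )
        mmn_data.append(ev)

    group_ms, subject_results = cluster.two_level_clustering(
        [r for r, _ in roe], cfg.mode, k_grid=k_grid,
        n_restarts=n_restarts, seed=rng_seed,
    )

    bundle: dict = {
        "seed": rng_seed,
        "config": dataclasses.asdict(cfg),
        "group_k": group_ms.k,
        "group_maps": group_ms.maps,
        "subject_k": [r.k for r in subject_results],
    }

    metrics = {"ROE": [], "RCE": [], "MMN": []}
    segs = {"ROE": [], "RCE": [], "MMN": []}
    for s in range(n_subjects):
        seg, met = _fit_metrics(roe[s][0], group_ms, cfg)
        segs["ROE"].append(seg)
        metrics["ROE"].append(met)
        if include_rce:
            seg_c, met_c = _fit_metrics(rce[s][0], group_ms, cfg)
            segs["RCE"].append(seg_c)
            metrics["RCE"].append(met_c)
        seg_m, met_m = _fit_metrics(mmn_data[s][0], group_ms, cfg)
        segs["MMN"].append(seg_m)
        metrics["MMN"].append(met_m)
    bundle["metrics"] = metrics

    cov_roe = np.array([m.coverage for m in metrics["ROE"]])
    cov_mmn = np.array([m.coverage for m in metrics["MMN"]])
    bundle["contrast_roe_mmn"] = stats_rest.coverage_contrast(
        cov_mmn, cov_roe, cfg.alpha
    )
    if include_rce:
        cov_rce = np.array([m.coverage for m in metrics["RCE"]])
        bundle["contrast_roe_rce"] = stats_rest.coverage_contrast(
            cov_rce, cov_roe, cfg.alpha
        )
        occ = cfg.occipital_channels or list(range(min(6, n_channels)))
        alpha_idx = [
            stats_rest.alpha_change_index(roe[s][0], rce[s][0], occ).index
            for s in range(n_subjects)
        ]
        bundle["alpha_change_index"] = np.array(alpha_idx)
        bundle["contrast_roe_rce_skipped"] = False
    else:
        bundle["contrast_roe_rce"] = None
        bundle["contrast_roe_rce_skipped"] = True

    # parcel-network permutation on the first subject's resting segmentation
    n_parcels = cfg.n_parcels
    names = synth.schaefer_parcel_names()[:n_parcels]
    parcels = synth.simulate_parcels(
        segs["ROE"][0].labels, n_parcels, fs=cfg.target_fs,
        parcel_names=names, seed=rng_seed + 900,
    )
    bundle["parcel_permutation"] = stats_rest.parcel_permutation_test(
        parcels, segs["ROE"][0],
        n_perm=n_perm_parcel or cfg.n_perm_parcel,
        z_crit=cfg.z_crit, seed=rng_seed + 901,
    )

    # event-locked detection statistics, pooled over subjects
    curves_std, curves_dev, mmn_stats = [], [], []
    for s in range(n_subjects):
        _, events, _ = mmn_data[s]
        std_sel = events.subset(events.std_preceding_deviant)
        dev_sel = events.subset(np.asarray(events.types) == "deviant")
        c_std = stats_evoked.detection_rate_curve(
            segs["MMN"][s], std_sel, "standard", cfg.epoch_ms
        )
        c_dev = stats_evoked.detection_rate_curve(
            segs["MMN"][s], dev_sel, "deviant", cfg.epoch_ms
        )
        curves_std.append(c_std)
        curves_dev.append(c_dev)
        mmn_stats.append(stats_evoked.mms_mmn(c_std, c_dev, cfg.mmn_window_ms))
    bundle["detection_curves"] = {"standard": curves_std, "deviant": curves_dev}
    bundle["mms_mmn"] = np.array(mmn_stats)
    return bundle


def run_experiment2(
    config: PipelineConfig | None = None,
    n_subjects: int = 5,
    n_channels: int = 32,
    K_meg: int = 4,
    K_eeg: int = 4,
    duration_s: float = 60.0,
    snr: float = 10.0,
    coupling: float = 0.0,
    k_grid=None,
    n_restarts: int = 10,
    n_perm: int | None = None,
    seed: int = 0,
) -> dict:
    """Synthetic-recipe version of the simultaneous EEG-MEG experiment.

    Identifies group microstates per modality, back-fits both, and runs the
    co-occurrence permutation test (mean-z rule) plus the cross-subject GEV
    correlation.  ``coupling`` controls how strongly the EEG label sequence
    follows the MEG one.
    """
    cfg = config or PipelineConfig()
    rng_seed = int(seed)
    layout_meg = synth.make_layout(n_channels, seed=rng_seed)
    layout_eeg = synth.make_layout(n_channels, seed=rng_seed + 1)
    maps_meg = synth.make_topographies(K_meg, layout_meg, "meg", seed=rng_seed + 2)
    maps_eeg = synth.make_topographies(K_eeg, layout_eeg, "eeg", seed=rng_seed + 3)
    k_grid = list(k_grid) if k_grid is not None else [k for k in cfg.k_grid]

    pairs = [
        synth.simulate_paired_modalities(
            layout_meg, layout_eeg, maps_meg, maps_eeg, duration_s,
            cfg.target_fs, snr=snr, coupling=coupling, seed=rng_seed + 10 + s,
        )
        for s in range(n_subjects)
    ]
    group_meg, _ = cluster.two_level_clustering(
        [p[0] for p in pairs], "meg", k_grid=k_grid,
        n_restarts=n_restarts, seed=rng_seed + 100,
    )
    group_eeg, _ = cluster.two_level_clustering(
        [p[1] for p in pairs], "eeg", k_grid=k_grid,
        n_restarts=n_restarts, seed=rng_seed + 200,
    )

    grids, gev_m, gev_e = [], [], []
    for s, (rec_m, rec_e, _) in enumerate(pairs):
        seg_m = fit.smooth_labels(
            fit.backfit(rec_m, group_meg, cfg.threshold), rec_m, group_meg,
            cfg.half_window, cfg.besag_lambda,
        )
        seg_e = fit.smooth_labels(
            fit.backfit(rec_e, group_eeg, cfg.threshold), rec_e, group_eeg,
            cfg.half_window, cfg.besag_lambda,
        )
        grids.append(
            crossmodal.cooccurrence_permutation(
                seg_m, seg_e, n_perm=n_perm or cfg.n_perm_cooc,
                seed=rng_seed + 500 + s,
            )
        )
        gev_m.append(fit.temporal_metrics(seg_m).gev)
        gev_e.append(fit.temporal_metrics(seg_e).gev)
    mean_z, assoc = crossmodal.group_association(grids, cfg.mean_z_crit)
    bundle = {
        "seed": rng_seed,
        "config": dataclasses.asdict(cfg),
        "group_k_meg": group_meg.k,
        "group_k_eeg": group_eeg.k,
        "cooccurrence": grids,
        "mean_z": mean_z,
        "association": assoc,
    }
    if n_subjects >= 4:
        bundle["gev_correlation"] = crossmodal.gev_correlation(
            np.array(gev_m), np.array(gev_e), cfg.alpha
        )
    return bundle
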