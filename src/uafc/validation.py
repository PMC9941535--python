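"""Parameter-recovery protocol: does the pipeline recover what was planted?

These routines run the analysis on synthetic cohorts and compare the
recovered quantities against the generator's ground truth: the UA-DC
coupling, the group-difference edges, and the edge-to-outcome link.  They
are the package's calibration evidence and are reused by the acceptance
script.

All recovery runs use the *unsmoothed* protocol (``fwhm_mm = 0``).  At
desk scale the toy parcels are only ~5 voxels across — barely 2.5x the
6 mm kernel FWHM — so smoothing leaks neighbouring parcels into each
other far more than it ever would with real atlas parcels; the unsmoothed
path measures the method rather than that scale artifact (the smoothing
operator itself is validated separately against a convolution oracle).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .connectivity import ROITimeSeries, fc_fisher_z
from .pipeline import DBSOutcomeModel, PipelineConfig
from .prediction import SVRConfig, build_feature_matrix, improvement_rate, loocv_svr_grid
from .simulate import SimConfig, simulate_cohort
from .stats import edge_group_test

__all__ = [
    "RECOVERY_PIPELINE",
    "compact_svr_grid",
    "ua_dc_recovery",
    "edge_recovery",
    "loocv_recovery",
    "null_edge_false_selection_rate",
]

RECOVERY_PIPELINE = PipelineConfig(fwhm_mm=0.0)


def compact_svr_grid(scaling_mode: str = "full-sample") -> SVRConfig:
    """Reduced hyperparameter grid used for multi-seed recovery runs."""
    return SVRConfig(
        C_grid=[2.0**k for k in (-1, 3, 7, 11)],
        gamma_grid=[2.0**k for k in (-9, -5, -1)],
        epsilon_grid=[0.1, 0.3],
        scaling_mode=scaling_mode,
    )


def _coupled_rois(cfg: SimConfig) -> list[tuple[int, float]]:
    """(roi, sign) for every UA-coupled ROI."""
    return [(r, +1.0) for r in cfg.dc_ua_rois_pos] + [
        (r, -1.0) for r in cfg.dc_ua_rois_neg
    ]


def ua_dc_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    sim_kwargs: dict | None = None,
) -> dict:
    """Recover the planted UA-DC coupling from full voxel-wise DC maps.

    For each seed, simulates a PD cohort (n = 60, low voxel noise, the
    generator's default coupling rho), runs preprocessing + degree
    centrality through the pipeline, and correlates serum UA with ROI-mean
    DC in each designated ROI (sign-flipping the negatively coupled set).
    Returns per-seed and pooled mean recovered correlations.
    """
    kwargs = dict(n_pd=60, n_hc=1, noise_sd=0.3)
    kwargs.update(sim_kwargs or {})
    per_seed = []
    planted = None
    for k in range(n_seeds):
        cfg = SimConfig(seed=(base_seed + k) % 2**31, **kwargs)
        planted = cfg.dc_ua_coupling
        cohort = simulate_cohort(cfg)
        model = DBSOutcomeModel.from_cohort(cohort, RECOVERY_PIPELINE)
        res = model.fit(stop_after="dc")
        pd_recs = [r for r in cohort.records if r.group == "PD"]
        ua = np.array([r.ua_umol_l for r in pd_recs])
        dc = res.roi_dc_table.loc[[r.subject_id for r in pd_recs]]
        vals = [
            sign * np.corrcoef(ua, dc[roi])[0, 1]
            for roi, sign in _coupled_rois(cfg)
        ]
        per_seed.append(float(np.mean(vals)))
    return {
        "planted": planted,
        "per_seed": per_seed,
        "mean_recovered": float(np.mean(per_seed)),
    }


def _panel_zfc(cohort, model: DBSOutcomeModel, panel: list[int]):
    """Preprocessed zFC matrices on a fixed ROI panel, split by group."""
    zpd, zhc, labels, pd_ids = [], [], [], []
    for rec in cohort.records:
        ts = model.roi_timeseries(rec.subject_id, panel)
        z = fc_fisher_z(ROITimeSeries(panel, ts.data))
        if rec.group == "PD":
            zpd.append(z)
            labels.append(improvement_rate(rec.updrs3_pre_off, rec.updrs3_post_on))
            pd_ids.append(rec.subject_id)
        else:
            zhc.append(z)
    return zpd, zhc, np.array(labels), pd_ids


def _planted_panel(cfg: SimConfig) -> tuple[list[int], set]:
    panel = sorted({r for e in cfg.group_diff_edges for r in e}
                   | set(cfg.dc_ua_rois_pos) | set(cfg.dc_ua_rois_neg))
    planted = {tuple(sorted(e, reverse=True)) for e in cfg.group_diff_edges}
    return panel, planted


def edge_recovery(n_seeds: int = 20, base_seed: int = 0, sim_kwargs: dict | None = None) -> dict:
    """Fraction of seeds in which BH-FDR edge selection recovers exactly
    the planted group-difference edges on the designated ROI panel."""
    exact = 0
    detail = []
    for k in range(n_seeds):
        cfg = SimConfig(seed=(base_seed + k) % 2**31, **(sim_kwargs or {}))
        panel, planted = _planted_panel(cfg)
        cohort = simulate_cohort(cfg)
        model = DBSOutcomeModel.from_cohort(cohort, RECOVERY_PIPELINE, restrict_labels=panel)
        zpd, zhc, _, _ = _panel_zfc(cohort, model, panel)
        res = edge_group_test(zpd, zhc)
        selected = {tuple(sorted(e, reverse=True)) for e in res.selected_edges}
        ok = selected == planted
        exact += ok
        detail.append(sorted(selected))
    return {"exact_fraction": exact / n_seeds, "per_seed_selected": detail}


def loocv_recovery(
    outcome_coupling: float,
    n_seeds: int = 7,
    base_seed: int = 0,
    scaling_mode: str = "full-sample",
) -> dict:
    """LOOCV-SVR Pearson r when predicting improvement from the planted
    edges' zFC, per seed.  ``outcome_coupling = 0`` gives null cohorts."""
    rs = []
    for k in range(n_seeds):
        cfg = SimConfig(seed=(base_seed + k) % 2**31, outcome_coupling=outcome_coupling)
        panel, _ = _planted_panel(cfg)
        edges = [tuple(sorted(e, reverse=True)) for e in cfg.group_diff_edges]
        cohort = simulate_cohort(cfg)
        model = DBSOutcomeModel.from_cohort(cohort, RECOVERY_PIPELINE, restrict_labels=panel)
        zpd, _, labels, pd_ids = _panel_zfc(cohort, model, panel)
        fm = build_feature_matrix(zpd, edges, labels, pd_ids)
        rs.append(float(loocv_svr_grid(fm, compact_svr_grid(scaling_mode)).r))
    return {"per_seed_r": rs, "median_r": float(np.median(rs))}


def null_edge_false_selection_rate(n_seeds: int = 10, base_seed: int = 0) -> float:
    """Fraction of null simulations (exchangeable groups) in which BH-FDR
    selects at least one edge; should not exceed the nominal level by more
    than Monte-Carlo error."""
    base = SimConfig()
    hits = 0
    for k in range(n_seeds):
        cfg = dataclasses.replace(
            base,
            seed=(base_seed + k) % 2**31,
            # identical edge-coupling distributions in both groups
            edge_weight_pd_mean=base.edge_weight_hc,
            edge_weight_pd_spread=0.0,
            outcome_coupling=0.0,
        )
        panel, _ = _planted_panel(cfg)
        cohort = simulate_cohort(cfg)
        model = DBSOutcomeModel.from_cohort(cohort, RECOVERY_PIPELINE, restrict_labels=panel)
        zpd, zhc, _, _ = _panel_zfc(cohort, model, panel)
        hits += bool(edge_group_test(zpd, zhc).selected_edges)
    return hits / n_seeds
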