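"""Synthetic rs-fMRI cohort generator with ground-truth-known structure.

No public dataset carries the structure this pipeline consumes (per-subject
4D BOLD, serum uric acid, pre/post-surgery UPDRS-III), so every stage is
validated against simulated cohorts in which the effects of interest are
*planted* and recorded in a ground-truth ledger:

* each ROI of a toy parcellation emits a band-limited (0.01-0.08 Hz)
  latent time series mixed into its member voxels;
* a subject-varying **global signal** is shared by all regions — real
  resting-state data have one, and (as in the modeled study) it is not
  regressed out, which makes connectivity edges positively dependent;
* every voxel of an ROI mixes the ROI latent with spatially smooth,
  zero-spatial-mean idiosyncratic modes (each carrying its own
  band-limited series), so the ROI's **within-region coherence** — the
  mean pairwise voxel correlation — is a tunable quantity that survives
  spatial smoothing and temporal filtering; the **hub gain** of a
  subject's designated ROIs shifts that coherence linearly and is coupled
  to the subject's serum uric acid, so UA correlates with voxel-wise
  degree centrality in those ROIs at a target population correlation rho
  (the modes cancel in the ROI mean, so ROI-level connectivity is
  unaffected);
* designated **group-difference edges** receive a shared cross-ROI
  component whose weight is high in HC and low (and subject-varying) in
  PD, planting PD < HC connectivity differences;
* each PD subject's UPDRS-III **improvement rate** is a linear function of
  its own outcome-edge coupling plus noise, clipped to [0, 1] (the
  observed quantity is a proportion).

The config seed fully determines every array and file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AtlasParcellation,
    SubjectRecord,
    Volume4D,
    save_atlas,
    save_volume,
)
from .preprocess import MotionParams

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "write_cohort", "build_toy_atlas"]

logger = logging.getLogger(__name__)

WM_LABEL = 90
CSF_LABEL = 91

# upper clip for the subject global-signal strength.  Keeps the per-ROI
# variance budget (global^2 + edge load + idiosyncratic = 1) satisfiable
# and, more importantly, keeps voxel-level cross-region correlations
# (~ coherence * g^2) below the degree-centrality threshold of 0.25, so a
# high-global-signal subject cannot flood the degree map with spurious
# supra-threshold cross-region edges.
_G_CLIP = 0.5


class InfeasibleCouplingError(ValueError):
    """Requested planted effect cannot be realized by the generative model."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the modeled study design: 32 PD + 31 HC analysable
    subjects, TR 2 s, 242 volumes of which the first 10 are discardable
    equilibration frames, serum UA ~ N(288, 87) umol/L in PD and
    N(327, 11) in HC, improvement rate mean 0.66 / sd 0.21.  The toy atlas
    has 20 ROIs (two flagged "undefined", mirroring atlas regions that
    vanish under resampling) plus WM and CSF compartments.
    """

    n_pd: int = 32
    n_hc: int = 31
    grid_shape: tuple[int, int, int] = (18, 22, 18)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 242
    n_discard: int = 10
    n_rois: int = 20
    excluded_rois: tuple[int, ...] = (13, 14)
    ua_mean_pd: float = 288.45
    ua_sd_pd: float = 87.05
    ua_mean_hc: float = 327.36
    ua_sd_hc: float = 10.57
    dc_ua_coupling: float = 0.6
    dc_ua_rois_pos: tuple[int, ...] = (3, 4, 5, 6)
    dc_ua_rois_neg: tuple[int, ...] = (9, 10, 11, 12)
    group_diff_edges: tuple[tuple[int, int], ...] = ((3, 9), (4, 10), (5, 11), (6, 12))
    outcome_edges: tuple[tuple[int, int], ...] = ((3, 9), (4, 10), (5, 11), (6, 12))
    improvement_mean: float = 0.66
    improvement_sd: float = 0.21
    outcome_coupling: float = 0.75  # corr between true edge coupling and improvement
    noise_sd: float = 0.6  # voxel white-noise sd relative to unit-variance latent
    roi_coherence_base: float = 0.5    # baseline within-ROI mean pairwise voxel corr
    hub_gain_spread: float = 0.25      # coherence shift per unit hub factor
    n_spatial_modes: int = 16          # idiosyncratic spatial modes per region (x2 scales)
    global_strength_mean: float = 0.32
    global_strength_sd: float = 0.15
    edge_weight_hc: float = 0.6
    edge_weight_pd_mean: float = 0.10
    edge_weight_pd_spread: float = 0.15
    drift_amplitude: float = 0.5
    transient_amplitude: float = 3.0
    motion_outlier_fraction: float = 0.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pd", "n_hc", "n_volumes", "n_rois"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not -1.0 < self.dc_ua_coupling < 1.0:
            raise ValueError("dc_ua_coupling must lie in (-1, 1)")
        if abs(self.dc_ua_coupling) > 0.95:
            raise InfeasibleCouplingError(
                f"|rho| = {abs(self.dc_ua_coupling)} > 0.95 cannot be realized: "
                "hub-gain coupling saturates"
            )
        if self.dc_ua_coupling != 0 and self.noise_sd > 2.0:
            raise InfeasibleCouplingError(
                f"noise_sd = {self.noise_sd} swamps the hub-gain signal; the "
                "requested UA-DC coupling is unattainable (keep noise_sd <= 2)"
            )
        roi_ids = set(range(1, self.n_rois + 1))
        usable = roi_ids - set(self.excluded_rois)
        for i, j in [*self.group_diff_edges, *self.outcome_edges]:
            if i == j or i not in usable or j not in usable:
                raise ValueError(
                    f"edge ({i}, {j}) must join two distinct non-excluded ROIs"
                )
        # variance budget: every ROI's latent must keep positive idiosyncratic power
        load = self._max_edge_load()
        budget = min(self.global_strength_mean + 2 * self.global_strength_sd, _G_CLIP)
        if budget**2 + load > 0.95:
            raise InfeasibleCouplingError(
                f"global-signal power plus edge loads ({budget**2 + load:.2f}) "
                "leave no idiosyncratic ROI variance"
            )
        if not 0 <= self.motion_outlier_fraction <= 1:
            raise ValueError("motion_outlier_fraction must lie in [0, 1]")
        if self.n_discard >= self.n_volumes:
            raise ValueError("n_discard must be < n_volumes")

    def _max_edge_load(self) -> float:
        w = max(self.edge_weight_hc, self.edge_weight_pd_mean + 2 * self.edge_weight_pd_spread)
        count: dict[int, int] = {}
        for i, j in self.group_diff_edges:
            count[i] = count.get(i, 0) + 1
            count[j] = count.get(j, 0) + 1
        return max(count.values(), default=0) * w**2

    @property
    def effective_rois(self) -> list[int]:
        return sorted(set(range(1, self.n_rois + 1)) - set(self.excluded_rois))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["excluded_rois"] = list(self.excluded_rois)
        d["dc_ua_rois_pos"] = list(self.dc_ua_rois_pos)
        d["dc_ua_rois_neg"] = list(self.dc_ua_rois_neg)
        d["group_diff_edges"] = [list(e) for e in self.group_diff_edges]
        d["outcome_edges"] = [list(e) for e in self.outcome_edges]
        return d


def build_toy_atlas(config: SimConfig) -> AtlasParcellation:
    """Deterministic toy parcellation: an ellipsoidal brain divided into
    compact 3D parcels (nearest-centroid assignment over a coarse lattice),
    plus central WM and CSF compartments.  Compactness matters: spatial
    smoothing mixes parcel borders, and sliver-shaped parcels would leak
    their neighbours' signal everywhere."""
    nx, ny, nz = config.grid_shape
    xx, yy, zz = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    brain = (xx**2 + yy**2 + zz**2) <= 0.95
    coords = np.argwhere(brain).astype(float)
    n_vox = len(coords)
    n_parcels = config.n_rois + 2  # ROIs + WM + CSF
    if n_vox < 4 * n_parcels:
        raise ValueError("grid too small for the requested ROI count")
    # coarse lattice cells; keep the n_parcels most populated as seeds
    splits = int(np.ceil(n_parcels ** (1.0 / 3.0)))
    cell_idx = np.zeros(n_vox, dtype=int)
    for d, size in enumerate(config.grid_shape):
        edges = np.linspace(0, size, splits + 1)[1:-1]
        cell_idx = cell_idx * splits + np.digitize(coords[:, d], edges)
    cells, counts = np.unique(cell_idx, return_counts=True)
    keep = cells[np.argsort(-counts, kind="stable")[:n_parcels]]
    centers = np.array([coords[cell_idx == cidx].mean(axis=0) for cidx in keep])
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    # central-most parcels become WM and CSF; the rest are ROIs ordered by
    # centroid scan position
    grid_center = (np.array(config.grid_shape) - 1) / 2.0
    central = np.argsort(((centers - grid_center) ** 2).sum(axis=1), kind="stable")
    wm_parcel, csf_parcel = int(central[0]), int(central[1])
    roi_parcels = [p for p in range(n_parcels) if p not in (wm_parcel, csf_parcel)]
    roi_parcels.sort(key=lambda p: tuple(centers[p]))
    label_of = {wm_parcel: WM_LABEL, csf_parcel: CSF_LABEL}
    for roi_id, p in zip(range(1, config.n_rois + 1), roi_parcels):
        label_of[p] = roi_id
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    ic = np.argwhere(brain)
    for v in range(n_vox):
        labels[tuple(ic[v])] = label_of[int(assign[v])]
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    return AtlasParcellation(
        labels=labels,
        label_table={r: f"ROI_{r:03d}" for r in range(1, config.n_rois + 1)},
        excluded_ids=frozenset(config.excluded_rois),
        tissue_table={WM_LABEL: "WM", CSF_LABEL: "CSF"},
        affine=affine,
    )


def _bandlimited_series(rng: np.random.Generator, n: int, count: int, tr_s: float,
                        low_hz: float, high_hz: float) -> np.ndarray:
    """(count, n) unit-variance series with power confined to the band."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    band = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.zeros((count, freqs.size), dtype=complex)
    k = int(band.sum())
    spec[:, band] = rng.standard_normal((count, k)) + 1j * rng.standard_normal((count, k))
    ts = np.fft.irfft(spec, n=n, axis=1)
    sd = ts.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ts / sd


@dataclass
class _SubjectTruth:
    """Per-subject latent draws recorded in the ground-truth ledger."""

    subject_id: str
    group: str
    ua: float
    hub_factor: dict[int, float]       # h_{s,k} per coupled ROI
    roi_coherence: dict[int, float]    # within-ROI mean pairwise voxel corr
    global_strength: float
    edge_weights: dict[str, float]     # "i-j" -> shared-component weight
    outcome_factor: float              # u_s driving PD edge weights + outcome
    improvement_raw: float             # before clipping
    improvement: float | None
    motion_outlier: bool


@dataclass
class SyntheticCohort:
    """A fully specified synthetic study: atlas, subjects, ground truth.

    BOLD volumes are generated lazily and deterministically per subject
    (``bold(subject_id)``) so cohorts never need to fit in memory at once.
    """

    config: SimConfig
    atlas: AtlasParcellation
    records: list[SubjectRecord]
    motion: dict[str, MotionParams]            # full-length (n_volumes rows)
    truth: dict[str, _SubjectTruth]
    _subject_seeds: dict[str, int] = field(default_factory=dict)
    _mode_fields: dict[int, np.ndarray] = field(default_factory=dict)

    def _modes_for(self, label: int) -> np.ndarray:
        """(2M, m_vox) spatial mode fields for a parcel: plane waves over
        voxel coordinates at two spatial scales, demeaned and
        RMS-normalized per parcel.  The smooth scale (wavelength ~ 6 vox)
        survives Gaussian smoothing and carries the tunable within-region
        incoherence; the fine scale (~ 2.2 vox) emulates the fine-grained
        physiological variance real BOLD keeps after smoothing, which
        holds voxel-level cross-region correlations below the degree
        threshold.  Both scales have zero spatial mean, so they cancel in
        the ROI average and leave ROI-level connectivity untouched."""
        if label not in self._mode_fields:
            M = self.config.n_spatial_modes
            pos = np.argwhere(self.atlas.labels == label).astype(float)  # C-order
            dirs = np.array(
                [[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
                 [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]],
                dtype=float,
            )
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            phi = np.empty((2 * M, len(pos)))
            for m in range(2 * M):
                wavelength = 6.0 if m < M else 2.2
                k = (np.pi / wavelength) * dirs[m % len(dirs)]
                phase = 2.399963 * (m + 1)  # golden-angle offsets
                f = np.cos(pos @ k + phase)
                f = f - f.mean()
                rms = np.sqrt((f**2).mean())
                phi[m] = f / (rms if rms > 1e-9 else 1.0)
            self._mode_fields[label] = phi
        return self._mode_fields[label]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def bold(self, subject_id: str) -> Volume4D:
        """Generate this subject's full 4D BOLD volume (all n_volumes
        frames, leading transient included)."""
        cfg = self.config
        tr = self.truth[subject_id]
        rng = np.random.default_rng(self._subject_seeds[subject_id])
        n_t = cfg.n_volumes
        roi_ids = [r for r in range(1, cfg.n_rois + 1)]
        tissue_ids = [WM_LABEL, CSF_LABEL]

        # independent unit-variance band-limited sources, drawn in fixed order
        n_edges = len(cfg.group_diff_edges)
        all_ids = roi_ids + tissue_ids
        M2 = 2 * cfg.n_spatial_modes  # smooth-scale + fine-scale modes
        sources = _bandlimited_series(
            rng, n_t, 1 + (1 + M2) * len(all_ids) + n_edges,
            cfg.tr_s, cfg.band_low_hz, cfg.band_high_hz,
        )
        g_series = sources[0]
        eta = {k: sources[1 + i] for i, k in enumerate(all_ids)}
        base = 1 + len(all_ids)
        mode_src = {
            k: sources[base + i * M2 : base + (i + 1) * M2] for i, k in enumerate(all_ids)
        }
        base += M2 * len(all_ids)
        edge_src = {e: sources[base + i] for i, e in enumerate(cfg.group_diff_edges)}

        g = tr.global_strength
        latent: dict[int, np.ndarray] = {}
        for k in roi_ids:
            shared = np.zeros(n_t)
            load = g**2
            for e in cfg.group_diff_edges:
                if k in e:
                    w = tr.edge_weights[f"{e[0]}-{e[1]}"]
                    shared = shared + w * edge_src[e]
                    load += w**2
            w_noise = np.sqrt(max(1.0 - load, 1e-6))
            latent[k] = w_noise * eta[k] + g * g_series + shared
        for k in tissue_ids:
            latent[k] = np.sqrt(max(1.0 - g**2, 1e-6)) * eta[k] + g * g_series

        labels = self.atlas.labels
        data = np.zeros((*cfg.grid_shape, n_t), dtype=np.float32)
        support = labels > 0
        n_sup = int(support.sum())
        noise = rng.standard_normal((n_sup, n_t)) * cfg.noise_sd
        drift = rng.standard_normal(n_sup) * cfg.drift_amplitude
        tline = np.linspace(-1.0, 1.0, n_t)
        flat_labels = labels[support]
        sig = np.empty((n_sup, n_t))
        for k in roi_ids + tissue_ids:
            sel = flat_labels == k
            m = int(sel.sum())
            if not m:
                continue
            # voxel = sqrt(coh) * ROI latent + sqrt(1-coh) * idiosyncratic
            # field built from zero-spatial-mean smooth plane-wave modes.
            # Mean pairwise voxel correlation ~ coh; the modes cancel in
            # the ROI mean, so ROI-level FC tracks the latent coupling,
            # and their spatial smoothness survives Gaussian smoothing.
            coh = tr.roi_coherence.get(k, cfg.roi_coherence_base)
            phi = self._modes_for(k)  # (2M, m)
            idio = (phi.T @ mode_src[k]) / np.sqrt(M2)  # (m, n_t)
            sig[sel] = np.sqrt(coh) * latent[k] + np.sqrt(1.0 - coh) * idio
        sig += noise + drift[:, None] * tline[None, :] + 100.0
        # leading equilibration transient: decaying offset on the discardable frames
        trans = np.zeros(n_t)
        nd = cfg.n_discard
        if nd > 0:
            trans[:nd] = cfg.transient_amplitude * np.exp(-np.arange(nd) / 3.0)
        sig += trans[None, :]
        data[support] = sig.astype(np.float32)
        affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
        return Volume4D(
            data=data,
            affine=affine,
            voxel_size_mm=(cfg.voxel_size_mm,) * 3,
            tr_s=cfg.tr_s,
            mask=support.copy(),
        )

    def ledger(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "subjects": {
                sid: {
                    "group": t.group,
                    "ua": t.ua,
                    "hub_factor": {str(k): v for k, v in t.hub_factor.items()},
                    "roi_coherence": {str(k): v for k, v in t.roi_coherence.items()},
                    "global_strength": t.global_strength,
                    "edge_weights": t.edge_weights,
                    "outcome_factor": t.outcome_factor,
                    "improvement_raw": t.improvement_raw,
                    "improvement": t.improvement,
                    "motion_outlier": t.motion_outlier,
                }
                for sid, t in self.truth.items()
            },
        }

    def cohort_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "ua_umol_l": round(r.ua_umol_l, 2),
                    "updrs3_pre_off": "" if r.updrs3_pre_off is None else round(r.updrs3_pre_off, 2),
                    "updrs3_pre_on": "" if r.updrs3_pre_on is None else round(r.updrs3_pre_on, 2),
                    "updrs3_post_off": "" if r.updrs3_post_off is None else round(r.updrs3_post_off, 2),
                    "updrs3_post_on": "" if r.updrs3_post_on is None else round(r.updrs3_post_on, 2),
                }
            )
        return pd.DataFrame(rows, columns=pd.Index([
            "subject_id", "group", "ua_umol_l", "updrs3_pre_off",
            "updrs3_pre_on", "updrs3_post_off", "updrs3_post_on",
        ]))


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort under ``config``.

    The master seed drives subject-level draws in a fixed order and spawns
    one child seed per subject for the BOLD arrays, so the same config is
    byte-identical run to run and subjects are independent of cohort size
    ordering.
    """
    cfg = config
    atlas = build_toy_atlas(cfg)
    master = np.random.default_rng(cfg.seed)
    seed_pool = np.random.SeedSequence(cfg.seed)
    children = seed_pool.spawn(cfg.n_pd + cfg.n_hc)

    rho = cfg.dc_ua_coupling
    records: list[SubjectRecord] = []
    motion: dict[str, MotionParams] = {}
    truth: dict[str, _SubjectTruth] = {}
    subject_seeds: dict[str, int] = {}
    outcome_noise: dict[str, float] = {}

    groups = ["PD"] * cfg.n_pd + ["HC"] * cfg.n_hc
    pd_idx = 0
    for s, group in enumerate(groups):
        sid = f"sub-{s + 1:03d}"
        if group == "PD":
            ua = float(master.normal(cfg.ua_mean_pd, cfg.ua_sd_pd))
            ua_z = (ua - cfg.ua_mean_pd) / cfg.ua_sd_pd
        else:
            ua = float(master.normal(cfg.ua_mean_hc, cfg.ua_sd_hc))
            ua_z = (ua - cfg.ua_mean_hc) / cfg.ua_sd_hc
        ua = max(ua, 50.0)  # physiological floor

        # hub factor h = rho * z_UA +/- sqrt(1-rho^2) * eta per coupled ROI;
        # within-ROI coherence shifts linearly with h, so ROI-mean DC is an
        # approximately linear readout of h
        hub_factor: dict[int, float] = {}
        coherence: dict[int, float] = {}
        for k in range(1, cfg.n_rois + 1):
            eta = float(master.standard_normal())
            if k in cfg.dc_ua_rois_pos:
                h = rho * ua_z + np.sqrt(1 - rho**2) * eta
            elif k in cfg.dc_ua_rois_neg:
                h = -rho * ua_z + np.sqrt(1 - rho**2) * eta
            else:
                h = eta
            hub_factor[k] = h
            coherence[k] = float(
                np.clip(cfg.roi_coherence_base + cfg.hub_gain_spread * h, 0.12, 0.8)
            )

        g = float(np.clip(
            master.normal(cfg.global_strength_mean, cfg.global_strength_sd),
            0.0, _G_CLIP,
        ))

        u = float(master.standard_normal())  # outcome/edge-coupling factor
        edge_weights: dict[str, float] = {}
        for e in cfg.group_diff_edges:
            key = f"{e[0]}-{e[1]}"
            if group == "HC":
                w = cfg.edge_weight_hc
            else:
                w = cfg.edge_weight_pd_mean + cfg.edge_weight_pd_spread * u
            edge_weights[key] = float(np.clip(w, 0.0, 0.9))

        eps = float(master.standard_normal())
        outcome_noise[sid] = eps

        # UPDRS-III scores; post-op med-on is assigned after the outcome
        # pass below, once improvement rates are known
        if group == "PD":
            pre_off = float(np.clip(master.normal(57.29, 12.16), 20.0, None))
            pre_on = pre_off * float(np.clip(master.normal(0.507, 0.08), 0.2, 0.9))
            post_off = pre_off * float(np.clip(master.normal(0.887, 0.10), 0.4, 1.4))
            scores = (pre_off, pre_on, post_off, None)
            pd_idx += 1
        else:
            scores = (None, None, None, None)
            _ = master.normal(size=3)  # keep the draw stream aligned across groups

        # motion: smooth random walk; outliers get a supra-threshold spike
        steps = master.normal(0.0, 0.02, size=(cfg.n_volumes, 6))
        walk = np.cumsum(steps, axis=0)
        is_outlier = bool(master.random() < cfg.motion_outlier_fraction)
        if is_outlier:
            frame = int(master.integers(cfg.n_discard + 5, cfg.n_volumes - 5))
            axis = int(master.integers(0, 6))
            walk[frame, axis] += 3.5 if axis < 3 else 3.5
        motion[sid] = MotionParams(walk)

        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                ua_umol_l=ua,
                updrs3_pre_off=scores[0],
                updrs3_pre_on=scores[1],
                updrs3_post_off=scores[2],
                updrs3_post_on=scores[3],
            )
        )
        truth[sid] = _SubjectTruth(
            subject_id=sid, group=group, ua=ua,
            hub_factor={k: hub_factor[k] for k in (*cfg.dc_ua_rois_pos, *cfg.dc_ua_rois_neg)},
            roi_coherence=coherence,
            global_strength=g, edge_weights=edge_weights,
            outcome_factor=u, improvement_raw=float("nan"),
            improvement=None, motion_outlier=is_outlier,
        )
        subject_seeds[sid] = int(children[s].generate_state(1)[0] % (2**31))

    # outcome pass: the improvement rate is a linear function of the
    # subject's TRUE outcome-edge coupling (Fisher z of the latent edge
    # correlation g^2 + w^2, standardized within the PD sample) plus noise,
    # clipped to [0, 1] because the observed quantity is a proportion.
    def _coupling_score(t: _SubjectTruth) -> float:
        zs = []
        for e in cfg.outcome_edges:
            w = t.edge_weights.get(f"{e[0]}-{e[1]}", 0.0)
            r_true = np.clip(t.global_strength**2 + w**2, 0.0, 0.99)
            zs.append(np.arctanh(r_true))
        return float(np.mean(zs)) if zs else 0.0

    pd_sids = [r.subject_id for r in records if r.group == "PD"]
    scores_arr = np.array([_coupling_score(truth[sid]) for sid in pd_sids])
    mu, sd = scores_arr.mean(), scores_arr.std()
    beta = cfg.outcome_coupling
    for sid, score in zip(pd_sids, scores_arr):
        z = (score - mu) / sd if sd > 1e-12 else 0.0
        raw = cfg.improvement_mean + cfg.improvement_sd * (
            beta * z + np.sqrt(max(1 - beta**2, 0.0)) * outcome_noise[sid]
        )
        improvement = float(np.clip(raw, 0.0, 1.0))
        truth[sid].improvement_raw = float(raw)
        truth[sid].improvement = improvement
        rec = next(r for r in records if r.subject_id == sid)
        assert rec.updrs3_pre_off is not None
        rec.updrs3_post_on = rec.updrs3_pre_off * (1.0 - improvement)

    return SyntheticCohort(
        config=cfg, atlas=atlas, records=records, motion=motion,
        truth=truth, _subject_seeds=subject_seeds,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, compress: bool = False) -> dict:
    """Materialize the cohort on disk; return the manifest.

    Writes one 4D NIfTI and one 6-column motion file per subject, the
    labeled atlas and its lookup table, the cohort TSV, the ground-truth
    ledger, and a manifest with per-file SHA-256 checksums.  NIfTI files
    are uncompressed by default so checksums are reproducible.  Refuses to
    overwrite an existing manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        raise FileExistsError(f"{manifest_path} already exists; refusing to overwrite")
    ext = ".nii.gz" if compress else ".nii"
    files: dict[str, str] = {}

    atlas_vol = out / f"atlas{ext}"
    atlas_tab = out / "atlas_labels.tsv"
    save_atlas(cohort.atlas, atlas_vol, atlas_tab)
    files["atlas"] = atlas_vol.name
    files["atlas_labels"] = atlas_tab.name

    if not cohort.records:
        warnings.warn("writing an empty cohort: atlas and metadata only", stacklevel=2)
        logger.warning("write_cohort called with 0 subjects")

    bold_files, motion_files = {}, {}
    for sid in cohort.subject_ids:
        bold_path = out / f"{sid}_bold{ext}"
        save_volume(cohort.bold(sid), bold_path)
        bold_files[sid] = bold_path.name
        mot_path = out / f"{sid}_motion.txt"
        np.savetxt(mot_path, cohort.motion[sid].values, fmt="%.6f")
        motion_files[sid] = mot_path.name

    cohort_path = out / "cohort.tsv"
    cohort.cohort_frame().to_csv(cohort_path, sep="\t", index=False)
    files["cohort_table"] = cohort_path.name

    ledger_path = out / "ground_truth.json"
    ledger_path.write_text(json.dumps(cohort.ledger(), indent=1, sort_keys=True))
    files["ground_truth"] = ledger_path.name

    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": len(cohort.records),
        "excluded_roi_ids": sorted(cohort.config.excluded_rois),
        "files": files,
        "bold": bold_files,
        "motion": motion_files,
        "checksums": {},
    }
    for name in [*files.values(), *bold_files.values(), *motion_files.values()]:
        manifest["checksums"][name] = _sha256(out / name)
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
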