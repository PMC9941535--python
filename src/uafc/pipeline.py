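"""End-to-end orchestration: cohort in, outcome-prediction results out.

The whole analysis is presented as a fitted model: ``DBSOutcomeModel`` is
built from a cohort (on disk or in memory) plus a ``PipelineConfig`` of
stage parameters, and ``fit()`` executes

    QC -> preprocess -> voxel-wise DC -> UA-DC ROI screening
       -> ROI zFC -> FDR edge tests -> LOOCV epsilon-SVR

returning a ``DBSOutcomeResults`` that carries every stage table, the
filter-count ledger, and a ``summary()``.  ``save_report`` writes the
stage artifacts (TSV/JSON) plus a human-readable markdown report;
``make_report`` regenerates the report from cached artifacts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, prediction, preprocess, stats
from .io import (
    AtlasParcellation,
    SubjectRecord,
    Volume4D,
    load_atlas,
    load_cohort_table,
    load_volume,
    exclude_dimension_mismatch,
)
from .preprocess import MotionParams, load_motion
from .simulate import SyntheticCohort

__all__ = ["PipelineConfig", "DBSOutcomeModel", "DBSOutcomeResults", "make_report"]

logger = logging.getLogger(__name__)

STAGES = ("qc", "preprocess", "dc", "screen", "fc", "edges", "predict")


@dataclass
class PipelineConfig:
    """Every stage parameter, with the standard defaults.

    The config snapshot is written verbatim into the output directory so a
    report is always traceable to the exact parameters that produced it.
    """

    discard_leading: int = 10
    fwhm_mm: float = 6.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 3.0
    filter_confounds: bool = True
    smooth_before_dc: bool = True
    dc_r_threshold: float = 0.25
    dc_block_size: int = 1024
    screening_alpha: float = 0.05
    screening_correction: str = "none"  # "none" (default) or "bh"
    edge_alpha: float = 0.05
    edge_test: str = "student"
    svr_C_grid: list[float] = field(default_factory=lambda: prediction.SVRConfig().C_grid)
    svr_gamma_grid: list[float] = field(default_factory=lambda: prediction.SVRConfig().gamma_grid)
    svr_epsilon_grid: list[float] = field(default_factory=lambda: prediction.SVRConfig().epsilon_grid)
    scaling_mode: str = "full-sample"
    baseline: str = "medoff"  # improvement-rate baseline condition
    seed: int = 0

    def svr_config(self) -> prediction.SVRConfig:
        return prediction.SVRConfig(
            C_grid=list(self.svr_C_grid),
            gamma_grid=list(self.svr_gamma_grid),
            epsilon_grid=list(self.svr_epsilon_grid),
            scaling_mode=self.scaling_mode,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _improvement(rec: SubjectRecord, baseline: str) -> float:
    pre = rec.updrs3_pre_off if baseline == "medoff" else rec.updrs3_pre_on
    if pre is None or rec.updrs3_post_on is None:
        raise ValueError(f"{rec.subject_id}: missing UPDRS-III scores for improvement rate")
    return prediction.improvement_rate(pre, rec.updrs3_post_on)


class DBSOutcomeModel:
    """The full connectivity-to-outcome analysis as a fittable model.

    Construct from an on-disk cohort (``from_cohort_dir``) or an in-memory
    synthetic cohort (``from_cohort``), then call :meth:`fit`.
    """

    def __init__(
        self,
        records: list[SubjectRecord],
        atlas: AtlasParcellation,
        bold_loader,
        motion: dict[str, MotionParams],
        config: PipelineConfig | None = None,
        restrict_labels: list[int] | None = None,
    ) -> None:
        self.records = records
        self.atlas = atlas
        self._bold_loader = bold_loader  # subject_id -> Volume4D (post-discard)
        self.motion = motion
        self.config = config or PipelineConfig()
        # optional analysis restriction to a label subset (tissue labels for
        # the nuisance signals are always kept); saves work when only a few
        # ROIs' time series are needed
        self.restrict_labels = None if restrict_labels is None else set(restrict_labels)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, config: PipelineConfig | None = None,
                    restrict_labels: list[int] | None = None) -> "DBSOutcomeModel":
        config = config or PipelineConfig()
        nd = config.discard_leading

        def loader(sid: str) -> Volume4D:
            vol = cohort.bold(sid)
            data = vol.data[..., nd:]
            from .io import default_mask

            return Volume4D(data, vol.affine, vol.voxel_size_mm, vol.tr_s, default_mask(data))

        motion = {
            sid: MotionParams(m.values[nd:]) for sid, m in cohort.motion.items()
        }
        return cls(list(cohort.records), cohort.atlas, loader, motion, config,
                   restrict_labels=restrict_labels)

    @classmethod
    def from_cohort_dir(cls, cohort_dir: str | Path, config: PipelineConfig | None = None) -> "DBSOutcomeModel":
        config = config or PipelineConfig()
        d = Path(cohort_dir)
        manifest = json.loads((d / "manifest.json").read_text())
        atlas = load_atlas(
            d / manifest["files"]["atlas"],
            d / manifest["files"]["atlas_labels"],
            excluded_ids=tuple(manifest.get("excluded_roi_ids", ())),
        )
        records = load_cohort_table(d / manifest["files"]["cohort_table"])
        nd = config.discard_leading
        bold_paths = {sid: d / name for sid, name in manifest["bold"].items()}

        def loader(sid: str) -> Volume4D:
            return load_volume(bold_paths[sid], discard_leading=nd)

        motion = {}
        for sid, name in manifest["motion"].items():
            motion[sid] = load_motion(d / name, discard_leading=nd)
        # subjects on a different grid cannot enter the voxel-wise analysis
        grids = {}
        import nibabel as nib

        for sid, p in bold_paths.items():
            grids[sid] = tuple(nib.load(str(p)).shape)
        records, dim_report = exclude_dimension_mismatch(records, grids)
        model = cls(records, atlas, loader, motion, config)
        model._dim_report = dim_report
        return model

    # -- fitting ------------------------------------------------------

    def clean_volume(self, subject_id: str) -> Volume4D:
        """Denoised volume for one subject: mask to atlas support, smooth
        (per config), linear detrend + band-pass, nuisance regression."""
        cfg = self.config
        vol = self._bold_loader(subject_id)
        if vol.mask.shape != self.atlas.labels.shape:
            raise RuntimeError(
                f"stage preprocess: subject {subject_id} grid "
                f"{vol.mask.shape} does not match atlas {self.atlas.labels.shape}"
            )
        mask = vol.mask & self.atlas.support
        if self.restrict_labels is not None:
            wanted = self.restrict_labels | set(self.atlas.tissue_table)
            mask = mask & np.isin(self.atlas.labels, sorted(wanted))
        vol = Volume4D(vol.data, vol.affine, vol.voxel_size_mm, vol.tr_s, mask)
        if cfg.smooth_before_dc:
            vol_s = preprocess.gaussian_smooth(vol, cfg.fwhm_mm)
        else:
            vol_s = vol
        ts = vol_s.masked_timeseries().astype(float)
        ts = preprocess.detrend_bandpass(ts, vol.tr_s, cfg.band_low_hz, cfg.band_high_hz)
        wm_mask = self.atlas.tissue_mask("wm") & mask
        csf_mask = self.atlas.tissue_mask("csf") & mask
        wm = vol_s.data[wm_mask].mean(axis=0) if wm_mask.any() else np.zeros(vol.n_frames)
        csf = vol_s.data[csf_mask].mean(axis=0) if csf_mask.any() else np.zeros(vol.n_frames)
        design, names = preprocess.build_confound_matrix(self.motion[subject_id], wm, csf)
        nonconst, const = design[:, :-1], design[:, -1:]
        if cfg.filter_confounds:
            keep = nonconst.std(axis=0) > 0
            if keep.any():
                nonconst = nonconst.copy()
                nonconst[:, keep] = preprocess.detrend_bandpass(
                    nonconst[:, keep].T, vol.tr_s, cfg.band_low_hz, cfg.band_high_hz
                ).T
        live = [i for i in range(nonconst.shape[1]) if nonconst[:, i].std() > 1e-14]
        design = np.column_stack([nonconst[:, live], const])
        design, dnames = preprocess.reduce_to_full_rank(
            design, [names[i] for i in live] + ["constant"], warn=False
        )
        # short scans: if the nuisance design spans (nearly) the whole
        # pass-band subspace, the residuals are numerically zero and every
        # downstream correlation is meaningless
        from .preprocess import _band_projector

        qf, qu = _band_projector(
            vol.n_frames, float(vol.tr_s), float(cfg.band_low_hz), float(cfg.band_high_hz)
        )
        band_dim = qf.shape[1] - qu.shape[1]
        residual_dim = band_dim - (design.shape[1] - 1)  # constant is out-of-band
        if residual_dim < 8:
            raise RuntimeError(
                f"stage preprocess: only {band_dim} pass-band dimensions for "
                f"{design.shape[1] - 1} nuisance regressors (subject {subject_id}); "
                "the scan is too short for this band and confound model"
            )
        ts = preprocess.nuisance_regress(ts, design, dnames)
        return vol.with_data(_unmask(ts, mask, vol.data.shape))

    def roi_timeseries(self, subject_id: str, roi_subset: list[int] | None = None) -> connectivity.ROITimeSeries:
        """Preprocessed mean time series per ROI for one subject (no DC)."""
        return connectivity.extract_roi_timeseries(
            self.clean_volume(subject_id), self.atlas, roi_subset
        )

    def fit(self, stop_after: str | None = None) -> "DBSOutcomeResults":
        """Run the pipeline, optionally stopping after a named stage."""
        if stop_after is not None and stop_after not in STAGES:
            raise ValueError(f"unknown stage {stop_after!r}; stages: {STAGES}")
        cfg = self.config
        counts: dict[str, int | None] = {"n_enrolled": len(self.records)}
        res = DBSOutcomeResults(config=cfg, filter_counts=counts)
        res.dimension_report = getattr(self, "_dim_report", None)

        # --- QC ---
        included, qc_report = preprocess.qc_exclude(
            self.records, self.motion, cfg.max_translation_mm, cfg.max_rotation_deg
        )
        res.qc_report = qc_report
        counts["n_included"] = len(included)
        pd_recs = [r for r in included if r.group == "PD"]
        hc_recs = [r for r in included if r.group == "HC"]
        logger.info("QC: %d/%d subjects retained", len(included), len(self.records))
        if stop_after == "qc":
            return res
        if len(pd_recs) < 3:
            raise RuntimeError(
                f"stage preprocess: too few PD subjects after QC ({len(pd_recs)})"
            )

        # --- preprocess + DC + ROI time series per subject ---
        dc_rows: dict[str, pd.Series] = {}
        roi_ts: dict[str, connectivity.ROITimeSeries] = {}
        for rec in included:
            clean = self.clean_volume(rec.subject_id)
            dcmap = connectivity.voxelwise_dc(
                clean, r_threshold=cfg.dc_r_threshold, block_size=cfg.dc_block_size
            )
            dc_rows[rec.subject_id] = connectivity.roi_mean_dc(dcmap, self.atlas)
            roi_ts[rec.subject_id] = connectivity.extract_roi_timeseries(clean, self.atlas)
        res.roi_dc_table = pd.DataFrame({sid: s for sid, s in dc_rows.items()}).T
        res.roi_timeseries = roi_ts
        counts["rois_screened"] = self.atlas.n_effective
        if stop_after in ("preprocess", "dc"):
            return res

        # --- UA-DC screening over PD subjects ---
        pd_ids = [r.subject_id for r in pd_recs]
        ua = np.array([r.ua_umol_l for r in pd_recs])
        screen = stats.screen_rois(
            res.roi_dc_table.loc[pd_ids],
            ua,
            alpha=cfg.screening_alpha,
            correction=cfg.screening_correction,
        )
        res.screen_table = screen
        selected_rois = [int(r) for r in screen.loc[screen["selected"], "roi_id"]]
        counts["rois_selected"] = len(selected_rois)
        logger.info(
            "screening (%s, alpha=%.3g): %d/%d ROIs selected",
            cfg.screening_correction, cfg.screening_alpha,
            len(selected_rois), self.atlas.n_effective,
        )
        if stop_after == "screen":
            return res
        if len(selected_rois) < 2:
            res.stop_reason = (
                f"only {len(selected_rois)} ROI(s) survived UA-DC screening; "
                "at least 2 are needed to form connectivity edges"
            )
            counts["edges_tested"] = 0
            counts["edges_selected"] = 0
            return res

        # --- zFC matrices over the screened ROIs ---
        zfc: dict[str, connectivity.ZFCMatrix] = {}
        for rec in included:
            sub = connectivity.ROITimeSeries(
                roi_ids=selected_rois,
                data=np.vstack(
                    [roi_ts[rec.subject_id].data[roi_ts[rec.subject_id].roi_ids.index(i)] for i in selected_rois]
                ),
            )
            zfc[rec.subject_id] = connectivity.fc_fisher_z(sub)
        res.zfc = zfc
        if stop_after == "fc":
            return res

        # --- group edge tests ---
        if len(hc_recs) < 2:
            raise RuntimeError(
                f"stage edges: need >= 2 HC subjects, have {len(hc_recs)}"
            )
        edge_res = stats.edge_group_test(
            [zfc[r.subject_id] for r in pd_recs],
            [zfc[r.subject_id] for r in hc_recs],
            alpha=cfg.edge_alpha,
            method=cfg.edge_test,
        )
        res.edge_result = edge_res
        counts["edges_tested"] = edge_res.n_edges
        counts["edges_selected"] = len(edge_res.selected_edges)
        logger.info(
            "edge tests: %d/%d edges survive BH-FDR at %.3g",
            counts["edges_selected"], counts["edges_tested"], cfg.edge_alpha,
        )
        if stop_after == "edges":
            return res
        if not edge_res.selected_edges:
            res.stop_reason = (
                "no edges survived FDR correction; there is no group-difference "
                "connectivity signal to predict from (expected for null cohorts)"
            )
            return res

        # --- LOOCV SVR prediction on PD subjects ---
        labels = np.array([_improvement(r, cfg.baseline) for r in pd_recs])
        features = prediction.build_feature_matrix(
            [zfc[r.subject_id] for r in pd_recs],
            edge_res.selected_edges,
            labels,
            subject_ids=pd_ids,
        )
        res.features = features
        res.prediction = prediction.loocv_svr_grid(features, cfg.svr_config())
        counts["n_folds"] = res.prediction.n_folds
        return res


def _unmask(ts: np.ndarray, mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    out[mask] = ts
    return out


@dataclass
class DBSOutcomeResults:
    """Everything the fitted pipeline produced, stage by stage."""

    config: PipelineConfig
    filter_counts: dict
    qc_report: dict | None = None
    dimension_report: dict | None = None
    roi_dc_table: pd.DataFrame | None = None
    roi_timeseries: dict | None = None
    screen_table: pd.DataFrame | None = None
    zfc: dict | None = None
    edge_result: stats.EdgeTestResult | None = None
    features: prediction.FeatureMatrix | None = None
    prediction: prediction.PredictionResult | None = None
    stop_reason: str | None = None

    def summary(self) -> str:
        c = self.filter_counts
        lines = [
            "UA-guided connectivity outcome analysis",
            "=" * 46,
            f"subjects enrolled     : {c.get('n_enrolled')}",
            f"subjects after QC     : {c.get('n_included')}",
            f"ROIs screened         : {c.get('rois_screened')}",
            f"ROIs selected (UA-DC) : {c.get('rois_selected')}",
            f"edges tested          : {c.get('edges_tested')}",
            f"edges selected (FDR)  : {c.get('edges_selected')}",
        ]
        if self.config.screening_correction == "none":
            lines.append(
                "note: ROI screening used UNCORRECTED p < "
                f"{self.config.screening_alpha:g} (set screening_correction='bh' for FDR)"
            )
        if self.stop_reason:
            lines += ["", f"stopped: {self.stop_reason}"]
        elif self.prediction is not None:
            lines += ["", self.prediction.summary()]
        return "\n".join(lines)

    # -- reporting ----------------------------------------------------

    def save_report(self, out_dir: str | Path) -> dict:
        """Write stage artifacts + JSON/markdown report; return the report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        if self.qc_report is not None:
            (out / "qc_report.json").write_text(json.dumps(self.qc_report, indent=1))
        if self.roi_dc_table is not None:
            self.roi_dc_table.to_csv(out / "roi_dc.tsv", sep="\t")
        if self.screen_table is not None:
            self.screen_table.to_csv(out / "screening.tsv", sep="\t", index=False)
        if self.edge_result is not None:
            self.edge_result.table.to_csv(out / "edge_tests.tsv", sep="\t", index=False)
            self.edge_result.t_matrix.to_csv(out / "edge_t_matrix.tsv", sep="\t")
        if self.prediction is not None:
            self.prediction.scatter_frame().to_csv(out / "prediction_scatter.tsv", sep="\t", index=False)
            (out / "prediction.json").write_text(
                json.dumps(prediction.evaluate_predictions(self.prediction), indent=1)
            )
        report = {
            "filter_counts": self.filter_counts,
            "config": self.config.to_dict(),
            "stop_reason": self.stop_reason,
            "warnings": [],
        }
        if self.config.screening_correction == "none":
            report["warnings"].append(
                "ROI screening used uncorrected p-values (the default); "
                "BH-FDR screening is available via screening_correction='bh'"
            )
        if self.prediction is not None:
            report["prediction"] = prediction.evaluate_predictions(self.prediction)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (out / "report.md").write_text(self.summary() + "\n")
        return report


def make_report(artifact_dir: str | Path) -> dict:
    """Regenerate the JSON report from stage artifacts on disk.

    Raises FileNotFoundError naming the first missing artifact.
    """
    d = Path(artifact_dir)
    required = ["config.yaml", "report.json"]
    for name in required:
        if not (d / name).exists():
            raise FileNotFoundError(f"missing pipeline artifact: {d / name}")
    report = json.loads((d / "report.json").read_text())
    counts = report["filter_counts"]
    if counts.get("edges_selected") and not (d / "edge_tests.tsv").exists():
        raise FileNotFoundError(f"missing pipeline artifact: {d / 'edge_tests.tsv'}")
    if counts.get("rois_selected") is not None and not (d / "screening.tsv").exists():
        raise FileNotFoundError(f"missing pipeline artifact: {d / 'screening.tsv'}")
    regenerated = dict(report)
    if (d / "screening.tsv").exists():
        screen = pd.read_csv(d / "screening.tsv", sep="\t")
        regenerated["filter_counts"]["rois_selected"] = int(screen["selected"].sum())
    if (d / "edge_tests.tsv").exists():
        edges = pd.read_csv(d / "edge_tests.tsv", sep="\t")
        regenerated["filter_counts"]["edges_tested"] = len(edges)
        regenerated["filter_counts"]["edges_selected"] = int(edges["selected"].sum())
    return regenerated
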