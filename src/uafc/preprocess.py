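"""BOLD denoising: QC exclusion, smoothing, detrend + band-pass, nuisance regression.

The default chain reproduces a standard resting-state stream: exclude
subjects with gross head motion (> 3.0 mm translation or > 3.0 deg
rotation), smooth with a 6 mm FWHM Gaussian, remove the linear trend and
band-pass to 0.01-0.08 Hz with an ideal frequency-domain filter, then
regress out the Friston-24 motion expansion plus mean white-matter and CSF
signals.  Confound columns are band-passed with the same filter before
regression by default, so the regression cannot reintroduce the frequencies
the filter removed; ``filter_confounds=False`` restores the literal
filter-then-regress-raw-order.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from .io import SubjectRecord, Volume4D

__all__ = [
    "MotionParams",
    "load_motion",
    "qc_exclude",
    "friston24_expand",
    "build_confound_matrix",
    "gaussian_smooth",
    "detrend_bandpass",
    "nuisance_regress",
    "preprocess_subject",
    "FWHM_TO_SIGMA",
]

# sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MotionParams:
    """Per-frame rigid-body motion: 3 translations (mm), 3 rotations (deg)."""

    values: np.ndarray  # (t, 6)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(
                f"motion parameters must be (t, 6), got {self.values.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def max_translation_mm(self) -> float:
        return float(np.max(np.abs(self.values[:, :3])))

    @property
    def max_rotation_deg(self) -> float:
        return float(np.max(np.abs(self.values[:, 3:])))


def load_motion(path: str | Path, discard_leading: int = 0) -> MotionParams:
    """Read a whitespace-delimited 6-column motion file, discarding the
    rows that correspond to discarded leading BOLD frames."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"motion file not found: {path}")
    vals = np.loadtxt(path, ndmin=2)
    if vals.shape[0] <= discard_leading:
        raise ValueError(f"{path}: fewer motion rows than discarded frames")
    return MotionParams(vals[discard_leading:])


def qc_exclude(
    records: list[SubjectRecord],
    motion: dict[str, MotionParams],
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 3.0,
) -> tuple[list[SubjectRecord], dict]:
    """Drop subjects whose head motion exceeded the thresholds.

    The comparison is strict (``>``): a subject at exactly 3.0 mm is
    retained.  A subject with no motion file is excluded with reason
    ``no_motion`` rather than silently retained.  Returns the retained
    records and a report listing every subject's maxima.
    """
    kept: list[SubjectRecord] = []
    report = {
        "max_translation_mm": max_translation_mm,
        "max_rotation_deg": max_rotation_deg,
        "subjects": [],
    }
    for rec in records:
        m = motion.get(rec.subject_id)
        entry: dict = {"subject_id": rec.subject_id}
        if m is None:
            rec.included = False
            rec.exclusion_reason = "no_motion"
            entry.update(excluded=True, reason="no_motion")
        else:
            rec.max_translation_mm = m.max_translation_mm
            rec.max_rotation_deg = m.max_rotation_deg
            entry.update(
                max_translation_mm=rec.max_translation_mm,
                max_rotation_deg=rec.max_rotation_deg,
            )
            if rec.max_translation_mm > max_translation_mm or rec.max_rotation_deg > max_rotation_deg:
                rec.included = False
                rec.exclusion_reason = "motion"
                entry.update(excluded=True, reason="motion")
            else:
                entry["excluded"] = False
                kept.append(rec)
        report["subjects"].append(entry)
    return kept, report


def friston24_expand(motion: MotionParams) -> tuple[np.ndarray, list[str]]:
    """Expand 6 rigid-body parameters into the 24-regressor Friston model.

    Columns are [R_t, R_{t-1}, R_t^2, R_{t-1}^2] for each of the six
    parameters; the lagged terms at the first frame are set to 0.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames for the Friston-24 expansion")
    r = motion.values
    lag = np.vstack([np.zeros((1, 6)), r[:-1]])
    cols = np.hstack([r, lag, r**2, lag**2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (
        [f"mot_{b}" for b in base]
        + [f"mot_{b}_lag" for b in base]
        + [f"mot_{b}_sq" for b in base]
        + [f"mot_{b}_lag_sq" for b in base]
    )
    return cols, names


def build_confound_matrix(
    motion: MotionParams,
    wm_signal: np.ndarray,
    csf_signal: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the full nuisance design: Friston-24 + WM + CSF + constant."""
    f24, names = friston24_expand(motion)
    wm = np.asarray(wm_signal, dtype=float).reshape(-1)
    csf = np.asarray(csf_signal, dtype=float).reshape(-1)
    if len(wm) != motion.n_frames or len(csf) != motion.n_frames:
        raise ValueError("WM/CSF signal length must match motion frame count")
    design = np.column_stack([f24, wm, csf, np.ones(motion.n_frames)])
    return design, names + ["wm", "csf", "constant"]


def gaussian_smooth(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Per-frame isotropic-in-mm Gaussian smoothing, normalized to the mask.

    Sigma per axis is ``fwhm / (2 sqrt(2 ln 2)) / voxel_size`` in voxel
    units, so anisotropic voxel sizes are honored.  Smoothing is
    mask-normalized: the kernel is renormalized over in-mask voxels so
    out-of-brain zeros do not bleed into the brain edge, and a constant
    in-mask image stays exactly constant.
    """
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in vol.voxel_size_mm]
    m = vol.mask.astype(float)
    denom = ndi.gaussian_filter(m, sigma=sigma_vox)
    data = vol.data * vol.mask[..., None]
    num = ndi.gaussian_filter(data, sigma=(*sigma_vox, 0.0))
    out = np.zeros_like(vol.data)
    valid = denom > 1e-12
    out[valid] = num[valid] / denom[valid, None]
    out[~vol.mask] = 0.0
    return vol.with_data(out)


@functools.lru_cache(maxsize=8)
def _band_projector(n: int, tr_s: float, low_hz: float, high_hz: float):
    """Orthonormal bases (Qf, Ut) defining the detrended-band projection.

    The filter projects onto span(F) ∩ T⊥, where F holds the in-band
    Fourier cosine/sine vectors and T = [1, t] the trend: vectors that lie
    entirely in the pass band *and* carry no constant/linear component.
    The projection is P_F − P_U with U the in-band part of the trend, so
    out-of-band bins are annihilated exactly, the output has zero mean and
    no linear trend, and the operation is exactly idempotent.
    """
    t = np.arange(n, dtype=float)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    band = np.flatnonzero((freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12))
    cols = []
    for k in band:
        arg = 2.0 * np.pi * k * t / n
        cols.append(np.cos(arg))
        if 0 < k < n / 2:
            cols.append(np.sin(arg))
    if not cols:
        return np.empty((n, 0)), np.empty((n, 0))
    F = np.column_stack(cols)
    Qf, Rf = np.linalg.qr(F)
    keep = np.abs(np.diag(Rf)) > 1e-10 * np.abs(np.diag(Rf)).max()
    Qf = Qf[:, keep]
    T = np.column_stack([np.ones(n), t - t.mean()])
    U = Qf @ (Qf.T @ T)  # in-band component of the trend
    Qu, sv, _ = np.linalg.svd(U, full_matrices=False)
    return Qf, Qu[:, sv > 1e-8 * max(sv.max(), 1e-30)]


def detrend_bandpass(
    ts: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Remove the least-squares linear trend and ideal band-pass filter.

    ``ts`` is (n_series, t).  Implemented as one orthogonal projection
    onto the span of the detrended in-band Fourier components, so the
    output retains only frequencies with ``low_hz <= f <= high_hz``, has
    zero mean and no linear trend, and the operation is exactly
    idempotent.

    Raises if the band lies outside (0, Nyquist) or fewer than 8 frames
    are available.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n = ts.shape[1]
    if n < 8:
        raise ValueError(f"need >= 8 frames to band-pass, got {n}")
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 < low_hz < high_hz):
        raise ValueError(f"invalid band ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz is not below Nyquist {nyquist:.4f} Hz"
        )
    Qf, Qu = _band_projector(n, float(tr_s), float(low_hz), float(high_hz))
    if Qf.shape[1] == 0:
        raise ValueError("pass band contains no Fourier component at this length")
    return (ts @ Qf) @ Qf.T - (ts @ Qu) @ Qu.T


def nuisance_regress(ts: np.ndarray, confounds: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Regress confounds out of each time series; return residuals.

    Residuals are the least-squares projection complement, hence orthogonal
    to every confound column.  A rank-deficient design is an error naming
    the collinear columns rather than a silently unstable fit.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != ts.shape[1]:
        raise ValueError(
            f"confounds have {C.shape[0]} frames but time series have {ts.shape[1]}"
        )
    if names is None:
        names = [f"c{i}" for i in range(C.shape[1])]
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        collinear = _collinear_columns(C, names)
        raise ValueError(
            f"confound matrix is rank deficient ({rank}/{C.shape[1]}); "
            f"collinear columns: {collinear}"
        )
    beta, *_ = np.linalg.lstsq(C, ts.T, rcond=None)
    return ts - (C @ beta).T


def reduce_to_full_rank(
    C: np.ndarray, names: list[str], warn: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that add no rank; residuals are unaffected.

    Band-pass filtering confounds projects them into a low-dimensional
    frequency subspace, so with short scans the filtered design can be
    exactly collinear by construction.  Dropping the redundant columns
    spans the same space, hence gives identical regression residuals.
    """
    kept_idx: list[int] = []
    kept = np.empty((C.shape[0], 0))
    dropped: list[str] = []
    for j in range(C.shape[1]):
        cand = np.column_stack([kept, C[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    if dropped and warn:
        warnings.warn(
            f"dropped {len(dropped)} collinear confound column(s): {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    return C[:, kept_idx], [names[j] for j in kept_idx]


def _collinear_columns(C: np.ndarray, names: list[str]) -> list[str]:
    """Name columns that add no rank (greedy QR-style scan)."""
    bad, kept = [], np.empty((C.shape[0], 0))
    for j in range(C.shape[1]):
        cand = np.column_stack([kept, C[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(names[j])
        else:
            kept = cand
    return bad


def preprocess_subject(
    vol: Volume4D,
    motion: MotionParams,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    fwhm_mm: float = 6.0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    filter_confounds: bool = True,
    order: tuple[str, ...] = ("smooth", "filter", "regress"),
) -> np.ndarray:
    """Run the per-subject denoising chain; return (n_mask_voxels, t) residuals.

    The default order is smooth -> detrend+band-pass -> nuisance
    regression.  ``order`` exposes the sequencing for sensitivity checks;
    it must be a permutation of those three stage names.
    """
    if sorted(order) != ["filter", "regress", "smooth"]:
        raise ValueError(f"order must permute smooth/filter/regress, got {order}")
    if motion.n_frames != vol.n_frames:
        raise ValueError(
            f"motion has {motion.n_frames} frames, BOLD has {vol.n_frames}"
        )
    wm_mask = np.zeros(vol.mask.shape, bool) if wm_mask is None else (wm_mask & vol.mask)
    csf_mask = np.zeros(vol.mask.shape, bool) if csf_mask is None else (csf_mask & vol.mask)

    current = vol
    ts: np.ndarray | None = None

    def _tissue_means(v: Volume4D) -> tuple[np.ndarray, np.ndarray]:
        wm = v.data[wm_mask].mean(axis=0) if wm_mask.any() else np.zeros(v.n_frames)
        csf = v.data[csf_mask].mean(axis=0) if csf_mask.any() else np.zeros(v.n_frames)
        return wm, csf

    for stage in order:
        if stage == "smooth":
            if ts is not None:
                warnings.warn("smoothing after masking operates on the 4D volume order only")
            current = gaussian_smooth(current, fwhm_mm)
        elif stage == "filter":
            if ts is None:
                ts = current.masked_timeseries().astype(float)
            ts = detrend_bandpass(ts, current.tr_s, low_hz, high_hz)
        elif stage == "regress":
            if ts is None:
                ts = current.masked_timeseries().astype(float)
            wm, csf = _tissue_means(current)
            design, names = build_confound_matrix(motion, wm, csf)
            nonconst, const = design[:, :-1], design[:, -1:]
            if filter_confounds and nonconst.shape[1]:
                keep = nonconst.std(axis=0) > 0
                if keep.any():
                    nonconst = nonconst.copy()
                    nonconst[:, keep] = detrend_bandpass(
                        nonconst[:, keep].T, current.tr_s, low_hz, high_hz
                    ).T
            # dead columns (e.g. identically-zero motion) carry no information
            live = [i for i in range(nonconst.shape[1]) if nonconst[:, i].std() > 1e-14]
            design = np.column_stack([nonconst[:, live], const])
            names = [names[i] for i in live] + ["constant"]
            design, names = reduce_to_full_rank(design, names, warn=filter_confounds)
            ts = nuisance_regress(ts, design, names)
    assert ts is not None
    return ts
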