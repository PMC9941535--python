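"""Voxel-wise weighted degree centrality and ROI-level functional connectivity.

Degree centrality (DC) treats every in-brain voxel as a network node with
the Pearson correlation between voxel time series as edge weight.  Weighted
DC of a voxel is the sum of its supra-threshold positive correlations
(default r >= 0.25) to all other in-mask voxels, subsequently divided by
the in-mask mean so maps are comparable across subjects.  The correlation
matrix is streamed in voxel blocks and never materialized in full; the
result is exactly (not approximately) the dense computation.

ROI-level analysis extracts mean BOLD time series per parcel, correlates
all pairs, and applies the Fisher z (arctanh) variance-stabilising
transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AtlasParcellation, Volume4D

__all__ = [
    "DCMap",
    "ROITimeSeries",
    "ZFCMatrix",
    "voxelwise_dc",
    "roi_mean_dc",
    "extract_roi_timeseries",
    "fc_fisher_z",
]


@dataclass
class DCMap:
    """Voxel-wise weighted degree centrality map.

    ``values`` holds NaN outside the mask.  ``normalized`` records whether
    the map was divided by its in-mask mean (in which case the in-mask mean
    is 1 by construction).
    """

    values: np.ndarray
    mask: np.ndarray
    r_threshold: float
    normalized: bool
    weighted: bool = True

    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class ROITimeSeries:
    """Mean in-mask BOLD time series per ROI, with a fixed ROI id order."""

    roi_ids: list[int]
    data: np.ndarray  # (n_rois, t)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.roi_ids):
            raise ValueError("ROI id count does not match time-series rows")
        if np.isnan(self.data).all(axis=1).any():
            raise ValueError("ROITimeSeries contains an all-NaN row")


@dataclass
class ZFCMatrix:
    """Symmetric ROI x ROI Fisher-z connectivity matrix; diagonal fixed at 0."""

    roi_ids: list[int]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        k = len(self.roi_ids)
        if self.z.shape != (k, k):
            raise ValueError(f"z matrix shape {self.z.shape} != ({k}, {k})")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("z matrix is not symmetric")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def lower_triangle_edges(self) -> list[tuple[int, int]]:
        """Edges (id_i, id_j) with i after j in the fixed ROI order."""
        ids = self.roi_ids
        return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i)]

    def lower_triangle_values(self) -> np.ndarray:
        k = self.n_rois
        idx = np.tril_indices(k, k=-1)
        return self.z[idx]

    def edge_value(self, id_i: int, id_j: int) -> float:
        i, j = self.roi_ids.index(id_i), self.roi_ids.index(id_j)
        return float(self.z[i, j])


def _standardized_timeseries(vol: Volume4D) -> np.ndarray:
    """In-mask time series, mean-removed and scaled to unit L2 norm, so
    correlations are plain dot products."""
    ts = vol.masked_timeseries().astype(np.float64)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    zero = norms == 0
    if zero.any():
        n_bad = int(zero.sum())
        raise ValueError(
            f"{n_bad} in-mask voxel(s) have zero temporal variance; "
            "re-mask (e.g. with the nonzero-variance default) before DC"
        )
    return ts / norms[:, None]


def voxelwise_dc(
    vol: Volume4D,
    r_threshold: float = 0.25,
    block_size: int = 1024,
    weighted: bool = True,
    normalize: bool = True,
) -> DCMap:
    """Weighted degree centrality of every in-mask voxel.

    For voxel i, DC(i) = sum over j != i of r_ij for all r_ij >=
    ``r_threshold`` (or the count of such j when ``weighted=False``).
    With ``normalize=True`` the map is divided by its in-mask mean.

    The voxel x voxel correlation matrix is processed ``block_size`` rows
    at a time; results are identical for any block size.
    """
    if vol.n_frames < 8:
        raise ValueError("need >= 8 frames for voxel-wise DC")
    if not vol.mask.any():
        raise ValueError("empty mask")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    X = _standardized_timeseries(vol)
    n = X.shape[0]
    dc = np.empty(n, dtype=np.float64)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r = X[start:stop] @ X.T  # (block, n)
        np.clip(r, -1.0, 1.0, out=r)
        supra = r >= r_threshold
        # exclude self-edges (r_ii = 1 always passes a threshold <= 1)
        rows = np.arange(start, stop)
        supra[np.arange(stop - start), rows] = False
        dc[start:stop] = (r * supra).sum(axis=1) if weighted else supra.sum(axis=1)
    if normalize:
        mean = dc.mean()
        if mean == 0:
            raise ZeroDivisionError(
                "global mean DC is zero (no supra-threshold edges); "
                "cannot normalize"
            )
        dc = dc / mean
    values = np.full(vol.mask.shape, np.nan)
    values[vol.mask] = dc
    return DCMap(values, vol.mask.copy(), r_threshold, normalize, weighted)


def roi_mean_dc(dc: DCMap, atlas: AtlasParcellation) -> pd.Series:
    """Mean normalized DC over each effective ROI's in-mask voxels.

    ROIs with no in-mask voxels get NaN (flagged missing, never silently
    dropped).  Raises on grid mismatch.
    """
    if atlas.labels.shape != dc.values.shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} != DC grid {dc.values.shape}"
        )
    out = {}
    for roi in atlas.effective_ids:
        sel = (atlas.labels == roi) & dc.mask
        out[roi] = float(dc.values[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="mean_dc")


def extract_roi_timeseries(
    vol: Volume4D,
    atlas: AtlasParcellation,
    roi_subset: list[int] | None = None,
) -> ROITimeSeries:
    """Per-frame mean BOLD over each ROI's in-mask voxels.

    ROI order follows ``roi_subset`` (default: all effective ROIs in
    ascending id order).  An ROI with no in-mask voxels is an error listing
    the offending id.
    """
    if atlas.labels.shape != vol.mask.shape:
        raise ValueError("atlas grid does not match BOLD grid")
    ids = list(roi_subset) if roi_subset is not None else atlas.effective_ids
    bad = set(ids) - set(atlas.effective_ids)
    if bad:
        raise ValueError(f"roi_subset contains non-effective ROIs: {sorted(bad)}")
    rows = []
    empty = []
    for roi in ids:
        sel = (atlas.labels == roi) & vol.mask
        if not sel.any():
            empty.append(roi)
            rows.append(np.zeros(vol.n_frames))
        else:
            rows.append(vol.data[sel].mean(axis=0))
    if empty:
        raise ValueError(f"ROI(s) with no in-mask voxels: {empty}")
    return ROITimeSeries(roi_ids=ids, data=np.vstack(rows))


def fc_fisher_z(ts: ROITimeSeries, clip_tol: float = 1e-12) -> ZFCMatrix:
    """Pairwise Pearson correlation of ROI time series, Fisher z transformed.

    The diagonal is set to 0 and excluded from all downstream edge lists.
    |r| within ``clip_tol`` of 1 is clipped before arctanh with a warning
    (a perfectly correlated pair usually signals duplicated ROIs).
    """
    if ts.data.shape[1] < 3:
        raise ValueError("need >= 3 frames for correlation")
    sd = ts.data.std(axis=1)
    constant = [ts.roi_ids[i] for i in np.flatnonzero(sd == 0)]
    if constant:
        raise ValueError(f"constant ROI time series: {constant}")
    r = np.corrcoef(ts.data)
    off = ~np.eye(len(ts.roi_ids), dtype=bool)
    near_one = off & (np.abs(r) >= 1.0 - clip_tol)
    if near_one.any():
        warnings.warn(
            f"{int(near_one.sum() // 2)} ROI pair(s) with |r| ~ 1 clipped "
            "before Fisher z (duplicated ROIs?)",
            RuntimeWarning,
            stacklevel=2,
        )
    r = np.clip(r, -(1.0 - clip_tol), 1.0 - clip_tol)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetry
    return ZFCMatrix(roi_ids=list(ts.roi_ids), z=z)
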