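"""Screening statistics: Pearson tests, two-sample t, BH-FDR, edge tests.

Everything here is implemented directly from the textbook formulas (only
the Student-t tail probability comes from scipy) so each piece can be
checked against brute-force oracles: permutation tests for the analytic
p-values and hand enumeration for the Benjamini-Hochberg step-up.

Two deliberate conventions, applied everywhere:

* All tests are two-tailed.
* ROI screening defaults to *uncorrected* p < alpha.  Screening a
  biomarker-correlated ROI set at an uncorrected threshold and then
  FDR-correcting the downstream edge tests is a lenient-then-strict design:
  the screening stage is exploratory feature reduction, the edge stage is
  confirmatory.  A BH-corrected screening mode is available via
  ``correction="bh"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import ZFCMatrix

__all__ = [
    "pearson_test",
    "two_sample_t",
    "bh_fdr",
    "screen_rois",
    "edge_group_test",
    "EdgeTestResult",
    "pearson_p_from_r",
    "t_test_p_from_t",
]


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Sample Pearson r with its t statistic and two-tailed p.

    t = r sqrt((n-2) / (1-r^2)) follows Student's t with n-2 df under the
    bivariate-normal null.  For |r| = 1 the statistic diverges and the
    limiting p = 0 is reported.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.linalg.norm(xc), np.linalg.norm(yc)
    if sx == 0 or sy == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    r = float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return r, float(t), min(p, 1.0)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a reported Pearson r at sample size n."""
    if not -1.0 < r < 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return min(2.0 * float(sps.t.sf(abs(t), df=n - 2)), 1.0)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance Student two-sample t with df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = min(2.0 * float(sps.t.sf(abs(t), df=na + nb - 2)), 1.0)
    return float(t), p


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t (Satterthwaite df); option for edge tests."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        raise ValueError("zero variance in both groups")
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = min(2.0 * float(sps.t.sf(abs(t), df=df)), 1.0)
    return float(t), p


def t_test_p_from_t(t: float, df: int) -> float:
    """Two-tailed p for a reported t statistic at the given df."""
    return min(2.0 * float(sps.t.sf(abs(t), df=df)), 1.0)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection flags.

    adjusted_(i) = min_{j >= i} p_(j) * m / j (on the ascending order),
    capped at 1, mapped back to the input order.  Rejection: adjusted <= q,
    matching the textbook step-up (largest k with p_(k) <= k q / m).
    Ties need no special handling; the running minimum absorbs them.
    """
    p = np.asarray(pvals, dtype=float).reshape(-1)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def screen_rois(
    dc_table: pd.DataFrame,
    ua: np.ndarray,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Correlate serum UA against per-ROI mean DC; flag significant ROIs.

    ``dc_table`` is subjects x ROIs (columns are ROI ids); ``ua`` is the
    matching UA vector.  Selection is by raw p < alpha (default) or BH
    q < alpha (``correction="bh"``).  The full per-ROI table is returned
    regardless of selection, ordered by ascending ROI id.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"correction must be 'none' or 'bh', got {correction!r}")
    ua = np.asarray(ua, dtype=float).reshape(-1)
    if len(dc_table) != ua.size:
        raise ValueError(
            f"{len(dc_table)} DC rows but {ua.size} UA values"
        )
    if len(dc_table) < 3:
        raise ValueError("need >= 3 subjects to screen")
    if dc_table.isna().any().any():
        bad = dc_table.columns[dc_table.isna().any()].tolist()
        raise ValueError(f"missing DC values in ROI column(s) {bad}; no silent imputation")
    rows = []
    for roi in sorted(dc_table.columns):
        r, t, p = pearson_test(dc_table[roi].to_numpy(), ua)
        rows.append({"roi_id": roi, "r": r, "t": t, "p": p})
    out = pd.DataFrame(rows)
    adjusted, _ = bh_fdr(out["p"].to_numpy(), alpha)
    out["q"] = adjusted
    crit = out["q"] if correction == "bh" else out["p"]
    out["selected"] = crit < alpha
    out.attrs.update(alpha=alpha, correction=correction, n_subjects=len(dc_table))
    return out


@dataclass
class EdgeTestResult:
    """Per-edge group comparison over the lower triangle of the zFC matrix."""

    table: pd.DataFrame  # roi_i, roi_j, t, p, q, selected
    t_matrix: pd.DataFrame  # symmetric ROI x ROI t values (diag 0)
    n_pd: int
    n_hc: int
    alpha: float

    @property
    def selected_edges(self) -> list[tuple[int, int]]:
        sel = self.table[self.table["selected"]]
        return [(int(r.roi_i), int(r.roi_j)) for r in sel.itertuples()]

    @property
    def n_edges(self) -> int:
        return len(self.table)


def edge_group_test(
    zfc_pd: list[ZFCMatrix],
    zfc_hc: list[ZFCMatrix],
    alpha: float = 0.05,
    method: str = "student",
) -> EdgeTestResult:
    """Two-sample test of every lower-triangle edge's zFC between groups.

    Edges are the k(k-1)/2 unordered ROI pairs (diagonal and the redundant
    upper triangle excluded).  Raw p-values are BH-FDR corrected across all
    edges; ``selected`` means q <= alpha.  The symmetric t-value matrix is
    returned for reporting.
    """
    if len(zfc_pd) < 2 or len(zfc_hc) < 2:
        raise ValueError("need >= 2 subjects per group")
    ids = zfc_pd[0].roi_ids
    for m in [*zfc_pd, *zfc_hc]:
        if m.roi_ids != ids:
            raise ValueError("ZFC matrices have mismatched ROI order")
    test = {"student": two_sample_t, "welch": welch_t}[method]
    k = len(ids)
    tri = np.tril_indices(k, k=-1)
    stack_pd = np.stack([m.z[tri] for m in zfc_pd])  # (n_pd, n_edges)
    stack_hc = np.stack([m.z[tri] for m in zfc_hc])
    rows = []
    tmat = np.zeros((k, k))
    for e in range(tri[0].size):
        i, j = int(tri[0][e]), int(tri[1][e])
        t, p = test(stack_pd[:, e], stack_hc[:, e])
        tmat[i, j] = tmat[j, i] = t
        rows.append({"roi_i": ids[i], "roi_j": ids[j], "t": t, "p": p})
    table = pd.DataFrame(rows)
    q, reject = bh_fdr(table["p"].to_numpy(), alpha)
    table["q"] = q
    table["selected"] = reject
    t_matrix = pd.DataFrame(tmat, index=ids, columns=ids)
    return EdgeTestResult(table, t_matrix, len(zfc_pd), len(zfc_hc), alpha)
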