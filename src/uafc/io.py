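"""Imaging and cohort I/O.

Houses the data model shared by every pipeline stage: a masked 4D BOLD
volume, an integer-labeled parcellation with an exclusion list, and typed
per-subject clinical records.  All file formats are the field's plain
standards: NIfTI-1 for volumes, TSV for tables, JSON for reports.

Coordinate convention: voxel indices are 0-based; world coordinates follow
the affine.  Mismatched geometry between a BOLD image and the atlas is an
error, never an automatic resample — silent resampling is a classic
connectomics bug.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "AtlasParcellation",
    "SubjectRecord",
    "load_volume",
    "save_volume",
    "load_atlas",
    "save_atlas",
    "load_cohort_table",
    "cohort_to_dataframe",
    "exclude_dimension_mismatch",
]

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "ua_umol_l",
    "updrs3_pre_off",
    "updrs3_pre_on",
    "updrs3_post_off",
    "updrs3_post_on",
]


@dataclass
class Volume4D:
    """A motion-corrected, spatially normalized 4D BOLD image.

    Attributes
    ----------
    data : (x, y, z, t) float array of BOLD intensities.
    affine : 4x4 voxel-to-world map.
    voxel_size_mm : spatial voxel edge lengths in mm.
    tr_s : repetition time in seconds (time between volumes).
    mask : 3D boolean array of in-brain voxels.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD data must retain at least 2 time points")
        if self.tr_s <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_s}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial shape {self.data.shape[:3]}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def masked_timeseries(self) -> np.ndarray:
        """Return the (n_voxels, t) matrix of in-mask time series."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(data, self.affine, self.voxel_size_mm, self.tr_s, self.mask)


def default_mask(data: np.ndarray) -> np.ndarray:
    """In-brain mask: voxels with nonzero temporal variance."""
    return np.var(data, axis=3) > 0


def load_volume(
    path: str | Path,
    discard_leading: int = 0,
    tr_s: float | None = None,
    mask: np.ndarray | None = None,
) -> Volume4D:
    """Load a 4D NIfTI image and drop the leading equilibration frames.

    The first ``discard_leading`` volumes are removed (scanner
    magnetization-stabilisation frames).  The default mask keeps voxels
    with nonzero temporal variance after the discard.

    Raises on missing/corrupt files, non-4D images, and
    ``t <= discard_leading``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BOLD image not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path} is not a 4D image (shape {img.shape})")
    if discard_leading < 0:
        raise ValueError("discard_leading must be >= 0")
    n_t = img.shape[3]
    if n_t <= discard_leading:
        raise ValueError(
            f"{path}: cannot discard {discard_leading} of {n_t} frames"
        )
    data = np.asarray(img.dataobj, dtype=np.float32)[..., discard_leading:]
    zooms = img.header.get_zooms()
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    if mask is None:
        mask = default_mask(data)
    return Volume4D(
        data=data,
        affine=img.affine,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        tr_s=tr_s,
        mask=mask,
    )


def save_volume(vol: Volume4D, path: str | Path) -> Path:
    """Write a Volume4D as NIfTI-1, recording TR in the header."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


@dataclass
class AtlasParcellation:
    """Integer-labeled 3D parcellation with an exclusion list.

    ``label_table`` maps label id -> region name for cortical/subcortical
    ROIs; ``tissue_table`` holds non-ROI tissue compartments (white matter,
    CSF) used only as nuisance-signal sources.  ``excluded_ids`` marks
    regions that are defined in the lookup table but unusable in analysis
    (the AAL3 nos. 133-134 situation, where 1 mm regions vanish at 3 mm
    resampling).
    """

    labels: np.ndarray
    label_table: dict[int, str]
    excluded_ids: frozenset[int] = frozenset()
    tissue_table: dict[int, str] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        self.excluded_ids = frozenset(int(i) for i in self.excluded_ids)
        bad = self.excluded_ids - set(self.label_table)
        if bad:
            raise ValueError(f"excluded ids not in label table: {sorted(bad)}")
        known = set(self.label_table) | set(self.tissue_table)
        present = set(np.unique(self.labels)) - {0}
        unknown = present - known
        if unknown:
            raise ValueError(
                f"atlas volume contains labels absent from table: {sorted(unknown)}"
            )
        if not self.effective_ids:
            raise ValueError("exclusion list removes every ROI")

    @property
    def n_defined(self) -> int:
        """Number of defined ROIs (before exclusion)."""
        return len(self.label_table)

    @property
    def effective_ids(self) -> list[int]:
        """Ascending ids of analysable ROIs: defined minus excluded."""
        return sorted(set(self.label_table) - self.excluded_ids)

    @property
    def n_effective(self) -> int:
        return len(self.effective_ids)

    def roi_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def tissue_mask(self, kind: str) -> np.ndarray:
        """Union mask of tissue labels whose name contains ``kind`` (wm/csf)."""
        ids = [i for i, name in self.tissue_table.items() if kind.lower() in name.lower()]
        out = np.zeros(self.labels.shape, dtype=bool)
        for i in ids:
            out |= self.labels == i
        return out

    @property
    def support(self) -> np.ndarray:
        """All labeled voxels (ROIs plus tissue compartments)."""
        return self.labels > 0


def load_atlas(
    path: str | Path,
    label_table_path: str | Path,
    excluded_ids: tuple[int, ...] | frozenset[int] = frozenset(),
) -> AtlasParcellation:
    """Load a labeled NIfTI atlas plus its TSV lookup table.

    The table needs columns ``id`` and ``name``; an optional ``kind``
    column distinguishes ``roi`` (default) from tissue compartments
    (``wm``, ``csf``).
    """
    path, label_table_path = Path(path), Path(label_table_path)
    if not path.exists():
        raise FileNotFoundError(f"atlas volume not found: {path}")
    if not label_table_path.exists():
        raise FileNotFoundError(f"label table not found: {label_table_path}")
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise ValueError(f"{path}: atlas volume has non-integer labels")
    labels = np.round(labels).astype(np.int32)
    table = pd.read_csv(label_table_path, sep="\t")
    if "id" not in table.columns or "name" not in table.columns:
        raise ValueError(f"{label_table_path}: needs 'id' and 'name' columns")
    if "kind" not in table.columns:
        table["kind"] = "roi"
    rois = table[table["kind"] == "roi"]
    tissue = table[table["kind"] != "roi"]
    return AtlasParcellation(
        labels=labels,
        label_table={int(r.id): str(r.name) for r in rois.itertuples()},
        excluded_ids=frozenset(int(i) for i in excluded_ids),
        tissue_table={int(r.id): str(r.name) for r in tissue.itertuples()},
        affine=img.affine,
    )


def save_atlas(atlas: AtlasParcellation, vol_path: str | Path, table_path: str | Path) -> None:
    affine = atlas.affine if atlas.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(vol_path))
    rows = [
        {"id": i, "name": n, "kind": "roi"} for i, n in sorted(atlas.label_table.items())
    ] + [
        {"id": i, "name": n, "kind": n.lower()} for i, n in sorted(atlas.tissue_table.items())
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


@dataclass
class SubjectRecord:
    """One row of the cohort table, plus derived QC/inclusion state."""

    subject_id: str
    group: str  # "PD" | "HC"
    ua_umol_l: float
    updrs3_pre_off: float | None = None
    updrs3_pre_on: float | None = None
    updrs3_post_off: float | None = None
    updrs3_post_on: float | None = None
    max_translation_mm: float | None = None
    max_rotation_deg: float | None = None
    included: bool = True
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise ValueError(f"{self.subject_id}: group must be PD or HC, got {self.group!r}")
        if not np.isfinite(self.ua_umol_l) or self.ua_umol_l <= 0:
            raise ValueError(f"{self.subject_id}: UA must be positive, got {self.ua_umol_l}")
        for name in ("updrs3_pre_off", "updrs3_pre_on", "updrs3_post_off", "updrs3_post_on"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.subject_id}: {name} must be >= 0, got {v}")


def load_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Parse the cohort TSV into typed records.

    Required header: subject_id, group, ua_umol_l, updrs3_pre_off,
    updrs3_pre_on, updrs3_post_off, updrs3_post_on.  UPDRS cells may be
    empty (healthy controls).  Malformed rows are rejected with their line
    number; duplicated subject ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated subject_id(s): {sorted(set(dupes))}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after header
        try:
            ua = float(row["ua_umol_l"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}:{line}: non-numeric UA value {row['ua_umol_l']!r}"
            ) from None

        def _score(col: str) -> float | None:
            v = row[col]
            if pd.isna(v) or v == "":
                return None
            return float(v)

        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    ua_umol_l=ua,
                    updrs3_pre_off=_score("updrs3_pre_off"),
                    updrs3_pre_on=_score("updrs3_pre_on"),
                    updrs3_post_off=_score("updrs3_post_off"),
                    updrs3_post_on=_score("updrs3_post_on"),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}:{line}: {e}") from None
    return records


def cohort_to_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def exclude_dimension_mismatch(
    records: list[SubjectRecord], grids: dict[str, tuple[int, ...]]
) -> tuple[list[SubjectRecord], dict]:
    """Exclude subjects whose image grid differs from the cohort mode.

    Mirrors the common situation where a few scans were acquired or
    reconstructed on a different matrix and cannot enter a voxel-wise
    analysis.  Returns retained records and a JSON-able report.
    """
    shapes = [grids[r.subject_id] for r in records if r.subject_id in grids]
    if not shapes:
        return list(records), {"mode_grid": None, "excluded": []}
    uniq, counts = np.unique([str(s) for s in shapes], return_counts=True)
    mode = uniq[np.argmax(counts)]
    kept, excluded = [], []
    for r in records:
        g = grids.get(r.subject_id)
        if g is None:
            r.included = False
            r.exclusion_reason = "no_image"
            excluded.append({"subject_id": r.subject_id, "reason": "no_image"})
        elif str(g) != mode:
            r.included = False
            r.exclusion_reason = "dimension_mismatch"
            excluded.append(
                {"subject_id": r.subject_id, "reason": "dimension_mismatch", "grid": list(g)}
            )
        else:
            kept.append(r)
    return kept, {"mode_grid": json.loads(mode.replace("(", "[").replace(")", "]")), "excluded": excluded}
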