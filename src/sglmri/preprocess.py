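"""Feature-matrix assembly and cleaning for atlas-grouped contrast maps.

The pipeline starts from per-subject Z-score contrast volumes (real NIfTI
or synthetic) and an integer-labeled atlas, and produces a clean
subjects x voxels matrix with a group structure:

    assemble -> filter_outliers -> drop_zero_columns -> normalize_voxelwise
             -> build_groups

Unlabeled voxels (atlas label 0) are excluded at assembly.  Voxels with any
|Z| > 5 entry are treated as outliers and the whole voxel column is dropped
for all subjects, keeping the matrix rectangular.  All-zero columns are
dropped.  Columns are then standardized voxel-wise (sample SD, n-1).
Every filter preserves the voxel bookkeeping, so any fitted weight can be
mapped back to a volume coordinate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Z-score magnitude above which an entry is treated as an outlier.
OUTLIER_Z = 5.0

VOXEL_COLUMNS = ["voxel_id", "area", "i", "j", "k", "task"]


@dataclass
class FeatureMatrix:
    """Subjects x voxels Z-score matrix with labels and voxel bookkeeping.

    values : (n, d) float array of Z-scores
    labels : length-n array in {-1, +1} (-1 control, +1 patient)
    subject_ids : length-n identifiers
    voxel_index : DataFrame with one row per column of ``values``:
        voxel_id (stable id), area (atlas label, > 0), i/j/k (0-based
        volume coordinate), task (dataset origin tag)
    """

    values: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    voxel_index: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n, d = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal number of rows")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be in {-1, +1}")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must equal number of rows")
        if len(self.voxel_index) != d:
            raise ValueError("voxel_index must have one row per feature column")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_columns(self, keep: np.ndarray) -> "FeatureMatrix":
        """New FeatureMatrix restricted to the given column positions."""
        return replace(
            self,
            values=self.values[:, keep],
            voxel_index=self.voxel_index.iloc[keep].reset_index(drop=True),
            meta=dict(self.meta),
        )

    # -- TSV + JSON sidecar round trip ------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.values, columns=self.voxel_index["voxel_id"].astype(str))
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "voxel_index": self.voxel_index.to_dict(orient="list"),
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        vi = pd.DataFrame(sidecar["voxel_index"])
        return cls(
            values=df.iloc[:, 2:].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            subject_ids=df["subject_id"].astype(str).tolist(),
            voxel_index=vi,
            meta=sidecar.get("meta", {}),
        )


@dataclass(frozen=True)
class GroupStructure:
    """Partition of feature columns into groups (atlas brain areas).

    membership : length-d int array, group index in 0..n_groups-1 for each
        feature column
    group_names : length-n_groups labels, e.g. "semantic/area-17"
    """

    membership: np.ndarray
    group_names: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=int)
        object.__setattr__(self, "membership", m)
        if m.size and (m.min() < 0 or m.max() >= len(self.group_names)):
            raise ValueError("membership indices out of range")
        counts = np.bincount(m, minlength=len(self.group_names))
        if np.any(counts == 0):
            raise ValueError("every group must be nonempty")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.n_groups)


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------

def assemble(zmaps, atlas: np.ndarray, labels, subject_ids=None, task: str = "task") -> FeatureMatrix:
    """Vectorize subject volumes into a subjects x voxels matrix.

    Parameters
    ----------
    zmaps : sequence of 3-D arrays (one per subject) or (n, d) matrix whose
        columns already correspond to the nonzero-labeled atlas voxels in
        C order.
    atlas : integer label volume; label 0 marks unlabeled voxels, which are
        excluded from the feature matrix.
    labels : length-n array in {-1, +1}.
    """
    atlas = np.asarray(atlas)
    labels = np.asarray(labels)
    flat_atlas = atlas.ravel(order="C")
    keep = np.flatnonzero(flat_atlas > 0)
    coords = np.array(np.unravel_index(keep, atlas.shape)).T

    zmaps = list(zmaps) if not isinstance(zmaps, np.ndarray) else zmaps
    if isinstance(zmaps, np.ndarray) and zmaps.ndim == 2:
        if zmaps.shape[1] != keep.size:
            raise ValueError(
                f"matrix has {zmaps.shape[1]} columns but atlas has {keep.size} labeled voxels"
            )
        values = np.asarray(zmaps, dtype=float)
    else:
        rows = []
        for vol in zmaps:
            vol = np.asarray(vol, dtype=float)
            if vol.shape != atlas.shape:
                raise ValueError(f"volume shape {vol.shape} != atlas shape {atlas.shape}")
            rows.append(vol.ravel(order="C")[keep])
        values = np.vstack(rows)

    n = values.shape[0]
    if labels.shape != (n,):
        raise ValueError("a label is required for every subject")
    if subject_ids is None:
        subject_ids = [f"sub{i:03d}" for i in range(n)]
    voxel_index = pd.DataFrame(
        {
            "voxel_id": keep,
            "area": flat_atlas[keep],
            "i": coords[:, 0],
            "j": coords[:, 1],
            "k": coords[:, 2],
            "task": task,
        }
    )
    return FeatureMatrix(values, labels, list(subject_ids), voxel_index,
                         meta={"atlas_shape": list(atlas.shape)})


def filter_outliers(fm: FeatureMatrix, threshold: float = OUTLIER_Z) -> tuple[FeatureMatrix, dict]:
    """Drop voxel columns containing any |Z| > threshold entry.

    The whole column is removed for all subjects (not just the offending
    entry), keeping the matrix rectangular.  Returns the filtered matrix
    and a removal report.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad_entries = np.abs(fm.values) > threshold
    bad_cols = np.flatnonzero(bad_entries.any(axis=0))
    keep = np.flatnonzero(~bad_entries.any(axis=0))
    report = {
        "threshold": threshold,
        "n_columns_dropped": int(bad_cols.size),
        "dropped_voxel_ids": fm.voxel_index["voxel_id"].iloc[bad_cols].tolist(),
        "n_outlier_entries": int(bad_entries.sum()),
    }
    out = fm.take_columns(keep)
    out.meta["outlier_report"] = report
    return out, report


def drop_zero_columns(fm: FeatureMatrix) -> tuple[FeatureMatrix, dict]:
    """Drop voxel columns that are zero for all subjects."""
    zero = np.all(fm.values == 0, axis=0)
    keep = np.flatnonzero(~zero)
    report = {
        "n_columns_dropped": int(zero.sum()),
        "dropped_voxel_ids": fm.voxel_index["voxel_id"].iloc[np.flatnonzero(zero)].tolist(),
    }
    out = fm.take_columns(keep)
    out.meta["zero_column_report"] = report
    return out, report


def normalize_voxelwise(
    fm: FeatureMatrix,
    mode: str = "pooled",
    train_rows: np.ndarray | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Standardize each voxel column to mean 0, SD 1 (sample SD, n-1).

    mode="pooled" computes statistics over all subjects (the original
    study design;
    note this leaks test-set statistics into training when followed by CV).
    mode="train-only" computes them over ``train_rows`` and applies them to
    all rows.  Zero-variance columns are dropped with a logged warning.
    """
    if fm.n_subjects < 2:
        raise ValueError("need at least 2 subjects to normalize")
    if mode == "pooled":
        ref = fm.values
    elif mode == "train-only":
        if train_rows is None:
            raise ValueError("train-only mode requires train_rows")
        ref = fm.values[np.asarray(train_rows)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        logger.warning("dropping %d zero-variance columns", degenerate.size)
    keep = np.flatnonzero(sd > 0)
    out = fm.take_columns(keep)
    out.values = (out.values - mean[keep]) / sd[keep]
    stats = pd.DataFrame(
        {
            "voxel_id": fm.voxel_index["voxel_id"].iloc[keep].to_numpy(),
            "mean": mean[keep],
            "sd": sd[keep],
        }
    )
    out.meta["normalization"] = {"mode": mode, "sd_convention": "sample (n-1)",
                                 "n_zero_variance_dropped": int(degenerate.size)}
    return out, stats


def build_groups(fm: FeatureMatrix) -> GroupStructure:
    """One group per distinct (task, atlas area) present among the columns."""
    keys = list(zip(fm.voxel_index["task"], fm.voxel_index["area"]))
    seen: dict[tuple, int] = {}
    names: list[str] = []
    membership = np.empty(len(keys), dtype=int)
    for col, key in enumerate(keys):
        if key not in seen:
            seen[key] = len(names)
            names.append(f"{key[0]}/area-{key[1]}")
        membership[col] = seen[key]
    return GroupStructure(membership, names)


def concat_tasks(fm_a: FeatureMatrix, fm_b: FeatureMatrix) -> tuple[FeatureMatrix, GroupStructure]:
    """Column-concatenate two task feature matrices over the same subjects.

    The same anatomical area measured in different tasks forms distinct
    groups: group ids of the second matrix are offset by the first's group
    count (e.g. 105 areas per task combine to 210 groups).
    """
    if fm_b.n_features == 0:
        return fm_a, build_groups(fm_a)
    if fm_a.subject_ids != fm_b.subject_ids or not np.array_equal(fm_a.labels, fm_b.labels):
        raise ValueError("subject rows and labels must match to concatenate tasks")
    if fm_a.voxel_index["task"].iloc[0] == fm_b.voxel_index["task"].iloc[0]:
        raise ValueError("task tags must differ between concatenated matrices")
    values = np.hstack([fm_a.values, fm_b.values])
    voxel_index = pd.concat([fm_a.voxel_index, fm_b.voxel_index], ignore_index=True)
    combined = FeatureMatrix(values, fm_a.labels, fm_a.subject_ids, voxel_index,
                             meta={"concatenated": True})
    groups_a = build_groups(fm_a)
    groups_b = build_groups(fm_b)
    membership = np.concatenate(
        [groups_a.membership, groups_b.membership + groups_a.n_groups]
    )
    groups = GroupStructure(membership, groups_a.group_names + groups_b.group_names)
    return combined, groups


def preprocess_pipeline(
    fm: FeatureMatrix, mode: str = "pooled", outlier_threshold: float = OUTLIER_Z
) -> tuple[FeatureMatrix, GroupStructure, dict]:
    """Run the fixed cleaning order and build the group structure.

    Order: filter_outliers -> drop_zero_columns -> normalize_voxelwise ->
    build_groups.  (Unlabeled voxels were already excluded at assembly.)
    Re-running on the output in mode="pooled" is idempotent after the first
    pass (already-standardized columns are unchanged).
    """
    areas_before = set(map(tuple, fm.voxel_index[["task", "area"]].itertuples(index=False)))
    fm1, outlier_report = filter_outliers(fm, outlier_threshold)
    fm2, zero_report = drop_zero_columns(fm1)
    fm3, norm_stats = normalize_voxelwise(fm2, mode=mode)
    groups = build_groups(fm3)
    areas_after = set(map(tuple, fm3.voxel_index[["task", "area"]].itertuples(index=False)))
    report = {
        "outliers": outlier_report,
        "zero_columns": zero_report,
        "lost_areas": sorted(map(str, areas_before - areas_after)),
        "n_features": fm3.n_features,
        "n_groups": groups.n_groups,
        "normalization_mode": mode,
    }
    return fm3, groups, report


# ---------------------------------------------------------------------------
# Volume round trip
# ---------------------------------------------------------------------------

def weights_to_volume(weights: np.ndarray, voxel_index: pd.DataFrame, shape, task=None) -> np.ndarray:
    """Write per-column values into a 3-D volume via the voxel bookkeeping."""
    vol = np.zeros(tuple(shape), dtype=float)
    vi = voxel_index
    w = np.asarray(weights, dtype=float)
    if task is not None:
        mask = (vi["task"] == task).to_numpy()
        vi = vi[mask]
        w = w[mask]
    vol[vi["i"].to_numpy(), vi["j"].to_numpy(), vi["k"].to_numpy()] = w
    return vol


def volume_to_weights(volume: np.ndarray, voxel_index: pd.DataFrame) -> np.ndarray:
    """Inverse of weights_to_volume: re-extract column values from a volume."""
    return np.asarray(volume)[
        voxel_index["i"].to_numpy(), voxel_index["j"].to_numpy(), voxel_index["k"].to_numpy()
    ]


def load_nifti_volume(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)


def save_nifti_volume(vol: np.ndarray, path: str | Path, integer: bool = False) -> None:
    import nibabel as nib

    arr = np.asarray(vol, dtype=np.int32 if integer else np.float64)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
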