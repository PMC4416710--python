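"""Stability of voxel and brain-area selection across cross-validated models.

Each nested-CV run produces many fitted weight vectors (e.g. 10 folds x
100 repeats = 1000 models).  A voxel counts as selected in a model iff its
|weight| exceeds the support tolerance; an area counts as selected iff any
of its member voxels is.  The summary reports, per voxel and per area,
selection counts and frequencies, signed weight averages (per-area
positive/negative means normalized by the largest such mean across areas),
and the ">80% occurrence" rule uses a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ZERO_TOL


@dataclass
class SelectionSummary:
    """Per-voxel and per-area selection statistics over an ensemble of models."""

    voxel_table: pd.DataFrame  # column, group, count, frequency, mean_pos, mean_neg
    area_table: pd.DataFrame  # group, name, frequency, pos/neg frequencies & weights
    n_models: int
    n_selected_per_model: np.ndarray  # support size of each model
    union_voxels: int  # voxels selected at least once
    union_areas: int  # areas selected at least once

    @property
    def mean_support(self) -> float:
        """Mean number of selected voxels per model."""
        return float(np.mean(self.n_selected_per_model))

    @property
    def sd_support(self) -> float:
        return float(np.std(self.n_selected_per_model, ddof=1)) if self.n_models > 1 else 0.0

    @property
    def max_occurrence(self) -> float:
        """Highest selection frequency of any single voxel."""
        return float(self.voxel_table["frequency"].max()) if len(self.voxel_table) else 0.0


def summarize(weight_vectors, groups, zero_tol: float = ZERO_TOL,
              converged=None) -> SelectionSummary:
    """Tally selections and signed weights over an ensemble of weight vectors.

    Parameters
    ----------
    weight_vectors : (n_models, d) array or list of length-d vectors.
    groups : GroupStructure (or membership array) over the d features.
    converged : optional boolean mask; non-converged models are excluded
        from the tallies but counted in the report denominator rationale
        (the frequency denominator is the number of models *used*).

    Per-area positive (negative) mean weight pools all positive (negative)
    selected voxel-weights across models within the area, then normalizes
    by the largest magnitude across areas, giving values in [-1, 1].
    """
    W = np.atleast_2d(np.asarray(weight_vectors, dtype=float))
    if converged is not None:
        W = W[np.asarray(converged, dtype=bool)]
    if W.shape[0] < 1:
        raise ValueError("need at least one model")
    membership = np.asarray(getattr(groups, "membership", groups), dtype=int)
    if membership.shape[0] != W.shape[1]:
        raise ValueError("group membership length must match weight dimension")
    names = getattr(groups, "group_names", None)
    n_models, d = W.shape

    selected = np.abs(W) > zero_tol
    counts = selected.sum(axis=0)
    freq = counts / n_models
    pos = np.where(selected & (W > 0), W, np.nan)
    neg = np.where(selected & (W < 0), W, np.nan)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_pos = np.nanmean(pos, axis=0)
        mean_neg = np.nanmean(neg, axis=0)
        mean_signed = np.where(
            counts > 0, (W * selected).sum(axis=0) / np.maximum(counts, 1), 0.0
        )
    voxel_table = pd.DataFrame(
        {
            "column": np.arange(d),
            "group": membership,
            "count": counts,
            "frequency": freq,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "mean_signed": mean_signed,
        }
    )

    group_ids = np.unique(membership)
    rows = []
    for g in group_ids:
        cols = membership == g
        any_sel = selected[:, cols].any(axis=1)  # per model
        pos_sel = (selected & (W > 0))[:, cols].any(axis=1)
        neg_sel = (selected & (W < 0))[:, cols].any(axis=1)
        pos_pool = W[:, cols][selected[:, cols] & (W[:, cols] > 0)]
        neg_pool = W[:, cols][selected[:, cols] & (W[:, cols] < 0)]
        rows.append(
            {
                "group": int(g),
                "name": names[g] if names is not None else str(g),
                "frequency": any_sel.mean(),
                "pos_frequency": pos_sel.mean(),
                "neg_frequency": neg_sel.mean(),
                "mean_pos_weight": pos_pool.mean() if pos_pool.size else 0.0,
                "mean_neg_weight": neg_pool.mean() if neg_pool.size else 0.0,
            }
        )
    area_table = pd.DataFrame(rows)
    # normalize signed area means by the extreme mean across areas
    max_pos = area_table["mean_pos_weight"].max()
    min_neg = area_table["mean_neg_weight"].min()
    area_table["norm_pos_weight"] = (
        area_table["mean_pos_weight"] / max_pos if max_pos > 0 else 0.0
    )
    area_table["norm_neg_weight"] = (
        -area_table["mean_neg_weight"] / min_neg if min_neg < 0 else 0.0
    )

    return SelectionSummary(
        voxel_table=voxel_table,
        area_table=area_table,
        n_models=n_models,
        n_selected_per_model=selected.sum(axis=1),
        union_voxels=int((counts > 0).sum()),
        union_areas=int(area_table.loc[area_table["frequency"] > 0, "group"].nunique()),
    )


def frequent_set(summary: SelectionSummary, threshold: float = 0.8,
                 level: str = "voxel") -> pd.DataFrame:
    """Items selected in strictly more than ``threshold`` of the models.

    A frequency of exactly the threshold is excluded.  Sorted by frequency
    (descending), then by mean absolute weight.
    """
    if level == "voxel":
        t = summary.voxel_table.copy()
        t["mean_abs"] = np.nanmax(
            np.abs(t[["mean_pos", "mean_neg"]].fillna(0.0).to_numpy()), axis=1
        )
    elif level == "area":
        t = summary.area_table.copy()
        t["mean_abs"] = np.maximum(
            t["mean_pos_weight"].abs(), t["mean_neg_weight"].abs()
        )
    else:
        raise ValueError("level must be 'voxel' or 'area'")
    out = t[t["frequency"] > threshold]
    return out.sort_values(["frequency", "mean_abs"], ascending=False).reset_index(drop=True)


def weight_map(summary: SelectionSummary, voxel_index: pd.DataFrame, shape,
               sign: str = "both", threshold: float = 0.8, task=None) -> np.ndarray:
    """Mean signed weights of frequently selected voxels as a 3-D volume.

    Per voxel: the mean weight over the models where it was selected
    (positive part, negative part, or their sum per ``sign``); voxels with
    selection frequency <= threshold are zeroed.
    """
    from .preprocess import weights_to_volume

    t = summary.voxel_table
    mp = np.nan_to_num(t["mean_pos"].to_numpy())
    mn = np.nan_to_num(t["mean_neg"].to_numpy())
    if sign == "positive":
        vals = mp
    elif sign == "negative":
        vals = mn
    elif sign == "both":
        vals = t["mean_signed"].to_numpy()
    else:
        raise ValueError("sign must be 'positive', 'negative' or 'both'")
    vals = np.where(t["frequency"].to_numpy() > threshold, vals, 0.0)
    return weights_to_volume(vals, voxel_index, shape, task=task)
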