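"""Voxel selection by combined face-selectivity and reliability.

Within each parcel, the selectivity statistic and the split-half reliability
are z-scored (population SD) and summed, v = v_s + v_r; the top fraction of
voxels by v is selected.  For whole-brain analyses, voxels more than k SDs
above the mean of v are selected.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = ["VoxelSelection", "parcel_select", "whole_brain_select", "zscore"]


def zscore(x: np.ndarray) -> np.ndarray:
    """Population z-score; constant input maps to all zeros with a warning."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        warnings.warn("constant scores: z set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


class VoxelSelection:
    """Per-voxel selection table: z-scored scores, combined metric, flags."""

    def __init__(self, v_s, v_r, v, selected, parcel):
        self.v_s = np.asarray(v_s, dtype=float)
        self.v_r = np.asarray(v_r, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.selected = np.asarray(selected, dtype=bool)
        self.parcel = np.asarray(parcel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": np.arange(len(self.v)),
                "parcel": self.parcel,
                "v_s": self.v_s,
                "v_r": self.v_r,
                "v": self.v,
                "selected": self.selected,
            }
        )


def _selectivity_score(selectivity: np.ndarray, is_p_value: bool) -> np.ndarray:
    """Larger = more face-selective.  Raw p-values are mapped through
    -log10(p) first so that small p (strong selectivity) ranks high."""
    s = np.asarray(selectivity, dtype=float)
    if is_p_value:
        s = -np.log10(np.clip(s, 1e-300, 1.0))
    return s


def parcel_select(
    selectivity: np.ndarray,
    reliability: np.ndarray,
    parcel_labels: np.ndarray,
    fraction: float = 0.10,
    selectivity_is_p_value: bool = False,
) -> VoxelSelection:
    """Select the top ``fraction`` of voxels per parcel by v = v_s + v_r.

    z-scoring is within-parcel; the count is ceil(fraction * parcel size);
    ties break by voxel index.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    s = _selectivity_score(selectivity, selectivity_is_p_value)
    r = np.asarray(reliability, dtype=float)
    parcels = np.asarray(parcel_labels)
    if not (len(s) == len(r) == len(parcels)):
        raise ValueError("selectivity, reliability and parcel_labels must align")
    n = len(s)
    v_s = np.zeros(n)
    v_r = np.zeros(n)
    selected = np.zeros(n, dtype=bool)
    for p in pd.unique(parcels):
        idx = np.flatnonzero(parcels == p)
        if len(idx) < 2:
            raise ValueError(f"parcel {p!r} has fewer than 2 voxels")
        v_s[idx] = zscore(s[idx])
        v_r[idx] = zscore(r[idx])
        v_p = v_s[idx] + v_r[idx]
        k = math.ceil(fraction * len(idx))
        # stable sort on -v gives deterministic index tie-breaking
        order = np.argsort(-v_p, kind="stable")
        selected[idx[order[:k]]] = True
    return VoxelSelection(v_s=v_s, v_r=v_r, v=v_s + v_r, selected=selected,
                          parcel=parcels)


def whole_brain_select(v: np.ndarray, k_sd: float = 1.5) -> np.ndarray:
    """Flag voxels with v > mean(v) + k_sd * sd(v)."""
    v = np.asarray(v, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 voxels")
    return v > v.mean() + k_sd * v.std()
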