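"""Preference mapping: per-dimension encoding predictions, ROI preference
profiles, and winner-take-all maps.

A voxel's prediction from dimension d alone is x_d * w_d + b; the dimension
with the highest held-out Spearman correlation is the voxel's preference
label.  Voxels whose best correlation is not positive get no winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import EncodingFit, spearman_columns

__all__ = ["PreferenceMap", "single_dim_predict", "preference_profile"]

NO_WINNER = -1  # exported winner label for voxels whose best r <= 0


@dataclass
class PreferenceMap:
    per_dim_r: np.ndarray  # voxels x dims
    winner: np.ndarray  # voxels, argmax dim (ties -> lowest index)
    best_r: np.ndarray  # voxels
    winner_exported: np.ndarray  # winner with NO_WINNER where best_r <= 0
    roi_profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": np.arange(len(self.winner)),
                "winner_dim": self.winner_exported,
                "best_r": self.best_r,
            }
        )


def single_dim_predict(
    fit: EncodingFit, test_latents: np.ndarray, d: int
) -> np.ndarray:
    """Prediction using only dimension d's weights plus the face bias."""
    X = np.asarray(test_latents, dtype=float)
    if not 0 <= d < fit.n_dims:
        raise ValueError(f"dimension {d} out of range for {fit.n_dims}-dim fit")
    return np.outer(X[:, d], fit.W[d]) + fit.b


def preference_profile(
    fit: EncodingFit,
    test_latents: np.ndarray,
    observed: np.ndarray,
    roi_labels: np.ndarray | None = None,
) -> PreferenceMap:
    """Spearman r per voxel per dimension, ROI mean profiles, and the
    winner-take-all label per voxel (argmax over dimensions, ties to the
    lowest index)."""
    observed = np.asarray(observed, dtype=float)
    n_vox = observed.shape[1]
    per_dim = np.zeros((n_vox, fit.n_dims))
    for d in range(fit.n_dims):
        pred = single_dim_predict(fit, test_latents, d)
        per_dim[:, d], _ = spearman_columns(pred, observed)
    winner = per_dim.argmax(axis=1)  # argmax takes the first maximum
    best = per_dim[np.arange(n_vox), winner]
    exported = np.where(best > 0, winner, NO_WINNER)

    roi_profiles: dict[str, np.ndarray] = {}
    if roi_labels is not None:
        roi_labels = np.asarray(roi_labels)
        for roi in pd.unique(roi_labels):
            roi_profiles[str(roi)] = per_dim[roi_labels == roi].mean(axis=0)
    return PreferenceMap(
        per_dim_r=per_dim,
        winner=winner,
        best_r=best,
        winner_exported=exported,
        roi_profiles=roi_profiles,
    )
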