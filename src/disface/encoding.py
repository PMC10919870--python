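"""Voxelwise encoding GLM: latent-value regressors, OLS fitting, held-out
prediction, Spearman evaluation, and split-half reliability.

Two design modes are supported.  In *amplitude* mode, rows are stimulus
presentations (or repeat-averaged stimuli) and each latent column carries
that stimulus's latent value — the parametric-modulation reading of
"weighted regressors".  In *hrf* mode, rows are time points and each latent
column is the HRF-convolved impulse train whose event amplitudes are the
latent values.  In both modes, the 20 test faces get indicator regressors
(so their single-trial structure does not bias the latent weights), plus a
constant face-bias column and, in hrf mode, per-run linear drift and motion
nuisance columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .hrf import convolve_events

__all__ = [
    "DesignMatrix",
    "EncodingFit",
    "PredictionResult",
    "build_design_amplitude",
    "build_design_hrf",
    "fit_glm",
    "predict_test",
    "evaluate",
    "split_half_reliability",
    "spearman_columns",
]


@dataclass
class DesignMatrix:
    values: np.ndarray  # observations x regressors
    column_roles: list[str]  # "latent:d" | "test_image:i" | "face_bias" |
    #                          "drift:run" | "motion:axis:run"
    mode: str  # "amplitude" | "hrf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.column_roles):
            raise ValueError("column_roles length must match design width")
        if sum(r == "face_bias" for r in self.column_roles) != 1:
            raise ValueError("design must contain exactly one face_bias column")

    @property
    def latent_columns(self) -> list[int]:
        return [i for i, r in enumerate(self.column_roles) if r.startswith("latent:")]


@dataclass
class EncodingFit:
    W: np.ndarray  # latent_dim x voxels
    b: np.ndarray  # voxels
    nuisance: dict[str, np.ndarray] = field(default_factory=dict)
    mode: str = "amplitude"

    @property
    def n_dims(self) -> int:
        return self.W.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.W.shape[1]


@dataclass
class PredictionResult:
    predicted: np.ndarray  # n_test x voxels
    per_voxel_r: np.ndarray  # voxels, Spearman across test images
    roi_means: dict[str, float] = field(default_factory=dict)
    constant_flags: np.ndarray | None = None


def build_design_amplitude(
    train_latents: np.ndarray, test_latents: np.ndarray | None = None
) -> DesignMatrix:
    """Design over presentations: training rows carry latent values, test
    rows carry an indicator per test image, all face rows carry the bias."""
    train_latents = np.asarray(train_latents, dtype=float)
    n_train, d = train_latents.shape
    n_test = 0 if test_latents is None else np.asarray(test_latents).shape[0]
    n = n_train + n_test
    X = np.zeros((n, d + n_test + 1))
    X[:n_train, :d] = train_latents
    for i in range(n_test):
        X[n_train + i, d + i] = 1.0
    X[:, -1] = 1.0  # face bias on every face row
    roles = [f"latent:{j}" for j in range(d)]
    roles += [f"test_image:{i}" for i in range(n_test)]
    roles += ["face_bias"]
    return DesignMatrix(values=X, column_roles=roles, mode="amplitude")


def build_design_hrf(
    runs: list[dict],
    latent_table: pd.DataFrame,
    test_ids: list[str],
    TR: float,
) -> DesignMatrix:
    """Design over time points, concatenated across runs.

    ``runs``: list of dicts with keys ``events`` (DataFrame: onset, duration,
    stimulus_id), ``n_timepoints`` (or ``series`` whose length is used), and
    optionally ``motion`` (3 x T traces).  ``latent_table``: training-stimulus
    latents indexed by stimulus_id.  Events whose stimulus_id is in
    ``test_ids`` get indicator regressors; any other stimulus must have a
    latent row.
    """
    d = latent_table.shape[1]
    test_index = {sid: i for i, sid in enumerate(test_ids)}
    n_runs = len(runs)
    n_tp = [
        r["n_timepoints"] if "n_timepoints" in r else r["series"].shape[0]
        for r in runs
    ]
    total = int(np.sum(n_tp))
    has_motion = any("motion" in r for r in runs)

    roles = [f"latent:{j}" for j in range(d)]
    roles += [f"test_image:{i}" for i in range(len(test_ids))]
    roles += ["face_bias"]
    roles += [f"drift:{r}" for r in range(n_runs)]
    if has_motion:
        for r in range(n_runs):
            roles += [f"motion:{ax}:{r}" for ax in "xyz"]
    X = np.zeros((total, len(roles)))
    col = {role: i for i, role in enumerate(roles)}

    offset = 0
    for r, run in enumerate(runs):
        T = n_tp[r]
        ev = run["events"]
        onsets = ev["onset"].to_numpy(dtype=float)
        sids = ev["stimulus_id"].tolist()
        is_test = np.array([s in test_index for s in sids])
        missing = [
            s for s, t in zip(sids, is_test) if not t and s not in latent_table.index
        ]
        if missing:
            raise ValueError(f"no latent row for stimulus {missing[0]!r}")

        train_onsets = onsets[~is_test]
        if len(train_onsets):
            amps = latent_table.loc[[s for s, t in zip(sids, is_test) if not t]]
            amps = amps.to_numpy(dtype=float)
            for j in range(d):
                X[offset : offset + T, col[f"latent:{j}"]] = convolve_events(
                    train_onsets, amps[:, j], T, TR
                )
        for sid, i in test_index.items():
            sel = [k for k, s in enumerate(sids) if s == sid]
            if sel:
                X[offset : offset + T, col[f"test_image:{i}"]] = convolve_events(
                    onsets[sel], np.ones(len(sel)), T, TR
                )
        X[offset : offset + T, col["face_bias"]] = 1.0
        X[offset : offset + T, col[f"drift:{r}"]] = np.linspace(-0.5, 0.5, T)
        if "motion" in run:
            for a, ax in enumerate("xyz"):
                X[offset : offset + T, col[f"motion:{ax}:{r}"]] = run["motion"][a]
        offset += T
    return DesignMatrix(values=X, column_roles=roles, mode="hrf")


def fit_glm(design: DesignMatrix, responses: np.ndarray) -> EncodingFit:
    """Per-voxel ordinary least squares.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning.  Residuals are orthogonal to the design columns up to numerical
    precision.
    """
    Y = np.asarray(responses, dtype=float)
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"responses have {Y.shape[0]} observations but design has {X.shape[0]}"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank-deficient (rank {rank} < {X.shape[1]} columns); "
            "using minimum-norm solution"
        )
    latent_idx = design.latent_columns
    W = beta[latent_idx]
    b = beta[design.column_roles.index("face_bias")]
    nuisance = {
        role: beta[i]
        for i, role in enumerate(design.column_roles)
        if not role.startswith("latent:") and role != "face_bias"
    }
    return EncodingFit(W=W, b=b, nuisance=nuisance, mode=design.mode)


def predict_test(fit: EncodingFit, test_latents: np.ndarray) -> np.ndarray:
    """Predicted voxel responses: X_test @ W + b (nuisance excluded)."""
    X = np.asarray(test_latents, dtype=float)
    if X.shape[1] != fit.n_dims:
        raise ValueError(
            f"test latents have {X.shape[1]} dims, fit expects {fit.n_dims}"
        )
    return X @ fit.W + fit.b


def spearman_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman correlation (rank then Pearson).

    Returns (r, constant_flags); columns constant in either input get r = 0
    and a flag instead of NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shapes must match")
    ra = rankdata(a, axis=0).astype(float)
    rb = rankdata(b, axis=0).astype(float)
    ra -= ra.mean(axis=0)
    rb -= rb.mean(axis=0)
    sa = ra.std(axis=0)
    sb = rb.std(axis=0)
    flags = (sa == 0) | (sb == 0)
    denom = np.where(flags, 1.0, sa * sb) * a.shape[0]
    r = np.einsum("ij,ij->j", ra, rb) / denom
    r[flags] = 0.0
    return r, flags


def evaluate(
    predicted: np.ndarray,
    observed: np.ndarray,
    roi_labels: np.ndarray | None = None,
) -> PredictionResult:
    """Per-voxel Spearman correlation between predicted and observed test
    responses, plus per-ROI mean r."""
    r, flags = spearman_columns(predicted, observed)
    if flags.any():
        warnings.warn(f"{int(flags.sum())} constant voxel(s): r recorded as 0")
    roi_means: dict[str, float] = {}
    if roi_labels is not None:
        roi_labels = np.asarray(roi_labels)
        for roi in pd.unique(roi_labels):
            roi_means[str(roi)] = float(r[roi_labels == roi].mean())
    return PredictionResult(
        predicted=np.asarray(predicted, dtype=float),
        per_voxel_r=r,
        roi_means=roi_means,
        constant_flags=flags,
    )


def split_half_reliability(
    trials: np.ndarray, n_splits: int = 100, seed: int = 0
) -> np.ndarray:
    """Split-half reliability of repeat-averaged test responses.

    ``trials``: (repeats, n_images, n_voxels).  Repeats are randomly split
    into two halves, each averaged, and the halves correlated (Spearman)
    across images per voxel; the result is averaged over ``n_splits``.
    """
    trials = np.asarray(trials, dtype=float)
    R = trials.shape[0]
    if R < 2:
        raise ValueError("need at least 2 repeats for split-half reliability")
    rng = np.random.default_rng(seed)
    acc = np.zeros(trials.shape[2])
    for _ in range(n_splits):
        perm = rng.permutation(R)
        h1 = trials[perm[: R // 2]].mean(axis=0)
        h2 = trials[perm[R // 2 :]].mean(axis=0)
        r, _ = spearman_columns(h1, h2)
        acc += r
    return acc / n_splits
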