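"""Permutation-based inference for encoding results.

All tests are resampling-based with add-one p-values,
p = (1 + #{null at least as extreme}) / (1 + resamples), so p is never 0.
Nulls: above-chance tests shuffle the 20 test-image labels of the observed
data; model comparisons swap the two models' predictions per test image;
ROI comparisons shuffle the voxel-to-ROI assignment.  Group-level tests
average the subject statistics and the subjects' aligned null samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PermutationResult",
    "perm_test_above_chance",
    "perm_test_model_diff",
    "perm_test_roi_diff",
    "group_level",
]

DEFAULT_RESAMPLES = 1000


@dataclass
class PermutationResult:
    observed: float
    null_samples: np.ndarray = field(repr=False)
    p_value: float
    tail: str  # "one" | "two"
    level: str = "individual"  # "individual" | "group"

    @property
    def resamples(self) -> int:
        return len(self.null_samples)


def _add_one_p(observed: float, null: np.ndarray, tail: str) -> float:
    if tail == "one":
        exceed = int(np.sum(null >= observed))
    elif tail == "two":
        exceed = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + exceed) / (1 + len(null))


def _std_ranks(M: np.ndarray) -> np.ndarray:
    """Column-standardized ranks, so r = mean of elementwise products."""
    R = rankdata(M, axis=0).astype(float)
    R -= R.mean(axis=0)
    sd = R.std(axis=0)
    sd[sd == 0] = np.inf  # constant columns contribute r = 0
    return R / sd


def _mean_spearman(Zp: np.ndarray, Zo: np.ndarray) -> float:
    """Mean over voxels of Spearman r, given standardized rank matrices."""
    return float(np.mean(np.einsum("ij,ij->j", Zp, Zo)) / Zp.shape[0])


def perm_test_above_chance(
    predicted: np.ndarray,
    observed: np.ndarray,
    resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
) -> PermutationResult:
    """Is the mean (over voxels) Spearman correlation between predicted and
    observed test responses above chance?  Null: permute the test-image
    labels of the observed data; one-tailed."""
    if resamples < 100:
        raise ValueError("resamples must be >= 100")
    Zp = _std_ranks(np.asarray(predicted, dtype=float))
    Zo = _std_ranks(np.asarray(observed, dtype=float))
    obs = _mean_spearman(Zp, Zo)
    rng = np.random.default_rng(seed)
    n = Zo.shape[0]
    null = np.array(
        [_mean_spearman(Zp, Zo[rng.permutation(n)]) for _ in range(resamples)]
    )
    return PermutationResult(
        observed=obs, null_samples=null, p_value=_add_one_p(obs, null, "one"),
        tail="one",
    )


def perm_test_model_diff(
    predsA: np.ndarray,
    predsB: np.ndarray,
    observed: np.ndarray,
    resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
) -> PermutationResult:
    """Difference in mean prediction correlation between two models.

    Null: for each test image, randomly swap which model's prediction row is
    attributed to A vs B; two-tailed."""
    if resamples < 100:
        raise ValueError("resamples must be >= 100")
    A = np.asarray(predsA, dtype=float)
    B = np.asarray(predsB, dtype=float)
    O = np.asarray(observed, dtype=float)
    if not (A.shape == B.shape == O.shape):
        raise ValueError("predsA, predsB and observed must share a shape")
    Zo = _std_ranks(O)
    n = A.shape[0]

    def stat(a, b):
        return _mean_spearman(_std_ranks(a), Zo) - _mean_spearman(_std_ranks(b), Zo)

    obs = stat(A, B)
    rng = np.random.default_rng(seed)
    null = np.empty(resamples)
    for i in range(resamples):
        swap = rng.random(n) < 0.5
        A2 = np.where(swap[:, None], B, A)
        B2 = np.where(swap[:, None], A, B)
        null[i] = stat(A2, B2)
    return PermutationResult(
        observed=obs, null_samples=null, p_value=_add_one_p(obs, null, "two"),
        tail="two",
    )


def perm_test_roi_diff(
    per_voxel_r: np.ndarray,
    roi_labels: np.ndarray,
    roi_a,
    roi_b,
    resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
) -> PermutationResult:
    """Difference in mean per-voxel prediction r between two ROIs.

    Null: shuffle the ROI assignment of the pooled voxels; two-tailed."""
    if resamples < 100:
        raise ValueError("resamples must be >= 100")
    r = np.asarray(per_voxel_r, dtype=float)
    labels = np.asarray(roi_labels)
    ia = np.flatnonzero(labels == roi_a)
    ib = np.flatnonzero(labels == roi_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both ROIs must contain voxels")
    pooled = np.concatenate([r[ia], r[ib]])
    na = len(ia)
    obs = float(pooled[:na].mean() - pooled[na:].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(resamples)
    for i in range(resamples):
        p = rng.permutation(pooled)
        null[i] = p[:na].mean() - p[na:].mean()
    return PermutationResult(
        observed=obs, null_samples=null, p_value=_add_one_p(obs, null, "two"),
        tail="two",
    )


def group_level(results: list[PermutationResult]) -> PermutationResult:
    """Group statistic = mean over subjects; group null sample i = mean over
    subjects of each subject's i-th null sample."""
    if len(results) == 0:
        raise ValueError("group_level requires at least one subject result")
    if len(results) == 1:
        import warnings

        warnings.warn("group_level with a single subject equals the individual test")
    lengths = {r.resamples for r in results}
    if len(lengths) != 1:
        raise ValueError(f"mismatched resample counts across subjects: {lengths}")
    tails = {r.tail for r in results}
    if len(tails) != 1:
        raise ValueError("subjects were tested with different tails")
    tail = tails.pop()
    obs = float(np.mean([r.observed for r in results]))
    null = np.mean([r.null_samples for r in results], axis=0)
    return PermutationResult(
        observed=obs, null_samples=null, p_value=_add_one_p(obs, null, tail),
        tail=tail, level="group",
    )
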