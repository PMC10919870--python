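"""Identity decoding: pseudo-inverse recovery of latents from voxel
responses and pairwise foil comparison over dimension subsets.

Decoding inverts the fitted encoding map: x_hat = pinv(W) applied to the
bias-corrected test responses.  Identity is then scored pairwise: a test
image is decoded correctly against a foil if its decoded latents correlate
more with its own true latents than with the foil's.  With 20 test images
and every other image as foil this yields 20*19 = 380 ordered comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .encoding import EncodingFit

__all__ = [
    "DecodedLatents",
    "DecodingResult",
    "decode_latents",
    "pairwise_identity_accuracy",
    "subset_battery",
    "classify_dimensions",
]


@dataclass
class DecodedLatents:
    x_hat: np.ndarray  # n_test x latent_dim


@dataclass
class DecodingResult:
    accuracy: float
    n_comparisons: int
    subset_name: str = "all"
    per_pair: np.ndarray | None = field(default=None, repr=False)


def decode_latents(fit: EncodingFit, y: np.ndarray) -> DecodedLatents:
    """x_hat = pinv(W) (y - b), using the Moore-Penrose pseudo-inverse of the
    latent_dim x voxels weight matrix."""
    y = np.asarray(y, dtype=float)
    if y.shape[1] != fit.n_voxels:
        raise ValueError(
            f"responses have {y.shape[1]} voxels, fit expects {fit.n_voxels}"
        )
    if fit.n_voxels < fit.n_dims:
        warnings.warn(
            f"decoding {fit.n_dims} dims from only {fit.n_voxels} voxels: "
            "the pseudo-inverse is underdetermined"
        )
    return DecodedLatents(x_hat=(y - fit.b) @ np.linalg.pinv(fit.W))


def _corr_rows(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Correlation of every row of ``a`` with every row of ``b`` -> (na, nb).
    Rows that are constant yield NaN (handled by the caller)."""
    if method == "spearman":
        a = rankdata(a, axis=1).astype(float)
        b = rankdata(b, axis=1).astype(float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(a, axis=1)
    sb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (a @ b.T) / np.outer(sa, sb)
    c[sa == 0, :] = np.nan
    c[:, sb == 0] = np.nan
    return c


def pairwise_identity_accuracy(
    x_hat: np.ndarray | DecodedLatents,
    x_true: np.ndarray,
    subset: list[int] | np.ndarray | None = None,
    subset_name: str = "all",
    method: str = "pearson",
) -> DecodingResult:
    """Pairwise foil decoding over a dimension subset.

    For every ordered (target, foil) pair, target != foil: correct iff
    corr(x_hat[target], x_true[target]) > corr(x_hat[target], x_true[foil]);
    exact ties count 0.5.  Pairs involving a constant subset vector are
    skipped with a warning and excluded from the denominator.
    """
    if isinstance(x_hat, DecodedLatents):
        x_hat = x_hat.x_hat
    x_hat = np.asarray(x_hat, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    if x_hat.shape != x_true.shape:
        raise ValueError("x_hat and x_true must have matching shapes")
    if subset is None:
        subset = np.arange(x_true.shape[1])
    subset = np.asarray(subset, dtype=int)
    if subset.size < 2:
        raise ValueError("subset must contain at least 2 dimensions")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    C = _corr_rows(x_hat[:, subset], x_true[:, subset], method)
    n = x_hat.shape[0]
    own = np.diag(C)
    correct = np.where(own[:, None] > C, 1.0, np.where(own[:, None] == C, 0.5, 0.0))
    valid = ~np.isnan(own[:, None]) & ~np.isnan(C)
    np.fill_diagonal(valid, False)
    n_valid = int(valid.sum())
    n_total = n * (n - 1)
    if n_valid < n_total:
        warnings.warn(
            f"{n_total - n_valid} pair(s) skipped: constant subset vector(s)"
        )
    if n_valid == 0:
        raise ValueError("no valid pairs: all subset vectors constant")
    acc = float(correct[valid].sum() / n_valid)
    return DecodingResult(
        accuracy=acc,
        n_comparisons=n_valid,
        subset_name=subset_name,
        per_pair=np.where(valid, correct, np.nan),
    )


def subset_battery(
    x_hat: np.ndarray | DecodedLatents,
    x_true: np.ndarray,
    subsets: dict[str, list[int] | np.ndarray],
    method: str = "pearson",
) -> list[DecodingResult]:
    """One pairwise decoding result per named dimension subset (e.g.
    identity_relevant / identity_irrelevant / entangled / all)."""
    results = []
    for name, idx in subsets.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"subset {name!r} is empty")
        results.append(
            pairwise_identity_accuracy(
                x_hat, x_true, subset=idx, subset_name=name, method=method
            )
        )
    return results


def classify_dimensions(
    importance: np.ndarray,
    factor_relevant: np.ndarray,
    gap_threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Assign each latent dimension to a subset from its factor-importance
    profile: a dimension whose top factor dominates (gap over the runner-up
    above ``gap_threshold``) is labeled by that factor's identity relevance;
    otherwise it is 'entangled'.  Returns index arrays for the standard
    subsets."""
    imp = np.asarray(importance, dtype=float)
    rel = np.asarray(factor_relevant, dtype=bool)
    relevant, irrelevant, entangled = [], [], []
    for l in range(imp.shape[0]):
        row = np.sort(imp[l])[::-1]
        top = row[0]
        gap = 0.0 if top == 0 else (top - (row[1] if len(row) > 1 else 0.0)) / top
        if gap < gap_threshold:
            entangled.append(l)
        elif rel[imp[l].argmax()]:
            relevant.append(l)
        else:
            irrelevant.append(l)
    out = {
        "identity_relevant": np.array(relevant, dtype=int),
        "identity_irrelevant": np.array(irrelevant, dtype=int),
        "entangled": np.array(entangled, dtype=int),
        "all": np.arange(imp.shape[0]),
    }
    if len(relevant) and len(entangled):
        out["relevant+entangled"] = np.array(sorted(relevant + entangled), dtype=int)
    return out
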