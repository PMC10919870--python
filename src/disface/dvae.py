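"""Disentangled variational autoencoders: β-VAE and FactorVAE objectives,
the published hyperparameter grid, latent traversals, and supervised
disentanglement scoring for model selection.

The encoder/decoder are fully connected multilayer perceptrons over
flattened grayscale images, trained by hand-written backpropagation with
Adam on the CPU.  The reconstruction likelihood is Bernoulli on [0,1]
pixels; the prior is a unit Gaussian.  FactorVAE adds a total-correlation
penalty estimated by a small discriminator via the density-ratio trick on
dimension-permuted latent batches.

Objectives (per image, summed over pixels / latent dimensions):

    beta-VAE:    L = recon + beta * KL(q(z|x) || N(0,I))
    FactorVAE:   L = recon + KL + gamma * TC_hat(z)

so a FactorVAE with gamma = 0 is exactly a beta-VAE with beta = 1 (a
standard VAE).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
from scipy.stats import rankdata

from .nn import Adam, drelu, glorot, relu, sigmoid, softplus

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "LatentMatrix",
    "encode",
    "decode",
    "extract_latents",
    "loss_terms",
    "train",
    "hyperparameter_grid",
    "full_grid",
    "latent_traversal",
    "write_traversal_gif",
    "disentanglement_score",
    "select_model",
]

FULL_LATENT_DIMS = (24, 32, 48, 64)
FULL_BETAS = (1, 2, 4, 6, 8, 16)
FULL_GAMMAS = (0, 10, 20, 30, 40, 50, 100)
FULL_N_SEEDS = 10
TRAVERSAL_RANGE = (-2.0, 2.0)


@dataclass(frozen=True)
class ModelConfig:
    family: str = "factor_vae"  # "beta_vae" | "factor_vae"
    latent_dim: int = 8
    beta: float = 1.0
    gamma: float = 10.0
    seed: int = 0
    epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    image_side: int = 32
    hidden: tuple[int, int] = (256, 128)
    disc_hidden: int = 64

    def __post_init__(self) -> None:
        if self.family not in ("beta_vae", "factor_vae"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.family == "beta_vae" and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def is_standard_vae(self) -> bool:
        """True for the configurations whose objective is the plain ELBO:
        a beta-VAE with beta = 1, equivalently a FactorVAE with gamma = 0."""
        return (self.family == "beta_vae" and self.beta == 1) or (
            self.family == "factor_vae" and self.gamma == 0
        )


@dataclass
class TrainedModel:
    params: dict
    disc_params: dict | None
    config: ModelConfig
    training_log: list[dict] = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return self.config.image_side**2


@dataclass
class LatentMatrix:
    """Posterior means for a stimulus set: stimuli x latent_dim."""

    values: np.ndarray
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.stimulus_ids):
            raise ValueError("row count must equal number of stimulus ids")


# ---------------------------------------------------------------------------
# parameter initialization and forward/backward passes


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict:
    p_in = config.image_side**2
    h1, h2 = config.hidden
    k = config.latent_dim
    # the posterior heads start at zero so an untrained model emits the prior
    return {
        "W1": glorot(rng, p_in, h1), "b1": np.zeros(h1),
        "W2": glorot(rng, h1, h2), "b2": np.zeros(h2),
        "Wm": np.zeros((h2, k)), "bm": np.zeros(k),
        "Wv": np.zeros((h2, k)), "bv": np.zeros(k),
        "V1": glorot(rng, k, h2), "c1": np.zeros(h2),
        "V2": glorot(rng, h2, h1), "c2": np.zeros(h1),
        "V3": glorot(rng, h1, p_in), "c3": np.zeros(p_in),
    }


def _init_disc(config: ModelConfig, rng: np.random.Generator) -> dict:
    k, h = config.latent_dim, config.disc_hidden
    return {
        "D1": glorot(rng, k, h), "e1": np.zeros(h),
        "D2": glorot(rng, h, h), "e2": np.zeros(h),
        "D3": glorot(rng, h, 1), "e3": np.zeros(1),
    }


def _enc_forward(p: dict, x: np.ndarray):
    a1 = x @ p["W1"] + p["b1"]
    h1 = relu(a1)
    a2 = h1 @ p["W2"] + p["b2"]
    h2 = relu(a2)
    mu = h2 @ p["Wm"] + p["bm"]
    logvar = h2 @ p["Wv"] + p["bv"]
    return mu, logvar, (x, a1, h1, a2, h2)


def _dec_forward(p: dict, z: np.ndarray):
    a1 = z @ p["V1"] + p["c1"]
    g1 = relu(a1)
    a2 = g1 @ p["V2"] + p["c2"]
    g2 = relu(a2)
    logits = g2 @ p["V3"] + p["c3"]
    return logits, (z, a1, g1, a2, g2)


def _disc_forward(dp: dict, z: np.ndarray):
    a1 = z @ dp["D1"] + dp["e1"]
    h1 = relu(a1)
    a2 = h1 @ dp["D2"] + dp["e2"]
    h2 = relu(a2)
    logit = (h2 @ dp["D3"] + dp["e3"])[:, 0]
    return logit, (z, a1, h1, a2, h2)


def _disc_backward(dp: dict, cache, dlogit: np.ndarray, want_input_grad: bool):
    """Backprop through the discriminator; returns (param grads, dz)."""
    z, a1, h1, a2, h2 = cache
    g3 = dlogit[:, None]
    grads = {
        "D3": h2.T @ g3, "e3": g3.sum(axis=0),
    }
    dh2 = g3 @ dp["D3"].T
    da2 = dh2 * drelu(a2)
    grads["D2"] = h1.T @ da2
    grads["e2"] = da2.sum(axis=0)
    dh1 = da2 @ dp["D2"].T
    da1 = dh1 * drelu(a1)
    grads["D1"] = z.T @ da1
    grads["e1"] = da1.sum(axis=0)
    dz = da1 @ dp["D1"].T if want_input_grad else None
    return grads, dz


def _kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Closed-form KL(q || N(0,I)) per sample, summed over dimensions."""
    return 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)


def _vae_losses(params: dict, x: np.ndarray, eps: np.ndarray):
    """Forward pass returning per-batch mean losses and all caches."""
    mu, logvar, enc_cache = _enc_forward(params, x)
    z = mu + eps * np.exp(0.5 * logvar)
    logits, dec_cache = _dec_forward(params, z)
    # Bernoulli negative log-likelihood, summed over pixels, mean over batch
    recon = np.mean(np.sum(softplus(logits) - x * logits, axis=1))
    kl = float(np.mean(_kl_gaussian(mu, logvar)))
    return recon, kl, mu, logvar, z, logits, enc_cache, dec_cache


def _vae_backward(params: dict, x, eps, mu, logvar, z, logits,
                  enc_cache, dec_cache, kl_weight: float, dz_extra=None):
    """Gradients of mean(recon) + kl_weight*mean(KL) (+ dz_extra path)."""
    B = x.shape[0]
    grads = {}

    dlogits = (sigmoid(logits) - x) / B
    _, a1d, g1, a2d, g2 = dec_cache
    grads["V3"] = g2.T @ dlogits
    grads["c3"] = dlogits.sum(axis=0)
    dg2 = dlogits @ params["V3"].T
    da2 = dg2 * drelu(a2d)
    grads["V2"] = g1.T @ da2
    grads["c2"] = da2.sum(axis=0)
    dg1 = da2 @ params["V2"].T
    da1 = dg1 * drelu(a1d)
    grads["V1"] = z.T @ da1
    grads["c1"] = da1.sum(axis=0)
    dz = da1 @ params["V1"].T
    if dz_extra is not None:
        dz = dz + dz_extra

    # reparameterization: z = mu + eps*exp(logvar/2)
    dmu = dz + kl_weight * mu / B
    dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar) + kl_weight * 0.5 * (
        np.exp(logvar) - 1.0
    ) / B

    xin, a1e, h1, a2e, h2 = enc_cache
    grads["Wm"] = h2.T @ dmu
    grads["bm"] = dmu.sum(axis=0)
    grads["Wv"] = h2.T @ dlogvar
    grads["bv"] = dlogvar.sum(axis=0)
    dh2 = dmu @ params["Wm"].T + dlogvar @ params["Wv"].T
    da2 = dh2 * drelu(a2e)
    grads["W2"] = h1.T @ da2
    grads["b2"] = da2.sum(axis=0)
    dh1 = da2 @ params["W2"].T
    da1 = dh1 * drelu(a1e)
    grads["W1"] = xin.T @ da1
    grads["b1"] = da1.sum(axis=0)
    return grads


def _as_batch(images: np.ndarray, side: int) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.size == 0:
        raise ValueError("batch must be nonempty")
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] != (side, side):
        raise ValueError(
            f"images of shape {images.shape[1:]} do not match configured side {side}"
        )
    return images.reshape(images.shape[0], -1)


# ---------------------------------------------------------------------------
# public operations


def encode(model: TrainedModel, image: np.ndarray):
    """Posterior (mean, log-variance) for one image or a batch."""
    x = _as_batch(image, model.config.image_side)
    mu, logvar, _ = _enc_forward(model.params, x)
    if np.asarray(image).ndim == 2:
        return mu[0], logvar[0]
    return mu, logvar


def decode(model: TrainedModel, z: np.ndarray) -> np.ndarray:
    """Decode latent vectors to images (Bernoulli means in [0,1])."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    logits, _ = _dec_forward(model.params, z)
    side = model.config.image_side
    return sigmoid(logits).reshape(-1, side, side)


def extract_latents(
    model: TrainedModel, images: np.ndarray, stimulus_ids: list[str] | None = None
) -> LatentMatrix:
    """Posterior means for a stimulus set (the encoding-model regressors)."""
    mu, _ = encode(model, np.asarray(images))
    mu = np.atleast_2d(mu)
    if stimulus_ids is None:
        stimulus_ids = [f"stim_{i:05d}" for i in range(mu.shape[0])]
    return LatentMatrix(values=mu, stimulus_ids=list(stimulus_ids))


def loss_terms(model: TrainedModel, batch: np.ndarray, seed: int = 0) -> dict:
    """Reconstruction, KL-to-prior, TC estimate and the family objective on a
    batch, with the reparameterization noise drawn from ``seed``."""
    x = _as_batch(batch, model.config.image_side)
    if x.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((x.shape[0], model.config.latent_dim))
    recon, kl, mu, logvar, z, logits, _, _ = _vae_losses(model.params, x, eps)
    cfg = model.config
    if cfg.family == "factor_vae" and cfg.gamma > 0:
        if model.disc_params is None:
            raise ValueError("FactorVAE with gamma > 0 requires a discriminator")
        logit, _ = _disc_forward(model.disc_params, z)
        tc = float(np.mean(logit))
        objective = recon + kl + cfg.gamma * tc
    else:
        tc = 0.0
        beta = cfg.beta if cfg.family == "beta_vae" else 1.0
        objective = recon + beta * kl
    return {
        "reconstruction": float(recon),
        "kl_to_prior": float(kl),
        "total_correlation": tc,
        "objective": float(objective),
    }


def kl_to_prior(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Closed-form Gaussian KL per posterior (public for diagnostics)."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    return _kl_gaussian(mu, logvar)


def train(config: ModelConfig, images: np.ndarray) -> TrainedModel:
    """Train a VAE on a stack of grayscale images.

    10% of the images are held out; the per-epoch log records the training
    loss terms and the held-out reconstruction loss.  Divergent training
    (non-finite loss) aborts with a diagnostic.
    """
    x_all = _as_batch(images, config.image_side)
    n = x_all.shape[0]
    if n < 2:
        raise ValueError("need at least 2 images to train")
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    use_tc = config.family == "factor_vae" and config.gamma > 0
    disc = _init_disc(config, rng) if use_tc else None

    n_hold = max(1, n // 10)
    perm = rng.permutation(n)
    hold, tr = x_all[perm[:n_hold]], x_all[perm[n_hold:]]
    opt = Adam(params, lr=config.learning_rate)
    dopt = Adam(disc, lr=config.learning_rate) if use_tc else None
    kl_weight = config.beta if config.family == "beta_vae" else 1.0
    k = config.latent_dim
    log: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(tr.shape[0])
        ep_recon, ep_kl, ep_tc, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, tr.shape[0], config.batch_size):
            xb = tr[order[start : start + config.batch_size]]
            if xb.shape[0] < 2:
                continue
            eps = rng.standard_normal((xb.shape[0], k))
            recon, kl, mu, logvar, z, logits, ec, dc = _vae_losses(params, xb, eps)
            if not (np.isfinite(recon) and np.isfinite(kl)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: recon={recon}, kl={kl}"
                )
            dz_extra = None
            tc = 0.0
            if use_tc:
                logit, cache = _disc_forward(disc, z)
                tc = float(np.mean(logit))
                # VAE gradient of gamma * mean(logit) through z
                _, dz_extra = _disc_backward(
                    disc, cache, np.full(z.shape[0], config.gamma / z.shape[0]), True
                )
            grads = _vae_backward(
                params, xb, eps, mu, logvar, z, logits, ec, dc, kl_weight, dz_extra
            )
            opt.step(params, grads)

            if use_tc:
                # discriminator update: real z vs dimension-permuted z
                z_d = z.copy()
                z_perm = np.column_stack(
                    [z_d[rng.permutation(z_d.shape[0]), j] for j in range(k)]
                )
                both = np.vstack([z_d, z_perm])
                labels = np.concatenate(
                    [np.ones(z_d.shape[0]), np.zeros(z_perm.shape[0])]
                )
                logit_b, cache_b = _disc_forward(disc, both)
                dlogit = (sigmoid(logit_b) - labels) / both.shape[0]
                dgrads, _ = _disc_backward(disc, cache_b, dlogit, False)
                dopt.step(disc, dgrads)

            ep_recon += recon
            ep_kl += kl
            ep_tc += tc
            nb += 1

        eps_h = rng.standard_normal((hold.shape[0], k))
        h_recon, h_kl, *_ = _vae_losses(params, hold, eps_h)
        log.append(
            {
                "epoch": epoch,
                "reconstruction": ep_recon / max(nb, 1),
                "kl": ep_kl / max(nb, 1),
                "tc": ep_tc / max(nb, 1),
                "holdout_reconstruction": float(h_recon),
            }
        )

    return TrainedModel(params=params, disc_params=disc, config=config,
                        training_log=log)


def hyperparameter_grid(
    base: ModelConfig | None = None,
    latent_dims: tuple[int, ...] = FULL_LATENT_DIMS,
    betas: tuple[float, ...] = FULL_BETAS,
    gammas: tuple[float, ...] = FULL_GAMMAS,
    n_seeds: int = FULL_N_SEEDS,
) -> list[ModelConfig]:
    """Cross product of families x latent dims x disentanglement values x
    seeds.  The gamma = 0 FactorVAE cell is the beta = 1 beta-VAE (a standard
    VAE), so it appears once — tagged beta_vae — rather than being duplicated.
    """
    if base is None:
        base = ModelConfig()
    configs: list[ModelConfig] = []
    for k, beta, seed in product(latent_dims, betas, range(n_seeds)):
        configs.append(
            ModelConfig(family="beta_vae", latent_dim=k, beta=float(beta),
                        gamma=0.0, seed=seed, epochs=base.epochs,
                        batch_size=base.batch_size,
                        learning_rate=base.learning_rate,
                        image_side=base.image_side, hidden=base.hidden)
        )
    for k, gamma, seed in product(latent_dims, gammas, range(n_seeds)):
        if gamma == 0:
            continue  # aliased to the beta=1 beta-VAE cell above
        configs.append(
            ModelConfig(family="factor_vae", latent_dim=k, beta=1.0,
                        gamma=float(gamma), seed=seed, epochs=base.epochs,
                        batch_size=base.batch_size,
                        learning_rate=base.learning_rate,
                        image_side=base.image_side, hidden=base.hidden)
        )
    return configs


def full_grid(base: ModelConfig | None = None) -> list[ModelConfig]:
    """The full published search: 240 beta-VAE + 240 FactorVAE configurations
    (gamma = 0 aliased)."""
    return hyperparameter_grid(base)


def latent_traversal(
    model: TrainedModel,
    image: np.ndarray,
    dim: int,
    lo: float = TRAVERSAL_RANGE[0],
    hi: float = TRAVERSAL_RANGE[1],
    steps: int = 9,
) -> np.ndarray:
    """Decode a sweep of one latent dimension, all others held at the image's
    posterior mean.  Returns (steps, side, side)."""
    k = model.config.latent_dim
    if not 0 <= dim < k:
        raise ValueError(f"dim {dim} out of range for latent_dim {k}")
    mu, _ = encode(model, image)
    mu = np.atleast_2d(mu)[0]
    zs = np.tile(mu, (steps, 1))
    zs[:, dim] = np.linspace(lo, hi, steps) if steps > 1 else [mu[dim]]
    return decode(model, zs)


def write_traversal_gif(model: TrainedModel, image: np.ndarray, dim: int,
                        path: str, lo: float = TRAVERSAL_RANGE[0],
                        hi: float = TRAVERSAL_RANGE[1], steps: int = 9,
                        fps: int = 5) -> None:
    import imageio.v3 as iio

    frames = latent_traversal(model, image, dim, lo, hi, steps)
    frames8 = (np.clip(frames, 0, 1) * 255).astype(np.uint8)
    iio.imwrite(path, frames8, extension=".gif", duration=1000 // fps, loop=0)


def disentanglement_score(
    latents: np.ndarray | LatentMatrix, true_factors: np.ndarray
) -> tuple[float, np.ndarray]:
    """Supervised disentanglement gap score with its importance matrix.

    importance[l, f] = |Spearman correlation| between latent l and factor f.
    For each factor, the gap is (largest - second largest importance) /
    largest over latents; the score is the mean gap over factors.  It is 1
    exactly when every factor aligns with a unique latent with zero
    cross-talk, and 0 when all latents carry every factor equally.
    """
    if isinstance(latents, LatentMatrix):
        latents = latents.values
    L = np.asarray(latents, dtype=float)
    F = np.asarray(true_factors, dtype=float)
    if L.shape[0] != F.shape[0]:
        raise ValueError("latents and factors must have matching row counts")
    if F.shape[1] < 2:
        raise ValueError("need at least 2 factors")

    def _std_ranks(M):
        R = rankdata(M, axis=0).astype(float)
        R -= R.mean(axis=0)
        sd = R.std(axis=0)
        return R, sd

    RL, sdL = _std_ranks(L)
    RF, sdF = _std_ranks(F)
    if np.any(sdL == 0):
        warnings.warn("constant latent column(s): importances set to 0")
    denom = np.outer(np.where(sdL == 0, np.inf, sdL), sdF) * L.shape[0]
    imp = np.abs(RL.T @ RF) / denom  # (n_latents, n_factors)

    gaps = []
    for f in range(imp.shape[1]):
        col = np.sort(imp[:, f])[::-1]
        top = col[0]
        second = col[1] if len(col) > 1 else 0.0
        gaps.append(0.0 if top == 0 else (top - second) / top)
    return float(np.mean(gaps)), imp


def select_model(results: list[tuple[ModelConfig, float]]) -> ModelConfig:
    """Pick the configuration with the highest disentanglement score; ties
    broken by smaller latent_dim, then smaller seed."""
    if not results:
        raise ValueError("select_model requires at least one scored model")
    return min(results, key=lambda cs: (-cs[1], cs[0].latent_dim, cs[0].seed))[0]


def save_config(config: ModelConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)


def load_config(path: str) -> ModelConfig:
    with open(path) as fh:
        d = json.load(fh)
    d["hidden"] = tuple(d["hidden"])
    return ModelConfig(**d)
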