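"""Simulated voxel responses with known ground truth.

Voxels are linear in the stimulus latents: a presentation of a stimulus with
latent vector x evokes y = x @ W* + b* + noise.  The time-series form adds
HRF convolution, per-run linear drift, motion-trace contributions and white
noise — the exact generative mirror of the encoding GLM, so noiseless
recovery is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..hrf import convolve_events

__all__ = [
    "GroundTruthEncoding",
    "SimulatedSession",
    "LocalizerStats",
    "make_ground_truth",
    "simulate_responses",
    "simulate_timeseries",
    "simulate_localizer",
    "STIM_DURATION",
    "ISI",
]

STIM_DURATION = 1.0  # seconds a face stays on screen
ISI = 2.0  # inter-stimulus interval, so one face every 3 s


@dataclass
class GroundTruthEncoding:
    """True generative parameters of the simulated voxels."""

    W_star: np.ndarray  # (n_dims, n_voxels)
    b_star: np.ndarray  # (n_voxels,) constant baseline / face bias
    drift_coefs: np.ndarray  # (n_runs, n_voxels) slope per run
    motion_coefs: np.ndarray  # (3, n_voxels)
    noise_sd: np.ndarray  # (n_voxels,) > 0
    sparsity_plan: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W_star = np.asarray(self.W_star, dtype=float)
        self.b_star = np.asarray(self.b_star, dtype=float)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_voxels,)
        ).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive for every voxel")
        d = self.W_star.shape[0]
        for v, dims in enumerate(self.sparsity_plan):
            if any(not 0 <= j < d for j in dims):
                raise ValueError(f"sparsity plan for voxel {v} has invalid dims {dims}")
            if len(dims) == 1:
                nz = np.flatnonzero(self.W_star[:, v])
                if nz.tolist() != dims:
                    raise ValueError(
                        f"voxel {v} declared single-dimension on {dims} but W* column "
                        f"has nonzeros at {nz.tolist()}"
                    )

    @property
    def n_dims(self) -> int:
        return self.W_star.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.W_star.shape[1]


def make_ground_truth(
    n_dims: int,
    n_voxels: int,
    seed: int = 0,
    single_dim_fraction: float = 0.5,
    signal_sd: float = 1.0,
    noise_sd: float = 0.1,
    n_runs: int = 1,
) -> GroundTruthEncoding:
    """Random ground truth: a mix of single-dimension voxels (one nonzero
    weight) and mixed voxels (dense weights), with drift/motion nuisance."""
    rng = np.random.default_rng(seed)
    n_single = int(round(single_dim_fraction * n_voxels))
    W = np.zeros((n_dims, n_voxels))
    plan: list[list[int]] = []
    for v in range(n_voxels):
        if v < n_single:
            d = int(rng.integers(n_dims))
            # magnitude bounded away from 0 so the driving dim is identifiable
            W[d, v] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5) * signal_sd
            plan.append([d])
        else:
            W[:, v] = rng.normal(0.0, signal_sd / np.sqrt(n_dims), size=n_dims)
            plan.append(list(range(n_dims)))
    return GroundTruthEncoding(
        W_star=W,
        b_star=rng.normal(0.0, 0.5, size=n_voxels),
        drift_coefs=rng.normal(0.0, 0.05, size=(n_runs, n_voxels)),
        motion_coefs=rng.normal(0.0, 0.1, size=(3, n_voxels)),
        noise_sd=np.full(n_voxels, float(noise_sd)),
        sparsity_plan=plan,
    )


def simulate_responses(
    latents: np.ndarray,
    truth: GroundTruthEncoding,
    repeats: int = 1,
    seed: int = 0,
    return_trials: bool = False,
):
    """Repeat-averaged responses to a stimulus set.

    Each presentation r of stimulus i gives ``y = x_i @ W* + b* + eps`` with
    i.i.d. Gaussian noise per voxel; the returned matrix averages over the
    ``repeats`` presentations.  With ``return_trials`` the full
    (repeats, n_stim, n_voxels) array is returned too (needed for split-half
    reliability).
    """
    latents = np.asarray(latents, dtype=float)
    if latents.ndim != 2 or latents.shape[1] != truth.n_dims:
        raise ValueError(
            f"latents shape {latents.shape} incompatible with W* "
            f"({truth.n_dims} dims expected)"
        )
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    clean = latents @ truth.W_star + truth.b_star
    trials = clean[None, :, :] + rng.normal(
        0.0, truth.noise_sd, size=(repeats,) + clean.shape
    )
    averaged = trials.mean(axis=0)
    if return_trials:
        return averaged, trials
    return averaged


@dataclass
class SimulatedSession:
    """Run-wise voxel time series with events and motion, plus averages."""

    runs: list[dict]  # each: {"series", "events", "motion"}
    TR: float
    averaged_test: np.ndarray  # (20, n_voxels)
    averaged_train: np.ndarray  # (n_train, n_voxels)


def simulate_timeseries(
    train_latents: np.ndarray,
    test_latents: np.ndarray,
    truth: GroundTruthEncoding,
    TR: float = 2.0,
    seed: int = 0,
    test_repeats: int = 2,
    test_ids: list[str] | None = None,
    train_ids: list[str] | None = None,
) -> SimulatedSession:
    """Simulate run-wise BOLD time series for a train + repeated-test session.

    Stimuli appear every ``STIM_DURATION + ISI`` = 3 s in shuffled order,
    split evenly over the runs declared by ``truth.drift_coefs``.  The voxel
    signal is the HRF-convolved, latent-weighted impulse train plus a
    constant baseline b*, per-run linear drift, motion contributions, and
    white noise.
    """
    if TR <= 0:
        raise ValueError("TR must be positive")
    train_latents = np.asarray(train_latents, dtype=float)
    test_latents = np.asarray(test_latents, dtype=float)
    rng = np.random.default_rng(seed)
    n_train, n_test = train_latents.shape[0], test_latents.shape[0]
    if train_ids is None:
        train_ids = [f"train_{i:05d}" for i in range(n_train)]
    if test_ids is None:
        test_ids = [f"test_{i:02d}" for i in range(n_test)]

    # presentation list: every training stimulus once, each test stimulus
    # test_repeats times, globally shuffled then chunked into runs
    pres = [("train", i) for i in range(n_train)]
    pres += [("test", i) for i in range(n_test) for _ in range(test_repeats)]
    order = rng.permutation(len(pres))
    pres = [pres[i] for i in order]

    n_runs = truth.drift_coefs.shape[0]
    chunks = np.array_split(np.arange(len(pres)), n_runs)
    soa = STIM_DURATION + ISI

    runs = []
    test_sum = np.zeros((n_test, truth.n_voxels))
    test_cnt = np.zeros(n_test)
    train_resp = np.zeros((n_train, truth.n_voxels))
    for r, chunk in enumerate(chunks):
        n_ev = len(chunk)
        onsets = np.arange(n_ev) * soa + soa  # first event after one SOA
        run_dur = onsets[-1] + soa + 20.0 if n_ev else 30.0
        n_tp = int(np.ceil(run_dur / TR))
        kinds = [pres[i] for i in chunk]
        amps = np.stack(
            [
                train_latents[i] if kind == "train" else test_latents[i]
                for kind, i in kinds
            ]
        )  # (n_ev, n_dims)

        signal = np.tile(truth.b_star, (n_tp, 1))
        for d in range(truth.n_dims):
            reg = convolve_events(onsets, amps[:, d], n_tp, TR)
            signal += reg[:, None] * truth.W_star[d][None, :]

        tgrid = np.linspace(-0.5, 0.5, n_tp)
        signal += tgrid[:, None] * truth.drift_coefs[r][None, :]

        motion = np.cumsum(rng.normal(0.0, 0.02, size=(3, n_tp)), axis=1)
        motion -= motion.mean(axis=1, keepdims=True)
        signal += motion.T @ truth.motion_coefs

        signal += rng.normal(0.0, truth.noise_sd, size=signal.shape)

        events = pd.DataFrame(
            {
                "onset": onsets,
                "duration": np.full(n_ev, STIM_DURATION),
                "stimulus_id": [
                    train_ids[i] if kind == "train" else test_ids[i]
                    for kind, i in kinds
                ],
            }
        )
        runs.append({"series": signal, "events": events, "motion": motion})

        # trial amplitudes for the averaged matrices (amplitude-domain view)
        for (kind, i), x in zip(kinds, amps):
            amp_resp = x @ truth.W_star + truth.b_star + rng.normal(
                0.0, truth.noise_sd
            )
            if kind == "train":
                train_resp[i] = amp_resp
            else:
                test_sum[i] += amp_resp
                test_cnt[i] += 1

    averaged_test = test_sum / np.maximum(test_cnt, 1)[:, None]
    return SimulatedSession(
        runs=runs, TR=TR, averaged_test=averaged_test, averaged_train=train_resp
    )


@dataclass
class LocalizerStats:
    """Per-voxel face-selectivity statistic (larger = more face-selective)."""

    selectivity_stat: np.ndarray
    parcel_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.selectivity_stat = np.asarray(self.selectivity_stat, dtype=float)
        if self.parcel_labels is not None:
            self.parcel_labels = np.asarray(self.parcel_labels)
            if len(self.parcel_labels) != len(self.selectivity_stat):
                raise ValueError("parcel_labels length must equal voxel count")


def simulate_localizer(
    n_voxels: int,
    face_voxel_mask: np.ndarray,
    shift: float = 3.0,
    seed: int = 0,
    parcel_labels: np.ndarray | None = None,
) -> LocalizerStats:
    """Draw a selectivity statistic per voxel: standard normal, shifted by
    ``shift`` SDs for voxels flagged face-selective in the ground truth."""
    face_voxel_mask = np.asarray(face_voxel_mask, dtype=bool)
    if len(face_voxel_mask) != n_voxels:
        raise ValueError("face_voxel_mask length must equal voxel count")
    rng = np.random.default_rng(seed)
    stat = rng.normal(0.0, 1.0, size=n_voxels) + shift * face_voxel_mask
    return LocalizerStats(selectivity_stat=stat, parcel_labels=parcel_labels)
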