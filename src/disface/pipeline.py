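"""End-to-end pipeline: simulate -> train -> encode -> roi -> prefmap ->
decode -> stats -> report.

Each stage reads its upstream artifacts from the output directory, writes
its own artifacts plus a manifest (inputs, seed, checksums), and can be
re-run independently.  Every random operation draws from a named substream
of the global seed, so ``run_all`` is deterministic end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding as dec
from . import dvae, encoding, io, preference, roi as roi_mod, stats as stats_mod
from .synth import faces, responses as resp

STAGES = ["simulate", "train", "encode", "roi", "prefmap", "decode", "stats",
          "report"]

PRESETS = {
    "ci": dict(
        n_train=300, side=32, n_voxels=60, face_fraction=0.6,
        noise_sd=0.1, signal_sd=1.0, single_dim_fraction=0.5,
        latent_dim=8, epochs=30, resamples=200,
        grid=[("factor_vae", 10.0), ("beta_vae", 1.0)],
    ),
    "desk": dict(
        n_train=1000, side=64, n_voxels=300, face_fraction=0.6,
        noise_sd=0.1, signal_sd=1.0, single_dim_fraction=0.5,
        latent_dim=16, epochs=20, resamples=1000,
        grid=[("factor_vae", 10.0), ("factor_vae", 30.0), ("beta_vae", 1.0),
              ("beta_vae", 4.0)],
    ),
    "full": dict(
        n_train=8000, side=64, n_voxels=1000, face_fraction=0.6,
        noise_sd=0.1, signal_sd=1.0, single_dim_fraction=0.5,
        latent_dim=24, epochs=30, resamples=1000,
        grid=None,  # full published grid via dvae.full_grid()
    ),
}

PARCELS = ["FFA", "OFA", "pSTS"]


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + STAGES.index(stage) + 1) % (2**31)


def _stage_dir(out: Path, stage: str, create: bool = False) -> Path:
    d = Path(out) / stage
    if create:
        d.mkdir(parents=True, exist_ok=True)
    elif not d.exists():
        raise FileNotFoundError(
            f"missing upstream artifacts for stage {stage!r}: run "
            f"`disface {stage}` (or run-all) first"
        )
    return d


def load_config(preset: str = "ci", overrides: dict | None = None) -> dict:
    cfg = dict(PRESETS[preset])
    cfg["preset"] = preset
    if overrides:
        cfg.update(overrides)
    return cfg


# ---------------------------------------------------------------------------


def run_simulate(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "simulate")
    d = _stage_dir(out, "simulate", create=True)
    ds = faces.sample_dataset(n_train=cfg["n_train"], seed=s, side=cfg["side"])
    n_fac = ds.n_factors
    nv = cfg["n_voxels"]
    rng = np.random.default_rng(s + 1)

    truth = resp.make_ground_truth(
        n_dims=n_fac, n_voxels=nv, seed=s + 2,
        single_dim_fraction=cfg["single_dim_fraction"],
        signal_sd=cfg["signal_sd"], noise_sd=cfg["noise_sd"],
    )
    # face-selective voxels: the ones with encoding weights; the rest are
    # "non-face" voxels with zeroed weights
    n_face = int(cfg["face_fraction"] * nv)
    face_mask = np.zeros(nv, dtype=bool)
    face_mask[:n_face] = True
    truth.W_star[:, ~face_mask] = 0.0
    parcels = np.array(
        [PARCELS[i % len(PARCELS)] for i in range(nv)], dtype=object
    )
    loc = resp.simulate_localizer(nv, face_mask, shift=3.0, seed=s + 3,
                                  parcel_labels=parcels)

    train_avg = resp.simulate_responses(ds.train_factors, truth, repeats=1,
                                        seed=s + 4)
    test_avg, test_trials = resp.simulate_responses(
        ds.test_factors, truth, repeats=ds.test_repeats, seed=s + 5,
        return_trials=True,
    )

    np.savez(d / "images.npz", train=ds.train_images, test=ds.test_images)
    io.write_matrix_tsv(d / "train_factors.tsv", ds.train_factors, ds.train_ids,
                        prefix="factor")
    io.write_matrix_tsv(d / "test_factors.tsv", ds.test_factors, ds.test_ids,
                        prefix="factor")
    np.savez(
        d / "truth.npz", W_star=truth.W_star, b_star=truth.b_star,
        drift_coefs=truth.drift_coefs, motion_coefs=truth.motion_coefs,
        noise_sd=truth.noise_sd, face_mask=face_mask,
    )
    np.savez(d / "responses.npz", train=train_avg, test=test_avg,
             test_trials=test_trials)
    pd.DataFrame(
        {"voxel_id": np.arange(nv), "parcel": parcels,
         "selectivity": loc.selectivity_stat}
    ).to_csv(d / "localizer.tsv", sep="\t", index=False)
    meta = {
        "n_train": cfg["n_train"], "side": cfg["side"], "n_voxels": nv,
        "test_repeats": ds.test_repeats,
        "identity_relevant": [bool(x) for x in ds.identity_relevant_mask],
        "factor_names": [f.name for f in ds.spec],
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    io.write_manifest(d, "simulate", s, {"preset": cfg["preset"]},
                      {"train_factors": io.sha256_of_array(ds.train_factors),
                       "test": io.sha256_of_array(test_avg)})


def run_train(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "train")
    sim = _stage_dir(out, "simulate")
    d = _stage_dir(out, "train", create=True)
    imgs = np.load(sim / "images.npz")
    train_factors, train_ids = io.read_matrix_tsv(sim / "train_factors.tsv")
    _, test_ids = io.read_matrix_tsv(sim / "test_factors.tsv")

    if cfg["grid"] is None:
        configs = dvae.full_grid(dvae.ModelConfig(
            image_side=cfg["side"], epochs=cfg["epochs"]))
    else:
        configs = [
            dvae.ModelConfig(
                family=fam, latent_dim=cfg["latent_dim"],
                beta=val if fam == "beta_vae" else 1.0,
                gamma=val if fam == "factor_vae" else 0.0,
                seed=s, epochs=cfg["epochs"], image_side=cfg["side"],
            )
            for fam, val in cfg["grid"]
        ]

    scored = []
    for i, mc in enumerate(configs):
        model = dvae.train(mc, imgs["train"])
        lat = dvae.extract_latents(model, imgs["train"], train_ids)
        score, imp = dvae.disentanglement_score(lat, train_factors)
        scored.append((mc, score, model, imp))
        tag = f"model_{i}"
        io.write_matrix_tsv(d / f"{tag}_train_latents.tsv", lat.values,
                            train_ids, prefix="latent")
        test_lat = dvae.extract_latents(model, imgs["test"], test_ids)
        io.write_matrix_tsv(d / f"{tag}_test_latents.tsv", test_lat.values,
                            test_ids, prefix="latent")
        np.savez(d / f"{tag}_params.npz", **model.params)
        (d / f"{tag}_config.json").write_text(json.dumps(
            {**asdict(mc), "disentanglement_score": score}, indent=2))
        np.savetxt(d / f"{tag}_importance.tsv", imp, delimiter="\t")

    best = dvae.select_model([(mc, sc) for mc, sc, _, _ in scored])
    best_i = next(i for i, (mc, *_ ) in enumerate(scored) if mc == best)
    (d / "selected.json").write_text(json.dumps(
        {"index": best_i, "config": asdict(best), "n_models": len(scored)},
        indent=2))
    io.write_manifest(d, "train", s, {"n_models": len(scored)},
                      {"selected": str(best_i)})


def run_encode(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "encode")
    sim = _stage_dir(out, "simulate")
    tr = _stage_dir(out, "train")
    d = _stage_dir(out, "encode", create=True)
    rsp = np.load(sim / "responses.npz")
    sel = json.loads((tr / "selected.json").read_text())

    results = {}
    for i in range(sel["n_models"]):
        tag = f"model_{i}"
        train_lat, _ = io.read_matrix_tsv(tr / f"{tag}_train_latents.tsv")
        test_lat, _ = io.read_matrix_tsv(tr / f"{tag}_test_latents.tsv")
        design = encoding.build_design_amplitude(train_lat)
        fit = encoding.fit_glm(design, rsp["train"])
        pred = encoding.predict_test(fit, test_lat)
        ev = encoding.evaluate(pred, rsp["test"])
        np.savez(d / f"{tag}_fit.npz", W=fit.W, b=fit.b)
        np.savez(d / f"{tag}_pred.npz", predicted=pred,
                 per_voxel_r=ev.per_voxel_r)
        results[tag] = float(np.mean(ev.per_voxel_r))

    rel = encoding.split_half_reliability(rsp["test_trials"], n_splits=50,
                                          seed=s)
    np.savez(d / "reliability.npz", reliability=rel)
    (d / "summary.json").write_text(json.dumps(
        {"mean_r_by_model": results,
         "mean_split_half_reliability": float(rel.mean())}, indent=2))
    io.write_manifest(d, "encode", s, {"n_models": sel["n_models"]},
                      {"reliability": io.sha256_of_array(rel)})


def run_roi(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "roi")
    sim = _stage_dir(out, "simulate")
    enc = _stage_dir(out, "encode")
    d = _stage_dir(out, "roi", create=True)
    loc = pd.read_csv(sim / "localizer.tsv", sep="\t")
    rel = np.load(enc / "reliability.npz")["reliability"]
    selection = roi_mod.parcel_select(
        loc["selectivity"].to_numpy(), rel, loc["parcel"].to_numpy(),
        fraction=0.10,
    )
    wb = roi_mod.whole_brain_select(selection.v, k_sd=1.5)
    df = selection.to_frame()
    df["whole_brain"] = wb
    df.to_csv(d / "selection.tsv", sep="\t", index=False)
    io.write_manifest(d, "roi", s, {},
                      {"selected": io.sha256_of_array(selection.selected)})


def _load_fit(enc: Path, tag: str) -> encoding.EncodingFit:
    f = np.load(enc / f"{tag}_fit.npz")
    return encoding.EncodingFit(W=f["W"], b=f["b"])


def run_prefmap(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "prefmap")
    sim = _stage_dir(out, "simulate")
    tr = _stage_dir(out, "train")
    enc = _stage_dir(out, "encode")
    d = _stage_dir(out, "prefmap", create=True)
    sel = json.loads((tr / "selected.json").read_text())
    tag = f"model_{sel['index']}"
    fit = _load_fit(enc, tag)
    test_lat, _ = io.read_matrix_tsv(tr / f"{tag}_test_latents.tsv")
    rsp = np.load(sim / "responses.npz")
    loc = pd.read_csv(sim / "localizer.tsv", sep="\t")
    pm = preference.preference_profile(fit, test_lat, rsp["test"],
                                       roi_labels=loc["parcel"].to_numpy())
    pm.to_frame().to_csv(d / "winners.tsv", sep="\t", index=False)
    prof = pd.DataFrame(pm.roi_profiles).T
    prof.columns = [f"dim_{j}" for j in range(prof.shape[1])]
    prof.to_csv(d / "roi_profiles.tsv", sep="\t")
    np.savez(d / "per_dim_r.npz", per_dim_r=pm.per_dim_r)
    io.write_manifest(d, "prefmap", s, {"model": tag},
                      {"winners": io.sha256_of_array(pm.winner)})


def run_decode(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "decode")
    sim = _stage_dir(out, "simulate")
    tr = _stage_dir(out, "train")
    enc = _stage_dir(out, "encode")
    d = _stage_dir(out, "decode", create=True)
    sel = json.loads((tr / "selected.json").read_text())
    tag = f"model_{sel['index']}"
    fit = _load_fit(enc, tag)
    test_lat, _ = io.read_matrix_tsv(tr / f"{tag}_test_latents.tsv")
    rsp = np.load(sim / "responses.npz")
    meta = json.loads((sim / "meta.json").read_text())

    decoded = dec.decode_latents(fit, rsp["test"])
    imp = np.loadtxt(tr / f"{tag}_importance.tsv", delimiter="\t")
    subsets = dec.classify_dimensions(
        imp, np.array(meta["identity_relevant"], dtype=bool))
    subsets = {k: v for k, v in subsets.items() if v.size >= 2}
    results = dec.subset_battery(decoded, test_lat, subsets)
    pd.DataFrame(
        [{"subset": r.subset_name, "accuracy": r.accuracy,
          "n_comparisons": r.n_comparisons} for r in results]
    ).to_csv(d / "decoding.tsv", sep="\t", index=False)
    np.savez(d / "decoded.npz", x_hat=decoded.x_hat)
    io.write_manifest(d, "decode", s, {"model": tag},
                      {"x_hat": io.sha256_of_array(decoded.x_hat)})


def run_stats(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "stats")
    sim = _stage_dir(out, "simulate")
    tr = _stage_dir(out, "train")
    enc = _stage_dir(out, "encode")
    d = _stage_dir(out, "stats", create=True)
    sel = json.loads((tr / "selected.json").read_text())
    rsp = np.load(sim / "responses.npz")
    B = cfg["resamples"]

    rows = []
    preds = {}
    for i in range(sel["n_models"]):
        tag = f"model_{i}"
        preds[tag] = np.load(enc / f"{tag}_pred.npz")["predicted"]
        res = stats_mod.perm_test_above_chance(preds[tag], rsp["test"],
                                               resamples=B, seed=s + i)
        rows.append({"test": f"above_chance:{tag}", "statistic": res.observed,
                     "p_value": res.p_value, "tail": res.tail, "resamples": B})
    tags = sorted(preds)
    for a in range(len(tags)):
        for b in range(a + 1, len(tags)):
            res = stats_mod.perm_test_model_diff(
                preds[tags[a]], preds[tags[b]], rsp["test"], resamples=B,
                seed=s + 100 + a * 10 + b)
            rows.append({"test": f"model_diff:{tags[a]}-{tags[b]}",
                         "statistic": res.observed, "p_value": res.p_value,
                         "tail": res.tail, "resamples": B})
    tag = f"model_{sel['index']}"
    per_r = np.load(enc / f"{tag}_pred.npz")["per_voxel_r"]
    loc = pd.read_csv(sim / "localizer.tsv", sep="\t")
    res = stats_mod.perm_test_roi_diff(per_r, loc["parcel"].to_numpy(),
                                       "OFA", "FFA", resamples=B, seed=s + 999)
    rows.append({"test": "roi_diff:OFA-FFA", "statistic": res.observed,
                 "p_value": res.p_value, "tail": res.tail, "resamples": B})
    pd.DataFrame(rows).to_csv(d / "stats.tsv", sep="\t", index=False)
    io.write_manifest(d, "stats", s, {"resamples": B}, {})


def run_report(cfg: dict, out: Path, seed: int) -> None:
    s = stage_seed(seed, "report")
    enc = _stage_dir(out, "encode")
    pref = _stage_dir(out, "prefmap")
    decd = _stage_dir(out, "decode")
    st = _stage_dir(out, "stats")
    d = _stage_dir(out, "report", create=True)
    summary = json.loads((enc / "summary.json").read_text())
    profiles = pd.read_csv(pref / "roi_profiles.tsv", sep="\t", index_col=0)
    decoding_tbl = pd.read_csv(decd / "decoding.tsv", sep="\t")
    stats_tbl = pd.read_csv(st / "stats.tsv", sep="\t")

    pd.DataFrame(
        [{"model": k, "mean_r": v} for k, v in
         summary["mean_r_by_model"].items()]
        + [{"model": "split_half_reliability",
            "mean_r": summary["mean_split_half_reliability"]}]
    ).to_csv(d / "encoding_by_model.tsv", sep="\t", index=False)
    profiles.to_csv(d / "preference_profiles.tsv", sep="\t")
    decoding_tbl.to_csv(d / "decoding_by_subset.tsv", sep="\t", index=False)
    stats_tbl.to_csv(d / "significance.tsv", sep="\t", index=False)

    try:  # figure export is best-effort; tables are the canonical output
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(decoding_tbl["subset"], 100 * decoding_tbl["accuracy"])
        ax.axhline(50, ls="--", c="k", lw=1)
        ax.set_ylabel("pairwise decoding accuracy (%)")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(d / "decoding_by_subset.png", dpi=100)
        plt.close(fig)
    except Exception:  # pragma: no cover
        pass
    io.write_manifest(d, "report", s, {}, {})


_RUNNERS = {
    "simulate": run_simulate, "train": run_train, "encode": run_encode,
    "roi": run_roi, "prefmap": run_prefmap, "decode": run_decode,
    "stats": run_stats, "report": run_report,
}


def run_stage(name: str, cfg: dict, out, seed: int) -> None:
    if name not in _RUNNERS:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    _RUNNERS[name](cfg, Path(out), seed)


def run_all(cfg: dict, out, seed: int) -> None:
    for name in STAGES:
        run_stage(name, cfg, out, seed)
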