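"""Tab-separated and array I/O for pipeline artifacts.

Factor tables, latent matrices, events tables (BIDS events.tsv dialect:
onset, duration, stimulus_id), voxel selections and decoding results all
travel as TSV with a stimulus_id / voxel_id key column; dense numeric
matrices use numpy's portable .npz container; images go out as PNG.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_events_tsv",
    "read_events_tsv",
    "write_png",
    "sha256_of_array",
    "write_manifest",
    "read_manifest",
]


def write_matrix_tsv(path, values: np.ndarray, ids: list[str],
                     prefix: str = "dim") -> None:
    values = np.asarray(values)
    df = pd.DataFrame(values, columns=[f"{prefix}_{j}" for j in range(values.shape[1])])
    df.insert(0, "stimulus_id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = df["stimulus_id"].astype(str).tolist()
    return df.drop(columns=["stimulus_id"]).to_numpy(dtype=float), ids


def write_events_tsv(path, events: pd.DataFrame) -> None:
    events[["onset", "duration", "stimulus_id"]].to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_png(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(image, 0.0, 1.0) * 255).astype(np.uint8))


def sha256_of_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def write_manifest(stage_dir, stage: str, seed: int, inputs: dict,
                   checksums: dict) -> None:
    manifest = {"stage": stage, "seed": seed, "inputs": inputs,
                "checksums": checksums}
    Path(stage_dir, "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_manifest(stage_dir) -> dict:
    return json.loads(Path(stage_dir, "manifest.json").read_text())
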