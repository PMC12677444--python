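"""Persistence of feature databases as a versioned archive."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .matching import FeatureSet

FORMAT_VERSION = 1

__all__ = ["save_feature_db", "load_feature_db"]


def save_feature_db(entries: list[FeatureSet], path: str | Path) -> None:
    """Write one record per image: ids, keypoint table, descriptor matrix."""
    payload = {"version": np.array(FORMAT_VERSION), "n_entries": np.array(len(entries))}
    for i, fs in enumerate(entries):
        payload[f"identity_{i}"] = np.array(fs.identity_id)
        payload[f"source_{i}"] = np.array(fs.source_id)
        payload[f"keypoints_{i}"] = fs.keypoints
        payload[f"descriptors_{i}"] = fs.descriptors
    np.savez_compressed(path, **payload)


def load_feature_db(path: str | Path) -> list[FeatureSet]:
    with np.load(path, allow_pickle=False) as data:
        version = int(data["version"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported feature-db version {version}")
        out = []
        for i in range(int(data["n_entries"])):
            out.append(
                FeatureSet(
                    keypoints=data[f"keypoints_{i}"],
                    descriptors=data[f"descriptors_{i}"],
                    source_id=str(data[f"source_{i}"]),
                    identity_id=str(data[f"identity_{i}"]),
                )
            )
    return out
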