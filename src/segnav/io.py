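"""Plain-text readers and writers for all pipeline artifacts.

Everything is TSV (UTF-8, tab-delimited, header row) or JSON sidecars;
no binary caches, so every intermediate can be inspected and diffed.
Time series are one file per subject, wide format (time x parcel, header
= parcel ids), indexed by a manifest TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_series",
    "read_series",
    "write_sidecar",
    "read_sidecar",
]


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_series(
    series: np.ndarray, subject_ids, out_dir
) -> Path:
    """Write per-subject time x parcel TSVs plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, mat in zip(subject_ids, series):
        mat = np.asarray(mat)
        fname = f"series_{sid}.tsv"
        df = pd.DataFrame(mat.T, columns=[str(p) for p in range(mat.shape[0])])
        df.to_csv(out_dir / fname, sep="\t", index=False)
        rows.append({"subject_id": sid, "file": fname,
                     "n_parcels": mat.shape[0], "n_timepoints": mat.shape[1]})
    manifest = out_dir / "series_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_series(manifest_path) -> tuple[np.ndarray, list[str]]:
    """Read a series manifest; returns ``(series, subject_ids)``."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    mats, sids = [], []
    for _, row in manifest.iterrows():
        df = pd.read_csv(manifest_path.parent / row["file"], sep="\t")
        mats.append(df.to_numpy(float).T)  # back to parcel x time
        sids.append(str(row["subject_id"]))
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent series shapes across subjects: {shapes}")
    return np.asarray(mats), sids


def write_sidecar(obj: dict, path) -> None:
    """Machine-readable key-value sidecar (JSON, sorted keys)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
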