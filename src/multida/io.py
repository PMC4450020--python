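"""File readers and writers: block CSVs, labels, loadings, manifests.

Block matrices travel as comma-delimited text with the sample ID in the
first column and feature names in the header row.  Fitted loadings are
written one TSV per block with columns ``rank``, ``feature_name``,
``loading`` (1-based feature indices in ``feature_index``); every run
also writes a JSON manifest capturing the options, seed, package
version, input checksums and convergence diagnostics, sufficient to
re-execute the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import MultiblockData
from .optimizer import FitOptions, LoadingSet

__all__ = [
    "read_block_csv",
    "write_block_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_loadings",
    "read_loadings",
    "write_manifest",
    "file_checksum",
]


def read_block_csv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a block matrix: returns (matrix, sample_ids, feature_names)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(s) for s in df.index], [str(c) for c in df.columns]


def write_block_csv(path, X: np.ndarray, sample_ids, feature_names) -> None:
    pd.DataFrame(X, index=list(sample_ids), columns=list(feature_names)).to_csv(
        path, index_label="sample_id"
    )


def read_labels_csv(path) -> tuple[list, list[str]]:
    """Read a two-column (sample_id, label) CSV: returns (labels, sample_ids)."""
    df = pd.read_csv(path, index_col=0)
    col = df.columns[0]
    return df[col].tolist(), [str(s) for s in df.index]


def write_labels_csv(path, labels, sample_ids) -> None:
    pd.DataFrame({"label": list(labels)}, index=list(sample_ids)).to_csv(
        path, index_label="sample_id"
    )


def write_loadings(loading_set: LoadingSet, out_dir) -> list[Path]:
    """Write one TSV per block: rank, feature_index, feature_name, loading."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j in range(loading_set.n_blocks):
        name = loading_set.block_names[j]
        rows = []
        for r in range(loading_set.n_ranks):
            alpha = loading_set.loadings[r][j]
            for p, value in enumerate(alpha):
                rows.append(
                    {
                        "rank": r + 1,
                        "feature_index": p + 1,
                        "feature_name": loading_set.feature_names[j][p],
                        "loading": value,
                    }
                )
        path = out_dir / f"loadings_{name}.tsv"
        df = pd.DataFrame(rows)
        # repr round-trips doubles exactly
        df["loading"] = df["loading"].map(repr)
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_loadings(out_dir, block_names) -> dict[str, np.ndarray]:
    """Read loadings TSVs back: block name -> (n_ranks x P_j) matrix."""
    out_dir = Path(out_dir)
    out = {}
    for name in block_names:
        df = pd.read_csv(
            out_dir / f"loadings_{name}.tsv", sep="\t", float_precision="round_trip"
        )
        n_ranks = int(df["rank"].max())
        p = int(df["feature_index"].max())
        mat = np.zeros((n_ranks, p))
        mat[df["rank"] - 1, df["feature_index"] - 1] = df["loading"]
        out[name] = mat
    return out


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    *,
    options: FitOptions | None = None,
    seed: int | None = None,
    inputs: dict[str, str] | None = None,
    loading_set: LoadingSet | None = None,
    data: MultiblockData | None = None,
    extra: dict | None = None,
) -> None:
    """Write the JSON run manifest (options, seed, checksums, diagnostics)."""
    manifest: dict = {"package_version": __version__}
    if seed is not None:
        manifest["seed"] = seed
    if options is not None:
        manifest["options"] = options.to_dict()
    if inputs is not None:
        manifest["input_checksums"] = inputs
    if data is not None:
        manifest["blocks"] = {
            "names": data.block_names,
            "shapes": [list(s) for s in data.shapes],
            "label_mapping": data.label_mapping,
        }
    if loading_set is not None:
        manifest["fit"] = {
            "n_ranks": loading_set.n_ranks,
            "converged": list(loading_set.converged),
            "lambdas": loading_set.lambdas,
            "objective_traces": loading_set.objective_traces,
            "degenerate": [list(map(bool, d)) for d in loading_set.degenerate],
            "final_slack": (
                loading_set.slacks[-1].m.tolist()
                if loading_set.slacks and loading_set.slacks[-1] is not None
                else None
            ),
            "final_margins": (
                loading_set.slacks[-1].margin_shift().tolist()
                if loading_set.slacks and loading_set.slacks[-1] is not None
                else None
            ),
        }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
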