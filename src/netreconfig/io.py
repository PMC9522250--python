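"""Plain-text file formats and run manifests.

Time series are TSV with a header row of node ids (rows = timepoints);
ratings are two-column TSV (time_s, value); partitions are long-format TSV
(node_id, layer, community); allegiance matrices are square TSV with a
node-id header; configuration is YAML or JSON.  Every written output can
carry a JSON manifest sufficient to re-run its stage.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_timeseries", "write_timeseries",
    "read_ratings", "write_ratings",
    "read_partition", "write_partition",
    "read_matrix", "write_matrix",
    "read_config", "write_manifest",
]


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    """T x N matrix and node ids from a TSV with a node-id header row.

    Rejects ragged rows, non-numeric cells, NaN cells, and duplicate node
    ids with the offending line or id in the message.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(set(header)) != len(header):
            dup = next(h for h in header if header.count(h) > 1)
            raise ValueError(f"duplicate node id in header: {dup!r}")
        n_cols = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != n_cols:
                raise ValueError(f"{path}:{lineno}: expected {n_cols} columns, "
                                 f"got {len(cells)}")
            try:
                vals = [float(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if any(np.isnan(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: NaN cell")
            rows.append(vals)
    return np.array(rows), header


def write_timeseries(path, series: np.ndarray, node_ids=None) -> None:
    series = np.asarray(series)
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(series.shape[1])]
    df = pd.DataFrame(series, columns=node_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ratings(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["time_s"].to_numpy(), df["value"].to_numpy()


def write_ratings(path, times, values) -> None:
    pd.DataFrame({"time_s": times, "value": values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_partition(path) -> np.ndarray:
    """(N, L) labels from long-format TSV (node_id, layer, community)."""
    df = pd.read_csv(path, sep="\t")
    return (df.pivot(index="node_id", columns="layer", values="community")
            .sort_index().to_numpy().astype(int))


def write_partition(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    n, L = labels.shape
    rows = [{"node_id": i, "layer": l, "community": int(labels[i, l])}
            for i in range(n) for l in range(L)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_matrix(path, matrix: np.ndarray, node_ids=None) -> None:
    matrix = np.asarray(matrix)
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, columns=node_ids).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, config: dict, inputs=(), seeds=None,
                   extra: dict | None = None) -> None:
    """JSON sidecar recording the resolved config, input checksums, and
    per-stage seeds of a run."""
    from . import __version__
    manifest = {
        "software": {"name": "netreconfig", "version": __version__},
        "config": config,
        "inputs": {str(p): _checksum(p) for p in inputs},
        "seeds": seeds or {},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
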