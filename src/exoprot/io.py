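"""Plain-text readers and writers for the pipeline's exchange formats.

All stages exchange tab-delimited text so that intermediate results are
diff-able and reproducible byte-for-byte:

* abundance matrix — first column ``protein_id``, remaining columns sample
  identifiers; empty cells encode missing (not-quantified) values;
* sample metadata — two columns, ``sample_id`` and ``group``;
* interaction edge list — three columns, ``node1``, ``node2``,
  ``combined_score`` (a STRING-style confidence in [0, 1]);
* ground truth — a JSON sidecar written by the simulator.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_edge_list",
    "write_edge_list",
    "read_ground_truth",
    "write_ground_truth",
]


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a protein x sample abundance table (missing cells become NaN)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein identifiers: {dups}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    return df.astype(float)


def write_abundance(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; returns a frame indexed by ``sample_id``."""
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "group" not in md.columns:
        raise ValueError("metadata must contain a 'group' column")
    md.index = md.index.astype(str)
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a three-column scored edge list (node1, node2, combined_score)."""
    edges = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = ["node1", "node2", "combined_score"]
    if list(edges.columns[:3]) != expected:
        raise ValueError(f"edge list must have columns {expected}, got {list(edges.columns)}")
    edges["combined_score"] = edges["combined_score"].astype(float)
    bad = edges[(edges.combined_score < 0) | (edges.combined_score > 1)]
    if len(bad):
        raise ValueError("combined_score outside [0, 1]")
    return edges


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
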