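"""Tabular I/O for expression matrices, sample metadata, probe maps and panels.

All on-disk formats are tab-delimited text (GEO series-matrix style for
expression: rows = probes/genes, columns = samples) or JSON for panels,
fitted models and per-sample scores.  Missing values are written as ``NA``;
both ``NA`` and the empty string are accepted on read.  Matrices are held
in memory as :class:`pandas.DataFrame` with ``NaN`` marking missing entries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GenePanel",
    "read_expression_table",
    "write_expression_table",
    "read_metadata",
    "read_probe_map",
    "check_samples_covered",
    "write_edge_list",
]

_NA_STRINGS = {"", "NA"}

VALID_GROUPS = {"case", "control"}


@dataclass
class GenePanel:
    """Ordered virus-response (VRG) and bacteria-response (BRG) gene lists.

    ``provenance`` records, per selected gene, the statistics used at
    selection time (mean fold changes, dataset counts, qualifying rule).
    """

    vrg: list[str]
    brg: list[str]
    provenance: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vrg = [g.upper() for g in self.vrg]
        self.brg = [g.upper() for g in self.brg]
        overlap = set(self.vrg) & set(self.brg)
        if overlap:
            raise ValueError(f"VRG and BRG lists overlap: {sorted(overlap)}")
        if len(set(self.vrg)) != len(self.vrg) or len(set(self.brg)) != len(self.brg):
            raise ValueError("panel gene lists contain duplicates")

    @property
    def genes(self) -> list[str]:
        return list(self.vrg) + list(self.brg)

    def to_json(self, path: str | Path) -> None:
        payload = {"vrg": self.vrg, "brg": self.brg, "provenance": self.provenance}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        payload = json.loads(Path(path).read_text())
        return cls(
            vrg=payload["vrg"],
            brg=payload["brg"],
            provenance=payload.get("provenance", {}),
        )


def _parse_table(path: str | Path) -> tuple[list[str], list[str], list[list[str]]]:
    """Split a TSV into header, row ids and string cells, checking shape."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    n_cols = len(header)
    ids: list[str] = []
    cells: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_cols}"
            )
        ids.append(fields[0])
        cells.append(fields[1:])
    return header[1:], ids, cells


def read_expression_table(path: str | Path, scale: str = "log2") -> pd.DataFrame:
    """Read a probe/gene x sample expression TSV as a log2-scale DataFrame.

    Parameters
    ----------
    path
        Tab-delimited file: first column feature ids, header row sample ids.
    scale
        ``"log2"`` if values are already log2 intensities, ``"linear"`` if
        raw intensities (log2-transformed on read, the first normalization
        step of the pipeline).

    Empty cells and ``NA`` become missing (``NaN``).  Duplicate feature ids
    and ragged rows are rejected.
    """
    if scale not in {"log2", "linear"}:
        raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")
    sample_ids, ids, cells = _parse_table(path)
    seen: set[str] = set()
    for pid in ids:
        if pid in seen:
            raise ValueError(f"{path}: duplicate feature id {pid!r}")
        seen.add(pid)
    values = np.full((len(ids), len(sample_ids)), np.nan)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell in _NA_STRINGS:
                continue
            values[i, j] = float(cell)
    df = pd.DataFrame(values, index=ids, columns=sample_ids)
    if scale == "linear":
        if (df <= 0).any().any():
            raise ValueError(f"{path}: non-positive intensity on linear scale")
        df = np.log2(df)
    df.index.name = "id"
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a log2 expression matrix; missing entries become ``NA``."""
    df.to_csv(path, sep="\t", na_rep="NA", index_label=df.index.name or "id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, class_label[, sex, age, timepoint]).

    ``group`` must normalize (case-insensitively) to ``case`` or ``control``.
    Returns a DataFrame indexed by ``sample_id``.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group", "class_label"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    meta["group"] = meta["group"].str.strip().str.lower()
    bad = sorted(set(meta["group"]) - VALID_GROUPS)
    if bad:
        raise ValueError(f"{path}: unknown group values {bad}; expected case/control")
    if "sex" in meta.columns:
        meta["sex"] = meta["sex"].str.strip().str.lower()
        bad_sex = sorted(set(meta["sex"].dropna()) - {"male", "female"})
        if bad_sex:
            raise ValueError(f"{path}: unknown sex values {bad_sex}")
    return meta.set_index("sample_id")


def check_samples_covered(expr: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Raise if any expression sample lacks a metadata row."""
    missing = [s for s in expr.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a probe->gene mapping TSV with columns probe_id, gene_symbol.

    Gene symbols are uppercased (platform annotation casing varies).  A probe
    may map to several genes (one row each).
    """
    pm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_symbol"}
    missing = required - set(pm.columns)
    if missing:
        raise ValueError(f"{path}: missing probe-map columns {sorted(missing)}")
    pm["gene_symbol"] = pm["gene_symbol"].str.upper()
    return pm[["probe_id", "gene_symbol"]].drop_duplicates()


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write an undirected weighted network as a Cytoscape-importable TSV.

    Columns ``source``, ``target``, ``pcc``; endpoints sorted within each
    row and rows sorted lexicographically; self-loops never written.
    """
    rows = []
    for u, v, data in network.edges(data=True):
        if u == v:
            continue
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, data.get("pcc", data.get("weight", math.nan))))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("source\ttarget\tpcc\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write per-sample scores (ng_v, ng_b, ...) as a TSV indexed by sample."""
    scores.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
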