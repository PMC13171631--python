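"""Readers and writers for the pipeline's tab-separated formats and trees.

All tables are plain TSV with a header; trees are newick with branch
lengths.  Taxonomy strings follow the GTDB convention
``d__...;p__...;c__...;o__...;f__...;g__...;s__...`` and may truncate
trailing ranks.
"""

from __future__ import annotations

import os
from typing import Iterable

import dendropy
import pandas as pd

from microcensus.census import TABLE_COLUMNS, GeneClusterTable

RANK_PREFIXES = [
    ("domain", "d__"),
    ("phylum", "p__"),
    ("class", "c__"),
    ("order", "o__"),
    ("family", "f__"),
    ("genus", "g__"),
    ("species", "s__"),
]


def read_sequences_tsv(path: str, habitats: Iterable[str] | None = None) -> GeneClusterTable:
    """Read a sequence-level census table, validating the schema.

    Duplicate sequence identifiers and unknown source values are rejected
    with the offending line named.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["seq_id"].duplicated()
    if dup.any():
        line = int(df.index[dup][0]) + 2  # header is line 1
        raise ValueError(f"{path}: duplicate seq_id at line {line}")
    return GeneClusterTable(df, habitats=habitats)


def write_sequences_tsv(table: GeneClusterTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_taxonomy_tsv(path: str) -> pd.DataFrame:
    """Read entity_id + GTDB-style taxonomy strings into one column per rank.

    Missing trailing ranks are tolerated and left empty.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "entity_id" not in raw.columns or "taxonomy" not in raw.columns:
        raise ValueError(f"{path}: need columns entity_id, taxonomy")
    out = {rank: [] for rank, _ in RANK_PREFIXES}
    for tax in raw["taxonomy"]:
        fields = {f[:3]: f[3:] for f in tax.split(";") if len(f) >= 3}
        for rank, prefix in RANK_PREFIXES:
            out[rank].append(fields.get(prefix, ""))
    df = pd.DataFrame(out)
    df.insert(0, "entity_id", raw["entity_id"])
    return df


def write_taxonomy_tsv(labels: pd.DataFrame, path: str) -> None:
    """Write a per-entity rank table back to GTDB-style strings."""
    rows = []
    rank_cols = [r for r, _ in RANK_PREFIXES if r in labels.columns]
    for entity, row in labels.iterrows():
        parts = []
        for rank, prefix in RANK_PREFIXES:
            if rank in rank_cols and str(row[rank]) not in ("", "nan"):
                value = str(row[rank])
                parts.append(value if value.startswith(prefix) else prefix + value)
        rows.append({"entity_id": entity, "taxonomy": ";".join(parts)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_newick(path: str, require_lengths: bool = True) -> dendropy.Tree:
    """Read a rooted newick tree (multifurcations and quoted labels fine).

    With ``require_lengths`` (RED mode) every non-root branch must carry a
    length.
    """
    tree = dendropy.Tree.get(
        path=path, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    if require_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(f"{path}: branch without length (required for RED)")
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", unquoted_underscores=True)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
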