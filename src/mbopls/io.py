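"""Readers and writers for the plain-text interchange formats.

Matrices are CSV/TSV with a header row of feature ids and a first column
of sample ids; empty cells, "NA" and "NaN" mark missing values.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import DataError, OmicsBlock, PopulationMembership, TraitVector

__all__ = ["read_matrix", "write_matrix", "read_block", "write_block",
           "read_trait_table", "read_trait", "read_qmatrix",
           "read_annotations", "write_annotations"]

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _delimiter(path, delimiter=None):
    if delimiter:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tsv", ".tab", ".txt"):
        return "\t"
    return ","


def read_matrix(path, delimiter=None) -> pd.DataFrame:
    """Read a sample x feature table; raises on duplicates/non-numeric cells."""
    sep = _delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate sample id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise DataError(f"duplicate feature id {dup!r} in {path}")
    out = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                      & df[col].notna()]
        if len(bad):
            raise DataError(
                f"non-numeric cell in {path}, column {col!r}, "
                f"row {bad.index[0]!r}")
        # astype(float) is correctly rounded, unlike pandas' fast parser
        out[col] = df[col].astype(float)
    return out


def write_matrix(df: pd.DataFrame, path, delimiter=None) -> None:
    sep = _delimiter(path, delimiter)
    # 17 significant digits round-trips float64 exactly
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


def read_block(path, platform="", annotations=None, delimiter=None) -> OmicsBlock:
    df = read_matrix(path, delimiter)
    return OmicsBlock(list(df.index), list(df.columns), df.to_numpy(float),
                      platform=platform or os.path.basename(str(path)),
                      annotations=annotations)


def write_block(block: OmicsBlock, path, delimiter=None) -> None:
    df = pd.DataFrame(block.values, index=pd.Index(block.sample_ids, name="sample_id"),
                      columns=block.feature_ids)
    write_matrix(df, path, delimiter)


def read_trait_table(path, delimiter=None) -> pd.DataFrame:
    return read_matrix(path, delimiter)


def read_trait(path, trait_name, delimiter=None) -> TraitVector:
    df = read_trait_table(path, delimiter)
    if trait_name not in df.columns:
        raise DataError(f"trait {trait_name!r} not found in {path}; "
                        f"available: {list(df.columns)}")
    return TraitVector(list(df.index), df[trait_name].to_numpy(float),
                       name=trait_name)


def read_qmatrix(path, delimiter=None) -> PopulationMembership:
    df = read_matrix(path, delimiter)
    return PopulationMembership(list(df.index), df.to_numpy(float),
                                subpopulation_labels=list(df.columns))


def read_annotations(path) -> dict:
    """Two-column TSV feature_id -> metabolite identifier."""
    ann = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"annotation line {ln} is not two-column TSV")
            ann[parts[0]] = parts[1]
    return ann


def write_annotations(ann: dict, path) -> None:
    with open(path, "w") as fh:
        for fid, met in ann.items():
            fh.write(f"{fid}\t{met}\n")


def write_edges_tsv(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_a\tfeature_b\trho_S\tp_value\n")
        for e in edges:
            fh.write(f"{e.feature_a}\t{e.feature_b}\t{e.rho_s:.6g}\t{e.p_value:.6g}\n")


def write_edges_graphml(edges, path) -> None:
    try:
        import networkx as nx
    except ImportError as exc:  # pragma: no cover
        raise DataError("networkx is required for GraphML export") from exc
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.feature_a, e.feature_b, rho_S=e.rho_s, p_value=e.p_value)
    nx.write_graphml(g, path)
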