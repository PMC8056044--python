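"""TSV readers and writers for the pipeline's file dialects.

* network edge list: 3 columns ``gene_a  gene_b  weight`` (the sparse
  '_top' style used by tissue-network releases); header optional.
* gene p-values: 2 columns ``gene  p``; MAGMA-style headers
  (``GENE``/``P``, any case, extra columns) are also accepted.
* truth, score and module tables: headered TSVs.

All writers produce files that round-trip through the matching
readers; malformed rows are rejected with their line number.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netprio.datatypes import (
    CombinedScoreTable,
    FunctionalScoreTable,
    GenePValueTable,
    ValidationError,
)
from netprio.synth import PlantedTruth


class ParseError(ValidationError):
    """Malformed input file; message carries the offending line number."""


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc


def _has_header(first_fields: list[str]) -> bool:
    """Heuristic: a numeric final field means a headerless data row."""
    try:
        float(first_fields[-1])
        return False
    except (ValueError, IndexError):
        return True


def read_network(path) -> nx.Graph:
    """Read a weighted edge list; validate weights, loops, duplicates."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    header = 0 if _has_header(first) else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected 3 columns, found {df.shape[1]}")
    if header == 0:
        cols = {c.lower(): c for c in df.columns}
        try:
            df = df[[cols["gene_a"], cols["gene_b"], cols["weight"]]]
        except KeyError:
            df = df.iloc[:, :3]
    else:
        df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "weight"]

    offset = 2 if header == 0 else 1
    graph = nx.Graph()
    seen = set()
    for i, (a, b, w) in enumerate(df.itertuples(index=False)):
        line = i + offset
        try:
            w = float(w)
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{line}: non-numeric weight {w!r}")
        if not (0.0 < w <= 1.0):
            raise ParseError(f"{path}:{line}: weight {w} outside (0, 1]")
        if a == b:
            raise ParseError(f"{path}:{line}: self-loop on {a!r}")
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            raise ParseError(f"{path}:{line}: duplicate edge {key}")
        seen.add(key)
        graph.add_edge(a, b, weight=w)
    return graph


def write_network(graph: nx.Graph, path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_gene_pvalues(path, source_label: str = "") -> GenePValueTable:
    """Read a (gene, p) table; accepts MAGMA-style GENE/P headers too."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    header = 0 if _has_header(first) else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str)
    if header == 0:
        cols = {c.strip().lower(): c for c in df.columns}
        gene_col = next((cols[k] for k in ("gene", "gene_id") if k in cols), None)
        p_col = next((cols[k] for k in ("p", "pvalue", "p_value") if k in cols), None)
        if gene_col is None or p_col is None:
            raise ParseError(
                f"{path}: need gene and p columns, found {list(df.columns)}"
            )
        df = df[[gene_col, p_col]]
    else:
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
        df = df.iloc[:, :2]
    df.columns = ["gene", "p"]

    offset = 2 if header == 0 else 1
    seen = set()
    values = {}
    for i, (gene, p) in enumerate(df.itertuples(index=False)):
        line = i + offset
        try:
            p = float(p)
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{line}: non-numeric p-value {p!r}")
        if not (0.0 < p <= 1.0):
            raise ParseError(f"{path}:{line}: p-value {p} outside (0, 1]")
        if gene in seen:
            raise ParseError(f"{path}:{line}: duplicate gene id {gene!r}")
        seen.add(gene)
        values[gene] = p
    return GenePValueTable(pd.Series(values), source_label=source_label)


def write_gene_pvalues(table: GenePValueTable, path) -> None:
    df = table.pvalues.rename("p").rename_axis("gene").reset_index()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_truth(truth: PlantedTruth, path) -> None:
    df = pd.DataFrame({
        "gene": truth.gene_ids,
        "module": [truth.module_of[g] for g in truth.gene_ids],
        "risk_signal": [int(g in truth.risk_signal_genes) for g in truth.gene_ids],
        "endo_signal": [int(g in truth.endo_signal_genes) for g in truth.gene_ids],
    })
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> PlantedTruth:
    df = _read_tsv(path)
    module_of = dict(zip(df["gene"], df["module"].astype(int)))
    return PlantedTruth(
        gene_ids=df["gene"].tolist(),
        module_of=module_of,
        disease_module_ids={m for m in set(module_of.values()) if m != 0},
        risk_signal_genes=set(df.loc[df["risk_signal"].astype(int) == 1, "gene"]),
        endo_signal_genes=set(df.loc[df["endo_signal"].astype(int) == 1, "gene"]),
    )


def write_functional_scores(table: FunctionalScoreTable, path) -> None:
    df = table.scores[["mean_uppr", "FS"]].rename_axis("gene").reset_index()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_functional_scores(path) -> FunctionalScoreTable:
    df = _read_tsv(path)
    out = df.set_index("gene")[["mean_uppr", "FS"]].astype(float)
    return FunctionalScoreTable(out)


def write_combined_scores(table: CombinedScoreTable, path) -> None:
    cols = [c for c in ("mean_uppr", "FS", "p", "PS", "CS")
            if c in table.scores.columns]
    df = table.scores[cols].rename_axis("gene").reset_index()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_module_assignment(partition, fs: FunctionalScoreTable, path) -> None:
    genes = sorted(partition.assignment)
    df = pd.DataFrame({
        "gene": genes,
        "module": [partition.assignment[g] for g in genes],
        "FS": [float(fs.scores.loc[g, "FS"]) if g in fs.scores.index else np.nan
               for g in genes],
    }).sort_values(["module", "FS"], ascending=[True, False])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
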