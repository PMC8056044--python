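"""Integration of functional and positional scores via the empirical joint CDF.

Each gene carries a functional score ``FS`` from the network
reprioritization and a positional score ``PS = -log10(p)`` from the
endophenotype GWAS.  The combined score of gene ``g_j`` is the value of
the empirical joint CDF at its score pair,

    CS(g_j) = #{g : FS(g) < FS(g_j)  and  PS(g) < PS(g_j)} / N,

the probability that a randomly chosen gene scores strictly lower on
both axes.  ``N`` counts the genes scored on both axes.  Both strict
inequalities are kept exactly as defined, so tied genes never dominate
each other and CS is invariant under any strictly increasing transform
of either axis.

Two implementations are provided: an O(N log N) sort-and-sweep using a
Fenwick tree over PS ranks, and an O(N^2) brute-force transcription of
the definition kept as a testing oracle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from netprio.datatypes import (
    CombinedScoreTable,
    FunctionalScoreTable,
    GenePValueTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


def positional_score(p_table: GenePValueTable) -> pd.Series:
    """``PS(g) = -log10(p_g)``; zero at p = 1."""
    ps = -np.log10(p_table.pvalues)
    ps.name = "PS"
    return ps


def _align(fs: FunctionalScoreTable, ps: pd.Series) -> pd.DataFrame:
    shared = fs.scores.index.intersection(ps.index)
    dropped = (len(fs.scores) - len(shared)) + (len(ps) - len(shared))
    if dropped:
        logger.info("dropped %d genes missing one of the two scores", dropped)
    if len(shared) < 2:
        raise ValidationError(
            f"need >= 2 genes scored on both axes, got {len(shared)}"
        )
    df = pd.DataFrame({"FS": fs.scores.loc[shared, "FS"], "PS": ps.loc[shared]})
    if "mean_uppr" in fs.scores.columns:
        df["mean_uppr"] = fs.scores.loc[shared, "mean_uppr"]
    return df


def _finish(df: pd.DataFrame, counts: np.ndarray) -> CombinedScoreTable:
    n = len(df)
    df = df.assign(CS=counts / n, _gene=df.index)
    # deterministic ranking: CS desc, ties by PS then FS desc, then gene id
    df = df.sort_values(["CS", "PS", "FS", "_gene"],
                        ascending=[False, False, False, True])
    df = df.drop(columns="_gene")
    return CombinedScoreTable(df, n=n)


class _Fenwick:
    """Fenwick (binary indexed) tree over rank counts."""

    __slots__ = ("tree",)

    def __init__(self, size: int) -> None:
        self.tree = [0] * (size + 1)

    def add(self, i: int) -> None:
        i += 1
        while i < len(self.tree):
            self.tree[i] += 1
            i += i & (-i)

    def count_below(self, i: int) -> int:
        """Number of inserted ranks strictly less than ``i``."""
        total = 0
        while i > 0:
            total += self.tree[i]
            i -= i & (-i)
        return total


def combined_score(fs: FunctionalScoreTable, ps: pd.Series) -> CombinedScoreTable:
    """Fast combined score: sort by FS, sweep a Fenwick tree over PS ranks.

    Genes tied on FS are processed as a block — they are all queried
    against the genes with strictly smaller FS before any of them is
    inserted — so within-block genes never dominate each other, exactly
    matching the strict-inequality definition.
    """
    df = _align(fs, ps)
    fs_v = df["FS"].to_numpy()
    ps_rank = pd.Series(df["PS"].to_numpy()).rank(method="dense").astype(int).to_numpy()

    order = np.argsort(fs_v, kind="stable")
    tree = _Fenwick(int(ps_rank.max()))
    counts = np.zeros(len(df), dtype=np.int64)

    i = 0
    while i < len(order):
        j = i
        while j < len(order) and fs_v[order[j]] == fs_v[order[i]]:
            j += 1
        block = order[i:j]
        for k in block:
            counts[k] = tree.count_below(ps_rank[k] - 1)
        for k in block:
            tree.add(ps_rank[k] - 1)
        i = j
    return _finish(df, counts)


def combined_score_bruteforce(fs: FunctionalScoreTable,
                              ps: pd.Series) -> CombinedScoreTable:
    """O(N^2) literal transcription of the CS definition (testing oracle)."""
    df = _align(fs, ps)
    fs_v = df["FS"].to_numpy()
    ps_v = df["PS"].to_numpy()
    counts = np.zeros(len(df), dtype=np.int64)
    for j in range(len(df)):
        counts[j] = int(np.sum((fs_v < fs_v[j]) & (ps_v < ps_v[j])))
    return _finish(df, counts)
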