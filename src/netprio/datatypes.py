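"""Core tabular containers shared across pipeline stages.

Networks are plain :class:`networkx.Graph` objects whose edges carry a
``weight`` attribute in (0, 1] — the predicted probability that two
genes functionally interact in the tissue of interest.  Score tables
are thin dataclasses around :class:`pandas.DataFrame` / ``Series`` so
that validation happens once at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented domain invariant."""


def validate_network(graph: nx.Graph) -> None:
    """Check the functional-network invariants.

    Undirected simple graph, no self-loops, every edge weighted with a
    value in (0, 1].
    """
    if graph.is_directed():
        raise ValidationError("functional network must be undirected")
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValidationError(f"self-loop on gene {u!r} is not allowed")
        w = data.get("weight")
        if w is None:
            raise ValidationError(f"edge ({u!r}, {v!r}) has no weight")
        if not (0.0 < w <= 1.0):
            raise ValidationError(
                f"edge ({u!r}, {v!r}) weight {w} outside (0, 1]"
            )


@dataclass
class GenePValueTable:
    """Per-gene association p-values from one GWAS source.

    Parameters
    ----------
    pvalues
        Series indexed by gene id with p-values in (0, 1].
    source_label
        Free-text provenance tag, e.g. ``"risk"`` or ``"endo"``.
    """

    pvalues: pd.Series
    source_label: str = ""

    def __post_init__(self) -> None:
        s = pd.Series(self.pvalues, dtype=float)
        if s.index.has_duplicates:
            dupes = s.index[s.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        bad = s[(s <= 0.0) | (s > 1.0) | s.isna()]
        if len(bad):
            raise ValidationError(
                f"p-values outside (0, 1] for genes {bad.index.tolist()[:5]}"
            )
        self.pvalues = s

    def __len__(self) -> int:
        return len(self.pvalues)

    @property
    def genes(self) -> list:
        return self.pvalues.index.tolist()


@dataclass
class FunctionalScoreTable:
    """Ensemble output of the PU reprioritization.

    ``scores`` has one row per network gene with columns ``mean_uppr``
    (mean unlabeled-predicted-positive rate over models, in [0, 1]) and
    ``FS`` (``-log10(mean_uppr)``, floored mean so FS is finite).
    """

    scores: pd.DataFrame
    n_models: int = 0

    def __post_init__(self) -> None:
        df = self.scores
        missing = {"mean_uppr", "FS"} - set(df.columns)
        if missing:
            raise ValidationError(f"score table missing columns {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate gene ids in functional score table")
        if (df["FS"] < 0).any():
            raise ValidationError("FS must be non-negative")
        if ((df["mean_uppr"] < 0) | (df["mean_uppr"] > 1)).any():
            raise ValidationError("mean_uppr must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def fs(self) -> pd.Series:
        return self.scores["FS"]


@dataclass
class CombinedScoreTable:
    """Joint-CDF combined scores over genes present on both axes.

    ``scores`` columns: ``FS``, ``PS``, ``CS``; sorted by ``CS``
    descending with deterministic tie-breaking (PS, then FS, then gene
    id).  ``n`` is the number of jointly scored genes, so
    ``CS`` lies in [0, (n-1)/n].
    """

    scores: pd.DataFrame
    n: int = 0

    def __post_init__(self) -> None:
        missing = {"FS", "PS", "CS"} - set(self.scores.columns)
        if missing:
            raise ValidationError(f"combined table missing columns {sorted(missing)}")
        cs = self.scores["CS"].to_numpy()
        if self.n and (np.any(cs < 0) or np.any(cs > (self.n - 1) / self.n)):
            raise ValidationError("CS outside [0, (N-1)/N]")

    def __len__(self) -> int:
        return len(self.scores)

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.scores.head(k)
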