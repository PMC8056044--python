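"""Network-based gene reprioritization with a positive-unlabeled SVM ensemble.

Every gene ``g`` in the functional network gets a feature vector
``f_g = [W_{g p_1}, ..., W_{g p_n}]`` of edge weights to the ``n``
positive (risk-GWAS significant) genes.  An ensemble of linear
soft-margin SVMs is trained, each against an independent balanced
random sample of unlabeled genes as putative negatives.  Model scores
are normalized to an unlabeled-predicted-positive rate

    UPPR_ij = #{g in U : M_i(g) > M_i(g_j)}
              / (#{g in U : M_i(g) > M_i(g_j)} + #{g in U : M_i(g_j) > M_i(g)})

(strict inequalities; ties excluded from both counts), and aggregated
to the functional score ``FS(g) = -log10(mean_i UPPR_ij)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from netprio.datatypes import (
    FunctionalScoreTable,
    GenePValueTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Ensemble and cross-validation settings.

    ``c_grid`` is searched by stratified k-fold CV maximizing held-out
    ROC AUC; a single-element grid skips the search.  Per-model
    randomness (negative sampling, CV folds) is derived from ``seed``
    and the model index, so the whole ensemble is reproducible.
    """

    n_models: int = 100
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValidationError("n_models must be >= 1")
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValidationError("c_grid must be non-empty with positive costs")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")


def select_positives(risk_table: GenePValueTable, alpha: float = 0.01,
                     network: nx.Graph | None = None) -> list[str]:
    """Genes with ``p < alpha``, restricted to network nodes if given.

    Returns a sorted gene list; raises if the selection is empty.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha}")
    sel = risk_table.pvalues[risk_table.pvalues < alpha].index
    if network is not None:
        off = [g for g in sel if g not in network]
        if off:
            logger.warning("dropping %d positive genes absent from network", len(off))
        sel = [g for g in sel if g in network]
    positives = sorted(sel)
    if not positives:
        raise ValidationError(
            f"no genes pass p < {alpha}; loosen alpha or check inputs"
        )
    logger.info("selected %d positive genes at p < %g", len(positives), alpha)
    return positives


def build_features(network: nx.Graph, positives: list[str]) -> pd.DataFrame:
    """Feature matrix: rows = all network genes, columns = positives.

    Entry (g, p) is the edge weight W_{gp}, 0 when the pair is not
    linked; a positive's own column entry is 0 (no self-loops).
    """
    if len(set(positives)) != len(positives):
        raise ValidationError("duplicate genes in positive set")
    missing = [p for p in positives if p not in network]
    if missing:
        raise ValidationError(f"positive genes absent from network: {missing[:5]}")
    nodes = sorted(network.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    X = np.zeros((len(nodes), len(positives)))
    for k, p in enumerate(positives):
        for nbr, data in network[p].items():
            X[idx[nbr], k] = data["weight"]
    return pd.DataFrame(X, index=nodes, columns=list(positives))


def sample_unlabeled_negatives(all_genes, positives, n: int,
                               rng: np.random.Generator | int) -> list[str]:
    """Uniform sample of ``n`` unlabeled genes, without replacement."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    unlabeled = sorted(set(all_genes) - set(positives))
    if n > len(unlabeled):
        raise ValidationError(
            f"cannot sample {n} negatives from {len(unlabeled)} unlabeled genes"
        )
    return sorted(rng.choice(unlabeled, size=n, replace=False))


def train_one_model(features: pd.DataFrame, positives: list[str],
                    negatives: list[str], cfg: TrainingConfig,
                    model_index: int = 0) -> pd.Series:
    """Fit one linear max-margin classifier; return decision values.

    The labeled rows (positives = 1, negatives = 0) train a linear
    soft-margin SVM; the cost C is chosen over ``cfg.c_grid`` by
    stratified k-fold CV on held-out ROC AUC.  The returned Series maps
    every gene in ``features`` to its signed distance from the
    separating hyperplane.  The chosen C is stored in ``.attrs["C"]``.
    """
    pos, neg = list(positives), list(negatives)
    if set(pos) & set(neg):
        raise ValidationError("positive and negative sets overlap")
    if not pos or not neg:
        raise ValidationError("training needs both classes")
    X = features.loc[pos + neg].to_numpy()
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    if np.all(X == X[0]):
        raise ValidationError("degenerate training set: all rows identical")

    fold_seed = int(
        np.random.SeedSequence([cfg.seed, model_index, 1]).generate_state(1)[0]
        % (2**31 - 1)
    )
    if len(cfg.c_grid) == 1:
        model = SVC(kernel="linear", C=cfg.c_grid[0])
        model.fit(X, y)
        chosen_c = cfg.c_grid[0]
    else:
        n_folds = min(cfg.n_folds, len(pos), len(neg))
        if n_folds < 2:
            raise ValidationError("too few examples per class for cross-validation")
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        search = GridSearchCV(
            SVC(kernel="linear"),
            {"C": list(cfg.c_grid)},
            cv=cv,
            scoring="roc_auc",
            n_jobs=1,
        )
        search.fit(X, y)
        model = search.best_estimator_
        chosen_c = search.best_params_["C"]

    decisions = pd.Series(
        model.decision_function(features.to_numpy()),
        index=features.index,
        name=f"model_{model_index}",
    )
    if not np.all(np.isfinite(decisions)):
        raise ValidationError("non-finite decision values")
    decisions.attrs["C"] = chosen_c
    return decisions


def compute_uppr(decisions: pd.Series, unlabeled, gene: str) -> float:
    """Unlabeled-predicted-positive rate of one gene under one model.

    Counts unlabeled genes with decision values strictly above and
    strictly below the gene's own value; ties (including the gene
    itself when unlabeled) enter neither count.  When every unlabeled
    gene is tied the ratio is undefined and the uninformative midpoint
    0.5 is returned.
    """
    if gene not in decisions.index:
        raise ValidationError(f"gene {gene!r} has no decision value")
    u = decisions.loc[list(unlabeled)].to_numpy()
    d = decisions.loc[gene]
    above = int(np.sum(u > d))
    below = int(np.sum(d > u))
    if above + below == 0:
        return 0.5
    return above / (above + below)


def compute_uppr_all(decisions: pd.Series, unlabeled) -> pd.Series:
    """Vectorized UPPR for every gene in ``decisions`` at once.

    Equivalent to calling :func:`compute_uppr` per gene (tested
    property); sorts the unlabeled decision values once and uses binary
    search for the strict above/below counts.
    """
    u = np.sort(decisions.loc[list(unlabeled)].to_numpy())
    d = decisions.to_numpy()
    below = np.searchsorted(u, d, side="left")
    above = u.size - np.searchsorted(u, d, side="right")
    denom = above + below
    with np.errstate(invalid="ignore"):
        uppr = np.where(denom > 0, above / np.maximum(denom, 1), 0.5)
    return pd.Series(uppr, index=decisions.index)


def functional_score(uppr_by_model: pd.DataFrame, n_unlabeled: int,
                     n_models: int | None = None) -> FunctionalScoreTable:
    """Aggregate per-model UPPRs into the functional score table.

    ``uppr_by_model`` has one row per gene and one column per model.
    A mean UPPR of exactly 0 is floored at ``0.5 / n_unlabeled`` before
    the logarithm so FS stays finite; FS > 2 still corresponds exactly
    to mean UPPR < 0.01 whenever the floor is below 0.01.
    """
    if uppr_by_model.shape[1] == 0:
        raise ValidationError("no models to aggregate")
    if n_unlabeled < 1:
        raise ValidationError("n_unlabeled must be >= 1")
    mean_uppr = uppr_by_model.mean(axis=1)
    floor = 0.5 / n_unlabeled
    floored = mean_uppr.where(mean_uppr > 0.0, floor)
    fs = -np.log10(floored)
    df = pd.DataFrame({"mean_uppr": mean_uppr, "FS": fs})
    df = df.sort_values("FS", ascending=False)
    return FunctionalScoreTable(df, n_models=n_models or uppr_by_model.shape[1])


def run_ngr(network: nx.Graph, risk_table: GenePValueTable,
            cfg: TrainingConfig, alpha: float = 0.01) -> FunctionalScoreTable:
    """Full reprioritization: positives -> features -> ensemble -> FS.

    Per-model seeds are spawned from ``cfg.seed`` so the whole run is
    reproducible; positives also receive UPPRs (against the unlabeled
    reference set) so every network gene gets a functional score.
    """
    positives = select_positives(risk_table, alpha, network=network)
    features = build_features(network, positives)
    all_genes = features.index.tolist()
    unlabeled = sorted(set(all_genes) - set(positives))
    if not unlabeled:
        raise ValidationError("no unlabeled genes: every network gene is positive")
    if len(positives) > len(unlabeled):
        raise ValidationError(
            "fewer unlabeled genes than positives; cannot draw balanced negatives"
        )

    upprs = {}
    chosen_cs = []
    for i in range(cfg.n_models):
        neg_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, i, 0]).generate_state(4)
        )
        negatives = sample_unlabeled_negatives(
            all_genes, positives, len(positives), neg_rng
        )
        decisions = train_one_model(features, positives, negatives, cfg, i)
        chosen_cs.append(decisions.attrs["C"])
        upprs[i] = compute_uppr_all(decisions, unlabeled)
    logger.info("per-model chosen C: %s", chosen_cs)

    table = functional_score(pd.DataFrame(upprs), len(unlabeled), cfg.n_models)
    table.scores.attrs["chosen_C"] = chosen_cs
    table.scores.attrs["n_positives"] = len(positives)
    return table
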