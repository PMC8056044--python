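"""Unit and property tests of the PU reprioritization core."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netprio import (
    SynthConfig,
    TrainingConfig,
    build_features,
    compute_uppr,
    functional_score,
    generate_network,
    generate_pvalues,
    run_ngr,
    sample_unlabeled_negatives,
    select_positives,
    train_one_model,
)
from netprio.datatypes import GenePValueTable, ValidationError
from netprio.ngr import compute_uppr_all


class TestSelectPositives:
    def test_threshold_is_strict(self):
        table = GenePValueTable(pd.Series({"A": 0.005, "B": 0.5, "C": 0.0099}))
        assert select_positives(table, 0.01) == ["A", "C"]

    def test_alpha_one_selects_everything_below_one(self):
        table = GenePValueTable(pd.Series({"A": 0.2, "B": 0.9, "C": 0.5}))
        assert select_positives(table, 1.0) == ["A", "B", "C"]

    def test_network_restriction_drops_off_network_genes(self):
        table = GenePValueTable(pd.Series({"A": 0.001, "B": 0.001, "C": 0.5}))
        g = nx.Graph()
        g.add_edge("A", "C", weight=0.5)
        assert select_positives(table, 0.01, network=g) == ["A"]

    def test_empty_selection_is_an_error(self):
        table = GenePValueTable(pd.Series({"A": 0.5, "B": 0.9}))
        with pytest.raises(ValidationError, match="alpha"):
            select_positives(table, 0.01)

    def test_count_matches_independent_scan(self, small_config, small_instance):
        network, _, risk, _ = small_instance
        positives = select_positives(risk, 0.01, network=network)
        brute = sorted(g for g, p in risk.pvalues.items()
                       if p < 0.01 and g in network)
        assert positives == brute


class TestBuildFeatures:
    def test_direct_lookup_and_absent_edges(self, toy_network):
        X = build_features(toy_network, ["p1", "p2"])
        assert X.loc["g1", "p1"] == 0.7
        assert X.loc["g1", "p2"] == 0.0
        assert X.loc["g2", "p2"] == 0.4

    def test_positive_own_column_is_zero(self, toy_network):
        X = build_features(toy_network, ["p1", "p2"])
        assert X.loc["p1", "p1"] == 0.0
        assert X.loc["p2", "p2"] == 0.0
        # but the cross entry reflects the p1-p2 edge
        assert X.loc["p1", "p2"] == 0.9

    def test_missing_positive_listed_in_error(self, toy_network):
        with pytest.raises(ValidationError, match="zzz"):
            build_features(toy_network, ["p1", "zzz"])

    def test_matrix_matches_dense_double_loop(self):
        cfg = SynthConfig(n_genes=50, module_sizes=(10,),
                          n_risk_signal=5, n_endo_signal=5, seed=4)
        network, _ = generate_network(cfg)
        positives = sorted(network.nodes)[:7]
        X = build_features(network, positives)
        for g in network.nodes:          # independent brute-force oracle
            for p in positives:
                w = network[g][p]["weight"] if network.has_edge(g, p) else 0.0
                assert X.loc[g, p] == w


class TestNegativeSampling:
    def test_exhaustive_sample_returns_all_unlabeled(self):
        genes = [f"g{i}" for i in range(12)]
        out = sample_unlabeled_negatives(genes, genes[:2], 10, rng=0)
        assert sorted(out) == sorted(genes[2:])

    def test_deterministic_under_seed(self):
        genes = [f"g{i}" for i in range(100)]
        a = sample_unlabeled_negatives(genes, genes[:10], 30, rng=42)
        b = sample_unlabeled_negatives(genes, genes[:10], 30, rng=42)
        assert a == b

    def test_oversampling_is_an_error(self):
        with pytest.raises(ValidationError):
            sample_unlabeled_negatives(["a", "b", "c"], ["a"], 5, rng=0)

    def test_draws_are_uniform(self):
        # 10,000 singleton draws over 4 genes; chi-square 99% bound df=3
        genes = ["a", "b", "c", "d", "p"]
        rng = np.random.default_rng(123)
        counts = {g: 0 for g in genes[:4]}
        for _ in range(10_000):
            (g,) = sample_unlabeled_negatives(genes, ["p"], 1, rng=rng)
            counts[g] += 1
        chi2 = sum((c - 2500) ** 2 / 2500 for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.99, df=3)


class TestTrainOneModel:
    def _features(self, rows: dict[str, list[float]]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_separable_classes_are_separated(self):
        rows = {f"p{i}": [1.0, 1.0] for i in range(4)}
        rows.update({f"n{i}": [0.0, 0.02 * i] for i in range(4)})
        rows["u0"] = [0.5, 0.5]
        X = self._features(rows)
        cfg = TrainingConfig(n_models=1, c_grid=(1.0,), n_folds=2)
        d = train_one_model(X, [f"p{i}" for i in range(4)],
                            [f"n{i}" for i in range(4)], cfg)
        assert d[[f"p{i}" for i in range(4)]].min() > \
            d[[f"n{i}" for i in range(4)]].max()

    def test_identical_features_get_identical_decision_value(self):
        rows = {"p0": [1.0, 0.9], "p1": [0.8, 1.0],
                "n0": [0.0, 0.1], "n1": [0.1, 0.0],
                "u_twin": [1.0, 0.9]}
        X = self._features(rows)
        cfg = TrainingConfig(n_models=1, c_grid=(1.0,))
        d = train_one_model(X, ["p0", "p1"], ["n0", "n1"], cfg)
        assert d["u_twin"] == pytest.approx(d["p0"], abs=1e-12)

    def test_recovers_analytic_max_margin_hyperplane(self):
        # closest hull points differ by (1, 1): normal must align with it
        rows = {"p0": [1.0, 1.0], "p1": [0.9, 1.1],
                "n0": [0.0, 0.0], "n1": [0.1, -0.1],
                # unlabeled unit probes to read the hyperplane normal back
                "o": [0.0, 0.0], "e1": [1.0, 0.0], "e2": [0.0, 1.0]}
        X = self._features(rows)
        cfg = TrainingConfig(n_models=1, c_grid=(1e6,))
        dp = train_one_model(X, ["p0", "p1"], ["n0", "n1"], cfg)
        w = np.array([dp["e1"] - dp["o"], dp["e2"] - dp["o"]])
        w /= np.linalg.norm(w)
        assert np.allclose(w, [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-3)

    def test_overlapping_classes_rejected(self):
        X = self._features({"a": [1.0], "b": [0.0]})
        cfg = TrainingConfig(n_models=1, c_grid=(1.0,))
        with pytest.raises(ValidationError):
            train_one_model(X, ["a"], ["a"], cfg)

    def test_degenerate_identical_rows_rejected(self):
        X = self._features({"a": [0.5], "b": [0.5]})
        cfg = TrainingConfig(n_models=1, c_grid=(1.0,))
        with pytest.raises(ValidationError):
            train_one_model(X, ["a"], ["b"], cfg)


class TestUppr:
    def test_hand_counted_example(self):
        d = pd.Series({"u1": 0.9, "u2": 0.5, "u3": 0.3, "u4": 0.1, "g": 0.7})
        assert compute_uppr(d, ["u1", "u2", "u3", "u4"], "g") == 0.25

    def test_maximum_gets_zero(self):
        d = pd.Series({"u1": 0.1, "u2": 0.2, "g": 0.9})
        assert compute_uppr(d, ["u1", "u2"], "g") == 0.0

    def test_all_tied_returns_half(self):
        d = pd.Series({"u1": 0.5, "u2": 0.5, "g": 0.5})
        assert compute_uppr(d, ["u1", "u2"], "g") == 0.5

    def test_missing_gene_rejected(self):
        d = pd.Series({"u1": 0.5})
        with pytest.raises(ValidationError):
            compute_uppr(d, ["u1"], "nope")

    def test_vectorized_equals_scalar_with_ties(self):
        rng = np.random.default_rng(5)
        vals = np.round(rng.normal(size=60), 1)  # rounding forces ties
        genes = [f"g{i}" for i in range(60)]
        d = pd.Series(vals, index=genes)
        unlabeled = genes[20:]
        fast = compute_uppr_all(d, unlabeled)
        for g in genes:
            assert fast[g] == pytest.approx(compute_uppr(d, unlabeled, g))

    def test_antitone_in_decision_value(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(50)]
        d = pd.Series(rng.normal(size=50), index=genes)
        uppr = compute_uppr_all(d, genes[10:])
        order = d.sort_values(ascending=False).index
        assert (uppr.loc[order].diff().dropna() >= 0).all()


class TestFunctionalScore:
    def _table(self, uppr_rows: dict[str, list[float]]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(uppr_rows, orient="index")

    def test_mean_uppr_001_gives_fs_2(self):
        out = functional_score(self._table({"g": [0.01]}), n_unlabeled=1000)
        assert out.scores.loc["g", "FS"] == pytest.approx(2.0)

    def test_mean_uppr_one_gives_fs_0(self):
        out = functional_score(self._table({"g": [1.0]}), n_unlabeled=10)
        assert out.scores.loc["g", "FS"] == 0.0

    def test_two_model_average(self):
        out = functional_score(self._table({"g": [0.1, 0.3]}), n_unlabeled=10)
        assert out.scores.loc["g", "FS"] == pytest.approx(0.69897, abs=1e-5)

    def test_zero_mean_floored_to_half_count(self):
        out = functional_score(self._table({"g": [0.0, 0.0]}), n_unlabeled=200)
        assert out.scores.loc["g", "FS"] == pytest.approx(-np.log10(0.5 / 200))

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValidationError):
            functional_score(pd.DataFrame(index=["g"]), n_unlabeled=10)


@pytest.fixture(scope="module")
def fs_table(small_instance):
    network, _, risk, _ = small_instance
    return run_ngr(network, risk, TrainingConfig(n_models=3, seed=7))


class TestRunNgr:
    def test_every_network_gene_scored(self, small_instance, fs_table):
        network, _, _, _ = small_instance
        assert set(fs_table.scores.index) == set(network.nodes)

    def test_deterministic_under_seed(self, small_instance, fs_table):
        network, _, risk, _ = small_instance
        again = run_ngr(network, risk, TrainingConfig(n_models=3, seed=7))
        pd.testing.assert_frame_equal(fs_table.scores, again.scores)

    def test_single_model_ensemble_matches_manual_pass(self, small_instance):
        network, _, risk, _ = small_instance
        cfg = TrainingConfig(n_models=1, seed=7)
        ensemble = run_ngr(network, risk, cfg)
        # manual single pass with the same derived per-model seed
        positives = select_positives(risk, 0.01, network=network)
        features = build_features(network, positives)
        unlabeled = sorted(set(features.index) - set(positives))
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0, 0]).generate_state(4)
        )
        negatives = sample_unlabeled_negatives(
            features.index, positives, len(positives), rng
        )
        d = train_one_model(features, positives, negatives, cfg, 0)
        uppr = compute_uppr_all(d, unlabeled)
        manual = functional_score(uppr.to_frame(0), len(unlabeled))
        pd.testing.assert_frame_equal(ensemble.scores, manual.scores)

    def test_planted_module_outranks_background(self, small_instance, fs_table):
        network, truth, risk, _ = small_instance
        positives = set(select_positives(risk, 0.01, network=network))
        held = sorted(truth.held_out_planted - positives)
        background = sorted(truth.background_genes - positives)
        fs = fs_table.scores["FS"]
        assert fs.loc[held].median() > fs.loc[background].median()
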