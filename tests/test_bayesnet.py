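import numpy as np
import pandas as pd
import pytest

from oitnet.bayesnet import (
    BayesNet,
    ExpertDAG,
    default_dag,
    fit_cpts,
    hand_till_auc,
    infer_marginals,
    joint_probability,
    predict_posterior,
    sample_from,
    scenario_table,
)
from oitnet.errors import ImpossibleEvidenceError
from tests.conftest import make_random_bn
from tests.oracles import bruteforce_marginals, pairwise_rank_auc


@pytest.fixture
def chain_bn():
    """a -> b -> c with hand-written CPTs."""
    dag = ExpertDAG(
        levels={"a": ("0", "1"), "b": ("0", "1"), "c": ("0", "1")},
        edges=(("a", "b"), ("b", "c")),
    )
    cpts = {
        "a": np.array([0.6, 0.4]),
        "b": np.array([[0.9, 0.1], [0.2, 0.8]]),
        "c": np.array([[0.7, 0.3], [0.0, 1.0]]),
    }
    return BayesNet(dag=dag, cpts=cpts)


@pytest.fixture
def collider_bn():
    """a -> c <- b, two parents with a 3-level child."""
    dag = ExpertDAG(
        levels={"a": ("0", "1"), "b": ("0", "1"), "c": ("x", "y", "z")},
        edges=(("a", "c"), ("b", "c")),
    )
    rng = np.random.default_rng(17)
    cpts = {
        "a": np.array([0.3, 0.7]),
        "b": np.array([0.55, 0.45]),
        "c": rng.dirichlet(np.ones(3), size=(2, 2)),
    }
    return BayesNet(dag=dag, cpts=cpts)


class TestExpertDAG:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            ExpertDAG(
                levels={"a": ("0", "1"), "b": ("0", "1")},
                edges=(("a", "b"), ("b", "a")),
            )

    def test_undeclared_endpoint_rejected(self):
        with pytest.raises(ValueError, match="declared"):
            ExpertDAG(levels={"a": ("0", "1")}, edges=(("a", "ghost"),))

    def test_default_structure_is_treatments_to_markers(self):
        dag = default_dag()
        assert set(dag.parents("mMCP1")) == {"sensitized", "diet", "oit"}
        assert dag.parents("sensitized") == ()
        # no marker-to-marker edges
        roots = {"sensitized", "diet", "oit"}
        assert all(p in roots for p, _ in dag.edges)


class TestFitCpts:
    def _data(self, rows):
        return pd.DataFrame(rows, columns=["p", "ch"])

    def _dag(self):
        return ExpertDAG(
            levels={"p": ("low", "high"), "ch": ("low", "high")},
            edges=(("p", "ch"),),
        )

    def test_deterministic_counts_give_probability_one(self):
        data = self._data([["high", "high"]] * 5 + [["low", "low"]] * 5)
        bn = fit_cpts(self._dag(), data, alpha=0.0)
        assert bn.cpts["ch"][1, 1] == 1.0

    def test_relative_frequencies(self):
        data = self._data(
            [["high", "high"]] * 3 + [["high", "low"]] + [["low", "low"]] * 2
        )
        bn = fit_cpts(self._dag(), data, alpha=0.0)
        np.testing.assert_allclose(bn.cpts["ch"][1], [0.25, 0.75])

    def test_unseen_parent_configuration_uniform(self):
        data = self._data([["high", "high"]] * 4)
        bn = fit_cpts(self._dag(), data, alpha=0.0)
        np.testing.assert_allclose(bn.cpts["ch"][0], [0.5, 0.5])

    def test_smoothing_shrinks_toward_uniform(self):
        data = self._data([["high", "high"]] * 3 + [["high", "low"]])
        bn = fit_cpts(self._dag(), data, alpha=1.0)
        np.testing.assert_allclose(bn.cpts["ch"][1], [2 / 6, 4 / 6])

    def test_missing_node_column_raises(self):
        with pytest.raises(ValueError, match="lacks"):
            fit_cpts(self._dag(), pd.DataFrame({"p": ["low"]}))

    def test_empty_data_raises(self):
        empty = pd.DataFrame({"p": [], "ch": []})
        with pytest.raises(ValueError, match="no complete rows"):
            fit_cpts(self._dag(), empty)

    def test_cpt_recovery_from_forward_samples(self):
        rng = np.random.default_rng(23)
        truth = make_random_bn(rng, max_nodes=5, max_levels=3)
        data = sample_from(truth, n=4000, seed=7)
        fitted = fit_cpts(truth.dag, data, alpha=0.0)
        # entries under well-observed parent configurations come back close
        for node in truth.dag.nodes:
            counts = fitted.counts[node].sum(axis=-1)
            mask = counts >= 200
            if mask.any():
                err = np.abs(fitted.cpts[node] - truth.cpts[node])[mask]
                assert err.max() < 0.08


class TestJointProbability:
    def test_chain_rule_product(self, chain_bn):
        p = joint_probability(chain_bn, {"a": "1", "b": "0", "c": "1"})
        assert p == pytest.approx(0.4 * 0.2 * 0.3)

    def test_zero_entry_gives_zero(self, chain_bn):
        assert joint_probability(chain_bn, {"a": "0", "b": "1", "c": "0"}) == 0.0

    def test_total_probability_is_one(self, chain_bn):
        import itertools

        total = sum(
            joint_probability(chain_bn, dict(zip("abc", combo)))
            for combo in itertools.product("01", "01", "01")
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_partial_assignment_raises(self, chain_bn):
        with pytest.raises(ValueError, match="misses"):
            joint_probability(chain_bn, {"a": "0"})


class TestInferMarginals:
    def test_empty_evidence_returns_priors(self, chain_bn):
        marg = infer_marginals(chain_bn, {})
        assert marg["a"]["1"] == pytest.approx(0.4)

    def test_full_assignment_gives_degenerate_marginals(self, chain_bn):
        marg = infer_marginals(chain_bn, {"a": "1", "b": "1", "c": "1"})
        for node in "abc":
            assert marg[node]["1"] == 1.0

    def test_collider_evidence_matches_bruteforce(self, collider_bn):
        marg = infer_marginals(collider_bn, {"c": "y"})
        oracle = bruteforce_marginals(collider_bn, {"c": "y"})
        for node in collider_bn.dag.nodes:
            for lvl, p in marg[node].items():
                assert p == pytest.approx(oracle[node][lvl], abs=1e-10)

    def test_impossible_evidence_raises(self, chain_bn):
        # c=0 is impossible when b=1 (CPT entry 0)
        with pytest.raises(ImpossibleEvidenceError):
            infer_marginals(chain_bn, {"b": "1", "c": "0"})

    def test_random_networks_match_bruteforce(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            bn = make_random_bn(rng, max_nodes=6, max_levels=3)
            nodes = list(bn.dag.nodes)
            ev_node = nodes[int(rng.integers(len(nodes)))]
            ev = {ev_node: bn.dag.levels[ev_node][0]}
            oracle = bruteforce_marginals(bn, ev)
            if oracle is None:
                continue
            marg = infer_marginals(bn, ev)
            for node in nodes:
                for lvl in bn.dag.levels[node]:
                    assert marg[node][lvl] == pytest.approx(
                        oracle[node][lvl], abs=1e-9
                    )


class TestPredictPosterior:
    def test_rows_sum_to_one_and_match_direct_inference(self, collider_bn):
        samples = pd.DataFrame({"a": ["0", "1"], "b": ["1", "0"]})
        posts = predict_posterior(collider_bn, "c", samples)
        np.testing.assert_allclose(posts.sum(axis=1), 1.0, atol=1e-12)
        direct = infer_marginals(collider_bn, {"a": "0", "b": "1"})["c"]
        for lvl in collider_bn.dag.levels["c"]:
            assert posts.iloc[0][lvl] == pytest.approx(direct[lvl], abs=1e-12)

    def test_independent_target_returns_prior(self):
        dag = ExpertDAG(levels={"t": ("0", "1"), "o": ("0", "1")}, edges=())
        bn = BayesNet(
            dag=dag,
            cpts={"t": np.array([0.25, 0.75]), "o": np.array([0.5, 0.5])},
        )
        posts = predict_posterior(bn, "t", pd.DataFrame({"o": ["0", "1"]}))
        np.testing.assert_allclose(posts["1"], [0.75, 0.75])

    def test_target_column_in_samples_raises(self, collider_bn):
        samples = pd.DataFrame({"a": ["0"], "b": ["0"], "c": ["x"]})
        with pytest.raises(ValueError, match="must not appear"):
            predict_posterior(collider_bn, "c", samples)


class TestHandTillAuc:
    def test_perfect_separation_scores_one(self):
        posts = pd.DataFrame({"neg": [0.9, 0.8, 0.2, 0.1],
                              "pos": [0.1, 0.2, 0.8, 0.9]})
        assert hand_till_auc(["neg", "neg", "pos", "pos"], posts) == 1.0

    def test_constant_scores_give_half(self):
        posts = pd.DataFrame({"a": [0.5] * 6, "b": [0.5] * 6})
        assert hand_till_auc(["a", "b"] * 3, posts) == 0.5

    def test_three_class_toy_matches_pair_counting_oracle(self):
        posts = pd.DataFrame(
            {
                "low": [0.7, 0.2, 0.1, 0.5, 0.3, 0.2],
                "mid": [0.2, 0.5, 0.3, 0.3, 0.4, 0.3],
                "high": [0.1, 0.3, 0.6, 0.2, 0.3, 0.5],
            }
        )
        y = ["low", "mid", "high", "low", "mid", "high"]
        assert hand_till_auc(y, posts) == pytest.approx(
            pairwise_rank_auc(y, posts), abs=1e-12
        )

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(31)
        posts = pd.DataFrame(rng.random((20, 3)), columns=["a", "b", "c"])
        y = rng.choice(["a", "b", "c"], size=20).tolist()
        base = hand_till_auc(y, posts)
        squashed = 1.0 / (1.0 + np.exp(-5 * posts))  # strictly increasing
        assert hand_till_auc(y, squashed) == pytest.approx(base, abs=1e-12)

    def test_absent_class_raises_unless_skipped(self):
        posts = pd.DataFrame({"a": [0.9, 0.1], "b": [0.1, 0.9], "c": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero members"):
            hand_till_auc(["a", "b"], posts)
        assert hand_till_auc(["a", "b"], posts, skip_missing=True) == 1.0


class TestScenarioTable:
    def test_baseline_column_equals_marginals(self, collider_bn):
        report = scenario_table(collider_bn, {"baseline": {}})
        marg = infer_marginals(collider_bn, {})
        for node in collider_bn.dag.nodes:
            for lvl in collider_bn.dag.levels[node]:
                assert report.table.loc[(node, lvl), "baseline"] == pytest.approx(
                    100 * marg[node][lvl]
                )

    def test_evidence_is_certain_in_its_own_column(self, collider_bn):
        report = scenario_table(collider_bn, {"fix_a": {"a": "1"}})
        assert report.table.loc[("a", "1"), "fix_a"] == 100.0

    def test_columns_sum_to_hundred_per_node(self, collider_bn):
        report = scenario_table(
            collider_bn, {"baseline": {}, "a1": {"a": "1"}, "both": {"a": "0", "b": "1"}}
        )
        sums = report.table.groupby(level="node").sum()
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-9)
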