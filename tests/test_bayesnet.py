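import itertools
import math

import numpy as np
import pandas as pd
import pytest

import synechonet as sn
from synechonet.bayesnet import _dag_to_cpdag
from synechonet.errors import NotExtendableError


def oracle_bic(df, parent_map):
    """Independent count-and-sum BIC oracle using pandas groupby."""
    m = len(df)
    total = 0.0
    for node, parents in parent_map.items():
        q = 3 ** len(parents)
        if parents:
            grouped = df.groupby(list(parents), observed=True)[node]
            ll = 0.0
            for _, vals in grouped:
                counts = vals.value_counts()
                ll += sum(c * math.log(c / len(vals)) for c in counts)
        else:
            counts = df[node].value_counts()
            ll = sum(c * math.log(c / m) for c in counts)
        total += ll - 0.5 * (3 - 1) * q * math.log(m)
    return total


def true_cpdag(dag: sn.Dag) -> sn.Cpdag:
    pa = {n: set(dag.parents(n)) for n in dag.nodes}
    dpa, und = _dag_to_cpdag(dag.nodes, pa)
    return sn.Cpdag(
        list(dag.nodes),
        {(p, c) for c, ps in dpa.items() for p in ps},
        {frozenset((a, b)) for a, nbrs in und.items() for b in nbrs},
    )


def all_dags_on(nodes):
    """Enumerate every DAG on the given (small) node set."""
    pairs = list(itertools.combinations(nodes, 2))
    for choice in itertools.product((None, 0, 1), repeat=len(pairs)):
        edges = set()
        for (a, b), c in zip(pairs, choice):
            if c == 0:
                edges.add((a, b))
            elif c == 1:
                edges.add((b, a))
        try:
            yield sn.Dag(list(nodes), edges)
        except ValueError:
            continue


class TestBicScore:
    def test_single_node_closed_form(self):
        # 10 observations all in one state: MLE log-likelihood 0,
        # penalty (2/2) ln 10
        df = pd.DataFrame({"A": [1] * 10})
        dag = sn.Dag(["A"], set())
        assert sn.bic_score(dag, df) == pytest.approx(-math.log(10), abs=1e-12)

    def test_score_equivalence_of_reversed_edge(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.choice((-1, 0, 1), size=(40, 2)), columns=["A", "B"])
        ab = sn.bic_score(sn.Dag(["A", "B"], {("A", "B")}), df)
        ba = sn.bic_score(sn.Dag(["A", "B"], {("B", "A")}), df)
        assert ab == pytest.approx(ba, abs=1e-10)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame(rng.choice((-1, 0, 1), size=(6, 2)), columns=["A", "B"])
        for parent_map in ({"A": (), "B": ()}, {"A": (), "B": ("A",)}, {"A": ("B",), "B": ()}):
            dag = sn.Dag(["A", "B"], {(p, c) for c, ps in parent_map.items() for p in ps})
            assert sn.bic_score(dag, df) == pytest.approx(oracle_bic(df, parent_map), abs=1e-10)

    def test_decomposability_on_random_dags(self):
        rng = np.random.default_rng(23)
        nodes = list("ABCDE")
        df = pd.DataFrame(rng.choice((-1, 0, 1), size=(60, 5)), columns=nodes)
        scorer = sn.BicScorer(df)
        for _ in range(10):
            edges = {
                (nodes[i], nodes[j])
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.4
            }
            dag = sn.Dag(nodes, edges)
            total = sn.bic_score(dag, df)
            families = sum(scorer.local_score(n, dag.parents(n)) for n in nodes)
            assert total == pytest.approx(families, abs=1e-10)

    def test_markov_equivalent_dags_share_scores_exhaustively(self):
        """All 3-node DAGs: equal (skeleton, v-structures) implies equal BIC."""
        rng = np.random.default_rng(24)
        df = pd.DataFrame(rng.choice((-1, 0, 1), size=(50, 3)), columns=list("ABC"))
        classes = {}
        for dag in all_dags_on(list("ABC")):
            c = true_cpdag(dag)
            key = (frozenset(map(tuple, map(sorted, c.skeleton()))), frozenset(c.v_structures()))
            classes.setdefault(key, []).append(sn.bic_score(dag, df))
        assert len(classes) > 1
        for scores in classes.values():
            assert max(scores) - min(scores) < 1e-10

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            sn.Dag(["A", "B"], {("A", "B"), ("B", "A")})


class TestGes:
    def test_independent_columns_give_empty_cpdag(self):
        rng = np.random.default_rng(30)
        df = pd.DataFrame(rng.choice((-1, 0, 1), size=(2000, 4)), columns=list("ABCD"))
        c = sn.ges(df)
        assert not c.directed_edges and not c.undirected_edges

    def test_two_node_dependence_is_an_undirected_edge(self):
        rng = np.random.default_rng(31)
        x = rng.integers(0, 3, 2000)
        y = np.where(rng.random(2000) < 0.9, x, rng.integers(0, 3, 2000))
        df = pd.DataFrame({"A": x - 1, "B": y - 1})
        c = sn.ges(df)
        assert c.directed_edges == set()
        assert c.undirected_edges == {frozenset(("A", "B"))}

    def test_collider_is_oriented(self):
        rng = np.random.default_rng(32)
        x = rng.integers(0, 3, 5000)
        y = rng.integers(0, 3, 5000)
        pick = rng.random(5000)
        z = np.where(pick < 0.45, x, np.where(pick < 0.9, y, rng.integers(0, 3, 5000)))
        df = pd.DataFrame({"X": x - 1, "Y": y - 1, "Z": z - 1})
        c = sn.ges(df)
        assert c.directed_edges == {("X", "Z"), ("Y", "Z")}
        assert c.v_structures() == {("X", "Z", "Y")}

    def test_recovers_known_network_in_most_seeds(self):
        ok = 0
        for s in range(10):
            net = sn.random_network(6, edge_prob=0.4, coupling=0.85, seed=100 + s)
            sample = sn.sample_pathway_states(net, 5000, seed=200 + s)
            rec = sn.ges(sn.to_observations(sample))
            truth = true_cpdag(net.dag)
            ok += rec.skeleton() == truth.skeleton() and rec.v_structures() == truth.v_structures()
        assert ok >= 9

    def test_non_trinary_values_rejected(self):
        df = pd.DataFrame({"A": [0, 2], "B": [0, 1]})
        with pytest.raises(ValueError, match="trinary"):
            sn.ges(df)

    def test_deterministic_given_data(self):
        rng = np.random.default_rng(33)
        sample = sn.sample_pathway_states(
            sn.random_network(5, edge_prob=0.5, coupling=0.8, seed=1), 500, seed=2
        )
        df = sn.to_observations(sample)
        a, b = sn.ges(df), sn.ges(df)
        assert a.directed_edges == b.directed_edges
        assert a.undirected_edges == b.undirected_edges


class TestCpdagToDag:
    def test_fully_directed_cpdag_is_identity(self):
        c = sn.Cpdag(["A", "B", "C"], {("A", "C"), ("B", "C")}, set())
        dag = sn.cpdag_to_dag(c)
        assert dag.edges == {("A", "C"), ("B", "C")}

    def test_single_undirected_edge_oriented_lexicographically(self):
        c = sn.Cpdag(["A", "B"], set(), {frozenset(("A", "B"))})
        assert sn.cpdag_to_dag(c).edges == {("A", "B")}

    def test_extension_preserves_v_structures_on_random_instances(self):
        for s in range(15):
            net = sn.random_network(6, edge_prob=0.4, coupling=0.8, seed=400 + s)
            c = true_cpdag(net.dag)
            ext = sn.cpdag_to_dag(c)
            assert true_cpdag(ext).v_structures() == c.v_structures()
            assert true_cpdag(ext).skeleton() == c.skeleton()

    def test_non_extendable_input_rejected(self):
        # a 4-cycle of undirected edges with no chords admits no consistent
        # extension without creating a new v-structure
        und = {frozenset(p) for p in [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]}
        with pytest.raises(NotExtendableError):
            sn.cpdag_to_dag(sn.Cpdag(list("ABCD"), set(), und))


class TestFitCpts:
    def test_root_node_frequencies_without_smoothing(self):
        df = pd.DataFrame({"A": [-1] * 2 + [0] * 3 + [1] * 5})
        model = sn.fit_cpts(sn.Dag(["A"], set()), df, pseudocount=0.0)
        np.testing.assert_allclose(model.cpts["A"], [0.2, 0.3, 0.5])

    def test_unseen_parent_configuration_uniform_with_laplace(self):
        df = pd.DataFrame({"A": [-1, -1, -1], "B": [1, 1, -1]})
        model = sn.fit_cpts(sn.Dag(["A", "B"], {("A", "B")}), df, pseudocount=1.0)
        np.testing.assert_allclose(model.cpts["B"][:, 2], [1 / 3, 1 / 3, 1 / 3])

    def test_columns_sum_to_one_on_random_data(self):
        rng = np.random.default_rng(40)
        df = pd.DataFrame(rng.choice((-1, 0, 1), size=(30, 4)), columns=list("ABCD"))
        dag = sn.Dag(list("ABCD"), {("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")})
        model = sn.fit_cpts(dag, df)
        for n in dag.nodes:
            np.testing.assert_allclose(model.cpts[n].sum(axis=0), 1.0, atol=1e-12)


class TestLinkStrength:
    def two_node_model(self, child_cpt):
        dag = sn.Dag(["P", "C"], {("P", "C")})
        return sn.BayesianNetworkModel(
            dag,
            {"P": (), "C": ("P",)},
            {"P": np.full(3, 1 / 3), "C": np.asarray(child_cpt, float)},
        )

    def test_independent_child_has_zero_strength(self):
        cpt = np.tile(np.array([0.2, 0.3, 0.5])[:, None], (1, 3))
        assert sn.link_strength(self.two_node_model(cpt), "P", "C").percent == 0.0

    def test_deterministic_copy_has_full_strength(self):
        assert sn.link_strength(self.two_node_model(np.eye(3)), "P", "C").percent == 100.0

    def test_worked_entropy_value(self):
        # H(C) = log2 3; H(C|P) = H(0.8, 0.1, 0.1) -> about 41.8%
        cpt = np.full((3, 3), 0.1)
        np.fill_diagonal(cpt, 0.8)
        ls = sn.link_strength(self.two_node_model(cpt), "P", "C")
        expected = 100 * (math.log2(3) - (-(0.8 * math.log2(0.8) + 0.2 * math.log2(0.1)))) / math.log2(3)
        assert ls.percent == pytest.approx(expected, abs=1e-9)
        assert ls.percent == pytest.approx(41.83, abs=0.01)

    def test_zero_iff_independent_in_model_joint(self):
        rng = np.random.default_rng(41)
        for s in range(5):
            net = sn.random_network(5, edge_prob=0.5, coupling=0.75, seed=500 + s)
            for p, c in sorted(net.dag.edges):
                ls = sn.link_strength(net, p, c)
                joint = net.joint_marginal((p, c)).table
                indep = np.outer(joint.sum(axis=1), joint.sum(axis=0))
                if np.allclose(joint, indep, atol=1e-12):
                    assert ls.percent == pytest.approx(0.0, abs=1e-6)
                else:
                    assert 0.0 < ls.percent <= 100.0

    def test_non_edge_rejected_and_conditional_mode_runs(self):
        model = self.two_node_model(np.eye(3))
        with pytest.raises(ValueError, match="not an edge"):
            sn.link_strength(model, "C", "P")
        assert sn.link_strength(model, "P", "C", mode="conditional").percent == 100.0


class TestModelSerialization:
    def test_round_trip(self, tmp_path):
        net = sn.random_network(4, edge_prob=0.5, coupling=0.8, seed=77)
        sn.write_model(net, tmp_path / "m.json")
        back = sn.read_model(tmp_path / "m.json")
        assert back.dag.nodes == net.dag.nodes
        assert back.dag.edges == net.dag.edges
        for n in net.dag.nodes:
            np.testing.assert_allclose(back.cpts[n], net.cpts[n])
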