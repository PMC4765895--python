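import itertools

import numpy as np
import pytest

from metconnect.expression import normalize
from metconnect.metexpress import (
    MetabolicModel,
    ModulePartition,
    Reaction,
    build_coexpression_network,
    build_enzyme_links,
    importance_scores,
    key_enzymes,
    module_auc,
    partition_modules,
    read_reactions,
    score_modules,
    write_reactions,
)
from metconnect.simulate import generate_expression

from conftest import make_dataset


def auc_oracle(scores, labels):
    """Exhaustive pair counting: wins + half-ties over all (cancer, normal) pairs."""
    cancer = [s for s, l in zip(scores, labels) if l == "cancer"]
    normal = [s for s, l in zip(scores, labels) if l == "normal"]
    wins = sum(
        1.0 if c > n else 0.5 if c == n else 0.0
        for c, n in itertools.product(cancer, normal)
    )
    auc = wins / (len(cancer) * len(normal))
    return max(auc, 1.0 - auc)


class TestCoexpressionNetwork:
    def test_shared_factor_creates_strong_edge(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=40)
        X = np.vstack([f + rng.normal(0, 1e-3, 40), 2 * f + rng.normal(0, 1e-3, 40)])
        net = build_coexpression_network(make_dataset(X), min_abs_pcc=0.7)
        assert net.graph.has_edge("g0", "g1")
        assert net.graph["g0"]["g1"]["weight"] == pytest.approx(1.0, abs=1e-4)

    def test_independent_noise_rarely_connected(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(200, 60))
        net = build_coexpression_network(make_dataset(X), min_abs_pcc=0.7)
        assert net.graph.number_of_edges() == 0
        assert len(net.nodes) == 200  # isolated genes retained

    def test_threshold_one_keeps_only_collinear_pairs(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=10)
        X = np.vstack([base, 3 * base + 1, rng.normal(size=10)])
        net = build_coexpression_network(make_dataset(X), min_abs_pcc=1.0)
        assert set(map(frozenset, net.graph.edges)) == {frozenset({"g0", "g1"})}

    def test_constant_gene_warns_and_is_isolated(self):
        rng = np.random.default_rng(2)
        X = np.vstack([np.full(10, 5.0), rng.normal(size=(3, 10))])
        with pytest.warns(UserWarning, match="constant"):
            net = build_coexpression_network(make_dataset(X), min_abs_pcc=0.5)
        assert net.graph.degree("g0") == 0


class TestPartitionModules:
    def test_disconnected_cliques_exactly_recovered(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(itertools.combinations(["a1", "a2", "a3", "a4"], 2))
        g.add_edges_from(itertools.combinations(["b1", "b2", "b3"], 2))
        from metconnect.metexpress import CoexpressionNetwork

        part = partition_modules(CoexpressionNetwork(graph=g, min_abs_pcc=0.7), seed=0)
        groups = {}
        for gene, mid in part.assignment.items():
            groups.setdefault(mid, set()).add(gene)
        assert {frozenset(v) for v in groups.values()} == {
            frozenset({"a1", "a2", "a3", "a4"}),
            frozenset({"b1", "b2", "b3"}),
        }

    def test_empty_edge_set_gives_singletons(self):
        import networkx as nx

        from metconnect.metexpress import CoexpressionNetwork

        g = nx.Graph()
        g.add_nodes_from(["x", "y", "z"])
        part = partition_modules(CoexpressionNetwork(graph=g, min_abs_pcc=0.7), seed=0)
        assert len(set(part.assignment.values())) == 3

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        from metconnect.simulate import SimulationConfig

        cfg = SimulationConfig(
            n_genes=300,
            n_normal=15,
            n_cancer=15,
            n_datasets=1,
            n_modules=4,
            module_size_range=(25, 35),
            n_cancer_modules=4,
            cancer_module_effect=2.0,
            noise_sd=0.5,
            de_fraction=0.05,
            n_drugs=10,
            instances_per_drug=2,
            n_reversers=2,
            n_enzymes=20,
            n_planted_key_enzymes=4,
            partners_per_key=2,
            n_reactions=20,
            n_planted_candidates=2,
            missing_rate=0.0,
            seed=23,
        )
        datasets, truth = generate_expression(cfg)
        net = build_coexpression_network(normalize(datasets[0]), min_abs_pcc=0.7)
        part = partition_modules(net, seed=23)
        genes = sorted(truth.planted_modules)
        planted = [truth.planted_modules[g] for g in genes]
        detected = [part.assignment[g] for g in genes]
        assert adjusted_rand_score(planted, detected) >= 0.8

    def test_deterministic_given_seed(self, small_config):
        datasets, _ = generate_expression(small_config)
        net = build_coexpression_network(normalize(datasets[0]))
        assert (
            partition_modules(net, seed=4).assignment
            == partition_modules(net, seed=4).assignment
        )


class TestModuleAuc:
    def test_perfect_separation(self):
        X = np.array([[0.0, 1.0, 2.0, 10.0, 11.0, 12.0]])
        ds = make_dataset(X)
        assert module_auc(["g0"], ds) == pytest.approx(1.0)

    def test_all_ties_is_half(self):
        ds = make_dataset(np.full((2, 6), 3.0))
        assert module_auc(["g0", "g1"], ds) == pytest.approx(0.5)

    def test_worked_pair_counting_example(self):
        # normal scores (1, 2, 3), cancer scores (2.5, 3.5): 5 of 6 pairs won
        X = np.array([[1.0, 2.0, 3.0, 2.5, 3.5]])
        ds = make_dataset(X, phenotype=["normal"] * 3 + ["cancer"] * 2)
        assert module_auc(["g0"], ds) == pytest.approx(5 / 6)

    def test_orientation_rewards_down_modules(self):
        X = np.array([[10.0, 11.0, 12.0, 0.0, 1.0, 2.0]])  # lower in cancer
        ds = make_dataset(X)
        assert module_auc(["g0"], ds) == pytest.approx(1.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            n = int(rng.integers(4, 9))
            n_cancer = int(rng.integers(1, n))
            labels = ["normal"] * (n - n_cancer) + ["cancer"] * n_cancer
            X = rng.integers(0, 4, size=(3, n)).astype(float)  # many ties
            ds = make_dataset(X, phenotype=labels)
            scores = np.median(X, axis=0)
            assert module_auc(["g0", "g1", "g2"], ds) == pytest.approx(
                auc_oracle(scores, labels)
            )

    def test_empty_module_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="no genes"):
            module_auc([], toy_dataset)


class TestEnzymeLinks:
    def test_product_substrate_chain_links(self):
        reactions = [
            Reaction("r1", "E1", frozenset({"A"}), frozenset({"B"})),
            Reaction("r2", "E2", frozenset({"B"}), frozenset({"C"})),
        ]
        assert build_enzyme_links(reactions) == {("E1", "E2")}

    def test_disjoint_metabolites_no_links(self):
        reactions = [
            Reaction("r1", "E1", frozenset({"A"}), frozenset({"B"})),
            Reaction("r2", "E2", frozenset({"C"}), frozenset({"D"})),
        ]
        assert build_enzyme_links(reactions) == set()

    def test_currency_compound_exclusion(self):
        reactions = [
            Reaction("r1", "E1", frozenset({"A"}), frozenset({"ATP"})),
            Reaction("r2", "E2", frozenset({"ATP"}), frozenset({"C"})),
        ]
        assert build_enzyme_links(reactions) == {("E1", "E2")}
        assert build_enzyme_links(reactions, {"ATP"}) == set()

    def test_symmetric_and_order_invariant(self):
        rng = np.random.default_rng(3)
        compounds = [f"c{i}" for i in range(8)]
        reactions = [
            Reaction(
                f"r{i}",
                f"E{rng.integers(5)}",
                frozenset(rng.choice(compounds, 2, replace=False)),
                frozenset(rng.choice(compounds, 2, replace=False)),
            )
            for i in range(12)
        ]
        links = build_enzyme_links(reactions)
        assert all(a < b for a, b in links)  # canonical unordered pairs
        assert build_enzyme_links(reactions[::-1]) == links

    def test_no_self_links(self):
        reactions = [
            Reaction("r1", "E1", frozenset({"A"}), frozenset({"B"})),
            Reaction("r2", "E1", frozenset({"B"}), frozenset({"C"})),
        ]
        assert build_enzyme_links(reactions) == set()

    def test_reaction_requires_substrate_and_product(self):
        with pytest.raises(ValueError, match="substrate"):
            Reaction("r1", "E1", frozenset(), frozenset({"B"}))

    def test_tsv_roundtrip(self, tmp_path):
        reactions = [
            Reaction("r1", "E1", frozenset({"A", "B"}), frozenset({"C"})),
            Reaction("r2", "E2", frozenset({"C"}), frozenset({"D", "E"})),
        ]
        write_reactions(reactions, tmp_path / "rx.tsv")
        back = read_reactions(tmp_path / "rx.tsv")
        assert back == reactions


def _hub_model_and_partition():
    """50 enzymes; module MA holds 5 of them; E00 links to 3 co-module enzymes."""
    reactions = []
    for i in range(50):
        reactions.append(
            Reaction(f"base{i}", f"E{i:02d}", frozenset({f"s{i}"}), frozenset({f"p{i}"}))
        )
    for j in (1, 2, 3):  # E00 product feeds E01..E03
        reactions.append(
            Reaction(f"hub{j}", f"E{j:02d}", frozenset({"p0"}), frozenset({f"q{j}"}))
        )
    assignment = {f"E{i:02d}": "MA" if i < 5 else f"S{i}" for i in range(50)}
    auc = {m: 0.9 for m in set(assignment.values())}
    return MetabolicModel(reactions=reactions), ModulePartition(assignment, auc)


class TestImportanceScores:
    def test_hypergeometric_closed_form(self):
        model, partition = _hub_model_and_partition()
        scores = {s.gene: s for s in importance_scores(partition, model)}
        hub = scores["E00"]
        assert (hub.d_in, hub.d_tot) == (3, 3)
        # tail p = C(5,3) * C(45,0) / C(50,3) = 10 / 19600
        assert hub.enrichment == pytest.approx(-np.log10(10 / 19600))
        assert hub.score == pytest.approx(0.9 * -np.log10(10 / 19600))

    def test_zero_links_zero_score(self):
        model, partition = _hub_model_and_partition()
        scores = {s.gene: s for s in importance_scores(partition, model)}
        assert scores["E10"].d_tot == 0
        assert scores["E10"].enrichment == 0.0
        assert scores["E10"].score == 0.0

    def test_score_scales_linearly_with_auc(self):
        model, partition = _hub_model_and_partition()
        doubled = ModulePartition(
            dict(partition.assignment), {m: min(2 * a, 2.0) for m, a in partition.auc.items()}
        )
        s1 = {s.gene: s.score for s in importance_scores(partition, model)}
        s2 = {s.gene: s.score for s in importance_scores(doubled, model)}
        assert s2["E00"] == pytest.approx(2 * s1["E00"])

    def test_unpartitioned_enzyme_skipped_with_warning(self):
        model, partition = _hub_model_and_partition()
        assignment = dict(partition.assignment)
        assignment.pop("E49")
        smaller = ModulePartition(assignment, partition.auc)
        with pytest.warns(UserWarning, match="absent"):
            scores = importance_scores(smaller, model)
        assert "E49" not in {s.gene for s in scores}

    def test_missing_auc_rejected(self):
        model, partition = _hub_model_and_partition()
        with pytest.raises(ValueError, match="AUC"):
            importance_scores(ModulePartition(dict(partition.assignment)), model)


class TestKeyEnzymes:
    def _with_scores(self, values):
        from metconnect.metexpress import ImportanceScore

        return [
            ImportanceScore(f"E{i}", "M", 1.0, 0, 0, v, v) for i, v in enumerate(values)
        ]

    def test_strictly_above_median(self):
        keys = key_enzymes(self._with_scores([1, 2, 3, 4, 5]))
        assert keys == {"E3", "E4"}

    def test_all_equal_yields_empty(self):
        assert key_enzymes(self._with_scores([2, 2, 2, 2])) == set()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            key_enzymes([])

    def test_label_permutation_invariance(self):
        model, partition = _hub_model_and_partition()
        relabeled = ModulePartition(
            {g: f"Z_{m}" for g, m in partition.assignment.items()},
            {f"Z_{m}": a for m, a in partition.auc.items()},
        )
        k1 = key_enzymes(importance_scores(partition, model))
        k2 = key_enzymes(importance_scores(relabeled, model))
        assert k1 == k2

    def test_shuffled_assignment_destroys_recovery(self, small_config):
        # negative control: random gene->module assignment should not reproduce
        # the planted key enzymes
        from metconnect.simulate import generate_study

        study = generate_study(small_config)
        nds = normalize(study.datasets[0])
        net = build_coexpression_network(nds)
        part = score_modules(partition_modules(net, seed=1), nds)
        keys_real = key_enzymes(importance_scores(part, study.model))
        planted = study.truth.planted_key_enzymes
        sens_real = len(keys_real & planted) / len(planted)

        rng = np.random.default_rng(0)
        genes = list(part.assignment)
        mods = list(part.assignment.values())
        rng.shuffle(mods)
        shuffled = score_modules(
            ModulePartition(dict(zip(genes, mods))), nds
        )
        keys_shuf = key_enzymes(importance_scores(shuffled, study.model))
        sens_shuf = len(keys_shuf & planted) / len(planted)
        assert sens_real >= 0.8
        assert sens_shuf < sens_real
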