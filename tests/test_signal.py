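"""Biological-signal metrics: complex pairs, network + RWR, class
prediction, clustering concordance."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omicsqc import (
    EvaluationConfig,
    FixtureSpec,
    GeneSetCollection,
    ValidationError,
    build_coexpression_network,
    class_prediction_cv_auroc,
    clustering_concordance,
    complex_pair_correlations,
    degrade_table,
    function_prediction_auroc,
    generate_dataset,
    rwr_propagate,
)
from omicsqc.signal import CoexpressionNetwork
from conftest import make_annotation, make_table


def make_network(edges, nodes=None):
    G = nx.Graph()
    if nodes:
        G.add_nodes_from(nodes)
    for a, b, w in edges:
        G.add_edge(a, b, weight=w)
    return CoexpressionNetwork(nodes=sorted(G.nodes), graph=G)


class TestComplexPairCorrelations:
    def test_identical_rows_give_intra_r_one(self):
        row = np.arange(8.0)
        vals = np.vstack([row, row, np.random.default_rng(0).normal(size=(4, 8))])
        t = make_table(vals, features=[f"f{i}" for i in range(6)])
        cpx = GeneSetCollection(
            "complex", {"C1": ["f0", "f1"], "C2": ["f2", "f3"], "C3": ["f4", "f5"]}
        )
        res = complex_pair_correlations(t, cpx, n_pairs=10, seed=0)
        assert res.intra_correlations.max() == pytest.approx(1.0)

    def test_latent_factor_separation(self, dataset, config):
        res = complex_pair_correlations(
            dataset.table, dataset.complexes, n_pairs=200, seed=config.random_seed
        )
        assert len(res.intra_correlations) == len(res.inter_correlations)
        assert res.separation_auroc > 0.9
        # generator's closed form: intra r concentrates near 0.8
        assert abs(np.mean(res.intra_correlations) - 0.8) < 0.1
        assert abs(np.mean(res.inter_correlations)) < 0.1

    def test_noise_table_separation_near_half(self):
        aurocs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(40, 20))
            feats = [f"f{i}" for i in range(40)]
            t = make_table(vals, features=feats)
            cpx = GeneSetCollection(
                "complex",
                {f"C{k}": feats[k * 5 : (k + 1) * 5] for k in range(8)},
            )
            res = complex_pair_correlations(t, cpx, n_pairs=100, seed=seed)
            aurocs.append(res.separation_auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_no_eligible_complex_errors(self):
        t = make_table(np.ones((3, 8)), features=["f1", "f2", "f3"])
        cpx = GeneSetCollection("complex", {"C1": ["g1", "g2"]})
        with pytest.raises(ValidationError):
            complex_pair_correlations(t, cpx)


class TestCoexpressionNetwork:
    def test_identical_pair_with_top_k_one(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=10)
        vals = np.vstack([row, row, rng.normal(size=10)])
        t = make_table(vals, features=["a", "b", "c"])
        net = build_coexpression_network(
            t, EvaluationConfig(network_top_k=1, quantifiable_min_fraction=0.5)
        )
        assert net.graph.has_edge("a", "b")
        assert net.graph["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_block_structure_edges_within_modules(self):
        ds = generate_dataset(
            FixtureSpec(seed=2, n_modules=2, module_size=20, n_features=40,
                        n_samples=50, missing_rate=0.0, n_qc=0)
        )
        net = build_coexpression_network(ds.table, EvaluationConfig(network_top_k=5))
        members = {m: set(v) for m, v in ds.complexes.sets.items()}
        within = sum(
            1 for a, b in net.graph.edges
            if any(a in mem and b in mem for mem in members.values())
        )
        assert within / net.graph.number_of_edges() >= 0.95

    def test_adjacency_symmetric(self, dataset, config):
        net = build_coexpression_network(dataset.table, config)
        A = net.adjacency().to_numpy()
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 0.0)


class TestRwr:
    def test_single_node_seed(self):
        net = make_network([], nodes=["a"])
        p = rwr_propagate(net, ["a"], restart=0.5)
        assert p["a"] == pytest.approx(1.0)

    def test_two_node_closed_form(self):
        net = make_network([("a", "b", 1.0)])
        p = rwr_propagate(net, ["a"], restart=0.5, tol=1e-12)
        assert p["a"] == pytest.approx(2 / 3, abs=1e-9)
        assert p["b"] == pytest.approx(1 / 3, abs=1e-9)

    def test_matches_linear_solve_on_small_networks(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(2, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        edges.append((nodes[i], nodes[j], float(rng.uniform(0.1, 1))))
            net = make_network(edges, nodes=nodes)
            seeds = [nodes[k] for k in rng.choice(n, size=max(1, n // 3), replace=False)]
            r = 0.4
            p = rwr_propagate(net, seeds, restart=r, tol=1e-12)
            # direct solve p = r (I - (1-r) M)^-1 p0, with dangling columns -> p0
            A = nx.to_numpy_array(net.graph, nodelist=net.nodes, weight="weight")
            colsum = A.sum(axis=0)
            p0 = np.zeros(n)
            for s in seeds:
                p0[net.nodes.index(s)] = 1 / len(seeds)
            M = np.where(colsum > 0, A / np.where(colsum > 0, colsum, 1.0), 0.0)
            M = M + np.outer(p0, (colsum == 0).astype(float))
            exact = r * np.linalg.solve(np.eye(n) - (1 - r) * M, p0)
            assert np.allclose(p.loc[net.nodes].to_numpy(), exact, atol=1e-6)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_seed_membership_monotone(self, dataset, config):
        net = build_coexpression_network(dataset.table, config)
        members = list(dataset.pathways.sets.values())[0]
        in_net = [m for m in members if m in set(net.nodes)]
        target, rest = in_net[0], in_net[1:]
        p_without = rwr_propagate(net, rest, restart=0.5)
        p_with = rwr_propagate(net, rest + [target], restart=0.5)
        assert p_with[target] >= p_without[target]

    def test_empty_effective_seed_errors(self):
        net = make_network([("a", "b", 1.0)])
        with pytest.raises(ValidationError):
            rwr_propagate(net, ["zzz"])


class TestFunctionPrediction:
    def test_modular_pathway_high_auroc(self, dataset, config):
        net = build_coexpression_network(dataset.table, config)
        res = function_prediction_auroc(net, dataset.pathways, config)
        assert res.median_auroc is not None and res.median_auroc > 0.9

    def test_random_pathway_near_half(self):
        aurocs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(60, 30))
            feats = [f"f{i}" for i in range(60)]
            t = make_table(vals, features=feats)
            cfg = EvaluationConfig(random_seed=seed, network_top_k=5)
            net = build_coexpression_network(t, cfg)
            members = [feats[i] for i in rng.choice(60, size=12, replace=False)]
            pws = GeneSetCollection("pathway", {"P1": members})
            res = function_prediction_auroc(net, pws, cfg)
            aurocs.append(res.per_pathway_auroc["P1"])
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_small_pathway_excluded(self, dataset, config):
        small = GeneSetCollection(
            "pathway", {"tiny": list(dataset.pathways.sets["M01"])[:4]}
        )
        res = function_prediction_auroc(
            build_coexpression_network(dataset.table, config), small, config
        )
        assert res.per_pathway_auroc == {}
        assert res.median_auroc is None


class TestClassPrediction:
    def test_separable_single_feature(self):
        rng = np.random.default_rng(3)
        n = 20
        classes = ["tumor"] * 10 + ["normal"] * 10
        sep = np.concatenate(
            [rng.normal(5.0, 0.1, 10), rng.normal(0.0, 0.1, 10)]
        )
        t = make_table(sep[None, :])
        ann = make_annotation(t.sample_ids, classes=classes)
        res = class_prediction_cv_auroc(t, ann, EvaluationConfig(random_seed=0))
        assert res.cv_auroc == 1.0
        assert res.out_of_fold_scores.notna().all()

    def test_permuted_labels_near_half(self):
        aurocs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(80, 40))
            t = make_table(vals)
            classes = rng.permutation(["tumor"] * 20 + ["normal"] * 20)
            ann = make_annotation(t.sample_ids, classes=list(classes))
            res = class_prediction_cv_auroc(t, ann, EvaluationConfig(random_seed=seed))
            aurocs.append(res.cv_auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.15

    def test_multiclass_rejected(self):
        t = make_table(np.random.default_rng(0).normal(size=(10, 15)))
        ann = make_annotation(t.sample_ids, classes=["a", "b", "c"] * 5)
        with pytest.raises(ValidationError, match="2 class levels"):
            class_prediction_cv_auroc(t, ann, EvaluationConfig())

    def test_small_class_rejected(self):
        t = make_table(np.random.default_rng(0).normal(size=(10, 8)))
        ann = make_annotation(t.sample_ids, classes=["a"] * 6 + ["b"] * 2)
        with pytest.raises(ValidationError, match="samples"):
            class_prediction_cv_auroc(t, ann, EvaluationConfig(cv_folds=5))


class TestClusteringConcordance:
    def test_two_separated_classes_hand_ari(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=30)
        # class A samples correlate with base, class B with -base
        cols = [base + rng.normal(scale=0.05, size=30) for _ in range(4)]
        cols += [-base + rng.normal(scale=0.05, size=30) for _ in range(4)]
        t = make_table(np.column_stack(cols))
        ann = make_annotation(t.sample_ids, classes=["A"] * 4 + ["B"] * 4)
        res = clustering_concordance(t, ann)
        assert res.ari_vs_class == pytest.approx(1.0)
        # single batch: ARI of a 2-cluster partition against one batch is 0
        assert res.ari_vs_batch == pytest.approx(0.0)
        assert res.cluster_labels.nunique() == 2

    def test_random_labels_near_zero(self):
        aris = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = make_table(rng.normal(size=(40, 20)))
            classes = list(rng.permutation(["A"] * 10 + ["B"] * 10))
            ann = make_annotation(t.sample_ids, classes=classes)
            aris.append(clustering_concordance(t, ann).ari_vs_class)
        assert abs(np.mean(aris)) < 0.2

    def test_sample_permutation_invariance(self, dataset):
        study = [s for s in dataset.annotation.sample_ids if not s.startswith("QC")]
        t = dataset.table.subset_samples(study)
        ann = dataset.annotation.subset(study)
        res = clustering_concordance(t, ann)
        perm = list(reversed(study))
        res_p = clustering_concordance(
            dataset.table.subset_samples(perm), dataset.annotation.subset(perm)
        )
        assert res_p.ari_vs_class == pytest.approx(res.ari_vs_class)
        assert res_p.ari_vs_batch == pytest.approx(res.ari_vs_batch)


class TestSignalOrdering:
    def test_clean_beats_degraded_per_seed(self):
        for seed in range(3):  # broader sweep lives in the acceptance suite
            ds = generate_dataset(FixtureSpec(seed=seed, missing_rate=0.0))
            noisy = degrade_table(ds.table, 2 * ds.spec.module_latent_sd, seed=seed + 900)
            cfg = EvaluationConfig(random_seed=seed)
            clean_sep = complex_pair_correlations(
                ds.table, ds.complexes, n_pairs=150, seed=seed
            ).separation_auroc
            noisy_sep = complex_pair_correlations(
                noisy, ds.complexes, n_pairs=150, seed=seed
            ).separation_auroc
            assert clean_sep > noisy_sep
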