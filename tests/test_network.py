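"""Glasso estimation, pruning algebra, patient signatures, and consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabosig import network
from metabosig.containers import FeatureMatrix, MetabolicNetwork, PatientSignature, SampleMetadata
from metabosig.synthetic import simulate_ggm
from oracles import glasso_bruteforce

from conftest import two_group_metadata


def random_network(rng, nodes=10, p_edge=0.3, provenance=""):
    names = [f"n{i}" for i in range(nodes)]
    edges = [
        (names[i], names[j])
        for i in range(nodes)
        for j in range(i + 1, nodes)
        if rng.random() < p_edge
    ]
    return MetabolicNetwork.from_edges(edges, provenance=provenance)


class TestPruneAlgebra:
    def test_simple_difference(self):
        g = MetabolicNetwork.from_edges([("a", "b"), ("b", "c")])
        s = MetabolicNetwork.from_edges([("b", "c")])
        out = network.prune(g, s)
        assert out.edges == {frozenset(("a", "b"))}
        assert out.nodes == {"a", "b"}

    def test_self_prune_empty(self):
        g = MetabolicNetwork.from_edges([("a", "b"), ("c", "d")])
        out = network.prune(g, g)
        assert out.edges == set() and out.nodes == set()

    def test_prune_by_empty_is_identity(self):
        g = MetabolicNetwork.from_edges([("a", "b"), ("c", "d")])
        out = network.prune(g, MetabolicNetwork())
        assert out.edges == g.edges and out.nodes == g.nodes

    def test_weights_inherited_from_general(self):
        w = {frozenset(("a", "b")): 0.4, frozenset(("b", "c")): -0.2}
        g = MetabolicNetwork.from_edges([("a", "b"), ("b", "c")], weights=w)
        out = network.prune(g, MetabolicNetwork.from_edges([("b", "c")]))
        assert out.weights == {frozenset(("a", "b")): 0.4}

    def test_algebra_on_random_graph_pairs(self):
        """Edge-count identity, disjointness, and composition on 1000
        random graph pairs of <= 20 nodes."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(2, 21))
            a = random_network(rng, nodes=n, p_edge=rng.uniform(0.1, 0.6))
            b = random_network(rng, nodes=n, p_edge=rng.uniform(0.1, 0.6))
            c = random_network(rng, nodes=n, p_edge=rng.uniform(0.1, 0.6))
            pab = network.prune(a, b)
            assert len(pab.edges) == len(a.edges) - len(a.edges & b.edges)
            assert not (pab.edges & b.edges)
            lhs = network.prune(pab, c)
            bc_union = MetabolicNetwork.from_edges(
                [tuple(sorted(e)) for e in (b.edges | c.edges)]
            )
            rhs = network.prune(a, bc_union)
            assert lhs.edges == rhs.edges


class TestGlassoFit:
    def test_identity_correlation_gives_empty_network(self):
        m = simulate_ggm(np.eye(6), n_samples=200, seed=0)
        net = network.fit_glasso_network(
            FeatureMatrix(m.values, "log-pareto"), lam=0.3
        )
        assert net.n_edges == 0

    def test_lambda_above_max_covariance_empties_network(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(50, 5))
        from metabosig.network import _standardized_correlation

        emp = _standardized_correlation(vals)
        lam_max = np.abs(emp - np.diag(np.diag(emp))).max()
        m = FeatureMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(50)], columns=list("abcde")),
            "log-pareto",
        )
        assert network.fit_glasso_network(m, lam=lam_max + 1e-6).n_edges == 0

    def test_two_variable_edge_sign(self):
        """For 2 variables with correlation r and lam < |r|, one edge with
        partial correlation of the same sign as r."""
        theta = np.array([[1.0, -0.5], [-0.5, 1.0]])  # positive correlation
        m = simulate_ggm(theta, n_samples=2000, seed=1)
        net = network.fit_glasso_network(FeatureMatrix(m.values, "log-pareto"), lam=0.1)
        assert net.n_edges == 1
        assert list(net.weights.values())[0] > 0

    def test_negative_lambda_rejected(self):
        m = simulate_ggm(np.eye(3), n_samples=10, seed=0)
        with pytest.raises(ValueError, match="lambda"):
            network.fit_glasso_network(FeatureMatrix(m.values, "log-pareto"), lam=-0.1)

    def test_matches_bruteforce_solver_small_problems(self):
        """Penalised precision estimates agree with an independent
        proximal-gradient solver to 1e-5 on random <= 4-variable problems."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            p = int(rng.integers(2, 5))
            n = int(rng.integers(10, 60))
            vals = rng.normal(size=(n, p))
            lam = float(rng.uniform(0.05, 0.5))
            est = network.fit_glasso_precision(vals, lam, max_iter=2000, tol=1e-12)
            from metabosig.network import _standardized_correlation

            ref = glasso_bruteforce(_standardized_correlation(vals), lam)
            assert np.max(np.abs(est - ref)) < 1e-5

    def test_edge_count_monotone_in_lambda(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(60, 12))
        m = FeatureMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(60)],
                         columns=[f"f{j}" for j in range(12)]),
            "log-pareto",
        )
        counts = [
            network.fit_glasso_network(m, lam=lam).n_edges
            for lam in np.linspace(0.05, 0.8, 10)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_block_screening_matches_direct_solve(self):
        """Component-wise solving is exact: same precision as one joint
        graphical-lasso call."""
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(21)
        vals = rng.normal(size=(80, 10))
        vals[:, 1] += 0.9 * vals[:, 0]
        vals[:, 5] += 0.8 * vals[:, 4]
        lam = 0.3
        est = network.fit_glasso_precision(vals, lam)
        from metabosig.network import _standardized_correlation

        _, ref = graphical_lasso(_standardized_correlation(vals), alpha=lam)
        assert np.allclose(est, ref, atol=1e-6)

    def test_recovers_planted_edges_on_grid(self):
        """A 10-node, 8-edge precision with partial correlations >= 0.4 is
        recovered exactly at some lambda on a 20-point grid (n=1000)."""
        ids = [f"m{i}" for i in range(10)]
        pairs = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (7, 8), (8, 9), (0, 9)]
        theta = np.eye(10)
        for i, j in pairs:
            theta[i, j] = theta[j, i] = -0.4
        m = simulate_ggm(theta, n_samples=1000, seed=3, feature_ids=ids)
        true_edges = {frozenset((ids[i], ids[j])) for i, j in pairs}
        hit = False
        for lam in np.logspace(np.log10(0.01), np.log10(0.9), 20):
            net = network.fit_glasso_network(FeatureMatrix(m.values, "log-pareto"), lam=lam)
            if net.edges == true_edges:
                hit = True
                break
        assert hit


def ggm_cohort(n_control, n_case, theta_control, theta_case=None, seed=0, prefix=""):
    """Two-group cohort drawn from known precisions, as log-pareto data."""
    p = theta_control.shape[0]
    ids = [f"v{i}" for i in range(p)]
    ctrl = simulate_ggm(theta_control, n_control, seed=seed, feature_ids=ids, sample_prefix="c")
    case = simulate_ggm(
        theta_case if theta_case is not None else theta_control,
        n_case, seed=seed + 1, feature_ids=ids, sample_prefix="d",
    )
    values = pd.concat([ctrl.values, case.values])
    matrix = FeatureMatrix(values, "log-pareto")
    meta = two_group_metadata(n_control, n_case, seed=seed)
    meta.table.index = list(values.index)
    return matrix, SampleMetadata(meta.table)


class TestDiseaseSpecificNetwork:
    def test_shared_strong_edge_is_pruned(self):
        theta = np.eye(4)
        theta[0, 1] = theta[1, 0] = -0.5
        matrix, meta = ggm_cohort(400, 400, theta, seed=2)
        net = network.disease_specific_network(matrix, meta, lam=0.2)
        assert frozenset(("v0", "v1")) not in net.edges

    def test_null_has_few_spurious_edges(self):
        """Identical case and control distributions at large n: the
        disease-specific network keeps at most 5% of the pooled edges."""
        rng = np.random.default_rng(3)
        theta = np.eye(12)
        for i, j in [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11)]:
            theta[i, j] = theta[j, i] = -0.45
        matrix, meta = ggm_cohort(800, 800, theta, seed=4)
        full = network.fit_glasso_network(matrix, lam=0.2)
        disease = network.disease_specific_network(matrix, meta, lam=0.2)
        assert disease.n_edges <= max(1, 0.05 * full.n_edges)

    def test_planted_case_only_edge_recovered(self):
        """A strong case-only edge shows up in the disease-specific network
        in most seeds. Pooling dilutes case-only structure by the case
        fraction, so the planted partial correlation must stay detectable
        after mixing (here 0.8 at equal group sizes -> pooled ~0.4)."""
        theta_c = np.eye(6)
        theta_d = theta_c.copy()
        theta_d[0, 1] = theta_d[1, 0] = -0.8
        hits = 0
        for seed in range(20):
            matrix, meta = ggm_cohort(60, 60, theta_c, theta_d, seed=100 + seed)
            net = network.disease_specific_network(matrix, meta, lam=0.26)
            hits += frozenset(("v0", "v1")) in net.edges
        assert hits >= 16

    def test_small_group_rejected(self):
        theta = np.eye(3)
        matrix, meta = ggm_cohort(10, 10, theta, seed=0)
        tiny = SampleMetadata(meta.table.iloc[[0, 1, 10, 11, 12]])
        with pytest.raises(ValueError, match=">= 3"):
            network.disease_specific_network(
                matrix.subset_samples(tiny.sample_ids), tiny, lam=0.2
            )


class TestPatientSignatures:
    def test_one_signature_per_patient(self):
        theta = np.eye(5)
        matrix, meta = ggm_cohort(20, 7, theta, seed=5)
        sigs = network.patient_signatures(matrix, meta, lam=0.3)
        assert len(sigs) == 7
        assert len({s.patient_id for s in sigs}) == 7

    @pytest.mark.parametrize("loo_cohort", ["case-only", "pooled"])
    def test_matches_direct_leave_one_out_refit(self, loo_cohort):
        """The signature battery equals a by-hand refit: for each patient,
        fit the disease-minus-one cohort, prune by control, prune by the
        full disease-specific network."""
        theta = np.eye(6)
        theta[0, 1] = theta[1, 0] = -0.4
        matrix, meta = ggm_cohort(25, 6, theta, seed=9)
        lam = 0.3
        sigs = {
            s.patient_id: s.metabolite_set
            for s in network.patient_signatures(matrix, meta, lam, loo_cohort=loo_cohort)
        }
        control_ids = meta.samples_in_group("control")
        case_ids = meta.samples_in_group("case")
        control_net = network.fit_glasso_network(matrix.subset_samples(control_ids), lam)
        full_net = network.fit_glasso_network(matrix, lam)
        disease = network.prune(full_net, control_net)
        for p in case_ids:
            rest = [c for c in case_ids if c != p]
            keep = rest if loo_cohort == "case-only" else control_ids + rest
            minus = network.fit_glasso_network(matrix.subset_samples(keep), lam)
            expected = network.prune(network.prune(minus, control_net), disease).nodes
            assert sigs[p] == expected

    def test_iid_case_group_gives_small_signatures(self):
        """Without planted case-only structure, signatures reflect only
        estimation noise and stay small."""
        theta = np.eye(20)
        matrix, meta = ggm_cohort(300, 100, theta, seed=11)
        sigs = network.patient_signatures(matrix, meta, lam=0.3)
        sizes = [len(s.metabolite_set) for s in sigs]
        assert np.median(sizes) <= 2  # <= 10% of 20 features


class TestConsensus:
    def sig(self, pid, members):
        return PatientSignature(pid, set(members))

    def test_strict_majority_rule(self):
        """At the study's battery size of 29, 20/29 passes the >50% rule
        and 14/29 (~0.483) does not."""
        sigs = []
        for i in range(29):
            members = []
            if i < 20:
                members.append("m1")
            if i < 14:
                members.append("m2")
            sigs.append(self.sig(f"p{i}", members))
        cons = network.consensus(sigs, threshold=0.5)
        assert cons.selected == {"m1"}
        assert cons.frequencies["m2"] == pytest.approx(14 / 29)

    def test_threshold_one_is_intersection(self):
        sigs = [self.sig("a", {"x", "y"}), self.sig("b", {"y", "z"})]
        cons = network.consensus(sigs, threshold=1.0)
        assert cons.selected == set()  # strict > 1.0 never passes
        cons99 = network.consensus(sigs, threshold=0.99)
        assert cons99.selected == {"y"}

    def test_all_empty_signatures(self):
        cons = network.consensus([self.sig("a", set()), self.sig("b", set())])
        assert cons.selected == set() and cons.frequencies == {}

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            network.consensus([self.sig("a", {"x"})], threshold=1.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_selection_shrinks_as_threshold_grows(self, seed):
        rng = np.random.default_rng(seed)
        sigs = [
            self.sig(f"p{i}", {f"m{j}" for j in range(8) if rng.random() < 0.5})
            for i in range(12)
        ]
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            sel = network.consensus(sigs, threshold=thr).selected
            if prev is not None:
                assert sel <= prev
            prev = sel


class TestConsensusCorrelationViews:
    def test_sign_partition(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        vals = pd.DataFrame(
            {"a": x, "b": x + 0.1 * rng.normal(size=60), "c": -x + 0.1 * rng.normal(size=60)},
            index=[f"s{i}" for i in range(60)],
        )
        m = FeatureMatrix(vals, "log")
        from metabosig.containers import ConsensusSignature

        cons = ConsensusSignature(
            frequencies={k: 1.0 for k in "abc"}, threshold=0.5,
            selected={"a", "b", "c"}, n_signatures=3,
        )
        pos, neg = network.consensus_correlation_views(cons, m)
        assert frozenset(("a", "b")) in pos.edges
        assert frozenset(("a", "c")) in neg.edges
        assert not (pos.edges & neg.edges)

    def test_perfect_anticorrelation_weight_one(self):
        vals = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, 5], "b": [5.0, 4, 3, 2, 1]},
            index=[f"s{i}" for i in range(5)],
        )
        from metabosig.containers import ConsensusSignature

        cons = ConsensusSignature({"a": 1.0, "b": 1.0}, 0.5, {"a", "b"}, 2)
        pos, neg = network.consensus_correlation_views(cons, FeatureMatrix(vals, "log"))
        assert pos.n_edges == 0
        assert neg.weights[frozenset(("a", "b"))] == pytest.approx(1.0)
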