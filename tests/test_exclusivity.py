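import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import minimize

from subtypex.exclusivity import (
    BackgroundModel,
    bh_fdr,
    extend_background_to_subtypes,
    find_triples,
    fit_background,
    poisson_binomial_cdf,
    poisson_binomial_pmf,
    screen_pairs,
)
from subtypex.exclusivity import test_pair as check_pair  # alias: avoid pytest collection

from conftest import toy_matrix


def maxent_oracle(vals: np.ndarray) -> np.ndarray:
    """Independent constrained maximum-entropy solve via a generic convex
    optimizer (dual minimization; lam[0] pinned to 0 to fix the additive
    gauge so the problem is strictly convex)."""
    m, n = vals.shape
    r, c = vals.sum(1), vals.sum(0)

    def unpack(z):
        return z[:m], np.r_[0.0, z[m:]]

    def f(z):
        mu, lam = unpack(z)
        eta = mu[:, None] + lam[None, :]
        return np.logaddexp(0, eta).sum() - (mu * r).sum() - (lam * c).sum()

    def g(z):
        mu, lam = unpack(z)
        p = 1 / (1 + np.exp(-(mu[:, None] + lam[None, :])))
        return np.r_[p.sum(1) - r, (p.sum(0) - c)[1:]]

    res = minimize(
        f, np.zeros(m + n - 1), jac=g, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    mu, lam = unpack(res.x)
    return 1 / (1 + np.exp(-(mu[:, None] + lam[None, :])))


def random_nondegenerate(rng, m, n, density=0.3):
    """Random binary matrix repaired to have no all-0/all-1 rows or columns."""
    vals = (rng.random((m, n)) < density).astype(np.int8)
    for _ in range(100):
        rs, cs = vals.sum(1), vals.sum(0)
        if ((rs > 0) & (rs < n)).all() and ((cs > 0) & (cs < m)).all():
            return vals
        for i in np.where(rs == 0)[0]:
            vals[i, rng.integers(n)] = 1
        for i in np.where(rs == n)[0]:
            vals[i, rng.integers(n)] = 0
        cs = vals.sum(0)
        for j in np.where(cs == 0)[0]:
            vals[rng.integers(m), j] = 1
        for j in np.where(cs == m)[0]:
            vals[rng.integers(m), j] = 0
    raise RuntimeError("could not repair matrix to non-degenerate form")


class TestFitBackground:
    def test_all_ones(self):
        m = toy_matrix({"A": [1, 1, 1], "B": [1, 1, 1]})
        model = fit_background(m)
        np.testing.assert_allclose(model.p, 1.0)

    def test_identity_two_by_two(self):
        m = toy_matrix({"A": [1, 0], "B": [0, 1]})
        model = fit_background(m)
        np.testing.assert_allclose(model.p, 0.5, atol=1e-6)

    def test_margins_match(self):
        rng = np.random.default_rng(0)
        vals = random_nondegenerate(rng, 8, 30)
        m = toy_matrix({f"E{i}": list(vals[i]) for i in range(8)})
        model = fit_background(m, tol=1e-8)
        np.testing.assert_allclose(model.p.sum(axis=1), vals.sum(axis=1), atol=1e-6)
        np.testing.assert_allclose(model.p.sum(axis=0), vals.sum(axis=0), atol=1e-6)
        assert model.max_margin_residual <= 1e-8

    def test_matches_independent_optimizer(self):
        rng = np.random.default_rng(1)
        vals = random_nondegenerate(rng, 6, 10)
        m = toy_matrix({f"E{i}": list(vals[i]) for i in range(6)})
        model = fit_background(m)
        np.testing.assert_allclose(model.p, maxent_oracle(vals.astype(float)), atol=1e-4)

    def test_degenerate_rows_clamped(self):
        m = toy_matrix({"A": [0, 0, 0, 0], "B": [1, 1, 1, 1], "C": [1, 0, 1, 0]})
        model = fit_background(m)
        np.testing.assert_allclose(model.prob("A"), 0.0)
        np.testing.assert_allclose(model.prob("B"), 1.0)

    def test_nonconvergence_hard_error(self):
        rng = np.random.default_rng(2)
        vals = random_nondegenerate(rng, 6, 20)
        m = toy_matrix({f"E{i}": list(vals[i]) for i in range(6)})
        with pytest.raises(RuntimeError, match="converge"):
            fit_background(m, tol=1e-12, max_iter=2)


class TestPoissonBinomial:
    def test_empty_probs(self):
        assert poisson_binomial_cdf(np.array([]), 0) == 1.0

    def test_out_of_range(self):
        p = np.array([0.5, 0.5])
        assert poisson_binomial_cdf(p, -1) == 0.0
        assert poisson_binomial_cdf(p, 2) == 1.0
        assert poisson_binomial_cdf(p, 5) == 1.0

    @given(
        p=st.floats(0.01, 0.99),
        n=st.integers(1, 50),
        x=st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_equal_probs_match_binomial(self, p, n, x):
        probs = np.full(n, p)
        expected = stats.binom.cdf(min(x, n), n, p)
        assert poisson_binomial_cdf(probs, x) == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(1, 11))
            probs = rng.random(n)
            x = int(rng.integers(0, n + 1))
            exact = 0.0
            for bits in itertools.product((0, 1), repeat=n):
                if sum(bits) <= x:
                    pr = 1.0
                    for b, p in zip(bits, probs):
                        pr *= p if b else 1 - p
                    exact += pr
            assert poisson_binomial_cdf(probs, x) == pytest.approx(exact, abs=1e-12)

    def test_invalid_probs_error(self):
        with pytest.raises(ValueError):
            poisson_binomial_cdf(np.array([1.2]), 0)

    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(4)
        pmf = poisson_binomial_pmf(rng.random(200))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)


def uniform_model(matrix, p):
    """Background with identical probability everywhere (for closed forms)."""
    n_ev, n_s = matrix.values.shape
    return BackgroundModel(
        event_ids=matrix.event_ids,
        sample_ids=matrix.sample_ids,
        p=np.full((n_ev, n_s), p),
        mu=np.zeros(n_ev),
        lam=np.zeros(n_s),
        max_margin_residual=0.0,
    )


class TestTestPair:
    def test_closed_form_zero_overlap(self):
        # both events p=0.5 on 4 samples, overlap 0:
        # ME p = P(Bin(4, 0.25) <= 0) = 0.75^4
        m = toy_matrix({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1]})
        model = uniform_model(m, 0.5)
        res = check_pair(model, m, "A", "B", "mutual_exclusivity")
        assert res.p_value == pytest.approx(0.31640625, abs=1e-12)
        assert res.overlap == 0
        assert res.expected_overlap == pytest.approx(1.0)

    def test_full_overlap_me_p_one(self):
        m = toy_matrix({"A": [1, 1, 1, 1], "B": [1, 1, 1, 1]})
        model = uniform_model(m, 0.5)
        assert check_pair(model, m, "A", "B").p_value == 1.0

    def test_tail_identity(self):
        rng = np.random.default_rng(5)
        vals = random_nondegenerate(rng, 4, 20)
        m = toy_matrix({f"E{i}": list(vals[i]) for i in range(4)})
        model = fit_background(m)
        me = check_pair(model, m, "E0", "E1", "mutual_exclusivity").p_value
        co = check_pair(model, m, "E0", "E1", "co_occurrence").p_value
        o = check_pair(model, m, "E0", "E1").overlap
        probs = model.prob("E0") * model.prob("E1")
        p_at_o = poisson_binomial_cdf(probs, o) - poisson_binomial_cdf(probs, o - 1)
        assert me + co - p_at_o == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        vals = random_nondegenerate(rng, 3, 15)
        m = toy_matrix({f"E{i}": list(vals[i]) for i in range(3)})
        model = fit_background(m)
        a = check_pair(model, m, "E0", "E2")
        b = check_pair(model, m, "E2", "E0")
        assert a.p_value == pytest.approx(b.p_value)
        assert a.overlap == b.overlap

    def test_same_gene_subtype_pair_refused(self):
        m = toy_matrix({"G": [1, 1, 0], "G::S1": [1, 0, 0], "G::S2": [0, 1, 0]})
        model = uniform_model(m, 0.5)
        with pytest.raises(ValueError, match="structurally exclusive"):
            check_pair(model, m, "G::S1", "G::S2")

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(7)
        vals = random_nondegenerate(rng, 5, 25)
        m = toy_matrix({f"E{i}": list(vals[i]) for i in range(5)})
        model = fit_background(m)
        p0 = check_pair(model, m, "E0", "E1").p_value
        perm = rng.permutation(25)
        vals_p = vals[:, perm]
        mp = toy_matrix({f"E{i}": list(vals_p[i]) for i in range(5)})
        model_p = fit_background(mp)
        assert check_pair(model_p, mp, "E0", "E1").p_value == pytest.approx(p0, abs=1e-6)


class TestBhFdr:
    def test_all_equal(self):
        q = bh_fdr(np.array([0.2, 0.2, 0.2]))
        np.testing.assert_allclose(q, 0.2)

    def test_hand_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_empty(self):
        assert bh_fdr(np.array([])).size == 0

    def test_input_order_preserved(self):
        p = np.array([0.5, 0.01, 0.03, 0.02])
        q = bh_fdr(p)
        np.testing.assert_allclose(q, [0.5, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(8)
        p = rng.random(100)
        expected = statsmodels.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


class TestScreenPairs:
    def test_single_event_empty_table(self):
        m = toy_matrix({"A": [1, 0, 1]})
        model = fit_background(m)
        table = screen_pairs(m, model, level="gene")
        assert len(table) == 0

    def test_subtype_level_excludes_same_gene(self):
        m = toy_matrix(
            {
                "G1": [1, 1, 0, 0],
                "G1::S1": [1, 0, 0, 0],
                "G1::S2": [0, 1, 0, 0],
                "G2": [0, 0, 1, 1],
                "G2::S1": [0, 0, 1, 0],
            }
        )
        model = uniform_model(m, 0.3)
        table = screen_pairs(m, model, level="subtype")
        pairs = set(map(tuple, table[["event_a", "event_b"]].to_numpy()))
        assert ("G1::S1", "G1::S2") not in pairs
        assert ("G1::S1", "G2::S1") in pairs

    def test_lexicographic_order(self):
        m = toy_matrix({"B": [1, 0, 1, 0], "A": [0, 1, 0, 1], "C": [1, 1, 0, 0]})
        model = uniform_model(m, 0.5)
        table = screen_pairs(m, model, level="gene")
        me = table[table["direction"] == "mutual_exclusivity"]
        assert list(map(tuple, me[["event_a", "event_b"]].to_numpy())) == [
            ("A", "B"), ("A", "C"), ("B", "C"),
        ]


class TestExtendBackground:
    def test_subtype_row_margin_matched(self):
        rng = np.random.default_rng(9)
        vals = random_nondegenerate(rng, 6, 40)
        rows = {f"E{i}": list(vals[i]) for i in range(6)}
        # subtype rows: split E0's carriers into two halves
        carriers = np.where(vals[0])[0]
        s1 = np.zeros(40, dtype=int)
        s1[carriers[: len(carriers) // 2]] = 1
        s2 = vals[0] - s1
        rows["E0::S1"], rows["E0::S2"] = list(s1), list(s2)
        m = toy_matrix(rows)
        gene_rows = [e for e in m.event_ids if not m.is_subtype_event(e)]
        gm = toy_matrix({e: list(m.values.loc[e]) for e in gene_rows})
        model = fit_background(gm)
        full = extend_background_to_subtypes(model, m)
        np.testing.assert_allclose(
            full.prob("E0::S1").sum(), s1.sum(), atol=1e-6
        )
        np.testing.assert_allclose(
            full.prob("E0::S2").sum(), s2.sum(), atol=1e-6
        )
        # per-sample effects frozen from the gene-level fit
        np.testing.assert_array_equal(full.lam, model.lam)


class TestFindTriples:
    @staticmethod
    def table_from_edges(edges, qs=None):
        rows = []
        for i, (a, b) in enumerate(edges):
            rows.append(
                {
                    "event_a": a, "event_b": b, "overlap": 0, "expected": 1.0,
                    "direction": "mutual_exclusivity",
                    "p": 0.001, "q": 0.01 if qs is None else qs[i], "significant": True,
                }
            )
        cols = ["event_a", "event_b", "overlap", "expected", "direction", "p", "q", "significant"]
        return pd.DataFrame(rows, columns=cols)

    def test_no_pairs_no_triples(self):
        m = toy_matrix({"A::S1": [1, 0], "B::S1": [0, 1]})
        table = self.table_from_edges([])
        assert find_triples(table, m) == []

    def test_hand_graph_single_triangle(self):
        events = ["A::S1", "B::S1", "C::S1", "D::S1", "E::S1"]
        m = toy_matrix({e: [1, 0, 0, 0, 0] for e in events})
        # one triangle A-B-C plus a dangling path C-D, D-E
        edges = [
            ("A::S1", "B::S1"), ("A::S1", "C::S1"), ("B::S1", "C::S1"),
            ("C::S1", "D::S1"), ("D::S1", "E::S1"),
        ]
        triples = find_triples(self.table_from_edges(edges), m)
        assert len(triples) == 1
        assert triples[0].events == ("A::S1", "B::S1", "C::S1")
        # oracle: exhaustive enumeration over all 3-subsets
        adj = set(map(frozenset, edges))
        exhaustive = [
            t for t in itertools.combinations(events, 3)
            if all(frozenset(p) in adj for p in itertools.combinations(t, 2))
        ]
        assert len(exhaustive) == len(triples)

    def test_same_gene_triangle_excluded(self):
        m = toy_matrix({"A::S1": [1, 0], "A::S2": [0, 1], "B::S1": [0, 0]})
        edges = [("A::S1", "A::S2"), ("A::S1", "B::S1"), ("A::S2", "B::S1")]
        assert find_triples(self.table_from_edges(edges), m) == []

    def test_q_threshold_respected(self):
        events = ["A::S1", "B::S1", "C::S1"]
        m = toy_matrix({e: [1, 0] for e in events})
        edges = [("A::S1", "B::S1"), ("A::S1", "C::S1"), ("B::S1", "C::S1")]
        table = self.table_from_edges(edges, qs=[0.01, 0.01, 0.2])
        assert find_triples(table, m, q_threshold=0.05) == []


class TestPowerMonotonicity:
    def test_detection_improves_as_suppression_deepens(self):
        """Detection of a planted subtype-restricted ME pair is monotone in
        the suppression depth (smaller epsilon -> more detections)."""
        from subtypex.io import build_gene_matrix, filter_nonsilent
        from subtypex.simulate import MEPlant, SimConfig, SubtypeSpec, simulate_cohort

        reps = 20
        rates = {}
        for eps in (0.0, 0.25, 0.5):
            detected = 0
            for rep in range(reps):
                cfg = SimConfig(
                    n_samples=250, n_genes_expr=120, n_driver_genes=10,
                    carrier_rate_range=(0.15, 0.3), load_sigma=0.4,
                    seed=1000 * rep + int(eps * 100),
                )
                cfg.carrier_rates = {"DRV01": 0.3, "DRV02": 0.3}
                cfg.subtype_specs["DRV01"] = SubtypeSpec(
                    k=2, proportions=(0.3, 0.7), de_block_size=5, log2_effect=0.0
                )
                cfg.planted_me = [MEPlant("DRV01", 1, "DRV02", epsilon=eps)]
                b = simulate_cohort(cfg)
                m = build_gene_matrix(
                    filter_nonsilent(b.mutations), b.driver_genes, b.expression.sample_ids
                )
                # subtype row straight from planted truth: this probes the
                # exclusivity module, not the clustering stage
                s1 = {s for s, v in b.truth.subtype_labels["DRV01"].items() if v == 1}
                rows = {e: list(m.values.loc[e]) for e in m.event_ids}
                rows["DRV01::S1"] = [1 if s in s1 else 0 for s in m.sample_ids]
                full = toy_matrix(rows, samples=m.sample_ids)
                model = extend_background_to_subtypes(fit_background(m), full)
                res = check_pair(model, full, "DRV01::S1", "DRV02")
                detected += res.p_value < 0.05
            rates[eps] = detected / reps
        assert rates[0.0] >= rates[0.25] >= rates[0.5]
        assert rates[0.0] > rates[0.5]
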