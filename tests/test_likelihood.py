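"""Pruning likelihood: worked cases, enumeration oracle, stratified
branches, masking monotonicity and simulation consistency."""

import math

import numpy as np
import pytest

from stratodec import (
    Area,
    Geography,
    ModelSpec,
    PruningEngine,
    Stratum,
    branch_transition,
    build_generator,
    build_state_space,
    enumeration_loglik,
    expm,
    pruning_loglik,
    read_newick,
    simulate_history,
)


class TestExpm:
    def test_t_zero_and_zero_matrix_give_identity(self):
        Q = np.array([[-1.0, 1.0], [0.5, -0.5]])
        assert np.allclose(expm(Q, 0.0), np.eye(2))
        assert np.allclose(expm(np.zeros((3, 3)), 2.5), np.eye(3))

    def test_two_state_closed_form(self):
        a, b, t = 0.7, 0.3, 1.7
        Q = np.array([[-a, a], [b, -b]])
        lam = a + b
        # closed form: P = pi + exp(-lam t) (I - pi), pi rows = (b, a)/lam
        pi = np.array([[b, a], [b, a]]) / lam
        expected = pi + math.exp(-lam * t) * (np.eye(2) - pi)
        assert np.allclose(expm(Q, t), expected, atol=1e-12)

    def test_agrees_with_taylor_series(self):
        rng = np.random.default_rng(7)
        n = 12
        R = rng.uniform(0, 0.4, size=(n, n))
        np.fill_diagonal(R, 0.0)
        Q = R - np.diag(R.sum(axis=1))
        t = 0.8
        term = np.eye(n)
        total = np.eye(n)
        for k in range(1, 60):
            term = term @ (Q * t) / k
            total = total + term
        assert np.abs(expm(Q, t) - total).max() < 1e-10

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            expm(np.array([[np.nan, 0.0], [0.0, 0.0]]), 1.0)


class TestBranchTransition:
    def test_zero_duration_is_identity(self, geo2):
        space = build_state_space(2)
        Qs = [build_generator(space, geo2, geo2.strata[0], 0.2, 0.1)]
        P = branch_transition(1.0, 1.0, geo2, Qs, space)
        assert np.allclose(P, np.eye(len(space)))

    def test_unstratified_equals_single_exponential(self, geo3):
        space = build_state_space(3)
        Q = build_generator(space, geo3, geo3.strata[0], 0.2, 0.07)
        P = branch_transition(0.3, 2.1, geo3, [Q], space)
        assert np.abs(P - expm(Q, 1.8)).max() < 1e-10

    def test_boundary_crossing_composes_and_masks(self, geo3_strat):
        space = build_state_space(3)
        Qs = [
            build_generator(space, geo3_strat, s, 0.2, 0.07) for s in geo3_strat.strata
        ]
        P = branch_transition(1.0, 2.0, geo3_strat, Qs, space)
        mask = np.array(
            [0 if bits & 1 else 1 for bits in space.states], dtype=float
        )
        expected = expm(Qs[1], 0.5) @ (mask[:, None] * expm(Qs[0], 0.5))
        assert np.abs(P - expected).max() < 1e-12
        # substochastic where masking removed mass, never superstochastic
        sums = P.sum(axis=1)
        assert (sums <= 1 + 1e-9).all()

    def test_parent_beyond_stratum_coverage_rejected(self):
        geo = Geography(
            areas=[Area(0, "X")], strata=[Stratum(10.0, 0.0, 1)]
        )
        space = build_state_space(1)
        Q = build_generator(space, geo, geo.strata[0], 0.1, 0.1)
        with pytest.raises(ValueError):
            branch_transition(0.0, 11.0, geo, [Q], space)


class TestPruningWorkedCases:
    def test_shared_singleton_likelihood_is_one_third(self, cherry, geo2):
        spec = ModelSpec(family="DEC", d=0.0, e=0.0)
        ll = pruning_loglik(cherry, {"A": 1, "B": 1}, spec, geo2)
        assert ll == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_split_singletons_likelihood_is_one_eighteenth(self, cherry, geo2):
        spec = ModelSpec(family="DEC", d=0.0, e=0.0)
        ll = pruning_loglik(cherry, {"A": 1, "B": 2}, spec, geo2)
        assert ll == pytest.approx(math.log(1 / 18), abs=1e-12)

    def test_impossible_data_returns_minus_inf(self, cherry, geo2):
        # d=e=0 BayArea-like: both daughters always inherit the ancestor
        spec = ModelSpec(family="BAYAREALIKE", d=0.0, e=0.0)
        assert pruning_loglik(cherry, {"A": 1, "B": 2}, spec, geo2) == -np.inf

    def test_plus_j_at_zero_matches_base(self, three_tip, geo3):
        tips = {"A": 0b001, "B": 0b011, "C": 0b100}
        for family in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            base = pruning_loglik(
                three_tip, tips, ModelSpec(family=family, d=0.2, e=0.05), geo3
            )
            pj = pruning_loglik(
                three_tip,
                tips,
                ModelSpec(family=family, plus_j=True, d=0.2, e=0.05, j=0.0),
                geo3,
            )
            assert pj == pytest.approx(base, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("newick", ["(A:1.0,B:1.0);", "((A:1.0,B:1.0):0.8,C:1.8);"])
    @pytest.mark.parametrize("family,plus_j", [("DEC", True), ("DIVALIKE", False), ("BAYAREALIKE", True)])
    def test_pruning_equals_enumeration(self, newick, family, plus_j, geo3):
        tree = read_newick(newick)
        rng = np.random.default_rng(42)
        for _ in range(3):
            spec = ModelSpec(
                family=family,
                plus_j=plus_j,
                d=float(10 ** rng.uniform(-2, 0)),
                e=float(10 ** rng.uniform(-2, -0.5)),
                j=float(rng.uniform(0, 2.9)) if plus_j else 0.0,
            )
            tips = {lab: int(rng.integers(1, 8)) for lab in tree.tip_labels}
            assert pruning_loglik(tree, tips, spec, geo3) == pytest.approx(
                enumeration_loglik(tree, tips, spec, geo3), abs=1e-10
            )

    def test_pruning_equals_enumeration_with_strata(self, three_tip, geo3_strat):
        spec = ModelSpec(family="DEC", plus_j=True, d=0.13, e=0.05, j=0.7)
        tips = {"A": 0b001, "B": 0b011, "C": 0b110}
        assert pruning_loglik(three_tip, tips, spec, geo3_strat) == pytest.approx(
            enumeration_loglik(three_tip, tips, spec, geo3_strat), abs=1e-10
        )


class TestLikelihoodProperties:
    def test_loglik_never_positive(self, three_tip, geo3):
        rng = np.random.default_rng(3)
        tips = {"A": 0b001, "B": 0b011, "C": 0b100}
        for _ in range(10):
            spec = ModelSpec(
                family="DEC",
                d=float(10 ** rng.uniform(-3, 1)),
                e=float(10 ** rng.uniform(-3, 1)),
            )
            assert pruning_loglik(three_tip, tips, spec, geo3) <= 0.0

    def test_tip_pattern_distribution_substochastic_under_masking(
        self, cherry, geo2
    ):
        """Summed over every nonempty tip pattern the model assigns total
        probability 1 when tips cannot go extinct (e = 0); with e > 0 the
        missing mass is exactly the null-absorption probability, and
        stratum masking removes further mass at boundary crossings."""
        strat = Geography(
            areas=geo2.areas,
            strata=[Stratum(0.5, 0.0, 0b11), Stratum(math.inf, 0.5, 0b10)],
        )
        patterns = [(a, b) for a in (1, 2, 3) for b in (1, 2, 3)]

        def total(spec, geo):
            out = 0.0
            for a, b in patterns:
                ll = pruning_loglik(cherry, {"A": a, "B": b}, spec, geo)
                if np.isfinite(ll):
                    out += math.exp(ll)
            return out

        no_extinction = ModelSpec(family="DEC", d=0.3, e=0.0)
        assert total(no_extinction, geo2) == pytest.approx(1.0, abs=1e-10)
        with_extinction = ModelSpec(family="DEC", d=0.3, e=0.15)
        t_free = total(with_extinction, geo2)
        t_con = total(with_extinction, strat)
        assert t_free < 1.0  # null absorption removes mass
        assert t_con <= 1.0 + 1e-10
        assert t_con < t_free  # the constraint really removes further mass

    def test_rescaling_handles_deep_trees(self, geo3):
        # likelihood of 64 tips over 4-unit-deep caterpillar must be finite
        from stratodec import simulate_tree

        tree = simulate_tree(64, 1.0, 0.0, seed=5, root_age=4.0)
        rng = np.random.default_rng(0)
        tips = {lab: int(rng.integers(1, 8)) for lab in tree.tip_labels}
        ll = pruning_loglik(tree, tips, ModelSpec(family="DEC", d=0.05, e=0.01), geo3)
        assert np.isfinite(ll) and ll < 0


class TestSimulationConsistency:
    def test_tip_pattern_frequencies_match_pruning_likelihoods(self, cherry, geo2):
        """Empirical 2-tip pattern frequencies from many simulated histories
        agree with the pruning likelihood of each pattern within 3 SE."""
        from stratodec.simulate import RangeSimulator

        spec = ModelSpec(family="DEC", plus_j=True, d=0.25, e=0.1, j=0.5)
        n = 100_000
        rng = np.random.default_rng(11)
        sim = RangeSimulator(cherry, spec, geo2, reject_null=False)
        counts = {}
        for k in range(n):
            hist = sim.sample(int(rng.integers(2**31)))
            if hist.has_null_tips:
                continue
            key = tuple(sorted(hist.tip_dict().items()))
            counts[key] = counts.get(key, 0) + 1
        # the pruning likelihood of a pattern is its unconditional
        # probability, so raw frequencies out of n are the right comparison
        for key, c in counts.items():
            lik = math.exp(pruning_loglik(cherry, dict(key), spec, geo2))
            p_emp = c / n
            se = math.sqrt(lik * (1 - lik) / n)
            assert abs(p_emp - lik) <= 3 * se + 1e-4, (key, p_emp, lik)
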