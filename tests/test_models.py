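"""Anagenetic generators and cladogenetic event tables for all families."""

import math

import numpy as np
import pytest

from stratodec import (
    ModelSpec,
    Stratum,
    build_clado_table,
    build_generator,
    build_state_space,
    expm,
    parse_model_name,
    reduce_to_dec,
)
from stratodec.models import JUMP, SUBSET_SYMPATRY, SYMPATRY, VICARIANCE

ALL = Stratum(math.inf, 0.0, (1 << 5) - 1)


def _stratum(n_areas):
    return Stratum(math.inf, 0.0, (1 << n_areas) - 1)


class TestGenerator:
    def test_two_area_rates_match_rules(self, geo2):
        space = build_state_space(2)
        Q = build_generator(space, geo2, geo2.strata[0], d=0.1, e=0.05)
        iX, iY, iXY = space.index(0b01), space.index(0b10), space.index(0b11)
        assert Q[iX, iXY] == pytest.approx(0.1)
        assert Q[iX, 0] == pytest.approx(0.05)
        assert Q[iX, iX] == pytest.approx(-0.15)
        assert Q[iXY, iX] == pytest.approx(0.05)
        assert Q[iXY, iY] == pytest.approx(0.05)
        assert Q[iXY, iXY] == pytest.approx(-0.10)
        assert Q[0].sum() == 0.0  # null range absorbing

    def test_zero_rates_give_zero_matrix(self, geo2):
        space = build_state_space(2)
        Q = build_generator(space, geo2, geo2.strata[0], 0.0, 0.0)
        assert not Q.any()

    def test_dispersal_rate_scales_with_source_areas(self, geo3):
        space = build_state_space(3)
        Q = build_generator(space, geo3, geo3.strata[0], d=0.2, e=0.0)
        # {X,Y} -> {X,Y,Z}: two source areas feed Z
        assert Q[space.index(0b011), space.index(0b111)] == pytest.approx(0.4)

    def test_masked_states_receive_no_rates(self, geo3_strat):
        space = build_state_space(3)
        old = geo3_strat.strata[1]  # X disallowed
        Q = build_generator(space, geo3_strat, old, d=0.1, e=0.05)
        for i, bits in enumerate(space.states):
            for jj, bits2 in enumerate(space.states):
                if i != jj and bits2 & 1:
                    assert Q[i, jj] == 0.0
            if bits & 1:
                assert not Q[i].any()  # masked rows carry no dynamics

    def test_rows_sum_to_zero_and_exponential_is_stochastic(self, geo3):
        space = build_state_space(3)
        Q = build_generator(space, geo3, geo3.strata[0], d=0.3, e=0.11)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        for t in (0.1, 1.0, 10.0):
            P = expm(Q, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert (P >= -1e-12).all()

    def test_max_range_size_blocks_expansion(self, geo3):
        space = build_state_space(3, max_range_size=2)
        Q = build_generator(space, geo3, geo3.strata[0], d=0.1, e=0.0)
        # doubles cannot expand to the (absent) triple
        assert np.allclose(Q[space.index(0b011)].sum(), 0.0, atol=1e-15)

    def test_dispersal_multipliers_scale_pairwise(self):
        from stratodec import Area, Geography

        geo = Geography(
            areas=[Area(0, "X"), Area(1, "Y")],
            dispersal_multipliers=[[1.0, 0.25], [1.0, 1.0]],
        )
        space = build_state_space(2)
        Q = build_generator(space, geo, geo.strata[0], d=0.4, e=0.0)
        assert Q[space.index(0b01), space.index(0b11)] == pytest.approx(0.1)
        assert Q[space.index(0b10), space.index(0b11)] == pytest.approx(0.4)


class TestCladoTable:
    def test_dec_singleton_is_pure_sympatry(self):
        space = build_state_space(2)
        t = build_clado_table(space, "DEC", False, 0.0, _stratum(2))
        l, r, p, c = t.events_for(space.index(0b01))
        assert len(p) == 1 and p[0] == 1.0
        assert l[0] == r[0] == space.index(0b01)
        assert c[0] == SYMPATRY

    def test_dec_two_area_ancestor_has_six_equiprobable_events(self):
        space = build_state_space(2)
        t = build_clado_table(space, "DEC", False, 0.0, _stratum(2))
        iX, iY, iXY = space.index(0b01), space.index(0b10), space.index(0b11)
        l, r, p, _ = t.events_for(iXY)
        got = sorted(zip(l.tolist(), r.tolist()))
        assert got == sorted(
            [(iX, iY), (iY, iX), (iXY, iX), (iX, iXY), (iXY, iY), (iY, iXY)]
        )
        assert np.allclose(p, 1 / 6)

    def test_jump_weight_three_puts_all_mass_on_jumps(self):
        # cap range size so every ancestor still has a free jump target
        space = build_state_space(3, max_range_size=2)
        t = build_clado_table(space, "DEC", True, 3.0, _stratum(3))
        assert (t.event_class == JUMP).all()
        _, _, p, c = t.events_for(space.index(0b001))
        assert p.sum() == pytest.approx(1.0)

    def test_jump_weight_three_with_saturated_ancestor_is_an_error(self):
        # the full range has no jump target, and j=3 zeroes all other events
        space = build_state_space(3)
        with pytest.raises(Exception, match="empty cladogenetic event set"):
            build_clado_table(space, "DEC", True, 3.0, _stratum(3))

    @pytest.mark.parametrize("family", ["DEC", "DIVALIKE", "BAYAREALIKE"])
    @pytest.mark.parametrize("plus_j,j", [(False, 0.0), (True, 0.7), (True, 2.5)])
    def test_rows_normalize_for_all_ancestors_up_to_five_areas(self, family, plus_j, j):
        space = build_state_space(5)
        t = build_clado_table(space, family, plus_j, j, ALL)
        sums = np.bincount(t.anc, weights=t.prob, minlength=len(space))
        for i, bits in enumerate(space.states):
            if bits:
                assert sums[i] == pytest.approx(1.0, abs=1e-12)
        assert sums[0] == 0.0  # null range never speciates

    def test_family_event_inventories(self):
        space = build_state_space(4)
        dec = build_clado_table(space, "DEC", False, 0.0, _stratum(4))
        diva = build_clado_table(space, "DIVALIKE", False, 0.0, _stratum(4))
        bay = build_clado_table(space, "BAYAREALIKE", False, 0.0, _stratum(4))
        assert not (diva.event_class == SUBSET_SYMPATRY).any()
        assert not (bay.event_class == SUBSET_SYMPATRY).any()
        assert not (bay.event_class == VICARIANCE).any()
        # DEC vicariance: one part always a singleton; DIVA-like also allows 2+2
        sizes = [
            (space.sizes[l], space.sizes[r])
            for l, r, c in zip(dec.left, dec.right, dec.event_class)
            if c == VICARIANCE
        ]
        assert all(min(s) == 1 for s in sizes)
        diva_sizes = [
            (space.sizes[l], space.sizes[r])
            for l, r, c in zip(diva.left, diva.right, diva.event_class)
            if c == VICARIANCE
        ]
        assert any(min(s) > 1 for s in diva_sizes)
        # BayArea-like: identical inheritance for every ancestor size
        assert (bay.left == bay.anc).all() and (bay.right == bay.anc).all()

    def test_jump_daughters_are_singletons_outside_the_ancestor(self):
        space = build_state_space(4)
        for family in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            t = build_clado_table(space, family, True, 1.0, _stratum(4))
            for anc, l, r, c in zip(t.anc, t.left, t.right, t.event_class):
                if c == JUMP:
                    new = l if l != anc else r
                    assert space.sizes[new] == 1
                    assert not space.states[new] & space.states[anc]

    def test_masking_removes_jump_targets_and_masked_ancestors(self):
        space = build_state_space(3)
        restricted = Stratum(math.inf, 0.0, 0b110)  # area X disallowed
        t = build_clado_table(space, "DEC", True, 1.0, restricted)
        for anc in np.unique(t.anc):
            assert not space.states[anc] & 1
        for l, r in zip(t.left, t.right):
            assert not space.states[l] & 1 and not space.states[r] & 1


class TestReduction:
    def test_plus_j_zero_table_identical_to_base(self):
        space = build_state_space(4)
        for family in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            base = build_clado_table(space, family, False, 0.0, _stratum(4))
            pj = build_clado_table(space, family, True, 0.0, _stratum(4))
            assert (base.anc == pj.anc).all()
            assert (base.left == pj.left).all()
            assert (base.right == pj.right).all()
            assert np.allclose(base.prob, pj.prob)

    def test_reduce_requires_j_zero(self):
        spec = ModelSpec(family="DEC", plus_j=True, d=0.1, e=0.1, j=0.0)
        assert reduce_to_dec(spec).plus_j is False
        with pytest.raises(ValueError):
            reduce_to_dec(ModelSpec(family="DEC", plus_j=True, d=0.1, e=0.1, j=0.5))

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("DEC", ("DEC", False)),
            ("dec+j", ("DEC", True)),
            ("DIVALIKE+J", ("DIVALIKE", True)),
            ("bayarealike", ("BAYAREALIKE", False)),
        ],
    )
    def test_model_name_parsing(self, name, expected):
        assert parse_model_name(name) == expected

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family="DEC", d=-0.1, e=0.0)
        with pytest.raises(ValueError):
            ModelSpec(family="DEC", plus_j=False, j=0.5)
        with pytest.raises(ValueError):
            ModelSpec(family="DEC", plus_j=True, j=3.5)
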