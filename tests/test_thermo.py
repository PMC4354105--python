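"""Gibbs energy transforms, reaction ranges and the NET feasibility LP."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoefm import (chain_model, drg_range_in_context, gen_thermo_fixture,
                       grid_net_oracle, isolated_drg_range, load_thermo,
                       minimal_infeasible_pattern, net_feasible,
                       pattern_cache_check, split_reversible, transform_dfg0)
from thermoefm.fixtures import FixtureSpec, gen_random_model
from thermoefm.thermo import (InfeasiblePattern, MetaboliteThermo, ThermoData,
                              reaction_constraint)

RT37 = 8.314e-3 * 310.15


class TestTransform:
    def test_vanishes_without_ionic_strength_and_ph(self):
        assert transform_dfg0(-42.0, n_h=3, z=-2, ph=0.0, ionic_strength=0.0) == -42.0

    @given(ph=st.floats(0, 14), i=st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_vanishes_for_neutral_protonless_species(self, ph, i):
        assert transform_dfg0(-10.0, n_h=0, z=0, ph=ph, ionic_strength=i) == -10.0

    def test_single_proton_ph7_hand_value(self):
        # -100 + 1 * R*T*ln(10)*7 at 310.15 K
        got = transform_dfg0(-100.0, n_h=1, z=0, ph=7.0, ionic_strength=0.0)
        assert got == pytest.approx(-58.438086477872766, abs=1e-9)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            transform_dfg0(0.0, 0, 0, 7.0, -0.1)


class TestIsolatedRange:
    def test_zero_stoichiometry_is_zero_range(self, chain3, simple_thermo):
        # build a model copy with an all-zero extra column via fixture model:
        # the uptake column only touches M0; easier: assert closed form on a
        # symmetric A->B reaction instead (next test) and the trivial (0,0)
        # case through a reaction whose metabolites are all excluded
        th = ThermoData({}, excluded=frozenset({"m0", "m1"}))
        lo, hi = isolated_drg_range(1, chain3, th)
        assert (lo, hi) == (0.0, 0.0)

    def test_symmetric_interval_for_equal_energies(self, chain3, simple_thermo):
        lo, hi = isolated_drg_range(1, chain3, simple_thermo)  # M0 -> M1
        width = RT37 * math.log(1e-1 / 1e-3)
        assert lo == pytest.approx(-width)
        assert hi == pytest.approx(width)

    def test_tight_bounds_pin_drg_and_orient_reaction(self):
        # A->B with dfG'(B) = -50 and c = 1 M exactly: drG = -50; the
        # reverse reaction is infeasible in isolation
        model = chain_model(1)
        th = ThermoData({"M0": MetaboliteThermo(0.0, 1.0, 1.0),
                         "M1": MetaboliteThermo(-50.0, 1.0, 1.0)})
        assert isolated_drg_range(1, model, th) == pytest.approx((-50.0, -50.0))
        rev = model.copy()
        for row in rev.S:
            row[1] = -row[1]
        assert isolated_drg_range(1, rev, th) == pytest.approx((50.0, 50.0))
        assert not net_feasible({1}, rev, th).feasible

    def test_exchange_reaction_uncharacterized(self, chain3, simple_thermo):
        assert isolated_drg_range(0, chain3, simple_thermo) is None


class TestNetFeasible:
    def test_empty_pattern_feasible_with_empty_witness(self, chain, motif_thermo):
        res = net_feasible(frozenset(), chain, motif_thermo)
        assert res.feasible and res.witness == {}

    def test_split_pair_infeasible_even_at_zero_epsilon(self, rev_pair_split):
        split, smap = rev_pair_split
        th = ThermoData({"A": MetaboliteThermo(0.0, 1e-4, 1e-2),
                         "B": MetaboliteThermo(0.0, 1e-4, 1e-2)})
        f = split.reaction_index("R_ab")
        b = split.reaction_index("R_ab_rev")
        assert net_feasible({f}, split, th).feasible
        assert net_feasible({b}, split, th).feasible
        assert not net_feasible({f, b}, split, th).feasible

    def test_motif_pairs_feasible_triple_one_directional(self, chain, motif_thermo):
        """Three consecutive reactions, individually and pairwise reversible,
        jointly feasible in only one direction."""
        triple = frozenset({1, 2, 3})
        assert not net_feasible(triple, chain, motif_thermo).feasible
        for k in (1, 2):
            import itertools
            for sub in itertools.combinations(sorted(triple), k):
                assert net_feasible(frozenset(sub), chain, motif_thermo).feasible

    def test_witness_satisfies_all_constraints(self, chain, motif_thermo):
        res = net_feasible({1, 2}, chain, motif_thermo)
        assert res.feasible
        for i in res.checked_reactions:
            con = reaction_constraint(i, chain, motif_thermo)
            drg = con.const + sum(
                v * res.witness[chain.metabolite_ids[m]]
                for m, v in con.coeffs.items())
            assert drg <= -motif_thermo.epsilon + 1e-6

    def test_uncharacterized_reactions_are_skipped(self, chain):
        th = ThermoData({"M0": MetaboliteThermo(0.0, 1e-4, 1e-2)})  # M1.. unknown
        res = net_feasible({1, 2, 3}, chain, th)
        assert res.feasible
        assert res.checked_reactions == frozenset()
        assert res.skipped_reactions == frozenset({1, 2, 3})


class TestMinimalPattern:
    def test_already_minimal_unchanged(self, chain, motif_thermo):
        p = minimal_infeasible_pattern({1, 2, 3}, chain, motif_thermo)
        assert p.reactions == frozenset({1, 2, 3})
        assert p.minimal

    def test_feasible_input_is_contract_violation(self, chain, motif_thermo):
        with pytest.raises(ValueError):
            minimal_infeasible_pattern({1, 2}, chain, motif_thermo)

    def test_superfluous_reactions_stripped(self, rev_pair_split):
        split, _ = rev_pair_split
        th = ThermoData({"A": MetaboliteThermo(0.0, 1e-4, 1e-2),
                         "B": MetaboliteThermo(0.0, 1e-4, 1e-2)})
        f = split.reaction_index("R_ab")
        b = split.reaction_index("R_ab_rev")
        p = minimal_infeasible_pattern({f, b, 0}, split, th)
        assert p.reactions == frozenset({f, b})
        # minimality: every proper subset feasible
        for i in p.reactions:
            assert net_feasible(p.reactions - {i}, split, th).feasible


class TestContextRange:
    def test_singleton_pattern_equals_isolated(self, chain, motif_thermo):
        iso = isolated_drg_range(2, chain, motif_thermo)
        ctx = drg_range_in_context(2, {2}, chain, motif_thermo)
        assert ctx == pytest.approx(iso)

    def test_context_interval_contained_in_isolated(self, chain, motif_thermo):
        iso = isolated_drg_range(2, chain, motif_thermo)
        ctx = drg_range_in_context(2, {1, 2, 3} - {0}, chain, motif_thermo)
        if ctx is not None:
            assert ctx[0] >= iso[0] - 1e-9
            assert ctx[1] <= iso[1] + 1e-9

    def test_partner_constraint_narrows_the_range(self):
        # chain M0 -> M1 -> M2 with M2 pinned at e^-5 M: the downstream
        # reaction's constraint forces x_M1 >= -5, raising the attainable
        # minimum of the upstream reaction's drG while leaving its maximum
        model = chain_model(2)
        c2 = math.exp(-5.0)
        th = ThermoData({"M0": MetaboliteThermo(0.0, 1e-3, 1e-1),
                         "M1": MetaboliteThermo(0.0, 1e-3, 1e-1),
                         "M2": MetaboliteThermo(0.0, c2, c2)})
        iso = isolated_drg_range(1, model, th)
        ctx = drg_range_in_context(1, {1, 2}, model, th)
        assert ctx is not None
        assert ctx[0] == pytest.approx(RT37 * (-5.0 - math.log(1e-1)), abs=1e-6)
        assert ctx[0] > iso[0] + 1.0
        assert ctx[1] == pytest.approx(iso[1], abs=1e-6)


class TestPatternCache:
    def test_empty_cache_never_hits(self):
        assert not pattern_cache_check({1, 2}, [])

    def test_equal_and_superset_patterns_hit(self):
        cache = [InfeasiblePattern(frozenset({1, 2}), True)]
        assert pattern_cache_check({1, 2}, cache)
        assert pattern_cache_check({0, 1, 2, 5}, cache)
        assert not pattern_cache_check({1}, cache)

    def test_superset_agrees_with_lp(self, chain, motif_thermo):
        cache = [InfeasiblePattern(frozenset({1, 2, 3}), True)]
        sup = frozenset({1, 2, 3, 4})
        assert pattern_cache_check(sup, cache)
        assert not net_feasible(sup, chain, motif_thermo).feasible


class TestMonotonicityAndGridOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_supersets_of_infeasible_patterns_stay_infeasible(self, seed):
        import numpy as np
        model = gen_random_model(FixtureSpec(m=4, r=9, density=0.5,
                                             n_reversible=2, seed=seed))
        split, _ = split_reversible(model)
        th = gen_thermo_fixture(split, seed=seed + 50)
        rng = np.random.default_rng(seed)
        interior = [j for j in range(split.n_reactions) if not split.exchange[j]]
        found = 0
        for _ in range(40):
            k = int(rng.integers(1, min(4, len(interior)) + 1))
            pat = frozenset(int(x) for x in rng.choice(interior, size=k, replace=False))
            if net_feasible(pat, split, th).feasible:
                continue
            found += 1
            extra = frozenset(int(x) for x in rng.choice(split.n_reactions, size=2))
            assert not net_feasible(pat | extra, split, th).feasible
        # at least some infeasible patterns must occur across seeds; not all
        # seeds need one, the parametrization covers the ensemble

    def test_grid_oracle_never_contradicts_lp_infeasibility(self, chain):
        """Soundness: LP-infeasible implies the grid finds no point."""
        import itertools
        import numpy as np
        rng = np.random.default_rng(7)
        trials = 0
        for seed in range(40):
            th = gen_thermo_fixture(chain, seed=seed)
            for pat in itertools.combinations([1, 2, 3], 3):
                pat = frozenset(pat)
                if not net_feasible(pat, chain, th).feasible:
                    trials += 1
                    assert not grid_net_oracle(pat, chain, th, points_per_dim=9)
        assert trials > 0

    def test_grid_oracle_trivialities(self, chain, motif_thermo, rev_pair_split):
        assert grid_net_oracle(frozenset(), chain, motif_thermo)
        split, _ = rev_pair_split
        th = ThermoData({"A": MetaboliteThermo(0.0, 1e-4, 1e-2),
                         "B": MetaboliteThermo(0.0, 1e-4, 1e-2)})
        f, b = split.reaction_index("R_ab"), split.reaction_index("R_ab_rev")
        for n in (5, 11, 21):
            assert not grid_net_oracle({f, b}, split, th, points_per_dim=n)


class TestThermoIO:
    def test_transformed_table_round_trip(self, tmp_path):
        p = tmp_path / "thermo.tsv"
        p.write_text("metabolite_id\tdfG0_prime_kJ_mol\tc_min_M\tc_max_M\n"
                     "glc\t-426.7\t1e-4\t1e-2\n"
                     "unk\t\t\t\n")
        th = load_thermo(p)
        assert th.dfg0_prime("glc") == pytest.approx(-426.7)
        assert th.bounds("glc") == (1e-4, 1e-2)
        assert th.dfg0_prime("unk") is None
        assert th.bounds("unk") == (th.default_c_min, th.default_c_max)

    def test_raw_table_applies_the_transform(self, tmp_path):
        p = tmp_path / "raw.tsv"
        p.write_text("metabolite_id\tdfG0_kJ_mol\tn_H\tcharge\n"
                     "x\t-100.0\t1\t0\n")
        th = load_thermo(p, ph=7.0, ionic_strength=0.0)
        assert th.dfg0_prime("x") == pytest.approx(-58.438086477872766)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ThermoData({"x": MetaboliteThermo(0.0, 1e-2, 1e-4)})
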