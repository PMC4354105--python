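"""Model reading, splitting, condition sub-models, compression and kernel."""

import os
import textwrap
from fractions import Fraction

import pytest

import cobra
from thermoefm import (build_condition_model, compress, kernel, matrix_rank,
                       merge_split_fluxes, read_model, split_reversible)
from thermoefm.fixtures import FixtureSpec, brute_force_efms, gen_random_model
from thermoefm.model_io import ModelFormatError, ModelValidationError

MODEL_TSV = textwrap.dedent("""\
    reaction_id\tequation\tis_exchange
    EX_glc\tglc_e -> glc\t1
    EX_ac\tac_e <=> ac\t1
    GLY\tglc -> 2 ac\t0
    SEC\tac ->\t1
    """)

DEGENERATE_SBML = textwrap.dedent("""\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
     <model id="degenerate">
      <listOfCompartments><compartment id="external"/></listOfCompartments>
      <listOfSpecies>
       <species id="A_ext" compartment="external" boundaryCondition="true"/>
      </listOfSpecies>
      <listOfReactions>
       <reaction id="EX_A" reversible="false">
        <listOfReactants><speciesReference species="A_ext"/></listOfReactants>
       </reaction>
      </listOfReactions>
     </model>
    </sbml>
    """)


class TestReadModel:
    def test_table_dialect(self, tmp_path):
        p = tmp_path / "model.tsv"
        p.write_text(MODEL_TSV)
        m = read_model(p)
        assert m.metabolite_ids == ["glc", "ac"]
        assert m.reaction_ids == ["EX_glc", "EX_ac", "GLY", "SEC"]
        assert m.reversible == [False, True, False, False]
        assert m.exchange == [True, True, False, True]
        # glc_e / ac_e appear only in exchange reactions -> external
        assert m.ext_stoich[0] == {"glc_e": Fraction(-1)}
        assert m.column(2) == [Fraction(-1), Fraction(2)]

    def test_chain_table(self, tmp_path):
        p = tmp_path / "chain.tsv"
        p.write_text("reaction_id\tequation\tis_exchange\n"
                     "R1\t-> A\t1\nR2\tA -> B\t0\nR3\tB ->\t1\n")
        m = read_model(p)
        assert (m.n_metabolites, m.n_reactions) == (2, 3)
        assert not any(m.reversible)

    def test_degenerate_sbml_no_internal_species(self, tmp_path):
        p = tmp_path / "deg.xml"
        p.write_text(DEGENERATE_SBML)
        m = read_model(p)
        assert m.n_metabolites == 0
        assert m.n_reactions == 1
        assert m.exchange == [True]

    def test_sbml_core_model_dimensions(self):
        p = os.path.join(os.path.dirname(cobra.__file__), "data", "textbook.xml.gz")
        m = read_model(p)
        assert (m.n_metabolites, m.n_reactions) == (72, 95)
        assert matrix_rank(m) == 67
        split, smap = split_reversible(m)
        assert split.n_reactions == 95 + sum(m.reversible)

    def test_duplicate_reaction_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("reaction_id\tequation\tis_exchange\n"
                     "R1\t-> A\t1\nR1\tA ->\t1\n")
        with pytest.raises(ModelValidationError, match="R1"):
            read_model(p)

    def test_parse_error_names_offender(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("reaction_id\tequation\tis_exchange\nR1\tA = B\t0\n")
        with pytest.raises(ModelFormatError, match="arrow"):
            read_model(p)


class TestSplitReversible:
    def test_no_reversible_identity(self, chain):
        split, smap = split_reversible(chain)
        assert split.reaction_ids == chain.reaction_ids
        assert split.S == chain.S
        assert smap.pairs == {}

    def test_backward_column_is_negation(self, rev_pair):
        split, smap = split_reversible(rev_pair)
        assert smap.pairs == {"R_ab": ("R_ab", "R_ab_rev")}
        f = split.reaction_index("R_ab")
        b = split.reaction_index("R_ab_rev")
        assert split.column(b) == [-v for v in split.column(f)]
        assert not any(split.reversible)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_round_trip(self, seed):
        """Merging split fluxes reproduces the original signed fluxes."""
        model = gen_random_model(FixtureSpec(m=4, r=8, n_reversible=2, seed=seed))
        split, smap = split_reversible(model)
        flux = {rid: Fraction(0) for rid in split.reaction_ids}
        for rid, (f, b) in smap.pairs.items():
            flux[f] = Fraction(3)
            flux[b] = Fraction(5)
        merged = merge_split_fluxes(flux, smap)
        for rid in smap.pairs:
            assert merged[rid] == Fraction(-2)
        assert set(merged) == set(model.reaction_ids)


class TestConditionModel:
    def test_full_medium_unchanged(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(MODEL_TSV)
        m = read_model(p)
        cond = build_condition_model(m, {"glc_e", "ac_e"})
        assert cond.reaction_ids == m.reaction_ids
        assert cond.reversible == m.reversible

    def test_absent_nutrient_uptake_removed_secretion_kept(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(MODEL_TSV)
        m = read_model(p)
        cond = build_condition_model(m, {"glc_e"})
        # reversible acetate exchange loses its uptake direction only
        j = cond.reaction_index("EX_ac")
        assert not cond.reversible[j]
        assert cond.S[cond.metabolite_ids.index("ac")][j] == Fraction(-1)

    def test_empty_medium_starves_the_network(self, tmp_path):
        from thermoefm import tefma_enumerate
        p = tmp_path / "m.tsv"
        p.write_text("reaction_id\tequation\tis_exchange\n"
                     "UP\tglc_e -> A\t1\nCONV\tA -> B\t0\nSEC\tB ->\t1\n")
        m = read_model(p)
        cond = build_condition_model(m, set())
        res = tefma_enumerate(cond, None)
        assert res.efms == []

    def test_unknown_nutrient_lists_valid_ids(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(MODEL_TSV)
        m = read_model(p)
        with pytest.raises(ValueError, match="ac_e"):
            build_condition_model(m, {"banana"})


class TestCompression:
    def test_chain_collapses_to_one_reaction(self, chain3):
        comp = compress(chain3)
        assert comp.model.n_reactions == 1
        (cid,) = comp.model.reaction_ids
        flux = comp.decompress_flux({cid: Fraction(1)})
        vals = set(flux.values())
        assert set(flux) == set(chain3.reaction_ids)
        assert len(vals) == 1  # 1:1:1 flux ratio

    def test_dead_end_reaction_removed_as_blocked(self, tmp_path):
        from thermoefm import read_model
        p = tmp_path / "m.tsv"
        p.write_text("reaction_id\tequation\tis_exchange\n"
                     "UP\t-> A\t1\nSEC\tA ->\t1\nDEAD\tA -> C\t0\nC_USE\tC -> D\t0\n")
        m = read_model(p)
        comp = compress(m)
        removed = {rid for rid, reason in comp.removed_reactions if reason == "blocked"}
        assert {"DEAD", "C_USE"} <= removed

    @pytest.mark.parametrize("seed", range(8))
    def test_efm_set_survives_compression_round_trip(self, seed):
        """EFMs of the compressed model, decompressed, equal the originals."""
        from thermoefm import TefmaOptions, tefma_enumerate
        model = gen_random_model(FixtureSpec(m=4, r=9, density=0.5,
                                             n_reversible=2, seed=seed))
        with_c = tefma_enumerate(model, None, TefmaOptions(check_mode="off", compress=True))
        without = tefma_enumerate(model, None, TefmaOptions(check_mode="off", compress=False))
        assert with_c.support_sets() == without.support_sets()
        assert {e.flux for e in with_c.efms} == {e.flux for e in without.efms}


class TestKernel:
    def test_identity_block_leads(self, diamond):
        kb = kernel(diamond)
        assert kb.dim == 2
        for i in range(kb.dim):
            assert [kb.matrix[i][j] for j in range(kb.dim)] == \
                [Fraction(int(i == j)) for j in range(kb.dim)]

    @pytest.mark.parametrize("seed", range(10))
    def test_kernel_columns_annihilate_s_exactly(self, seed):
        model = gen_random_model(FixtureSpec(m=5, r=10, n_reversible=1, seed=seed))
        kb = kernel(model)
        assert kb.dim == model.n_reactions - matrix_rank(model)
        for j in range(kb.dim):
            for row in model.S:
                assert sum(row[kb.row_order[i]] * kb.matrix[i][j]
                           for i in range(kb.n_rows)) == 0

    def test_chain_kernel_is_uniform(self, chain3):
        kb = kernel(chain3)
        assert kb.dim == 1
        col = [kb.matrix[i][0] for i in range(kb.n_rows)]
        assert len(set(col)) == 1
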