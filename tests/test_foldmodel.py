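"""Constrained folding, structure formats, energies, and bootstrap support."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tstructseq import foldmodel
from tstructseq.engines import (
    BuiltinEngine,
    EngineCapabilityError,
    ViennaEngine,
    _forbidden_by_constraints,
    exhaustive_mfe,
)
from tstructseq.params import STACK, hairpin_energy
from tstructseq.structures import (
    FoldConstraintSet,
    SecondaryStructure,
    StructureError,
)

from test_reactivity import _profile_for_primer


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestMakeConstraints:
    def test_threshold_boundary(self):
        prof = _profile_for_primer(10, "P", {5: 0.009, 6: 0.0079})
        cset = foldmodel.make_constraints(prof)
        assert set(cset.positions) == {5}

    def test_all_below_threshold_empty(self):
        prof = _profile_for_primer(10, "P", {5: 0.001})
        assert len(foldmodel.make_constraints(prof)) == 0

    def test_na_positions_never_constrained(self):
        prof = _profile_for_primer(10, "P", {5: 0.02})
        prof.p_dms[7] = 0.5  # value present but coverage flag unset
        cset = foldmodel.make_constraints(prof)
        assert 7 not in cset

    def test_region_reindexing(self):
        prof = _profile_for_primer(100, "P", {45: 0.02, 60: 0.02, 90: 0.02})
        cset = foldmodel.make_constraints(prof, region=(41, 80))
        assert set(cset.positions) == {5, 20}


class TestMfeFold:
    def test_perfect_stem_loop(self, builtin_engine):
        st_ = foldmodel.mfe_fold("GGGGAAAACCCC", None, builtin_engine)
        assert st_.pairs == ((1, 12), (2, 11), (3, 10), (4, 9))

    def test_modified_base_excluded_from_helix_interior(self, builtin_engine):
        cset = FoldConstraintSet([2])
        st_ = foldmodel.mfe_fold("GGGGAAAACCCC", cset, builtin_engine)
        pair_set = st_.pair_set
        if (2, 11) in pair_set:
            # allowed only as a helix-terminal pair
            assert not ((1, 12) in pair_set and (3, 10) in pair_set)
        unconstrained = foldmodel.mfe_fold("GGGGAAAACCCC", None, builtin_engine)
        assert st_.energy >= unconstrained.energy

    def test_unpairable_sequence_empty_structure(self, builtin_engine):
        st_ = foldmodel.mfe_fold("AAAA", None, builtin_engine)
        assert st_.pairs == () and st_.energy == 0.0

    def test_constraint_out_of_bounds_error(self, builtin_engine):
        with pytest.raises(StructureError, match="out of bounds"):
            foldmodel.mfe_fold("GGGGAAAACCCC", FoldConstraintSet([99]), builtin_engine)

    def test_constraint_monotonicity_on_random_sequences(self, builtin_engine, rng):
        for _ in range(15):
            seq = random_seq(rng, int(rng.integers(12, 30)))
            free = foldmodel.mfe_fold(seq, None, builtin_engine).energy
            k = int(rng.integers(1, 4))
            cset = FoldConstraintSet(
                rng.choice(np.arange(1, len(seq) + 1), size=k, replace=False))
            constrained = foldmodel.mfe_fold(seq, cset, builtin_engine)
            assert constrained.energy >= free - 1e-9
            assert not _forbidden_by_constraints(seq, constrained.pair_set,
                                                 frozenset(cset.positions))


class TestEnergyOf:
    def test_empty_structure_zero(self, builtin_engine):
        st_ = SecondaryStructure(name="", length=8, pairs=())
        assert foldmodel.energy_of("ACGUACGU", st_, builtin_engine) == 0.0

    def test_roundtrip_matches_reported_mfe(self, builtin_engine, rng):
        for _ in range(10):
            seq = random_seq(rng, 25)
            st_ = builtin_engine.mfe_fold(seq)
            assert foldmodel.energy_of(seq, st_, builtin_engine) == pytest.approx(
                st_.energy, abs=0.01)

    def test_toy_hairpin_equals_hand_summed_terms(self, builtin_engine):
        # GGGGAAAACCCC: three GC-on-GC stacks + size-4 hairpin loop
        st_ = SecondaryStructure(name="", length=12,
                                 pairs=((1, 12), (2, 11), (3, 10), (4, 9)))
        expected = (3 * STACK[("GC", "GC")] + hairpin_energy(4)) / 100.0
        assert foldmodel.energy_of("GGGGAAAACCCC", st_, builtin_engine) == pytest.approx(expected)

    def test_noncomplementary_pair_error_lists_offenders(self, builtin_engine):
        st_ = SecondaryStructure(name="", length=12, pairs=((1, 12), (2, 8)))
        with pytest.raises(StructureError, match=r"\(2, 8\)"):
            foldmodel.energy_of("GAGGAAAACCUC", st_, builtin_engine)

    def test_vienna_roundtrip(self):
        eng = ViennaEngine()
        st_ = eng.mfe_fold("GGGGAAAACCCC")
        assert eng.energy_of("GGGGAAAACCCC", st_) == pytest.approx(st_.energy, abs=0.01)


class TestStructureFormats:
    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_dotbracket_roundtrip_lossless(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 40)
        st_ = BuiltinEngine().mfe_fold(seq)
        back = SecondaryStructure.from_dotbracket(st_.dotbracket)
        assert back.pairs == st_.pairs

    def test_ct_roundtrip_preserves_sequence_and_pairs(self, builtin_engine, rng):
        seq = random_seq(rng, 50)
        st_ = builtin_engine.mfe_fold(seq)
        st_named = SecondaryStructure(name="frag", length=st_.length,
                                      pairs=st_.pairs, energy=st_.energy)
        back, seq_back = SecondaryStructure.from_ct(st_named.to_ct(seq))
        assert seq_back == seq
        assert back.pairs == st_.pairs
        assert back.energy == pytest.approx(st_.energy)

    def test_pseudoknot_rejected(self):
        with pytest.raises(StructureError, match="pseudoknot"):
            SecondaryStructure(name="", length=20, pairs=((1, 10), (5, 15)))

    def test_min_hairpin_enforced(self):
        with pytest.raises(StructureError, match="hairpin"):
            SecondaryStructure(name="", length=10, pairs=((3, 6),))

    def test_constraint_file_roundtrip(self):
        cset = FoldConstraintSet([3, 7, 11])
        assert FoldConstraintSet.from_text(cset.to_text()).positions == cset.positions

    def test_rnastructure_dialect_lists_modified_positions(self):
        text = FoldConstraintSet([4, 9]).to_rnastructure_con()
        block = text.split("Mod:")[1].split("Pairs:")[0]
        assert [t for t in block.split() if t not in ("-1",)] == ["4", "9"]


class TestBootstrap:
    SEQ = "GGGGGAAAACCCCC"  # 5-pair stem with an A/C-rich tetraloop

    def test_empty_constraints_full_support(self, builtin_engine):
        support = foldmodel.bootstrap_support(self.SEQ, FoldConstraintSet(),
                                              builtin_engine, n=50, seed=1)
        full = builtin_engine.mfe_fold(self.SEQ).pair_set
        assert set(support.support) == set(full)
        assert all(v == 1.0 for v in support.support.values())

    def test_seeded_determinism(self, builtin_engine):
        cset = FoldConstraintSet([3, 7])
        a = foldmodel.bootstrap_support(self.SEQ, cset, builtin_engine, n=200, seed=7)
        b = foldmodel.bootstrap_support(self.SEQ, cset, builtin_engine, n=200, seed=7)
        assert a.support == b.support

    def test_full_fraction_gives_unit_support_for_model_pairs(self, builtin_engine):
        cset = FoldConstraintSet([3, 7])
        support = foldmodel.bootstrap_support(self.SEQ, cset, builtin_engine,
                                              n=20, fraction=1.0, seed=3)
        for pair in support.full_structure.pairs:
            assert support.support[pair] == 1.0

    def test_planted_constraint_sensitive_pair(self, builtin_engine):
        """Pair (1,14) is forbidden whenever the helix-interior constraint (3)
        is drawn, and kept when the loop constraint (7) is drawn; with
        fraction 0.5 of two constraints its support is Binomial(n, 1/2)/n."""
        cset = FoldConstraintSet([3, 7])
        n = 1000
        support = foldmodel.bootstrap_support(self.SEQ, cset, builtin_engine,
                                              n=n, fraction=0.5, seed=5)
        p = support.support.get((1, 14), 0.0)
        # 5 sigma binomial tolerance at n = 1000
        assert abs(p - 0.5) < 5 * np.sqrt(0.25 / n)

    def test_consensus_rule(self, builtin_engine):
        cset = FoldConstraintSet([3, 7])
        support = foldmodel.bootstrap_support(self.SEQ, cset, builtin_engine,
                                              n=200, fraction=0.5, seed=5)
        for pair in support.consensus:
            assert support.support[pair] > 0.5
        # frequencies are multiples of 1/n
        for v in support.support.values():
            assert (v * 200) == pytest.approx(round(v * 200))

    def test_zero_replicates_error(self, builtin_engine):
        with pytest.raises(ValueError):
            foldmodel.bootstrap_support(self.SEQ, FoldConstraintSet(), builtin_engine, n=0)


class TestViennaAdapter:
    def test_refuses_modification_constraints(self):
        eng = ViennaEngine()
        with pytest.raises(EngineCapabilityError, match="builtin"):
            eng.mfe_fold("GGGGAAAACCCC", FoldConstraintSet([2]))

    def test_unconstrained_fold_is_valid_structure(self):
        eng = ViennaEngine()
        st_ = eng.mfe_fold("GGGGAAAACCCC")
        assert st_.pairs and st_.energy < 0
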