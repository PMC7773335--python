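import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repseq_subsets.features import (
    FEATURE_NAMES,
    PROPERTY_FEATURES,
    PropertyTable,
    clonotype_property,
    cdr3_length,
    feature_vector,
    junction_insertions,
    middle_region,
    repertoire_property_average,
)
from repseq_subsets.io import Repertoire

from conftest import make_clonotype, make_repertoire

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_text = st.text(alphabet=AA, min_size=1, max_size=25)


class TestMiddleRegion:
    def test_odd_length(self):
        assert middle_region("CASSLGQAYEQYF") == "LGQAY"

    def test_shorter_than_k(self):
        assert middle_region("CASF") == "CASF"

    def test_even_length_left_biased(self):
        assert middle_region("CASSLGQAYEQF") == "SLGQA"

    def test_bad_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            middle_region("CA*SF")

    @given(aa_text)
    def test_length_and_containment(self, s):
        m = middle_region(s)
        assert len(m) == min(5, len(s))
        assert m in s


class TestClonotypeProperty:
    def test_homopolymer_is_scale_value(self, prop_table):
        for scale in ("kf4", "strength", "volume"):
            assert clonotype_property("AAAAAAA", scale, prop_table) == \
                pytest.approx(prop_table.value(scale, "A"))

    def test_toy_scale_mean(self):
        table = PropertyTable({"toy": {
            **{a: 0.0 for a in AA}, "L": 1, "G": 2, "Q": 3, "A": 4, "Y": 5}})
        assert clonotype_property("LGQAY", "toy", table) == pytest.approx(3.0)

    def test_depends_only_on_middle(self, prop_table):
        base = clonotype_property("CASSLGQAYEQYF", "strength", prop_table)
        mutated = clonotype_property("WWWWLGQAYRRRR", "strength", prop_table)
        assert base == pytest.approx(mutated)

    def test_unknown_scale_lists_available(self, prop_table):
        with pytest.raises(KeyError, match="kf1"):
            clonotype_property("CASSF", "bogus", prop_table)


class TestRepertoireAverage:
    def test_weighted_linear_combination(self):
        table = PropertyTable({"toy": {**{a: 0.0 for a in AA}, "W": -1.0, "M": 1.0}})
        rep = make_repertoire([3, 1])
        rep.clonotypes[0].cdr3aa = "WWWWW"
        rep.clonotypes[1].cdr3aa = "MMMMM"
        assert repertoire_property_average(rep, "toy", table, weighted=True) == \
            pytest.approx(-0.5)
        assert repertoire_property_average(rep, "toy", table, weighted=False) == \
            pytest.approx(0.0)

    def test_single_clonotype_both_modes(self, prop_table):
        rep = make_repertoire([4])
        rep.clonotypes[0].cdr3aa = "CASSLGQAYEQYF"
        v = clonotype_property("CASSLGQAYEQYF", "kf4", prop_table)
        for weighted in (True, False):
            assert repertoire_property_average(rep, "kf4", prop_table, weighted) == \
                pytest.approx(v)

    def test_weighted_equals_per_molecule_expansion(self, prop_table):
        """Oracle: expand each clonotype `count` times and take a flat mean."""
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 30, size=200)
        rep = make_repertoire(list(counts))
        for c in rep.clonotypes:
            c.cdr3aa = "".join(rng.choice(list(AA), rng.integers(8, 16)))
        expanded = [
            clonotype_property(c.cdr3aa, "strength", prop_table)
            for c in rep.clonotypes for _ in range(c.count)
        ]
        oracle = sum(expanded) / len(expanded)
        assert repertoire_property_average(rep, "strength", prop_table) == \
            pytest.approx(oracle, rel=1e-10)

    def test_convexity_and_permutation_invariance(self, prop_table):
        rng = np.random.default_rng(6)
        rep = make_repertoire(list(rng.integers(1, 9, size=40)))
        for c in rep.clonotypes:
            c.cdr3aa = "".join(rng.choice(list(AA), 10))
        vals = [clonotype_property(c.cdr3aa, "kf1", prop_table) for c in rep]
        avg = repertoire_property_average(rep, "kf1", prop_table)
        assert min(vals) - 1e-12 <= avg <= max(vals) + 1e-12
        perm = Repertoire("D", "S", "TRB",
                          [rep.clonotypes[i] for i in rng.permutation(len(rep))])
        assert repertoire_property_average(perm, "kf1", prop_table) == \
            pytest.approx(avg, rel=1e-12)

    def test_empty_errors(self, prop_table):
        with pytest.raises(ValueError):
            repertoire_property_average(Repertoire("D", "S", "TRB", []),
                                        "kf1", prop_table)


class TestJunctionInsertions:
    def test_with_d_segment(self):
        c = make_clonotype(cdr3nt="A" * 30, v_end=10, d_start=13, d_end=20, j_start=23)
        assert junction_insertions(c) == (12, 4, 2, 2)

    def test_abutting_no_d(self):
        c = make_clonotype(cdr3nt="A" * 15, v_end=10, d_start=-1, d_end=-1, j_start=11)
        assert junction_insertions(c) == (0, 0, None, None)

    def test_overlap_clamped(self):
        c = make_clonotype(cdr3nt="A" * 30, v_end=10, d_start=9, d_end=20, j_start=23)
        ndn, n_ins, vdins, djins = junction_insertions(c)
        assert vdins == 0
        assert n_ins == vdins + djins

    def test_undefined_markers(self):
        c = make_clonotype(v_end=-1, j_start=-1)
        assert junction_insertions(c) == (None, None, None, None)

    def test_marker_out_of_range_errors(self):
        c = make_clonotype(cdr3nt="AAA", v_end=1, d_start=2, d_end=2, j_start=99)
        with pytest.raises(ValueError, match="beyond"):
            junction_insertions(c)

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(1, 12))
    @settings(max_examples=60)
    def test_bounded_by_ndn(self, vdins, djins, d_len):
        v_end = 3
        d_start = v_end + 1 + vdins
        d_end = d_start + d_len - 1
        j_start = d_end + 1 + djins
        c = make_clonotype(cdr3nt="A" * (j_start + 3), v_end=v_end,
                           d_start=d_start, d_end=d_end, j_start=j_start)
        ndn, n_ins, vd, dj = junction_insertions(c)
        assert n_ins <= ndn
        assert (vd, dj) == (vdins, djins)


class TestCdr3Length:
    def test_units(self):
        c = make_clonotype(cdr3nt="TGTGCCAGCAGCTTC", cdr3aa="CASSF")
        assert cdr3_length(c, "aa") == 5
        assert cdr3_length(c, "nt") == 15
        assert cdr3_length(c, "nt") == 3 * cdr3_length(c, "aa")

    def test_bad_unit(self):
        with pytest.raises(ValueError):
            cdr3_length(make_clonotype(), "codons")


class TestFeatureVector:
    def test_has_28_named_entries(self, prop_table, toy_repertoire):
        fv = feature_vector(toy_repertoire, prop_table)
        assert list(fv) == FEATURE_NAMES
        assert len(fv) == 28
        assert len(PROPERTY_FEATURES) == 23

    def test_single_clonotype_equals_raw(self, prop_table):
        rep = make_repertoire([7])
        c = rep.clonotypes[0]
        fv = feature_vector(rep, prop_table)
        assert fv["kf4"] == pytest.approx(clonotype_property(c.cdr3aa, "kf4", prop_table))
        assert fv["cdr3_length"] == len(c.cdr3nt)
        ndn, n_ins, vd, dj = junction_insertions(c)
        assert fv["ndn_length"] == ndn
        assert fv["n_insertions"] == n_ins

    def test_count_rescaling_invariance(self, prop_table):
        rep = make_repertoire([6, 3, 1])
        doubled = make_repertoire([12, 6, 2])
        for a, b in zip(rep, doubled):
            b.cdr3aa = a.cdr3aa
        fa = feature_vector(rep, prop_table)
        fb = feature_vector(doubled, prop_table)
        for k in FEATURE_NAMES:
            if not (math.isnan(fa[k]) and math.isnan(fb[k])):
                assert fa[k] == pytest.approx(fb[k], rel=1e-12)

    def test_all_finite_on_marked_repertoire(self, prop_table, toy_repertoire):
        fv = feature_vector(toy_repertoire, prop_table)
        assert all(math.isfinite(v) for v in fv.values())


def test_property_table_complete(prop_table):
    for scale in prop_table.scales:
        for aa in AA:
            assert math.isfinite(prop_table.value(scale, aa))
    assert "provenance" in prop_table.provenance or prop_table.provenance


def test_kf4_is_inverted_hydrophobicity(prop_table):
    """kf4 high for charged/polar residues, low for hydrophobic ones."""
    assert prop_table.value("kf4", "R") > prop_table.value("kf4", "L")
    assert prop_table.value("kf4", "K") > prop_table.value("kf4", "F")


def test_volume_bulky_residues_top5(prop_table):
    vol = prop_table.scale("volume")
    top5 = sorted(vol, key=vol.get, reverse=True)[:5]
    assert set(top5) == set("WRKYF")
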