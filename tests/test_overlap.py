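import numpy as np
import pytest

from repseq_subsets.io import Repertoire
from repseq_subsets.normalization import recompute_frequencies
from repseq_subsets.overlap import (
    build_sharing_network,
    overlap_d,
    overlap_f2,
    overlap_result,
    shared_clonotypes,
)

from conftest import make_clonotype


def rep_from_spec(spec, donor="D1", subset="S", chain="TRB"):
    """spec: list of (v, cdr3nt, count)."""
    clonotypes = [make_clonotype(count=n, cdr3nt=nt, v=v, v_end=1, d_start=2,
                                 d_end=3, j_start=5) for v, nt, n in spec]
    return recompute_frequencies(Repertoire(donor, subset, chain, clonotypes))


def brute_force_shared(a, b):
    """O(n*m) nested-loop oracle."""
    out = []
    for ca in a.clonotypes:
        for cb in b.clonotypes:
            if ca.v_gene == cb.v_gene and ca.cdr3nt == cb.cdr3nt:
                out.append((ca.key, ca.freq, cb.freq))
    return out


class TestSharedClonotypes:
    def test_identical_repertoires(self):
        a = rep_from_spec([("V1", "TGTTGT", 2), ("V2", "TGTTGC", 1)])
        assert len(shared_clonotypes(a, a)) == 2

    def test_disjoint(self):
        a = rep_from_spec([("V1", "TGTTGT", 1)])
        b = rep_from_spec([("V1", "TGTTGC", 1)])
        assert shared_clonotypes(a, b) == []

    def test_same_nt_different_v_not_shared(self):
        a = rep_from_spec([("V1", "TGTTGT", 1)])
        b = rep_from_spec([("V2", "TGTTGT", 1)])
        assert shared_clonotypes(a, b) == []

    def test_chain_mismatch_errors(self):
        a = rep_from_spec([("V1", "TGTTGT", 1)], chain="TRB")
        b = rep_from_spec([("V1", "TGTTGT", 1)], chain="TRA")
        with pytest.raises(ValueError, match="chain"):
            shared_clonotypes(a, b)

    def test_hash_equals_brute_force(self):
        """Oracle equivalence on random <=100-clonotype repertoires."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            def random_rep():
                n = rng.integers(5, 100)
                spec = [(f"V{rng.integers(1, 6)}",
                         "TGT" + "".join(rng.choice(list("ACGT"), 6)),
                         int(rng.integers(1, 9))) for _ in range(n)]
                # dedupe keys
                seen, ded = set(), []
                for v, nt, c in spec:
                    if (v, nt) not in seen:
                        seen.add((v, nt))
                        ded.append((v, nt, c))
                return rep_from_spec(ded)
            a, b = random_rep(), random_rep()
            fast = sorted(shared_clonotypes(a, b))
            slow = sorted(brute_force_shared(a, b))
            assert fast == slow


class TestF2:
    def test_self_overlap_is_one(self):
        a = rep_from_spec([("V1", "TGTTGT", 5), ("V2", "TGTTGC", 3), ("V3", "TGTTGG", 2)])
        assert overlap_f2(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_zero(self):
        a = rep_from_spec([("V1", "TGTTGT", 1)])
        b = rep_from_spec([("V1", "TGTTGC", 1)])
        assert overlap_f2(a, b) == 0.0

    def test_half_shared(self):
        a = rep_from_spec([("V1", "AAA", 1), ("V1", "CCC", 1)])
        b = rep_from_spec([("V1", "AAA", 1), ("V1", "GGG", 1)])
        assert overlap_f2(a, b) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(8)
        a = rep_from_spec([(f"V{i%4}", "TGT" + "".join(rng.choice(list("ACGT"), 5)),
                            int(rng.integers(1, 20))) for i in range(50)])
        b = rep_from_spec([(f"V{i%4}", "TGT" + "".join(rng.choice(list("ACGT"), 5)),
                            int(rng.integers(1, 20))) for i in range(50)])
        f_ab, f_ba = overlap_f2(a, b), overlap_f2(b, a)
        assert f_ab == pytest.approx(f_ba, abs=1e-15)
        assert 0.0 <= f_ab <= 1.0

    def test_order_permutation_invariance(self):
        a = rep_from_spec([("V1", "AAA", 3), ("V1", "CCC", 2), ("V1", "GGG", 1)])
        b = rep_from_spec([("V1", "GGG", 1), ("V1", "CCC", 2), ("V1", "AAA", 3)])
        assert overlap_f2(a, b) == pytest.approx(overlap_f2(b, a), abs=1e-15)
        assert overlap_f2(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_mass_variant(self):
        a = rep_from_spec([("V1", "AAA", 1), ("V1", "CCC", 1)])
        b = rep_from_spec([("V1", "AAA", 1), ("V1", "GGG", 1)])
        assert overlap_f2(a, b, variant="mass") == pytest.approx(0.5)


class TestD:
    def test_self_overlap(self):
        a = rep_from_spec([("V1", "AAA", 1), ("V1", "CCC", 1), ("V1", "GGG", 1)])
        assert overlap_d(a, a) == pytest.approx(1 / 3)

    def test_disjoint(self):
        a = rep_from_spec([("V1", "AAA", 1)])
        b = rep_from_spec([("V1", "CCC", 1)])
        assert overlap_d(a, b) == 0.0

    def test_two_by_two_sharing_one(self):
        a = rep_from_spec([("V1", "AAA", 1), ("V1", "CCC", 1)])
        b = rep_from_spec([("V1", "AAA", 1), ("V1", "GGG", 1)])
        assert overlap_d(a, b) == pytest.approx(0.25)

    def test_empty_errors(self):
        a = rep_from_spec([("V1", "AAA", 1)])
        with pytest.raises(ValueError):
            overlap_d(a, Repertoire("D1", "S", "TRB", []))


class TestSharingNetwork:
    def two_subsets(self):
        a = rep_from_spec([("V1", "AAA", 2), ("V1", "CCC", 98)], subset="X")
        b = rep_from_spec([("V1", "AAA", 4), ("V1", "GGG", 96)], subset="Y")
        return [a, b]

    def test_single_shared_cloud_mean_freq(self):
        net = build_sharing_network(self.two_subsets(), top_n=2000)
        shared = net.nodes[net.nodes["shared"]]
        assert len(shared) == 2  # one instance per subset
        assert shared["cloud_freq"].unique() == pytest.approx([0.03])
        assert len(net.edges) == 1

    def test_no_sharing_edgeless(self):
        a = rep_from_spec([("V1", "AAA", 1)], subset="X")
        b = rep_from_spec([("V1", "CCC", 1)], subset="Y")
        net = build_sharing_network([a, b], top_n=2000)
        assert len(net.edges) == 0
        assert len(net.nodes) == 2

    def test_focal_filter(self):
        a = rep_from_spec([("V1", "AAA", 1), ("V1", "TTT", 1)], subset="X")
        b = rep_from_spec([("V1", "AAA", 1), ("V1", "GGG", 1)], subset="Y")
        c = rep_from_spec([("V1", "GGG", 1), ("V1", "CCC", 1)], subset="Z")
        net = build_sharing_network([a, b, c], top_n=2000, focal_subset="Z")
        shared = net.nodes[net.nodes["shared"]]
        # only the Y-Z cloud (GGG) plus Z's own unshared node
        assert set(shared["cdr3nt"]) == {"GGG"}
        unshared = net.nodes[~net.nodes["shared"]]
        assert set(unshared["subset"]) == {"Z"}

    def test_requires_two_repertoires(self):
        with pytest.raises(ValueError):
            build_sharing_network([self.two_subsets()[0]])

    def test_top_n_applied(self):
        a = rep_from_spec([("V1", f"AA{i}", 100 - i) for i in range(10)], subset="X")
        b = rep_from_spec([("V1", f"AA{i}", 100 - i) for i in range(10)], subset="Y")
        net = build_sharing_network([a, b], top_n=3)
        assert len(net.nodes) == 6


def test_overlap_result_symmetric_fields():
    a = rep_from_spec([("V1", "AAA", 1), ("V1", "CCC", 1)], subset="X")
    b = rep_from_spec([("V1", "AAA", 1), ("V1", "GGG", 1)], subset="Y")
    r1, r2 = overlap_result(a, b), overlap_result(b, a)
    assert r1.n_shared == r2.n_shared == 1
    assert r1.f2 == pytest.approx(r2.f2)
    assert r1.d == pytest.approx(r2.d)
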