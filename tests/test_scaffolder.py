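"""Overlap merging, IR detection, layouts, N-bridging."""

import numpy as np
import pytest

from plastokmer import (
    Assembly,
    ConnectivityMatrix,
    extract_layout,
    find_inverted_repeat,
    layout_outputs,
    overlap_merge,
    pseudo_circularize,
    rescaffold_with_matrix,
    revcomp,
)
from plastokmer.dna import random_seq
from plastokmer.scaffolder import NoInvertedRepeatError, _longest_overlap
from plastokmer.validate import rotations_equal


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestLongestOverlap:
    def test_exact_overlap(self, rng):
        a, b = random_seq(500, rng), random_seq(500, rng)
        assert _longest_overlap(a + b[:100], b, 50) == 100

    def test_no_overlap(self, rng):
        assert _longest_overlap(random_seq(300, rng), random_seq(300, rng), 50) == 0

    def test_mismatch_budget(self, rng):
        a, b = random_seq(500, rng), random_seq(500, rng)
        ov = list(b[:100])
        ov[60] = {"A": "C"}.get(ov[60], "A")  # one mismatch inside the overlap
        assert _longest_overlap(a + "".join(ov), b, 50, 0.0) == 0
        assert _longest_overlap(a + "".join(ov), b, 50, 0.05) == 100


class TestOverlapMerge:
    def test_two_scaffolds_with_end_overlap(self, rng):
        x = random_seq(1000, rng)
        a, b = x[:600], x[500:]  # 100 bp shared
        merged = overlap_merge(Assembly.from_sequences([a, b]), 50)
        assert merged.n_scaffolds == 1
        assert merged.total_length == len(a) + len(b) - 100
        s = merged.scaffolds[0].sequence
        assert s == x or s == revcomp(x)

    def test_self_overlap_circularizes(self, rng):
        core = random_seq(2000, rng)
        linear = core + core[:100]
        merged = overlap_merge(Assembly.from_sequences([linear]), 50)
        assert merged.circular
        assert merged.total_length == 2000
        assert rotations_equal(merged.scaffolds[0].sequence, core)

    def test_three_piece_tiling_closure(self, truth):
        """The circle cut into three fragments with 200 bp mutual overlaps
        (cuts inside the IR copies and the LSC) closes back into the truth
        circle up to rotation/strand."""
        c = truth.circle
        p1 = c[200:20400]                    # LSC + 200 bp into IR
        p2 = c[20200:29400]                  # IR suffix + SSC + 200 bp into IR'
        p3 = c[29200:] + c[:400]             # IR' suffix + LSC wrap
        merged = overlap_merge(Assembly.from_sequences([p1, p2, p3]), 50)
        assert merged.circular
        assert rotations_equal(merged.scaffolds[0].sequence, c)

    def test_ir_duplication_closes_collapsed_unitigs(self, truth, plastome_reads):
        """A canonical De Bruijn assembly collapses the two IR copies onto
        one contig; the merge duplicates it and closes the circle."""
        from plastokmer import debruijn_assemble, filter_size
        from plastokmer.validate import circular_identity, plastome_variants

        asm = filter_size(debruijn_assemble(plastome_reads, 31), 31)
        assert asm.n_scaffolds == 3  # LSC, IR, SSC unitigs
        merged = overlap_merge(asm, 30)
        assert merged.circular
        main, variants = plastome_variants(truth.lsc, truth.ir, truth.ssc)
        assert circular_identity(merged.scaffolds[0].sequence, main, variants) == 100.0

    def test_unmergeable_pass_through(self, rng):
        seqs = [random_seq(400, rng) for _ in range(3)]
        merged = overlap_merge(Assembly.from_sequences(seqs), 50)
        assert merged.n_scaffolds == 3
        assert sorted(s.sequence for s in merged.scaffolds) == sorted(seqs)

    def test_contained_scaffold_absorbed(self, rng):
        x = random_seq(1000, rng)
        merged = overlap_merge(Assembly.from_sequences([x, x[200:500]]), 50)
        assert merged.n_scaffolds == 1 and merged.scaffolds[0].sequence == x

    def test_output_is_concatenation_of_inputs(self, rng):
        """Merging never alters non-junction bases."""
        x = random_seq(900, rng)
        a, b, c = x[:400], x[320:650], x[580:]
        merged = overlap_merge(Assembly.from_sequences([a, b, c]), 50)
        assert merged.n_scaffolds == 1
        s = merged.scaffolds[0].sequence
        assert s == x or s == revcomp(x)

    def test_min_overlap_floor(self, rng):
        with pytest.raises(ValueError):
            overlap_merge(Assembly.from_sequences(["A" * 100]), 10)


class TestPseudoCircularize:
    def test_definition(self):
        asm = Assembly.from_sequences(["ACGTACGT"], circular=True)
        out = pseudo_circularize(asm, 3)
        assert out.scaffolds[0].sequence == "ACGTACGTACG"
        assert not out.circular

    def test_n_zero(self):
        asm = Assembly.from_sequences(["ACGTACGT"], circular=True)
        assert pseudo_circularize(asm, 0).scaffolds[0].sequence == "ACGTACGT"

    def test_n_too_large(self):
        asm = Assembly.from_sequences(["ACGT"], circular=True)
        with pytest.raises(ValueError):
            pseudo_circularize(asm, 5)

    def test_linear_input_rejected(self):
        with pytest.raises(ValueError):
            pseudo_circularize(Assembly.from_sequences(["ACGT"]), 2)


def brute_force_ir(circle, min_ir):
    """O(L^2)-ish oracle: longest disjoint revcomp interval pair on a circle."""
    L = len(circle)
    d = circle + circle
    best = 0
    for start in range(L):
        for length in range(min_ir, L // 2 + 1):
            if start + length > 2 * L:
                break
            sub = revcomp(d[start:start + length])
            p = d.find(sub)
            while p != -1:
                s1, s2 = sorted((start % L, p % L))
                if s1 + length <= s2 and s2 + length <= s1 + L:
                    best = max(best, length)
                    break
                p = d.find(sub, p + 1)
            else:
                break  # no match at this length -> none at longer lengths
    return best


class TestFindInvertedRepeat:
    def test_constructed_circle(self, rng):
        lsc, ir, ssc = random_seq(20000, rng), random_seq(5000, rng), random_seq(4000, rng)
        circle = lsc + ir + ssc + revcomp(ir)
        (i1, i2), lsc_iv, ssc_iv = find_inverted_repeat(circle, min_ir=1000)
        # maximal extension may add a base or two past the constructed
        # boundaries when flanking bases happen to complement
        slack = 3
        assert abs((i1[1] - i1[0]) - 5000) <= slack
        assert abs((i2[1] - i2[0]) - 5000) <= slack
        assert abs(i1[0] - 20000) <= slack and abs(i2[0] - 29000) <= slack
        assert abs((lsc_iv[1] - lsc_iv[0]) - 20000) <= slack
        assert abs((ssc_iv[1] - ssc_iv[0]) - 4000) <= slack

    def test_detection_invariant_under_rotation(self, rng):
        lsc, ir, ssc = random_seq(3000, rng), random_seq(800, rng), random_seq(500, rng)
        circle = lsc + ir + ssc + revcomp(ir)
        rot = circle[1200:] + circle[:1200]
        (i1, i2), _, _ = find_inverted_repeat(rot, min_ir=500)
        assert i1[1] - i1[0] == 800

    def test_no_ir_raises(self, rng):
        with pytest.raises(NoInvertedRepeatError):
            find_inverted_repeat(random_seq(10000, rng), min_ir=500)

    def test_agrees_with_bruteforce_on_small_circles(self, rng):
        lsc, ir, ssc = random_seq(1500, rng), random_seq(600, rng), random_seq(400, rng)
        circle = lsc + ir + ssc + revcomp(ir)
        (i1, _), _, _ = find_inverted_repeat(circle, min_ir=500)
        assert (i1[1] - i1[0]) == brute_force_ir(circle, 500) == 600


class TestLayouts:
    @pytest.fixture()
    def circle_asm(self, truth):
        return Assembly.from_sequences([truth.circle], circular=True)

    def test_three_linear(self, circle_asm, truth):
        recs = layout_outputs(circle_asm, "three_linear", min_ir=1000)
        lengths = {n.split(":")[0]: len(s) for n, s in recs}
        assert set(lengths) == {"LSC", "IR", "SSC"}
        for name, expect in (("LSC", 20000), ("IR", 5000), ("SSC", 4000)):
            assert abs(lengths[name] - expect) <= 3  # IR boundary slack

    def test_layout_reconstructs_circle(self, circle_asm, truth):
        lay = extract_layout(circle_asm, min_ir=1000)
        assert rotations_equal(lay.circular_sequence, truth.circle)

    def test_two_circular_differ_only_in_ssc(self, circle_asm):
        (n1, c1), (n2, c2) = layout_outputs(circle_asm, "two_circular", min_ir=1000)
        assert len(c1) == len(c2)
        assert c1 != c2
        lay = extract_layout(circle_asm, min_ir=1000)
        flipped = lay.lsc + lay.ir + revcomp(lay.ssc) + revcomp(lay.ir)
        assert {c1, c2} == {lay.circular_sequence, flipped}

    def test_one_circular_seeded_choice(self, circle_asm):
        a = layout_outputs(circle_asm, "one_circular", min_ir=1000, seed=5)
        b = layout_outputs(circle_asm, "one_circular", min_ir=1000, seed=5)
        assert a == b

    def test_without_ir_only_one_circular_allowed(self, rng):
        asm = Assembly.from_sequences([random_seq(10000, rng)], circular=True)
        with pytest.raises(NoInvertedRepeatError):
            layout_outputs(asm, "three_linear", min_ir=1000)
        recs = layout_outputs(asm, "one_circular", min_ir=1000)
        assert len(recs) == 1


class TestRescaffoldWithMatrix:
    def test_supported_join_bridges_with_n(self, rng):
        a, b = random_seq(500, rng), random_seq(500, rng)
        m = ConnectivityMatrix()
        m.add((0, "R"), (1, "L"), 10)
        out = rescaffold_with_matrix(Assembly.from_sequences([a, b]), m,
                                     min_support=3, gap_n=100)
        assert out.n_scaffolds == 1
        assert out.scaffolds[0].sequence == a + "N" * 100 + b

    def test_below_min_support_is_identity(self, rng):
        a, b = random_seq(500, rng), random_seq(500, rng)
        m = ConnectivityMatrix()
        m.add((0, "R"), (1, "L"), 2)
        out = rescaffold_with_matrix(Assembly.from_sequences([a, b]), m, 3, 100)
        assert out.n_scaffolds == 2

    def test_chain_plus_back_edge_closes_circle(self, rng):
        a, b, c = (random_seq(400, rng) for _ in range(3))
        m = ConnectivityMatrix()
        m.add((0, "R"), (1, "L"), 10)  # A -> B
        m.add((1, "R"), (2, "L"), 8)   # B -> C
        m.add((2, "R"), (0, "L"), 6)   # C -> back to A
        out = rescaffold_with_matrix(Assembly.from_sequences([a, b, c]), m, 3, 50)
        assert out.circular
        assert out.n_gaps == 3

    def test_orientation_flip_join(self, rng):
        a, b = random_seq(300, rng), random_seq(300, rng)
        m = ConnectivityMatrix()
        m.add((0, "R"), (1, "R"), 5)
        out = rescaffold_with_matrix(Assembly.from_sequences([a, b]), m, 3, 10)
        assert out.n_scaffolds == 1
        s = out.scaffolds[0].sequence
        assert s == a + "N" * 10 + revcomp(b) or s == b + "N" * 10 + revcomp(a)
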