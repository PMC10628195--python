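import numpy as np
import pytest

from heterotrace.core_io import HaplotypeSequence, InputError, revcomp
from heterotrace.duplicates import (
    annotate_palindromes,
    pair_duplicates,
    read_hits,
    scan_duplicates,
    write_hits,
)
from heterotrace.simulate import array_to_seq, mutate_array, seq_to_array


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return array_to_seq(rng.integers(0, 4, n).astype(np.uint8))


def dp_identity_oracle(a: str, b: str) -> float:
    """Percent identity of the best Smith-Waterman local alignment
    (independent dynamic-programming oracle via biopython)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    matches = 0
    length = 0
    for (sa, ea), (sb, _eb) in zip(*aln.aligned):
        for i in range(ea - sa):
            length += 1
            matches += a[sa + i] == b[sb + i]
    return 100.0 * matches / length if length else 0.0


QUERY = HaplotypeSequence("gene", random_seq(1_000, 100))


class TestScanDuplicates:
    def test_planted_exact_reverse_complement(self):
        seg = QUERY.seq[300:400]
        background = random_seq(10_000, 101)
        target_seq = background[:5_000] + revcomp(seg) + background[5_000:]
        hits = scan_duplicates(QUERY, HaplotypeSequence("t", target_seq))
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        assert h.identity == 100.0
        assert (h.start, h.end) == (5_000, 5_100)
        assert (h.query_start, h.query_end) == (300, 400)
        assert h.length == 100
        assert not h.intact

    def test_planted_forward_hit(self):
        seg = QUERY.seq[100:350]
        target_seq = random_seq(4_000, 102) + seg + random_seq(4_000, 103)
        (h,) = scan_duplicates(QUERY, HaplotypeSequence("t", target_seq))
        assert h.strand == "+"
        # local alignment may extend a few chance-matching bases past the
        # planted boundary
        assert abs(h.query_start - 100) <= 8 and abs(h.query_end - 350) <= 8
        assert abs(h.start - 4_000) <= 8 and abs(h.end - 4_250) <= 8
        assert len(h.sequence) == h.length
        assert seg[20:230] in h.sequence

    def test_intact_copy_labelled(self):
        target_seq = random_seq(2_000, 104) + QUERY.seq + random_seq(2_000, 105)
        (h,) = scan_duplicates(QUERY, HaplotypeSequence("t", target_seq))
        assert h.intact

    def test_empirical_null(self):
        """Random 10-kb targets: no >= 30 bp hit at >= 70% identity."""
        n_hits = 0
        for seed in range(100):
            target = HaplotypeSequence("t", random_seq(10_000, 200 + seed))
            n_hits += len(scan_duplicates(QUERY, target))
        assert n_hits == 0

    def test_divergent_hit_identity_vs_dp_oracle(self):
        """10% substitutions: hit recovered, identity within 3 points of the
        DP local-alignment oracle."""
        rng = np.random.default_rng(9)
        seg = QUERY.seq[200:500]
        diverged = array_to_seq(mutate_array(seq_to_array(seg), 0.10, rng))
        target_seq = random_seq(3_000, 106) + diverged + random_seq(3_000, 107)
        hits = scan_duplicates(QUERY, HaplotypeSequence("t", target_seq))
        assert hits
        h = max(hits, key=lambda x: x.length)
        oracle = dp_identity_oracle(QUERY.seq[h.query_start : h.query_end], diverged)
        assert h.identity == pytest.approx(oracle, abs=3.0)

    def test_all_hit_identities_match_dp_oracle(self):
        rng = np.random.default_rng(10)
        parts = [random_seq(1_000, 108)]
        for i, (a, b) in enumerate([(0, 150), (400, 600), (700, 1000)]):
            seg = QUERY.seq[a:b]
            seg = array_to_seq(mutate_array(seq_to_array(seg), 0.05, rng))
            parts += [seg, random_seq(800, 120 + i)]
        target = HaplotypeSequence("t", "".join(parts))
        hits = scan_duplicates(QUERY, target)
        assert len(hits) == 3
        for h in hits:
            oracle = dp_identity_oracle(
                QUERY.seq[h.query_start : h.query_end], h.sequence
            )
            assert h.identity == pytest.approx(oracle, abs=3.0)

    def test_reverse_complement_symmetry(self):
        """Reverse-complementing the target flips strands and mirrors
        intervals."""
        seg = QUERY.seq[250:450]
        target_seq = random_seq(2_000, 109) + seg + random_seq(1_500, 110)
        fwd = scan_duplicates(QUERY, HaplotypeSequence("t", target_seq))
        rev = scan_duplicates(QUERY, HaplotypeSequence("t", revcomp(target_seq)))
        assert len(fwd) == len(rev) == 1
        L = len(target_seq)
        assert rev[0].strand != fwd[0].strand
        assert (rev[0].start, rev[0].end) == (L - fwd[0].end, L - fwd[0].start)
        assert rev[0].identity == fwd[0].identity

    def test_query_shorter_than_word(self):
        with pytest.raises(InputError):
            scan_duplicates(HaplotypeSequence("q", "ACGTA"), QUERY, word=8)


class TestPalindromes:
    def test_inverted_pair_flagged(self):
        block = QUERY.seq + random_seq(50, 111) + revcomp(QUERY.seq)
        target = HaplotypeSequence(
            "t", random_seq(1_000, 112) + block + random_seq(1_000, 113)
        )
        hits = annotate_palindromes(scan_duplicates(QUERY, target))
        intact = [h for h in hits if h.intact]
        assert len(intact) == 2
        assert all(h.palindrome for h in intact)

    def test_distant_copies_not_flagged(self):
        target = HaplotypeSequence(
            "t",
            random_seq(500, 114) + QUERY.seq + random_seq(8_000, 115)
            + revcomp(QUERY.seq) + random_seq(500, 116),
        )
        hits = annotate_palindromes(
            scan_duplicates(QUERY, target), max_spacing=5_000
        )
        assert not any(h.palindrome for h in hits)


class TestPairDuplicates:
    def _planted_pairs(self, n=5, seed=20):
        """Y carries n partials; Z inherits them with slight divergence."""
        rng = np.random.default_rng(seed)
        y_parts, z_parts = [random_seq(500, seed + 1)], [random_seq(700, seed + 2)]
        for i in range(n):
            a = 50 + i * 180
            seg = QUERY.seq[a : a + 150]
            y_parts += [seg, random_seq(400, seed + 10 + i)]
            div = array_to_seq(mutate_array(seq_to_array(seg), 0.03, rng))
            z_parts += [div, random_seq(350, seed + 30 + i)]
        y = HaplotypeSequence("Y", "".join(y_parts))
        z = HaplotypeSequence("Z", "".join(z_parts))
        return scan_duplicates(QUERY, y), scan_duplicates(QUERY, z)

    def test_five_shared_duplicates_paired_in_order(self):
        hits_y, hits_z = self._planted_pairs()
        assert len(hits_y) == len(hits_z) == 5
        pairing = pair_duplicates(hits_y, hits_z)
        assert pairing.n_pairs == 5
        assert pairing.order_preserved
        assert all(i >= 70 for i in pairing.identities)

    def test_empty_pairing(self):
        hits_y, _ = self._planted_pairs()
        pairing = pair_duplicates(hits_y, [])
        assert pairing.n_pairs == 0
        assert not pairing.order_preserved

    def test_reversed_list_clears_order_flag(self):
        hits_y, hits_z = self._planted_pairs()
        # mirror Z's coordinates: same hits, reversed physical order
        L = max(h.end for h in hits_z) + 500
        for h in hits_z:
            h.start, h.end = L - h.end, L - h.start
        pairing = pair_duplicates(hits_y, hits_z)
        assert pairing.n_pairs == 5
        assert not pairing.order_preserved

    def test_each_hit_used_once(self):
        hits_y, hits_z = self._planted_pairs()
        pairing = pair_duplicates(hits_y, hits_z + hits_z[:1])
        used_b = [id(b) for _, b in pairing.pairs]
        assert len(used_b) == len(set(used_b))

    def test_same_length_flag_semantics(self):
        from heterotrace.duplicates import DuplicateHit

        seg = QUERY.seq[100:250]
        a = DuplicateHit("A", 10, 160, "+", 100, 250, 100.0, seg)
        b_same = DuplicateHit("B", 500, 650, "+", 100, 250, 100.0, seg)
        b_longer = DuplicateHit("B", 500, 655, "+", 100, 255, 100.0,
                                QUERY.seq[100:255])
        assert pair_duplicates([a], [b_same]).same_length == [True]
        assert pair_duplicates([a], [b_longer]).same_length == [False]


class TestHitsIo:
    def test_round_trip(self, tmp_path):
        seg = QUERY.seq[300:400]
        target_seq = random_seq(2_000, 117) + revcomp(seg) + random_seq(500, 118)
        hits = scan_duplicates(QUERY, HaplotypeSequence("t", target_seq))
        p = tmp_path / "hits.tsv"
        write_hits(hits, p)
        assert read_hits(p) == hits


class TestSimulatedDuplicates(object):
    def test_simulation_truth_recovered(self, sim_wy):
        hits_y = scan_duplicates(sim_wy.query_gene, sim_wy.reference)
        truth = sim_wy.truth.duplicates
        assert len(hits_y) == len(truth)
        for h, t in zip(sorted(hits_y, key=lambda x: x.start), truth):
            assert abs(h.start - t.start) <= 8 and abs(h.end - t.end) <= 8
            assert h.strand == t.strand

    def test_z_inherits_and_pairs(self, sim_wy):
        z = HaplotypeSequence("Z", sim_wy.truth.sequences["Z"])
        hits_y = scan_duplicates(sim_wy.query_gene, sim_wy.reference)
        hits_z = scan_duplicates(sim_wy.query_gene, z)
        pairing = pair_duplicates(hits_y, hits_z)
        assert pairing.n_pairs == len(sim_wy.truth.duplicates)
        assert pairing.order_preserved

    def test_w_lost_partials_kept_intact_palindromes(self, sim_wy):
        w = HaplotypeSequence("W", sim_wy.truth.sequences["W"])
        hits_w = annotate_palindromes(scan_duplicates(sim_wy.query_gene, w))
        assert all(h.intact for h in hits_w)
        assert len(hits_w) == 4  # two inverted-pair blocks
        assert all(h.palindrome for h in hits_w)
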