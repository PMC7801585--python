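"""Six-frame translation, local alignment (with exhaustive oracle),
genome scanning, locus merging, the iterative search loop and the motif
filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomlgt._codon import translate
from venomlgt.formats_io import SequenceRecord
from venomlgt.homology_search import (
    SearchParams,
    build_motif,
    filter_by_motif,
    iterative_search,
    local_align,
    merge_hits,
    scan_genome,
    six_frame_translate,
)
from venomlgt.synthetic_data import random_nt, simulate_cds, _revcomp

from Bio.Align import substitution_matrices

B62 = substitution_matrices.load("BLOSUM62")


class TestSixFrame:
    def test_forward_frame_zero(self):
        tracks = six_frame_translate("ATGAAA")
        fwd0 = next(t for t in tracks if t.strand == "+" and t.frame == 0)
        assert fwd0.peptide == "MK"

    def test_reverse_frames_translate_reverse_complement(self):
        seq = "ATGAAACCCGGG"
        tracks = six_frame_translate(seq)
        rev0 = next(t for t in tracks if t.strand == "-" and t.frame == 0)
        assert rev0.peptide == translate(_revcomp(seq))

    def test_coordinate_round_trip(self):
        rng = np.random.default_rng(0)
        seq = random_nt(60, 0.4, rng)
        for track in six_frame_translate(seq):
            for i in range(len(track.peptide)):
                s, e = track.to_genomic(i, i + 1)
                assert e - s == 3
                codon = seq[s:e]
                if track.strand == "-":
                    codon = _revcomp(codon)
                assert translate(codon) == track.peptide[i]

    def test_stops_emitted_as_asterisk(self):
        tracks = six_frame_translate("ATGTAAAAA")
        fwd0 = next(t for t in tracks if t.strand == "+" and t.frame == 0)
        assert fwd0.peptide == "M*K"


def oracle_local_align(q, t, gap_open=11.0, gap_extend=1.0):
    """Exhaustive enumerator of local alignments for tiny sequences.

    Alignments start and end with an aligned pair; gap runs of length k
    cost gap_open + k*gap_extend. Adjacent insert/delete runs are skipped
    (replacing them with an aligned pair never lowers the score, so the
    maximum is unaffected).
    """
    best = 0.0

    def extend(i, j, score):
        nonlocal best
        # current column (i, j) is aligned
        s = score + B62[q[i], t[j]]
        best = max(best, s)
        # continue with another aligned pair
        if i + 1 < len(q) and j + 1 < len(t):
            extend(i + 1, j + 1, s)
        # gap in target (consume query), must resume with aligned pair
        for a in range(1, len(q) - i - 1):
            if i + a + 1 < len(q) and j + 1 < len(t):
                extend(i + a + 1, j + 1, s - gap_open - a * gap_extend)
        # gap in query (consume target)
        for b in range(1, len(t) - j - 1):
            if i + 1 < len(q) and j + b + 1 < len(t):
                extend(i + 1, j + b + 1, s - gap_open - b * gap_extend)

    for i0 in range(len(q)):
        for j0 in range(len(t)):
            extend(i0, j0, 0.0)
    return best


AA = "ARNDCQEGHILKMFPSTWYV"


class TestLocalAlign:
    def test_exact_triplet_score(self):
        aln = local_align("MKT", "MKT")
        assert aln.score == 15.0  # M=5, K=5, T=5 on the BLOSUM62 diagonal
        assert aln.identity == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MKT")

    def test_score_symmetry(self):
        a, b = "MKTAYW", "MKTW"
        assert local_align(a, b).score == local_align(b, a).score

    def test_never_crosses_stops(self):
        aln = local_align("MKTW", "MK*TW")
        # best is either MK or TW, never the full 4-mer through the stop
        assert aln.score < local_align("MKTW", "MKTW").score

    def test_no_positive_alignment_returns_none(self):
        # cysteine against glycine only: all pair scores negative
        assert local_align("CC", "GG") is None

    @given(st.data())
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_exhaustive_enumerator(self, data):
        q = data.draw(st.text(AA, min_size=1, max_size=6))
        t = data.draw(st.text(AA, min_size=1, max_size=6))
        expected = oracle_local_align(q, t)
        aln = local_align(q, t)
        got = aln.score if aln else 0.0
        assert got == pytest.approx(max(expected, 0.0))


class TestScanGenome:
    def _genome_with(self, cds, strand="+", length=3000, seed=0):
        rng = np.random.default_rng(seed)
        g = list(random_nt(length, 0.4, rng))
        start = 1200
        insert = cds if strand == "+" else _revcomp(cds)
        g[start:start + len(cds)] = insert
        return "".join(g), start, start + len(cds)

    def test_planted_exact_copy_found(self):
        rng = np.random.default_rng(5)
        cds = simulate_cds(80, 0.4, rng)
        genome, s, e = self._genome_with(cds)
        query = SequenceRecord("q", translate(cds), "aa")
        hits = scan_genome(query, six_frame_translate(genome), score_min=60)
        top = max(hits, key=lambda h: h.score)
        assert top.strand == "+"
        assert top.start <= s and top.end >= e - 3
        assert top.identity == 1.0

    def test_reverse_strand_copy_reported_on_forward_axis(self):
        rng = np.random.default_rng(6)
        cds = simulate_cds(80, 0.4, rng)
        genome, s, e = self._genome_with(cds, strand="-")
        query = SequenceRecord("q", translate(cds), "aa")
        hits = scan_genome(query, six_frame_translate(genome), score_min=60)
        top = max(hits, key=lambda h: h.score)
        assert top.strand == "-"
        assert top.start < top.end
        assert top.start <= s + 3 and top.end >= e - 3

    def test_random_genome_high_threshold_no_hits(self):
        rng = np.random.default_rng(7)
        genome = random_nt(5000, 0.4, rng)
        query = SequenceRecord("q", translate(simulate_cds(60, 0.4, rng)),
                               "aa")
        hits = scan_genome(query, six_frame_translate(genome), score_min=200)
        assert hits == []


def _hit(start, end, strand="+", score=80.0, pep=None, query="q"):
    from venomlgt.homology_search import AlignmentHit
    n = (end - start) // 3
    pep = pep or "M" * n
    return AlignmentHit(query_id=query, start=start, end=end, strand=strand,
                        frame=0, score=score, query_aligned=pep,
                        target_aligned=pep, identity=1.0,
                        pep_start=start // 3, pep_end=end // 3)


class TestMergeHits:
    def test_abutting_hits_merge(self):
        loci = merge_hits([_hit(0, 150), _hit(150, 450)], min_len=50)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (0, 450)
        assert len(loci[0].peptide) == 150

    def test_opposite_strands_stay_separate(self):
        loci = merge_hits([_hit(0, 300), _hit(100, 400, strand="-")],
                          min_len=50)
        assert len(loci) == 2

    def test_short_merged_peptide_dropped(self):
        loci = merge_hits([_hit(0, 90)], min_len=50)  # 30 aa < 50
        assert loci == []

    def test_distant_hits_not_joined(self):
        loci = merge_hits([_hit(0, 300), _hit(2000, 2300)],
                          max_join_gap=1000, min_len=50)
        assert len(loci) == 2


class TestIterativeSearch:
    def test_exact_copy_fixpoint_after_two_iterations(self):
        rng = np.random.default_rng(11)
        cds = simulate_cds(80, 0.4, rng)
        g = list(random_nt(4000, 0.4, rng))
        g[1000:1000 + len(cds)] = cds
        genome = SequenceRecord("chr", "".join(g), "nt")
        seed = SequenceRecord("s", translate(cds), "aa")
        state = iterative_search([seed], genome,
                                 SearchParams(extend_to_orf=False))
        assert state.converged
        assert state.n_iterations == 2
        assert state.new_per_iteration == [1, 0]
        assert state.loci[0].discovery_iteration == 1

    def test_no_homology_zero_loci_one_iteration(self):
        rng = np.random.default_rng(12)
        genome = SequenceRecord("chr", random_nt(3000, 0.4, rng), "nt")
        seed = SequenceRecord("s", translate(simulate_cds(60, 0.4, rng)),
                              "aa")
        state = iterative_search([seed], genome,
                                 SearchParams(score_min=200))
        assert state.converged and state.loci == []
        assert state.n_iterations == 1

    def test_needs_a_seed(self):
        genome = SequenceRecord("chr", "ACGT" * 100, "nt")
        with pytest.raises(ValueError):
            iterative_search([], genome)

    def test_locus_count_monotone(self, small_dataset):
        out, truth = small_dataset
        from venomlgt.formats_io import read_fasta
        genome = read_fasta(out / "genome.fasta", "nt")[0]
        seeds = read_fasta(out / "seeds.fasta", "aa")
        state = iterative_search(seeds, genome, SearchParams())
        assert state.converged
        assert all(n >= 0 for n in state.new_per_iteration)
        assert state.new_per_iteration[-1] == 0


class TestMotif:
    BLOCK = ["MKTAYWCDE", "MKTAYWCDE", "MKSAYWCDE", "MRTAYWCDD"]

    def test_member_retained_by_own_profile(self):
        profile = build_motif(self.BLOCK)
        loci = merge_hits([_hit(0, 300, pep="AAAA" + self.BLOCK[3] + "A" * 87)],
                          min_len=50)
        assert filter_by_motif(loci, profile) == loci

    def test_random_peptide_rejected(self):
        rng = np.random.default_rng(3)
        profile = build_motif(self.BLOCK)
        pep = "".join(rng.choice(list(AA), size=100))
        loci = merge_hits([_hit(0, 300, pep=pep)], min_len=50)
        assert filter_by_motif(loci, profile) == []

    def test_identical_block_gives_point_masses(self):
        profile = build_motif(["MKTAY"] * 10, pseudocount=0.5)
        # dominant residue frequency: (10 + 0.5) / (10 + 20*0.5)
        assert profile.frequencies.max(axis=1) == pytest.approx(
            np.full(5, 10.5 / 20.0))

    def test_narrow_block_rejected(self):
        with pytest.raises(ValueError, match="width"):
            build_motif(["MKT", "MKT"])

    def test_gap_heavy_column_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            build_motif(["MKTAY", "M-TAY", "M-TAY", "M-TAY"])
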