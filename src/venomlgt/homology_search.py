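"""Iterative translated homology search over a genome.

A desk-scale analogue of the iterative TBLASTN/GeneWise screen used to
find diverged gene-family loci: the genome is translated in all six
frames, each query peptide is aligned locally (Smith–Waterman, BLOSUM62,
affine gaps) against every inter-stop segment, hits above a raw score
threshold are merged into loci, and the translated loci join the query
set for the next round until no new locus appears. Alignments never
cross stop codons. A position-frequency motif profile can then be used
to retain only loci carrying the family's conserved block.

Coordinates are 0-based, half-open, on the forward genome axis; reverse
strand hits carry strand "-". The raw-score threshold stands in for an
E-value cutoff and is config-exposed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._codon import translate
from .formats_io import SequenceRecord

__all__ = [
    "AlignmentHit",
    "Locus",
    "MotifProfile",
    "SearchState",
    "SearchParams",
    "FrameTrack",
    "six_frame_translate",
    "local_align",
    "LocalAlignment",
    "scan_genome",
    "merge_hits",
    "iterative_search",
    "build_motif",
    "filter_by_motif",
]


@dataclass(frozen=True)
class FrameTrack:
    """One of the six translation frames with its coordinate map."""

    strand: str          # "+" or "-"
    frame: int           # 0, 1, 2 (offset on the translated strand)
    peptide: str         # '*' marks stops
    genome_length: int

    def to_genomic(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """Map a half-open peptide index range to a forward-axis interval."""
        if self.strand == "+":
            return (self.frame + 3 * pep_start, self.frame + 3 * pep_end)
        L = self.genome_length
        return (L - self.frame - 3 * pep_end, L - self.frame - 3 * pep_start)


def six_frame_translate(genome: SequenceRecord | str) -> list[FrameTrack]:
    """Translate a nucleotide sequence in all six frames.

    Returns 3 forward + 3 reverse-complement frames; the peptide index
    ``i`` of frame ``f`` maps back to an exact 3-bp genomic interval via
    :meth:`FrameTrack.to_genomic`.
    """
    seq = genome.residues if isinstance(genome, SequenceRecord) else genome
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    L = len(seq)
    tracks: list[FrameTrack] = []
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            tracks.append(FrameTrack(strand=strand, frame=f,
                                     peptide=translate(s[f:]),
                                     genome_length=L))
    return tracks


# ---------------------------------------------------------------------------
# Local alignment engine

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_MAX_RESIDUE_SCORE = 11.0  # max diagonal entry of BLOSUM62 (W/W)


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    # gap of length k costs gap_open + k*gap_extend (BLAST convention)
    al = Align.PairwiseAligner()
    al.substitution_matrix = _BLOSUM62
    al.mode = "local"
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


@dataclass(frozen=True)
class LocalAlignment:
    """Best-scoring local alignment between two peptides."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    query_aligned: str   # with '-' for gaps
    target_aligned: str

    @property
    def identity(self) -> float:
        cols = len(self.query_aligned)
        if cols == 0:
            return 0.0
        same = sum(1 for a, b in zip(self.query_aligned, self.target_aligned)
                   if a == b and a != "-")
        return same / cols


def _segments(peptide: str) -> list[tuple[int, str]]:
    """Split a peptide at stop codons; returns (offset, segment) pairs."""
    out = []
    pos = 0
    for seg in peptide.split("*"):
        if seg:
            out.append((pos, seg))
        pos += len(seg) + 1
    return out


_TIE_CAP = 64  # optimal alignments examined for the deterministic tie-break


def _best_alignment(aligner: Align.PairwiseAligner, query: str, target: str
                    ) -> LocalAlignment | None:
    if not query or not target:
        return None
    score = aligner.score(query, target)
    if score <= 0:
        return None
    alns = aligner.align(query, target)
    best = None
    key = None
    for aln in itertools.islice(alns, _TIE_CAP):
        qb, tb = aln.aligned
        ts, te = int(tb[0][0]), int(tb[-1][1])
        qs, qe = int(qb[0][0]), int(qb[-1][1])
        # tie-break: smallest target start, then longest, then smallest
        # query start
        k = (ts, -(te - ts), qs)
        if key is None or k < key:
            key = k
            qa, ta = _aligned_strings(query, target, qb, tb)
            best = LocalAlignment(score=float(score),
                                  query_start=qs, query_end=qe,
                                  target_start=ts, target_end=te,
                                  query_aligned=qa, target_aligned=ta)
    return best


def _aligned_strings(query: str, target: str, qb, tb) -> tuple[str, str]:
    qa_parts: list[str] = []
    ta_parts: list[str] = []
    for i, (qr, tr) in enumerate(zip(qb, tb)):
        if i:
            pq, pt = qb[i - 1], tb[i - 1]
            qa_parts.append(query[pq[1]:qr[0]])
            ta_parts.append("-" * (qr[0] - pq[1]))
            qa_parts.append("-" * (tr[0] - pt[1]))
            ta_parts.append(target[pt[1]:tr[0]])
        qa_parts.append(query[qr[0]:qr[1]])
        ta_parts.append(target[tr[0]:tr[1]])
    return "".join(qa_parts), "".join(ta_parts)


def local_align(query: str, target: str,
                gap_open: float = 11.0,
                gap_extend: float = 1.0) -> LocalAlignment | None:
    """Smith–Waterman local alignment with BLOSUM62 and affine gaps.

    A gap of length k costs ``gap_open + k*gap_extend``. Stop codons
    ('*') effectively score minus infinity: alignments never cross them.
    Returns None when no positive-scoring alignment exists. Ties among
    optimal alignments resolve to the smallest target start, then the
    longest alignment.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    aligner = _make_aligner(gap_open, gap_extend)
    best = None
    key = None
    for t_off, t_seg in _segments(target):
        for q_off, q_seg in _segments(query):
            aln = _best_alignment(aligner, q_seg, t_seg)
            if aln is None:
                continue
            shifted = LocalAlignment(
                score=aln.score,
                query_start=aln.query_start + q_off,
                query_end=aln.query_end + q_off,
                target_start=aln.target_start + t_off,
                target_end=aln.target_end + t_off,
                query_aligned=aln.query_aligned,
                target_aligned=aln.target_aligned,
            )
            k = (-shifted.score, shifted.target_start,
                 -(shifted.target_end - shifted.target_start),
                 shifted.query_start)
            if key is None or k < key:
                key = k
                best = shifted
    return best


@dataclass(frozen=True)
class AlignmentHit:
    """One above-threshold local alignment placed on the genome."""

    query_id: str
    start: int           # forward-axis, 0-based half-open
    end: int
    strand: str
    frame: int
    score: float
    query_aligned: str
    target_aligned: str  # translated genomic segment, with gaps
    identity: float
    pep_start: int = 0   # range on the frame's peptide track
    pep_end: int = 0

    @property
    def target_peptide(self) -> str:
        return self.target_aligned.replace("-", "")


def _orf_extend(hit: AlignmentHit, tracks: Sequence[FrameTrack]
                ) -> tuple[int, int, str]:
    """Extend a hit to its enclosing open reading frame (stop-to-stop) in
    its own frame; returns (genomic start, genomic end, ORF peptide)."""
    track = next(t for t in tracks
                 if t.strand == hit.strand and t.frame == hit.frame)
    pep = track.peptide
    lo, hi = hit.pep_start, hit.pep_end
    while lo > 0 and pep[lo - 1] != "*":
        lo -= 1
    while hi < len(pep) and pep[hi] != "*":
        hi += 1
    start, end = track.to_genomic(lo, hi)
    return start, end, pep[lo:hi]


def _scan_segment(aligner, query: str, seg: str, seg_off: int,
                  score_min: float, out: list[tuple[float, int, int, str, str]]
                  ) -> None:
    """Best-hit-then-mask recursion inside one inter-stop segment."""
    if not seg or _MAX_RESIDUE_SCORE * min(len(seg), len(query)) < score_min:
        return
    if aligner.score(query, seg) < score_min:
        return
    aln = _best_alignment(aligner, query, seg)
    if aln is None or aln.score < score_min:
        return
    out.append((aln.score, seg_off + aln.target_start,
                seg_off + aln.target_end, aln.query_aligned,
                aln.target_aligned))
    # mask by splitting: alignments are non-overlapping within a frame
    _scan_segment(aligner, query, seg[:aln.target_start], seg_off,
                  score_min, out)
    _scan_segment(aligner, query, seg[aln.target_end:],
                  seg_off + aln.target_end, score_min, out)


def scan_genome(query: SequenceRecord,
                tracks: Sequence[FrameTrack],
                score_min: float = 60.0,
                gap_open: float = 11.0,
                gap_extend: float = 1.0) -> list[AlignmentHit]:
    """All non-overlapping local alignments of one peptide query against
    the six translated frames, each with score ≥ ``score_min``.

    Found by iterated best-hit-then-mask within every inter-stop segment
    of every frame.
    """
    aligner = _make_aligner(gap_open, gap_extend)
    qpep = query.residues.upper()
    hits: list[AlignmentHit] = []
    for track in tracks:
        for seg_off, seg in _segments(track.peptide):
            found: list[tuple[float, int, int, str, str]] = []
            _scan_segment(aligner, qpep, seg, seg_off, score_min, found)
            for score, ps, pe, qa, ta in found:
                g_start, g_end = track.to_genomic(ps, pe)
                cols = len(qa)
                same = sum(1 for a, b in zip(qa, ta) if a == b and a != "-")
                hits.append(AlignmentHit(
                    query_id=query.id, start=g_start, end=g_end,
                    strand=track.strand, frame=track.frame,
                    score=score, query_aligned=qa, target_aligned=ta,
                    identity=same / cols if cols else 0.0,
                    pep_start=ps, pep_end=pe,
                ))
    hits.sort(key=lambda h: (h.start, h.end, h.strand, -h.score))
    return hits


@dataclass
class Locus:
    """A merged genomic interval supported by translated alignments."""

    locus_id: str
    start: int
    end: int
    strand: str
    score: float              # best member-hit score
    peptide: str              # concatenated aligned segments, genomic order
    best_query: str
    identity: float           # identity of the best-scoring member hit
    discovery_iteration: int = 0
    n_hits: int = 1

    def overlaps(self, start: int, end: int, strand: str) -> bool:
        return self.strand == strand and self.start < end and start < self.end


def merge_hits(hits: Sequence[AlignmentHit],
               max_join_gap: int = 1000,
               min_len: int = 50,
               max_len: int = 2000,
               id_prefix: str = "locus",
               tracks: Sequence[FrameTrack] | None = None) -> list[Locus]:
    """Merge same-strand hits whose intervals overlap or lie within
    ``max_join_gap`` bp into loci.

    The locus peptide is the concatenation of member aligned segments in
    translation order (ascending genomic start on "+", descending on "-").
    When ``tracks`` is given, each merged locus is instead extended to the
    enclosing open reading frame of its best member hit and its peptide
    becomes that ORF translation (a stand-in for gene-structure assembly
    around a seed alignment). Merged loci whose translated length falls
    outside [min_len, max_len] amino acids are dropped.
    """
    loci: list[Locus] = []
    dropped = 0
    for strand in ("+", "-"):
        group = sorted([h for h in hits if h.strand == strand],
                       key=lambda h: (h.start, h.end))
        cluster: list[AlignmentHit] = []
        for h in group + [None]:  # type: ignore[list-item]
            if cluster and (h is None
                            or h.start > max(c.end for c in cluster) + max_join_gap):
                members = cluster
                ordered = sorted(members, key=lambda m: m.start,
                                 reverse=(strand == "-"))
                peptide = "".join(m.target_peptide for m in ordered)
                best = max(members, key=lambda m: (m.score, -m.start))
                start = min(m.start for m in members)
                end = max(m.end for m in members)
                if tracks is not None:
                    o_start, o_end, o_pep = _orf_extend(best, tracks)
                    start, end = min(start, o_start), max(end, o_end)
                    peptide = o_pep
                if min_len <= len(peptide) <= max_len:
                    loci.append(Locus(
                        locus_id="",
                        start=start,
                        end=end,
                        strand=strand,
                        score=best.score,
                        peptide=peptide,
                        best_query=best.query_id,
                        identity=best.identity,
                        n_hits=len(members),
                    ))
                else:
                    dropped += 1
                cluster = []
            if h is not None:
                cluster.append(h)
    loci.sort(key=lambda l: (l.start, l.end, l.strand))
    for i, loc in enumerate(loci):
        loc.locus_id = f"{id_prefix}_{i:04d}"
    return loci


@dataclass
class SearchParams:
    """Tunables of the iterative search."""

    score_min: float = 60.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    max_join_gap: int = 1000
    locus_min_len: int = 50
    locus_max_len: int = 2000
    max_iter: int = 10
    extend_to_orf: bool = True


@dataclass
class SearchState:
    """Search state at (or short of) the fixpoint."""

    queries: dict[str, str]            # query id -> peptide
    loci: list[Locus]
    n_iterations: int
    new_per_iteration: list[int]
    converged: bool


def iterative_search(seeds: Sequence[SequenceRecord],
                     genome: SequenceRecord,
                     params: SearchParams | None = None) -> SearchState:
    """Iterate translated search until no new locus is found.

    Iteration t scans with every query not yet scanned (seeds first, then
    peptides of loci discovered so far — each query is scanned exactly
    once, which yields the same fixpoint as rescanning all queries every
    round). A hit region is a *new* locus only when it does not overlap
    an existing locus on the same strand by ≥ 1 bp. Stops at zero new
    loci or ``max_iter`` (then flagged unconverged).
    """
    if not seeds:
        raise ValueError("iterative_search needs at least one seed")
    p = params or SearchParams()
    tracks = six_frame_translate(genome)
    queries: dict[str, str] = {s.id: s.residues.upper() for s in seeds}
    pending: list[SequenceRecord] = list(seeds)
    loci: list[Locus] = []
    new_per_iteration: list[int] = []
    converged = False
    iteration = 0
    counter = 0
    while iteration < p.max_iter:
        iteration += 1
        hits: list[AlignmentHit] = []
        for q in pending:
            hits.extend(scan_genome(q, tracks, score_min=p.score_min,
                                    gap_open=p.gap_open,
                                    gap_extend=p.gap_extend))
        pending = []
        candidates = merge_hits(hits, max_join_gap=p.max_join_gap,
                                min_len=p.locus_min_len,
                                max_len=p.locus_max_len,
                                tracks=tracks if p.extend_to_orf else None)
        n_new = 0
        for cand in candidates:
            if any(l.overlaps(cand.start, cand.end, cand.strand) for l in loci):
                continue
            counter += 1
            cand.locus_id = f"locus_{counter:04d}"
            cand.discovery_iteration = iteration
            loci.append(cand)
            queries[cand.locus_id] = cand.peptide
            pending.append(SequenceRecord(id=cand.locus_id,
                                          residues=cand.peptide,
                                          alphabet="aa"))
            n_new += 1
        new_per_iteration.append(n_new)
        if n_new == 0:
            converged = True
            break
    loci.sort(key=lambda l: (l.start, l.end))
    return SearchState(queries=queries, loci=loci,
                       n_iterations=iteration,
                       new_per_iteration=new_per_iteration,
                       converged=converged)


# ---------------------------------------------------------------------------
# Motif profile filter

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA20)}


@dataclass
class MotifProfile:
    """Position frequency matrix over the 20 amino acids with log-odds
    scoring against a uniform background."""

    frequencies: np.ndarray   # (width, 20), columns sum to 1
    threshold: float
    width: int

    def log_odds(self) -> np.ndarray:
        return np.log2(self.frequencies * 20.0)

    def best_window_score(self, peptide: str) -> float:
        """Max sliding-window log-odds score; -inf for short peptides.
        Residues outside the 20-letter alphabet score 0 (neutral)."""
        lo = self.log_odds()
        pep = peptide.upper()
        if len(pep) < self.width:
            return -math.inf
        best = -math.inf
        for i in range(len(pep) - self.width + 1):
            s = 0.0
            for j in range(self.width):
                idx = _AA_INDEX.get(pep[i + j])
                if idx is not None:
                    s += lo[j, idx]
            best = max(best, s)
        return best


def build_motif(aligned_block: Sequence[str],
                pseudocount: float = 0.5,
                max_gap_fraction: float = 0.2) -> MotifProfile:
    """Build a motif profile from a gap-light aligned block.

    Columns with more than ``max_gap_fraction`` gaps are rejected; gaps in
    accepted columns are ignored (frequencies renormalized). The retention
    threshold defaults to the score attained by the weakest block member
    against its own profile.
    """
    if not aligned_block:
        raise ValueError("empty block")
    width = len(aligned_block[0])
    if width < 5:
        raise ValueError(f"block width {width} < 5")
    if any(len(s) != width for s in aligned_block):
        raise ValueError("block sequences of unequal length")
    freqs = np.full((width, 20), pseudocount, dtype=float)
    for j in range(width):
        col = [s[j].upper() for s in aligned_block]
        n_gap = sum(1 for c in col if c == "-")
        if n_gap / len(col) > max_gap_fraction:
            raise ValueError(f"column {j}: more than "
                             f"{max_gap_fraction:.0%} gaps")
        for c in col:
            idx = _AA_INDEX.get(c)
            if idx is not None:
                freqs[j, idx] += 1.0
    freqs /= freqs.sum(axis=1, keepdims=True)
    profile = MotifProfile(frequencies=freqs, threshold=-math.inf, width=width)
    member_scores = [profile.best_window_score(s.replace("-", ""))
                     for s in aligned_block]
    profile.threshold = min(member_scores)
    return profile


def filter_by_motif(loci: Sequence[Locus], profile: MotifProfile,
                    threshold: float | None = None) -> list[Locus]:
    """Retain loci whose peptide carries a window scoring at or above the
    profile threshold."""
    thr = profile.threshold if threshold is None else threshold
    return [l for l in loci if profile.best_window_score(l.peptide) >= thr]
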