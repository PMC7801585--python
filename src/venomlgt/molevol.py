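"""Pairwise molecular-evolution statistics and gene-order analysis.

The rate estimator is Nei–Gojobori (1986) counting on gap-free codon pair
alignments: per-position synonymous site fractions with stop-creating
changes excluded and renormalized, difference counts averaged over all
substitution orderings that avoid stops, and Jukes–Cantor correction
d = -(3/4)·ln(1 - 4p/3). ω = dN/dS, with dS = 0 pairs flagged rather than
reported as infinite.

Also here: Kimura two-parameter distances, the dS-saturation filter,
the pathway-level selection scan over per-pathway median ω, percentile
ranks, and macro-synteny block calling from ortholog gene orders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _codon
from .formats_io import GeneOrderMap, OrthologTable

__all__ = [
    "CodonPairAlignment",
    "RateEstimate",
    "PathwayScan",
    "SyntenyBlock",
    "ng86",
    "k2p",
    "filter_saturated",
    "pathway_scan",
    "percentile_rank",
    "call_macro_synteny",
]

SATURATED = math.inf  # sentinel for distances past the correction domain


@dataclass(frozen=True)
class CodonPairAlignment:
    """Two equal-length, gap-free, in-frame coding sequences."""

    seq_a: str
    seq_b: str
    pair_id: str = ""

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(f"{self.pair_id}: unequal lengths {len(a)} != {len(b)}")
        if len(a) == 0 or len(a) % 3:
            raise ValueError(f"{self.pair_id}: length {len(a)} not a positive multiple of 3")
        for seq, tag in ((a, "A"), (b, "B")):
            if "-" in seq:
                raise ValueError(f"{self.pair_id}: gap in sequence {tag}")
            for i in range(0, len(seq), 3):
                if _codon.is_stop(seq[i:i + 3]):
                    raise ValueError(f"{self.pair_id}: stop codon at {i} in {tag}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


@dataclass
class RateEstimate:
    """NG86 site and difference counts with corrected rates for one pair."""

    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # nan when dS == 0 or saturated
    ds_zero: bool
    saturated: bool


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return SATURATED
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(pair: CodonPairAlignment, ds_max: float = 2.0) -> RateEstimate:
    """Nei–Gojobori counting estimate of dN, dS and ω for one pair.

    Site counts are averaged over the two sequences; S + N equals the
    alignment length exactly. Saturation (p ≥ 3/4, or dS > ds_max) sets
    the ``saturated`` flag with dS = +inf in the undefined case.
    """
    S = N = 0.0
    Sd = Nd = 0.0
    for ca, cb in pair.codons():
        fa = _codon.codon_site_fractions(ca)
        fb = _codon.codon_site_fractions(cb)
        S += (sum(fa) + sum(fb)) / 2.0
        N += 3.0 - (sum(fa) + sum(fb)) / 2.0
        sd, nd = _codon.codon_path_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    ds_zero = (dS == 0.0)
    saturated = math.isinf(dS) or math.isinf(dN) or dS > ds_max
    if dN == 0.0 and dS > 0.0:
        omega = 0.0          # no nonsynonymous change at all
    elif ds_zero or math.isinf(dS) or math.isinf(dN):
        omega = math.nan
    else:
        omega = dN / dS
    return RateEstimate(pair.pair_id, S, N, Sd, Nd, pS, pN, dS, dN,
                        omega, ds_zero, saturated)


_PURINES = {"A", "G"}
_UNAMBIG = frozenset("ACGT")


def k2p(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between equal-length nucleotide
    sequences. Sites with gaps or ambiguity codes are excluded pairwise.

    K = -(1/2)·ln(1 - 2P - Q) - (1/4)·ln(1 - 2Q) with P, Q the transition
    and transversion fractions. Out-of-domain logs return the saturated
    sentinel (+inf).
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("k2p: unequal sequence lengths")
    # refuse amino-acid input: these letters are amino acids but never
    # IUPAC nucleotide codes
    aa_only = frozenset("EFILPQXZJO*")
    for seq in (a, b):
        bad = set(seq) & aa_only
        if bad:
            raise ValueError(
                f"k2p is defined for nucleotide sequences; found "
                f"amino-acid letters {sorted(bad)}")
    nt_ok = frozenset("ACGTURYSWKMBDHVN-.")
    for seq in (a, b):
        bad = set(seq) - nt_ok
        if bad:
            raise ValueError(
                f"k2p is defined for nucleotide sequences; found {sorted(bad)}")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _UNAMBIG or y not in _UNAMBIG:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("k2p: no comparable sites")
    P, Q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return SATURATED
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def filter_saturated(estimates: Iterable[RateEstimate],
                     ds_max: float = 2.0) -> list[RateEstimate]:
    """Drop pairs with dS > ds_max (strict) or an undefined correction.

    Pairs with dS exactly at the bound are retained; ds_zero pairs are
    retained here (their ω is nan and is excluded downstream where a real
    ω is needed).
    """
    out = []
    for est in estimates:
        if math.isinf(est.dS) or math.isinf(est.dN):
            continue
        if est.dS > ds_max:
            continue
        out.append(est)
    return out


@dataclass
class PathwayScan:
    """Pathway-level selection scan result."""

    table: pd.DataFrame  # index: pathway; columns: n_genes, median_omega, z, p, class_
    mean_median: float
    sd_median: float

    def elevated(self) -> list[str]:
        return list(self.table.index[self.table["class_"] == "elevated"])

    def conserved(self) -> list[str]:
        return list(self.table.index[self.table["class_"] == "conserved"])


def pathway_scan(estimates: Iterable[RateEstimate],
                 pathway_map: Mapping[str, Sequence[str]],
                 min_genes: int = 3,
                 alpha: float = 0.01,
                 conserved_eps: float = 0.02) -> PathwayScan:
    """Scan pathways for elevated or conserved median ω.

    ``pathway_map`` maps pathway id -> gene (pair) ids. Only pathways with
    at least ``min_genes`` genes carrying a defined ω are analyzed. Each
    pathway median is z-scored against the mean/SD of all pathway medians;
    elevated = one-sided upper-tail normal p < alpha; conserved = median ≤
    conserved_eps.
    """
    omega = {e.pair_id: e.omega for e in estimates
             if not (math.isnan(e.omega) or math.isinf(e.omega))}
    rows = []
    for pw in sorted(pathway_map):
        vals = [omega[g] for g in pathway_map[pw] if g in omega]
        if len(vals) < min_genes:
            continue
        rows.append((pw, len(vals), float(np.median(vals))))
    if len(rows) < 2:
        raise ValueError("pathway_scan: fewer than 2 analyzable pathways")
    medians = np.array([r[2] for r in rows])
    mu, sd = float(medians.mean()), float(medians.std(ddof=1))
    if sd == 0.0:
        z = np.zeros_like(medians)
        p = np.full_like(medians, 0.5)
    else:
        z = (medians - mu) / sd
        p = stats.norm.sf(z)
    classes = []
    for med, pp in zip(medians, p):
        if med <= conserved_eps:
            classes.append("conserved")
        elif sd > 0 and pp < alpha:
            classes.append("elevated")
        else:
            classes.append("neutral")
    table = pd.DataFrame(
        {"n_genes": [r[1] for r in rows],
         "median_omega": medians,
         "z": z, "p": p, "class_": classes},
        index=pd.Index([r[0] for r in rows], name="pathway"),
    )
    return PathwayScan(table=table, mean_median=mu, sd_median=sd)


def percentile_rank(value: float, reference: Sequence[float]) -> float:
    """Percent of reference values strictly below ``value``.

    Ties are excluded from the numerator.
    """
    ref = [r for r in reference]
    if not ref:
        raise ValueError("percentile_rank: empty reference")
    below = sum(1 for r in ref if r < value)
    return 100.0 * below / len(ref)


@dataclass(frozen=True)
class SyntenyBlock:
    """A run of ortholog pairs in conserved (possibly inverted) order."""

    scaffold_a: str
    scaffold_b: str
    genes_a: tuple[str, ...]   # species-A gene ids, in A order
    orientation: str           # "same" | "inverted"

    @property
    def n_genes(self) -> int:
        return len(self.genes_a)


def _positions(gmap: GeneOrderMap, species: str) -> dict[str, tuple[str, int]]:
    """gene -> (scaffold, index within scaffold)."""
    out: dict[str, tuple[str, int]] = {}
    for sc, genes in gmap.orders[species].items():
        for i, (g, _strand) in enumerate(genes):
            out[g] = (sc, i)
    return out


def _maximal_runs(entries: list[tuple[int, str, str, int]],
                  gaps_a: list[int],
                  max_gap: int) -> list[tuple[int, int, str]]:
    """Enumerate maximal collinear runs over the ortholog sub-order of one
    A scaffold.

    ``entries[i] = (a_index, gene_a, b_scaffold, b_index)``;
    ``gaps_a[i]`` = number of non-ortholog A genes between ortholog i-1 and i.
    Returns (start, end_exclusive, orientation) index ranges into entries.
    """
    runs: list[tuple[int, int, str]] = []
    n = len(entries)
    for direction, oname in ((+1, "same"), (-1, "inverted")):
        i = 0
        while i < n:
            j = i
            while j + 1 < n:
                _, _, sc1, b1 = entries[j]
                _, _, sc2, b2 = entries[j + 1]
                if sc2 != sc1:
                    break
                if gaps_a[j + 1] > max_gap:
                    break
                step = (b2 - b1) * direction
                if step < 1 or step - 1 > max_gap:
                    break
                j += 1
            if j > i:
                runs.append((i, j + 1, oname))
                i = j  # maximal runs may share an endpoint gene
            else:
                i += 1
    return runs


def call_macro_synteny(gene_orders: GeneOrderMap,
                       ortholog_table: OrthologTable,
                       min_block: int = 3,
                       max_gap: int = 1) -> list[SyntenyBlock]:
    """Call macro-synteny blocks from ortholog gene orders.

    A block is a maximal run of consecutive species-A orthologs whose
    partners lie on one species-B scaffold in strictly increasing (same) or
    strictly decreasing (inverted) B order, allowing up to ``max_gap``
    intervening non-orthologous genes on either side. Runs shorter than
    ``min_block`` are discarded and each ortholog is assigned to at most one
    block (longest block first; ties by leftmost A position).
    """
    sp_a, sp_b = ortholog_table.species_a, ortholog_table.species_b
    for sp in (sp_a, sp_b):
        if sp not in gene_orders.orders:
            raise KeyError(f"species {sp!r} missing from gene orders")
    pos_b = _positions(gene_orders, sp_b)
    for ga, gb in ortholog_table.pairs.items():
        if gb not in pos_b:
            raise ValueError(f"gene {gb!r} in ortholog table but not in orders")

    candidates: list[SyntenyBlock] = []
    for sc_a in sorted(gene_orders.orders[sp_a]):
        genes = gene_orders.orders[sp_a][sc_a]
        entries: list[tuple[int, str, str, int]] = []
        gaps_a: list[int] = []
        last_idx = None
        for idx, (g, _strand) in enumerate(genes):
            if g not in ortholog_table.pairs:
                continue
            sc_b, b_idx = pos_b[ortholog_table.pairs[g]]
            gaps_a.append(0 if last_idx is None else idx - last_idx - 1)
            entries.append((idx, g, sc_b, b_idx))
            last_idx = idx
        for start, end, orient in _maximal_runs(entries, gaps_a, max_gap):
            if end - start < min_block:
                continue
            candidates.append(SyntenyBlock(
                scaffold_a=sc_a,
                scaffold_b=entries[start][2],
                genes_a=tuple(e[1] for e in entries[start:end]),
                orientation=orient,
            ))

    # longest-first assignment; each ortholog in at most one block
    def sort_key(b: SyntenyBlock):
        return (-b.n_genes, b.scaffold_a, b.genes_a)

    used: set[str] = set()
    blocks: list[SyntenyBlock] = []
    for blk in sorted(candidates, key=sort_key):
        kept = tuple(g for g in blk.genes_a if g not in used)
        if len(kept) != blk.n_genes:
            # overlap with an already-assigned block: trim to the unused
            # prefix/suffix run; drop if no contiguous run of min_block left
            kept = _longest_free_run(blk.genes_a, used)
        if len(kept) < min_block:
            continue
        used.update(kept)
        blocks.append(SyntenyBlock(blk.scaffold_a, blk.scaffold_b, kept,
                                   blk.orientation))
    blocks.sort(key=lambda b: (b.scaffold_a, b.genes_a))
    return blocks


def _longest_free_run(genes: tuple[str, ...], used: set[str]) -> tuple[str, ...]:
    best: tuple[str, ...] = ()
    cur: list[str] = []
    for g in genes:
        if g in used:
            if len(cur) > len(best):
                best = tuple(cur)
            cur = []
        else:
            cur.append(g)
    if len(cur) > len(best):
        best = tuple(cur)
    return best
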