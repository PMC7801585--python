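"""Standard genetic code helpers shared by the simulator and the rate
estimators. Kept independent of Biopython so the counting conventions
(stop-change exclusion, renormalized site fractions) are explicit."""

from __future__ import annotations

from functools import lru_cache

BASES = "ACGT"

# standard code, codon -> one-letter amino acid ('*' = stop)
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, a in _CODE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c in _CODE if c not in STOP_CODONS))

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def aa(codon: str) -> str:
    return _CODE[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(cds: str) -> str:
    """Translate an in-frame nucleotide string; trailing partial codon is
    dropped; codons with non-ACGT characters become X."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3].upper()
        out.append(_CODE.get(codon, "X"))
    return "".join(out)


def is_transition(b1: str, b2: str) -> bool:
    return TRANSITIONS.get(b1) == b2


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position synonymous fraction of the three single-nucleotide
    changes, excluding changes that create a stop (renormalized).

    Each position counts as exactly one site split between synonymous and
    nonsynonymous by these fractions, so S + N per codon is exactly 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    fracs = []
    for pos in range(3):
        n_syn = n_non = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if _CODE[alt] == _CODE[codon]:
                n_syn += 1
            else:
                n_non += 1
        total = n_syn + n_non
        fracs.append(n_syn / total if total else 0.0)
    return tuple(fracs)


@lru_cache(maxsize=None)
def codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous change counts between two codons.

    All orderings of the differing positions are enumerated; paths passing
    through a stop codon are excluded and the remainder averaged. If every
    path is stop-blocked, each differing position is classified directly
    against the current codon (degenerate fallback, kept deterministic).
    """
    if c1 == c2:
        return (0.0, 0.0)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    from itertools import permutations

    totals = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            totals.append((sd, nd))
    if not totals:
        # all paths blocked: classify each change in the c1 context
        sd = nd = 0.0
        for pos in diff:
            alt = c1[:pos] + c2[pos] + c1[pos + 1:]
            ref = _CODE[alt] if alt not in STOP_CODONS else None
            if ref is not None and ref == _CODE[c1]:
                sd += 1
            else:
                nd += 1
        return (sd, nd)
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return (s, n)
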