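"""Venom-protein calling from venom-gland expression plus proteome peptides.

A venom protein (VP) is a venom-gland-expressed gene whose protein exactly
contains more than ``min_peptides`` (default 3, i.e. at least 4) distinct
proteomic peptides as contiguous substrings. Peptides shared across
proteins count for every protein but are flagged. On top of the calls sits
the candidate scatter (venom-gland TPM vs. specialization) and the
filter-cascade ranking of "Lar-like" candidates: species-specific,
VP-supported, venom-specialized, rapidly evolving paralog pair, and
LGT-positive gene tree, ranked by venom-gland TPM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import ExpressionMatrix, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideMatchTable",
    "VenomCall",
    "CandidateEvidence",
    "match_peptides",
    "call_venom_proteins",
    "venom_scatter",
    "rank_lar_like",
]


@dataclass
class PeptideMatchTable:
    """Exact-substring matches between peptides and proteins."""

    by_protein: dict[str, set[str]]   # protein id -> distinct matched peptides
    by_peptide: dict[str, set[str]]   # peptide -> protein ids
    shared_peptides: set[str] = field(default_factory=set)

    def count(self, protein_id: str) -> int:
        return len(self.by_protein.get(protein_id, ()))


def _fold_il(s: str) -> str:
    return s.replace("I", "J").replace("L", "J")


def match_peptides(peptides: Iterable[str],
                   proteins: Iterable[SequenceRecord],
                   il_equivalence: bool = False) -> PeptideMatchTable:
    """Match peptides to proteins by exact contiguous substring occurrence.

    Matching is case-normalized; duplicate peptide strings are collapsed.
    ``il_equivalence`` optionally folds isoleucine and leucine together (a
    mass-spectrometry convention, off by default).
    """
    peps: list[str] = []
    seen: set[str] = set()
    for p in peptides:
        p = p.strip().upper()
        if not p:
            raise ValueError("empty peptide")
        if p not in seen:
            seen.add(p)
            peps.append(p)
    by_protein: dict[str, set[str]] = {}
    by_peptide: dict[str, set[str]] = {p: set() for p in peps}
    for rec in proteins:
        body = rec.residues.upper()
        hay = _fold_il(body) if il_equivalence else body
        hits = set()
        for p in peps:
            needle = _fold_il(p) if il_equivalence else p
            if needle in hay:
                hits.add(p)
                by_peptide[p].add(rec.id)
        if hits:
            by_protein[rec.id] = hits
    shared = {p for p, prots in by_peptide.items() if len(prots) > 1}
    return PeptideMatchTable(by_protein=by_protein, by_peptide=by_peptide,
                             shared_peptides=shared)


@dataclass
class VenomCall:
    """Venom-protein call and its evidence for one gene."""

    gene_id: str
    vg_tpm: float
    n_peptides: int
    is_vp: bool
    specialization: float = math.nan
    is_species_specific: bool = False


def call_venom_proteins(match_table: PeptideMatchTable,
                        vg_expressed: Iterable[str],
                        gene_ids: Iterable[str],
                        vg_tpm: Mapping[str, float] | None = None,
                        min_peptides: int = 3) -> dict[str, VenomCall]:
    """Call VPs: venom-gland expressed and strictly more than
    ``min_peptides`` distinct matched peptides (≥ 4 at the default)."""
    vg_set = set(vg_expressed)
    calls: dict[str, VenomCall] = {}
    for g in gene_ids:
        n = match_table.count(g)
        calls[g] = VenomCall(
            gene_id=g,
            vg_tpm=float(vg_tpm.get(g, math.nan)) if vg_tpm else math.nan,
            n_peptides=n,
            is_vp=(g in vg_set and n > min_peptides),
        )
    return calls


def venom_scatter(matrix: ExpressionMatrix,
                  calls: Mapping[str, VenomCall],
                  specialization: Mapping[str, float],
                  vg_expressed: Iterable[str],
                  specific_set: Iterable[str]) -> pd.DataFrame:
    """Per-gene scatter behind the VP figure: x = venom-gland TPM,
    y = specialization, with proteome-evidence and species-specific flags.

    Only venom-gland-expressed genes appear.
    """
    vg = matrix.vg_sample
    spec = set(specific_set)
    rows = []
    for g in sorted(set(vg_expressed)):
        call = calls.get(g)
        rows.append({
            "gene_id": g,
            "vg_tpm": float(matrix.values.at[g, vg]),
            "specialization": float(specialization.get(g, 0.0)),
            "has_proteome_evidence": bool(call and call.n_peptides > 0),
            "is_vp": bool(call and call.is_vp),
            "is_species_specific": g in spec,
        })
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["vg_tpm", "specialization", "has_proteome_evidence",
                 "is_vp", "is_species_specific"])


@dataclass
class CandidateEvidence:
    """Per-filter evidence for one ranked candidate."""

    gene_id: str
    vg_tpm: float
    specialization: float
    is_vp: bool
    is_species_specific: bool
    pair_omega_percentile: float | None  # None when no paralog pair exists
    lgt_verdict: str | None              # None when no tree exists
    passed: bool = True

    def as_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "vg_tpm": self.vg_tpm,
            "specialization": self.specialization,
            "is_vp": self.is_vp,
            "is_species_specific": self.is_species_specific,
            "pair_omega_percentile": self.pair_omega_percentile,
            "lgt_verdict": self.lgt_verdict,
        }


def rank_lar_like(scatter: pd.DataFrame,
                  omega_percentiles: Mapping[str, float] | None = None,
                  lgt_verdicts: Mapping[str, str] | None = None,
                  s_min: float = 0.9,
                  p_min: float = 95.0) -> list[CandidateEvidence]:
    """Rank Lar-like candidates through the evidence filter cascade.

    A gene survives when it is species-specific, a called VP, specialized
    (index ≥ s_min), its paralog-pair ω percentile ≥ p_min when a pair
    exists, and its gene-tree verdict is ``lgt`` when a tree exists.
    Survivors are ranked by venom-gland TPM descending, ties broken
    lexicographically by gene id. Missing component tables skip that
    filter with a logged warning.
    """
    if omega_percentiles is None:
        logger.warning("rank_lar_like: no ω-percentile table; filter skipped")
    if lgt_verdicts is None:
        logger.warning("rank_lar_like: no LGT verdict table; filter skipped")
    survivors: list[CandidateEvidence] = []
    for g, row in scatter.iterrows():
        pct = omega_percentiles.get(g) if omega_percentiles is not None else None
        verdict = lgt_verdicts.get(g) if lgt_verdicts is not None else None
        ev = CandidateEvidence(
            gene_id=str(g),
            vg_tpm=float(row["vg_tpm"]),
            specialization=float(row["specialization"]),
            is_vp=bool(row["is_vp"]),
            is_species_specific=bool(row["is_species_specific"]),
            pair_omega_percentile=pct,
            lgt_verdict=verdict,
        )
        if not (ev.is_species_specific and ev.is_vp):
            continue
        if ev.specialization < s_min:
            continue
        if omega_percentiles is not None and pct is not None and pct < p_min:
            continue
        if lgt_verdicts is not None and verdict is not None and verdict != "lgt":
            continue
        survivors.append(ev)
    survivors.sort(key=lambda e: (-e.vg_tpm, e.gene_id))
    return survivors
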