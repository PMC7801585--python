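"""Two-species comparative dataset generator with planted ground truth.

Emulates the statistical structure the analysis chain assumes for a
generalist/specialist parasitoid pair: ortholog CDS pairs evolved at known
ω under a proposal/acceptance substitution scheme, species-specific genes,
stage × venom-gland expression with planted venom specialization, proteome
peptide evidence for planted venom proteins, an AT-rich genome with low-GC
islands and planted diverged gene-family loci (including one reachable
only transitively through another locus), taxonomy-labeled gene trees with
planted LGT topology, gene orders with conserved blocks, and domain count
tables with one focal-exclusive domain. Everything planted is recorded in
a :class:`PlantedTruth` JSON record — the acceptance surface for recovery
tests.

One global integer seed drives a hierarchical per-component stream, so
adding a component never perturbs the others; identical configs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _codon
from .formats_io import (
    DomainCountTable,
    ExpressionMatrix,
    GeneOrderMap,
    OrthologTable,
    SequenceRecord,
    TaxLabeledTree,
    read_newick_labeled,
    write_domain_counts,
    write_expression_table,
    write_fasta,
    write_gene_order,
    write_newick_labeled,
    write_ortholog_table,
)
from .homology_search import local_align

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "ExpressionProfile",
    "simulate_cds",
    "mutate_cds",
    "evolve_pair",
    "simulate_expression",
    "simulate_peptides",
    "simulate_genome",
    "simulate_gene_tree",
    "generate_dataset",
]

import pandas as pd


def _stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component RNG stream."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class SimConfig:
    """Study conditions of the default synthetic dataset."""

    seed: int = 0
    # ortholog pairs: (true omega, target pairwise dS, number of pairs)
    omega_grid: tuple = (
        (0.15, 0.3, 278),   # background purifying selection
        (0.5, 0.3, 15),     # elevated pathway
        (0.01, 0.3, 45),    # strongly conserved pathways
        (0.15, 3.0, 12),    # saturated pairs (removed by the dS filter)
    )
    kappa: float = 1.0          # transition/transversion proposal odds
    codon_range: tuple = (150, 400)
    n_specific_a: int = 150
    n_specific_b: int = 150
    n_planted_vp: int = 10
    specialization_factor: float = 50.0
    stages: tuple = ("E", "L1", "L2", "P1", "P2", "P3", "AF", "AM")
    vg_sample: str = "VG"
    n_concurrent_p3af: int = 5
    tpm_log_mean: float = np.log(5.0)   # background log-normal TPM
    tpm_log_sd: float = 1.5
    # genome
    genome_length: int = 2_000_000
    background_gc: float = 0.27
    island_gc: float = 0.16
    island_fraction: float = 0.10
    island_size: int = 40_000
    n_planted_loci: int = 12            # includes intermediate + transitive
    locus_identity_range: tuple = (0.70, 0.95)
    lar_codons: int = 200
    extension_codons: int = 150
    score_min: float = 60.0             # search threshold the truth honors
    # trees
    n_lgt_trees: int = 50
    n_vertical_trees: int = 50
    # families / domains
    warm_family_size: int = 9
    n_background_domains: int = 30
    other_species: tuple = ("hym1", "hym2", "hym3", "hym4", "hym5")

    @property
    def n_ortholog_pairs(self) -> int:
        return sum(n for _, _, n in self.omega_grid)

    def validate(self) -> None:
        for om, ds, n in self.omega_grid:
            if om < 0 or ds < 0 or n < 0:
                raise ValueError("omega_grid entries must be non-negative")
        if not (0 < self.background_gc < 1 and 0 < self.island_gc < 1):
            raise ValueError("GC values must lie in (0, 1)")
        lo, hi = self.locus_identity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("locus identity range must be within (0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class PlantedTruth:
    """Everything the simulator planted, JSON-serializable."""

    seed: int
    species: tuple = ("A", "B")
    ortholog_pairs: dict = field(default_factory=dict)
    lar_pair: dict = field(default_factory=dict)
    specific_a: list = field(default_factory=list)
    specific_b: list = field(default_factory=list)
    vp_ids_a: list = field(default_factory=list)
    vp_ids_b: list = field(default_factory=list)
    venom_specialized_a: list = field(default_factory=list)
    concurrent_p3af: list = field(default_factory=list)
    elevated_pathways: list = field(default_factory=list)
    conserved_pathways: list = field(default_factory=list)
    lgt_tree_ids: list = field(default_factory=list)
    vertical_tree_ids: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    islands: list = field(default_factory=list)
    background_gc: float = 0.27
    island_gc: float = 0.16
    lar_like_id: str = ""
    warm_like_id: str = ""
    warm_family: list = field(default_factory=list)
    warm_domain: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["species"] = tuple(data["species"])
        return cls(**data)


# ---------------------------------------------------------------------------
# sequence-level generators

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probs(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])  # A C G T


def random_nt(length: int, gc: float, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=length, p=_base_probs(gc))
    return bytes(_BASES[idx]).decode()


def simulate_cds(n_codons: int, gc_bias: float,
                 rng: np.random.Generator) -> str:
    """A random in-frame CDS: starts with ATG, no internal stop codons,
    base composition at the requested GC bias."""
    if n_codons < 1:
        raise ValueError("n_codons must be ≥ 1")
    probs = _base_probs(gc_bias)
    codons = rng.choice(4, size=(n_codons, 3), p=probs)
    seqs = ["".join("ACGT"[b] for b in row) for row in codons]
    for i in range(1, n_codons):
        while _codon.is_stop(seqs[i]):
            row = rng.choice(4, size=3, p=probs)
            seqs[i] = "".join("ACGT"[b] for b in row)
    seqs[0] = "ATG"
    return "".join(seqs)


def mutate_cds(cds: str, identity: float, rng: np.random.Generator) -> str:
    """A point-mutated copy at the given nucleotide identity; mutations
    never create an in-frame stop codon."""
    L = len(cds)
    n_mut = int(round(L * (1.0 - identity)))
    seq = list(cds)
    positions = list(rng.permutation(L))
    done = 0
    for pos in positions:
        if done >= n_mut:
            break
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for b in choices:
            codon_start = 3 * (pos // 3)
            trial = seq[codon_start:codon_start + 3]
            trial[pos % 3] = b
            if not _codon.is_stop("".join(trial)):
                seq[pos] = b
                done += 1
                break
    return "".join(seq)


def evolve_pair(cds: str, omega: float, target_ds: float, kappa: float,
                rng: np.random.Generator) -> tuple[str, str, dict]:
    """Evolve two descendants of ``cds`` under a proposal/acceptance
    substitution scheme.

    Single-nucleotide changes are proposed at uniform positions with a
    Kimura-style kernel (transition odds ``kappa`` against each of the two
    transversions); stop-creating proposals are rejected outright;
    nonsynonymous proposals are accepted with relative probability ω
    against synonymous ones. Each branch accumulates synonymous
    substitutions until its expected synonymous divergence reaches
    ``target_ds / 2``, so the pairwise divergence reaches ``target_ds``.
    Realized substitution counts are returned.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if target_ds < 0:
        raise ValueError("target_ds must be non-negative")
    # synonymous site count of the ancestor (NG86 convention)
    S = sum(sum(_codon.codon_site_fractions(cds[i:i + 3]))
            for i in range(0, len(cds), 3))
    target_syn_branch = 0.5 * target_ds * S
    p_acc_syn = min(1.0, 1.0 / omega) if omega > 1 else 1.0
    p_acc_non = min(1.0, omega)
    p_transition = kappa / (kappa + 2.0)
    counts = {"syn": 0, "nonsyn": 0}
    out: list[str] = []
    for _branch in range(2):
        seq = list(cds)
        syn = non = 0
        guard = 0
        max_props = int(200 * len(cds) * max(1.0, target_ds))
        while syn < target_syn_branch and guard < max_props:
            guard += 1
            pos = int(rng.integers(len(seq)))
            old = seq[pos]
            if rng.random() < p_transition:
                new = _codon.TRANSITIONS[old]
            else:
                tv = [b for b in "ACGT" if b != old
                      and _codon.TRANSITIONS[old] != b]
                new = tv[int(rng.integers(2))]
            cs = 3 * (pos // 3)
            old_codon = "".join(seq[cs:cs + 3])
            new_codon = old_codon[:pos % 3] + new + old_codon[pos % 3 + 1:]
            if _codon.is_stop(new_codon):
                continue
            synonymous = _codon.aa(new_codon) == _codon.aa(old_codon)
            p_acc = p_acc_syn if synonymous else p_acc_non
            if p_acc < 1.0 and rng.random() >= p_acc:
                continue
            seq[pos] = new
            if synonymous:
                syn += 1
            else:
                non += 1
        counts["syn"] += syn
        counts["nonsyn"] += non
        out.append("".join(seq))
    return out[0], out[1], counts


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionProfile:
    """Planted expression pattern for one gene.

    Final TPM per sample = ``overrides[sample]`` when present, else the
    gene's background draw scaled by ``default_scale``.
    """

    overrides: dict = field(default_factory=dict)
    default_scale: float = 1.0


def simulate_expression(gene_catalog: Sequence[str],
                        planted_profiles: Mapping[str, ExpressionProfile],
                        rng: np.random.Generator,
                        stages: Sequence[str] = SimConfig.stages,
                        vg_sample: str = "VG",
                        log_mean: float = np.log(5.0),
                        log_sd: float = 1.5) -> ExpressionMatrix:
    """Background log-normal TPM per gene × sample with planted patterns,
    columns renormalized to 10^6 (the TPM invariant)."""
    if not gene_catalog:
        raise ValueError("empty gene catalog")
    samples = list(stages) + [vg_sample]
    base = rng.lognormal(mean=log_mean, sigma=log_sd,
                         size=(len(gene_catalog), len(samples)))
    for i, g in enumerate(gene_catalog):
        prof = planted_profiles.get(g)
        if prof is None:
            continue
        for j, s in enumerate(samples):
            if s in prof.overrides:
                base[i, j] = prof.overrides[s]
            else:
                base[i, j] *= prof.default_scale
    base = base / base.sum(axis=0, keepdims=True) * 1e6
    df = pd.DataFrame(base, index=list(gene_catalog), columns=samples)
    meta = {s: "stage" for s in stages}
    meta[vg_sample] = "venom_gland"
    return ExpressionMatrix(df, meta, stage_order=list(stages))


# ---------------------------------------------------------------------------
# peptides

def simulate_peptides(proteins: Sequence[SequenceRecord],
                      planted_vp_ids: Sequence[str],
                      rng: np.random.Generator,
                      min_planted: int = 4,
                      max_planted: int = 7,
                      noise_prob: float = 0.15) -> list[str]:
    """Proteome peptide evidence.

    Each planted VP contributes ``min_planted``–``max_planted`` distinct
    exact substrings (8–25 aa) of its own protein, each verified to occur
    in no other protein; every other protein contributes 0–3 peptides.
    The emitted list is globally unique.
    """
    by_id = {p.id: p for p in proteins}
    missing = [v for v in planted_vp_ids if v not in by_id]
    if missing:
        raise ValueError(f"planted VP ids not among proteins: {missing}")
    bodies = {p.id: p.residues.upper() for p in proteins}
    peptides: list[str] = []
    seen: set[str] = set()

    def draw_from(pid: str, k: int) -> int:
        body = bodies[pid]
        if len(body) < 8:
            raise ValueError(f"protein {pid} shorter than minimal peptide")
        got = 0
        for _attempt in range(50 * k):
            if got >= k:
                break
            ln = int(rng.integers(8, min(26, len(body) + 1)))
            start = int(rng.integers(0, len(body) - ln + 1))
            pep = body[start:start + ln]
            if pep in seen:
                continue
            if any(pep in other for oid, other in bodies.items() if oid != pid):
                continue
            seen.add(pep)
            peptides.append(pep)
            got += 1
        return got

    for pid in planted_vp_ids:
        k = int(rng.integers(min_planted, max_planted + 1))
        got = draw_from(pid, k)
        if got < min_planted:
            raise RuntimeError(f"could not draw {min_planted} unique "
                               f"peptides for planted VP {pid}")
    vp_set = set(planted_vp_ids)
    for p in proteins:
        if p.id in vp_set or len(p.residues) < 8:
            continue
        if rng.random() < noise_prob:
            draw_from(p.id, int(rng.integers(1, 4)))
    return peptides


# ---------------------------------------------------------------------------
# genome

def simulate_genome(seed_cds: str, config: SimConfig,
                    rng: np.random.Generator
                    ) -> tuple[SequenceRecord, list[dict], list[list[int]]]:
    """An AT-rich genome with low-GC islands and planted family loci.

    Planted loci are stop-free point-mutated copies of ``seed_cds`` at
    identities from the configured range; roughly one third land on the
    reverse strand. One *intermediate* locus carries the seed homolog plus
    a novel extension ORF, and one *transitive* locus is a diverged copy
    of that extension alone — verified at generation time to be invisible
    (alignment score < score_min) to the seed and to every other planted
    locus, while visible to the intermediate. Returns the genome record,
    the planted locus table and the island coordinates.
    """
    L = config.genome_length
    seed_pep = _codon.translate(seed_cds)
    total_material = config.n_planted_loci * (len(seed_cds)
                                              + 3 * config.extension_codons)
    if L < 10 * total_material:
        raise ValueError("genome too short for the planted material")

    genome = np.frombuffer(random_nt(L, config.background_gc, rng).encode(),
                           dtype=np.uint8).copy()

    # low-GC islands on an island_size grid
    n_islands = max(1, int(round(L * config.island_fraction
                                 / config.island_size)))
    n_blocks = L // config.island_size
    block_ids = rng.choice(n_blocks, size=n_islands, replace=False)
    islands: list[list[int]] = []
    for b in sorted(int(x) for x in block_ids):
        s, e = b * config.island_size, (b + 1) * config.island_size
        patch = random_nt(e - s, config.island_gc, rng)
        genome[s:e] = np.frombuffer(patch.encode(), dtype=np.uint8)
        islands.append([s, e])

    # build planted locus sequences
    lo, hi = config.locus_identity_range
    extension = simulate_cds(config.extension_codons, config.background_gc, rng)
    inter_id = float(rng.uniform(0.82, 0.9))
    intermediate = mutate_cds(seed_cds, inter_id, rng) + extension
    ext_pep = _codon.translate(extension)

    transitive = None
    for _attempt in range(40):
        cand = mutate_cds(extension, float(rng.uniform(0.82, 0.9)), rng)
        cand_pep = _codon.translate(cand)
        to_seed = local_align(cand_pep, seed_pep)
        to_parent = local_align(cand_pep, ext_pep)
        seed_score = to_seed.score if to_seed else 0.0
        parent_score = to_parent.score if to_parent else 0.0
        if seed_score < 0.8 * config.score_min and \
                parent_score >= 1.5 * config.score_min:
            transitive = cand
            break
    if transitive is None:
        raise RuntimeError("could not construct a transitive locus "
                           "honoring the score threshold")

    planted: list[tuple[str, str, float, bool, str]] = []
    planted.append((intermediate, "seed", inter_id, False, "intermediate"))
    planted.append((transitive, "intermediate_extension",
                    1.0 - _mismatch_frac(transitive, extension), True,
                    "transitive"))
    for i in range(config.n_planted_loci - 2):
        ident = float(rng.uniform(lo, hi))
        planted.append((mutate_cds(seed_cds, ident, rng), "seed", ident,
                        False, f"copy{i:02d}"))

    # placement: non-overlapping, clear of islands and of each other
    occupied = [tuple(iv) for iv in islands]
    margin = 2500  # > max_join_gap so neighboring loci never merge
    loci: list[dict] = []
    for seq, source, ident, transitive_flag, tag in planted:
        strand = "-" if rng.random() < 0.33 else "+"
        placed = False
        for _try in range(1000):
            start = int(rng.integers(0, L - len(seq)))
            end = start + len(seq)
            if any(s - margin < end and start < e + margin
                   for s, e in occupied):
                continue
            insert = seq if strand == "+" else _revcomp(seq)
            genome[start:end] = np.frombuffer(insert.encode(), dtype=np.uint8)
            occupied.append((start, end))
            loci.append({"tag": tag, "start": start, "end": end,
                         "strand": strand, "identity": round(ident, 4),
                         "source": source, "transitive": transitive_flag})
            placed = True
            break
        if not placed:
            raise RuntimeError("overlap exhaustion while placing loci")
    loci.sort(key=lambda d: d["start"])
    rec = SequenceRecord(id="chr1", residues=bytes(genome).decode(),
                         alphabet="nt", description="synthetic genome")
    return rec, loci, islands


_RC = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.upper().encode().translate(_RC)[::-1].decode()


def _mismatch_frac(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


# ---------------------------------------------------------------------------
# gene trees

_MET_NAMES = ["Apis", "Nasonia", "Drosophila", "Tribolium", "Bombyx",
              "Polistes", "Fopius"]
_MIC_NAMES = ["Serratia", "Pseudomonas", "Wolbachia", "Bacillus",
              "Enterobacter", "Rickettsia", "Burkholderia", "Spiroplasma"]
_OUT_NAMES = ["Ecoli", "Synechococcus"]


def _clade(labels: list[str], rng: np.random.Generator) -> str:
    """Random nested bifurcating newick for the given leaf labels."""
    items = list(labels)
    while len(items) > 1:
        i = int(rng.integers(len(items) - 1))
        a = items.pop(i)
        b = items.pop(i)
        bl1, bl2 = rng.uniform(0.05, 0.5, size=2)
        items.insert(i, f"({a}:{bl1:.3f},{b}:{bl2:.3f})")
    return items[0]


def simulate_gene_tree(is_lgt: bool,
                       rng: np.random.Generator,
                       focal_tips: Sequence[str] = ("f1", "f2"),
                       backbone: Mapping[str, Sequence[str]] | None = None,
                       ) -> TaxLabeledTree:
    """A rooted taxonomy-labeled gene tree.

    Vertical topology: focal tips sister to the metazoan clade, microbial
    tips outside, rooted on the outgroup. LGT topology: the focal clade
    attaches inside the microbial clade, so its sister group is entirely
    microbial and focal + metazoan tips are not monophyletic.
    """
    bb = backbone or {"metazoan": _MET_NAMES, "microbial": _MIC_NAMES,
                      "outgroup": _OUT_NAMES}
    n_met = int(rng.integers(3, min(6, len(bb["metazoan"]) + 1)))
    n_mic = int(rng.integers(4, min(7, len(bb["microbial"]) + 1)))
    met = [f"{n}|metazoan" for n in rng.choice(bb["metazoan"], size=n_met,
                                               replace=False)]
    mic = [f"{n}|microbial" for n in rng.choice(bb["microbial"], size=n_mic,
                                                replace=False)]
    out = f"{bb['outgroup'][int(rng.integers(len(bb['outgroup'])))]}|outgroup"
    focal = [f"{t}|focal" for t in focal_tips]
    bl = lambda: f"{rng.uniform(0.05, 0.5):.3f}"
    focal_clade = _clade(focal, rng)
    met_clade = _clade(met, rng)
    if is_lgt:
        n_sister = int(rng.integers(1, 3))
        sister = _clade(mic[:n_sister], rng)
        rest = _clade(mic[n_sister:], rng)
        inner = (f"(({focal_clade}:{bl()},{sister}:{bl()}):{bl()},"
                 f"{rest}:{bl()})")
        core = f"({met_clade}:{bl()},{inner}:{bl()})"
    else:
        mic_clade = _clade(mic, rng)
        core = (f"(({focal_clade}:{bl()},{met_clade}:{bl()}):{bl()},"
                f"{mic_clade}:{bl()})")
    newick = f"({core}:{bl()},{out}:{bl()});"
    return read_newick_labeled(newick)


# ---------------------------------------------------------------------------
# orchestration

def generate_dataset(config: SimConfig, outdir: str | Path) -> PlantedTruth:
    """Write the full synthetic dataset and its truth record to ``outdir``.

    Exactly one gene (the Lar-like candidate) satisfies every candidate
    filter: species-specific, venom-specialized, VP-supported, top venom
    expression, an LGT-positive gene tree, and a rapidly evolving paralog
    pair. One member of the planted species-B family (the Warm-like
    candidate) carries VP evidence and a venom-shifted expression peak
    against its family's larval mode.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    seed = config.seed
    truth = PlantedTruth(seed=seed, background_gc=config.background_gc,
                         island_gc=config.island_gc)

    # --- ortholog pairs ----------------------------------------------------
    rng = _stream(seed, "orthologs")
    cds_records: list[SequenceRecord] = []
    pair_ids: list[str] = []
    for omega, target_ds, n in config.omega_grid:
        for _ in range(n):
            i = len(pair_ids)
            pid = f"og{i:04d}"
            n_codons = int(rng.integers(*config.codon_range))
            anc = simulate_cds(n_codons, config.background_gc, rng)
            a, b, counts = evolve_pair(anc, omega, target_ds, config.kappa, rng)
            cds_records.append(SequenceRecord(f"{pid}_A", a, "nt"))
            cds_records.append(SequenceRecord(f"{pid}_B", b, "nt"))
            truth.ortholog_pairs[pid] = {
                "omega": omega, "target_ds": target_ds,
                "syn": counts["syn"], "nonsyn": counts["nonsyn"],
                "pathway": None,
                "saturated_planted": target_ds > 2.0,
            }
            pair_ids.append(pid)

    # --- pathway map -------------------------------------------------------
    by_omega: dict[float, list[str]] = {}
    for pid in pair_ids:
        by_omega.setdefault(truth.ortholog_pairs[pid]["omega"], []).append(pid)
    unsat = lambda pids: [p for p in pids
                          if not truth.ortholog_pairs[p]["saturated_planted"]]
    pathway_rows: list[tuple[str, str]] = []

    def assign(pids: list[str], pw: str) -> None:
        for p in pids:
            truth.ortholog_pairs[p]["pathway"] = pw
            pathway_rows.append((p, pw))

    elev = unsat(by_omega.get(0.5, []))
    assign(elev, "pw_elev00")
    truth.elevated_pathways = ["pw_elev00"]
    cons = unsat(by_omega.get(0.01, []))
    for k in range(3):
        assign(cons[k * 15:(k + 1) * 15], f"pw_cons{k:02d}")
    truth.conserved_pathways = [f"pw_cons{k:02d}" for k in range(3)]
    background = unsat(by_omega.get(0.15, []))
    for k in range(20):
        assign(background[k * 13:(k + 1) * 13], f"pw_bg{k:02d}")
    pd.DataFrame(sorted(pathway_rows), columns=["gene_id", "pathway"]).to_csv(
        outdir / "pathway_map.tsv", sep="\t", index=False)

    # --- species-specific genes -------------------------------------------
    rng = _stream(seed, "specific")
    lar_id, larp_id = "spA0000", "spA0001"
    lar_anc = simulate_cds(config.lar_codons, config.background_gc, rng)
    lar_cds, larp_cds, lar_counts = evolve_pair(lar_anc, 0.9, 0.3,
                                                config.kappa, rng)
    truth.lar_pair = {"genes": [lar_id, larp_id], "omega": 0.9,
                      "target_ds": 0.3, **lar_counts}
    spA = {lar_id: lar_cds, larp_id: larp_cds}
    for i in range(2, config.n_specific_a):
        spA[f"spA{i:04d}"] = simulate_cds(int(rng.integers(100, 350)),
                                          config.background_gc, rng)
    warm_anc = simulate_cds(250, config.background_gc, rng)
    spB: dict[str, str] = {}
    for i in range(config.warm_family_size):
        spB[f"spB{i:04d}"] = mutate_cds(warm_anc, 0.9, rng)
    for i in range(config.warm_family_size, config.n_specific_b):
        spB[f"spB{i:04d}"] = simulate_cds(int(rng.integers(100, 350)),
                                          config.background_gc, rng)
    warm_id = "spB0000"
    truth.specific_a = sorted(spA)
    truth.specific_b = sorted(spB)
    truth.lar_like_id = lar_id
    truth.warm_like_id = warm_id
    truth.warm_family = [f"spB{i:04d}" for i in range(config.warm_family_size)]

    for gid in truth.specific_a:
        cds_records.append(SequenceRecord(gid, spA[gid], "nt"))
    for gid in truth.specific_b:
        cds_records.append(SequenceRecord(gid, spB[gid], "nt"))
    write_fasta(outdir / "cds.fasta", cds_records)
    proteins = [SequenceRecord(r.id, _codon.translate(r.residues), "aa")
                for r in cds_records]
    write_fasta(outdir / "proteins.fasta", proteins)

    # --- ortholog table ----------------------------------------------------
    table = OrthologTable(species_a="A", species_b="B",
                          pairs={f"{p}_A": f"{p}_B" for p in pair_ids})
    write_ortholog_table(outdir / "ortholog_table.tsv", table)

    # --- expression --------------------------------------------------------
    genes_a = [f"{p}_A" for p in pair_ids] + truth.specific_a
    genes_b = [f"{p}_B" for p in pair_ids] + truth.specific_b

    vp_vg = [30000.0, 9000.0, 8000.0, 7000.0, 6000.0, 5500.0,
             4500.0, 4000.0, 3500.0, 3000.0]
    vps_a = [lar_id, "og0000_A", "og0001_A", "spA0002", "spA0003",
             larp_id, "og0002_A", "og0003_A", "spA0004", "spA0005"]
    vps_a = vps_a[:config.n_planted_vp]
    specialized_a = [lar_id, larp_id, "spA0002", "spA0003"]
    profiles_a: dict[str, ExpressionProfile] = {}
    for gid, vg in zip(vps_a, vp_vg):
        if gid in specialized_a:
            profiles_a[gid] = ExpressionProfile(
                overrides={config.vg_sample: vg}, default_scale=0.01)
        else:
            profiles_a[gid] = ExpressionProfile(
                overrides={config.vg_sample: vg}, default_scale=1.0)
    # non-VP specialized decoys: specific + specialized but no peptides
    for gid, vg in (("spA0006", 2000.0), ("spA0007", 1500.0),
                    ("spA0008", 1200.0)):
        profiles_a[gid] = ExpressionProfile(
            overrides={config.vg_sample: vg}, default_scale=0.01)
        specialized_a.append(gid)
    concurrent = [f"spA{i:04d}" for i in range(10, 10 + config.n_concurrent_p3af)]
    rng = _stream(seed, "expression_A")
    for gid in concurrent:
        p3 = float(rng.uniform(200.0, 600.0))
        profiles_a[gid] = ExpressionProfile(
            overrides={"P3": p3, "AF": p3 * float(rng.uniform(0.6, 1.4))},
            default_scale=0.005)
    matrix_a = simulate_expression(genes_a, profiles_a, rng,
                                   stages=config.stages,
                                   vg_sample=config.vg_sample,
                                   log_mean=config.tpm_log_mean,
                                   log_sd=config.tpm_log_sd)
    write_expression_table(outdir / "expression_A.tsv", matrix_a)
    truth.vp_ids_a = sorted(vps_a)
    truth.venom_specialized_a = sorted(specialized_a)
    truth.concurrent_p3af = concurrent

    rng = _stream(seed, "expression_B")
    profiles_b: dict[str, ExpressionProfile] = {}
    for i, gid in enumerate(truth.warm_family):
        if gid == warm_id:
            profiles_b[gid] = ExpressionProfile(
                overrides={config.vg_sample: 5000.0, "L1": 400.0},
                default_scale=0.05)
        else:
            profiles_b[gid] = ExpressionProfile(
                overrides={"L1": float(rng.uniform(800.0, 1200.0))},
                default_scale=0.05)
    vps_b = [warm_id, "og0004_B", "og0005_B"]
    for gid, vg in zip(vps_b[1:], (6000.0, 4000.0)):
        profiles_b[gid] = ExpressionProfile(
            overrides={config.vg_sample: vg}, default_scale=1.0)
    matrix_b = simulate_expression(genes_b, profiles_b, rng,
                                   stages=config.stages,
                                   vg_sample=config.vg_sample,
                                   log_mean=config.tpm_log_mean,
                                   log_sd=config.tpm_log_sd)
    write_expression_table(outdir / "expression_B.tsv", matrix_b)
    truth.vp_ids_b = sorted(vps_b)

    # --- peptides ----------------------------------------------------------
    prot_a = [p for p in proteins if p.id in set(genes_a)]
    prot_b = [p for p in proteins if p.id in set(genes_b)]
    peps_a = simulate_peptides(prot_a, sorted(vps_a), _stream(seed, "peptides_A"))
    peps_b = simulate_peptides(prot_b, sorted(vps_b), _stream(seed, "peptides_B"))
    (outdir / "peptides_A.txt").write_text("\n".join(peps_a) + "\n")
    (outdir / "peptides_B.txt").write_text("\n".join(peps_b) + "\n")

    # --- genome with planted loci -------------------------------------------
    rng = _stream(seed, "genome")
    genome, loci, islands = simulate_genome(lar_cds, config, rng)
    write_fasta(outdir / "genome.fasta", [genome])
    truth.loci = loci
    truth.islands = islands
    write_fasta(outdir / "seeds.fasta",
                [SequenceRecord("seed_lar", _codon.translate(lar_cds), "aa")])

    # conserved-block alignment across seed-derived planted locus peptides
    block_cols = slice(60, 90)  # codons; gap-free by construction
    block: list[SequenceRecord] = [
        SequenceRecord("seed_lar", _codon.translate(lar_cds)[block_cols], "aa")]
    for loc in loci:
        if loc["source"] != "seed":
            continue
        s, e = loc["start"], loc["end"]
        sub = genome.residues[s:e]
        if loc["strand"] == "-":
            sub = _revcomp(sub)
        block.append(SequenceRecord(
            f"block_{loc['tag']}", _codon.translate(sub)[block_cols], "aa"))
    write_fasta(outdir / "aligned_block.fasta", block)

    # --- gene trees --------------------------------------------------------
    rng = _stream(seed, "trees")
    lgt_ids = [lar_id, larp_id] + [f"lgt_{i:03d}"
                                   for i in range(config.n_lgt_trees - 2)]
    lgt_ids = lgt_ids[:config.n_lgt_trees]
    vert_ids = [f"og{i:04d}_A" for i in range(config.n_vertical_trees)]
    for tid in lgt_ids:
        tree = simulate_gene_tree(True, rng, focal_tips=(f"{tid}_c1",
                                                         f"{tid}_c2"))
        write_newick_labeled(outdir / "trees" / f"{tid}.nwk", tree)
    for tid in vert_ids:
        tree = simulate_gene_tree(False, rng, focal_tips=(f"{tid}_c1",
                                                          f"{tid}_c2"))
        write_newick_labeled(outdir / "trees" / f"{tid}.nwk", tree)
    truth.lgt_tree_ids = lgt_ids
    truth.vertical_tree_ids = vert_ids

    # --- gene orders (macro-synteny substrate) ------------------------------
    rng = _stream(seed, "orders")
    orders: dict[str, dict[str, list[tuple[str, str]]]] = {"A": {}, "B": {}}
    strand = lambda: "+" if rng.random() < 0.5 else "-"

    def interleave(ogs: list[str], fillers: list[str]) -> list[tuple[str, str]]:
        out = []
        fi = iter(fillers)
        for k, g in enumerate(ogs):
            out.append((g, strand()))
            if k % 5 == 4:  # a single non-ortholog gene every 5 orthologs
                f = next(fi, None)
                if f:
                    out.append((f, strand()))
        return out

    a_specific_rest = [g for g in truth.specific_a]
    orders["A"]["scA1"] = interleave([f"og{i:04d}_A" for i in range(100)],
                                     a_specific_rest[:20])
    orders["A"]["scA2"] = interleave([f"og{i:04d}_A" for i in range(100, 200)],
                                     a_specific_rest[20:40])
    orders["A"]["scA3"] = interleave(
        [f"og{i:04d}_A" for i in range(200, config.n_ortholog_pairs)],
        a_specific_rest[40:])
    used = {g for sc in orders["A"].values() for g, _ in sc}
    orders["A"]["scA4"] = [(g, strand()) for g in truth.specific_a
                           if g not in used]

    orders["B"]["scB1"] = [(f"og{i:04d}_B", strand()) for i in range(100)]
    orders["B"]["scB2"] = [(f"og{i:04d}_B", strand())
                           for i in range(149, 99, -1)]   # inversion
    shuffled = [f"og{i:04d}_B" for i in range(150, 200)]
    rng.shuffle(shuffled)
    orders["B"]["scB3"] = [(g, strand()) for g in shuffled]
    orders["B"]["scB4"] = [(f"og{i:04d}_B", strand())
                           for i in range(200, config.n_ortholog_pairs)]
    orders["B"]["scB5"] = [(g, strand()) for g in truth.specific_b]
    gmap = GeneOrderMap(orders)
    write_gene_order(outdir / "gene_order.tsv", gmap)

    # --- domain counts and families -----------------------------------------
    rng = _stream(seed, "domains")
    species_cols = ["A", "B", *config.other_species]
    counts = rng.poisson(5.0, size=(config.n_background_domains,
                                    len(species_cols)))
    dom_ids = [f"dom{i:02d}" for i in range(config.n_background_domains)]
    df = pd.DataFrame(counts, index=dom_ids, columns=species_cols)
    truth.warm_domain = "dom_mucinbd"
    df.loc["dom_mucinbd"] = 0
    df.at["dom_mucinbd", "B"] = config.warm_family_size
    write_domain_counts(outdir / "domain_counts.tsv",
                        DomainCountTable(df))

    fam_rows = [
        ("fam_lar", "A", "", ",".join([lar_id, larp_id])),
        ("fam_warm", "B", "dom_mucinbd", ",".join(truth.warm_family)),
        ("fam_bgA", "A", "dom07", "spA0020,spA0021"),
        ("fam_bgB", "B", "dom05", "spB0020,spB0021,spB0022"),
    ]
    pd.DataFrame(fam_rows, columns=["family_id", "species", "domain_id",
                                    "genes"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False)

    truth.to_json(outdir / "truth.json")
    return truth
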