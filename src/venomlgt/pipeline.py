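"""End-to-end candidate discovery over a dataset directory.

Runs expression classification, venom-protein calling, pairwise dN/dS and
the pathway scan, gene-tree LGT classification, genome signatures, the
optional iterative homolog search, and finally the Lar-like candidate
ranking and Warm-like family flags — emitting one evidence-bearing JSON
report plus TSV side tables. Filters form a cascade with per-filter
evidence retained even for excluded genes, so every verdict can be audited
against the stage that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression_class as ec
from . import genome_signatures as gs
from . import lgt_phylo as lp
from . import molevol as me
from . import venomics as vn
from .formats_io import (
    AnalysisConfig,
    read_domain_counts,
    read_expression_table,
    read_fasta,
    read_gene_order,
    read_newick_labeled,
    read_ortholog_table,
)
from .homology_search import SearchParams, iterative_search

logger = logging.getLogger(__name__)

__all__ = ["CandidateReport", "StageError", "run_discovery", "write_report"]

STAGES = ("load", "expression", "venomics", "molevol", "homology_search",
          "lgt", "signatures", "integrate")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CandidateReport:
    """Evidence-bearing result of a discovery run."""

    config_hash: str
    seed: int
    thresholds: dict
    lar_candidates: list          # ordered candidate evidence dicts
    warm_flags: list              # flagged family members with evidence
    evidence: dict                # per-gene flags and statistics (species A)
    tables: dict = field(default_factory=dict)  # side DataFrames

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "thresholds": self.thresholds,
            "lar_candidates": self.lar_candidates,
            "warm_flags": self.warm_flags,
            "evidence": self.evidence,
            "summaries": {k: v for k, v in self.tables.items()
                          if not isinstance(v, pd.DataFrame)},
        }


def config_hash(config: AnalysisConfig) -> str:
    keys = {k: getattr(config, k) for k in sorted(vars(config))
            if k != "defaulted_keys"}
    blob = yaml.safe_dump(keys, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _species_venomics(matrix, peptide_path: Path, proteins, config):
    calls = ec.classify_high(matrix, alpha_stage=config.alpha_high_stage,
                             alpha_vg=config.alpha_high_vg,
                             mode=config.n99_mode)
    spec = ec.specialization_index(matrix, matrix.vg_sample,
                                   mode=config.spec_index_mode)
    peptides = [ln.strip() for ln in peptide_path.read_text().splitlines()
                if ln.strip()]
    gene_set = set(matrix.gene_ids)
    prot = [p for p in proteins if p.id in gene_set]
    matches = vn.match_peptides(peptides, prot,
                                il_equivalence=config.il_equivalence)
    vg_expressed = calls.expressed[matrix.vg_sample]
    vg_tpm = matrix.values[matrix.vg_sample].to_dict()
    vcalls = vn.call_venom_proteins(matches, vg_expressed, matrix.gene_ids,
                                    vg_tpm, min_peptides=config.min_peptides)
    return calls, spec, matches, vcalls, vg_expressed


def _family_omegas(families: pd.DataFrame, cds_by_id, config,
                   reference: list[float]) -> dict[str, float]:
    """Max paralog-pair ω percentile per family member (equal-length
    members only; others are skipped with a warning)."""
    out: dict[str, float] = {}
    for _, row in families.iterrows():
        genes = [g for g in str(row["genes"]).split(",") if g]
        best: dict[str, float] = {}
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = cds_by_id.get(genes[i]), cds_by_id.get(genes[j])
                if a is None or b is None or len(a) != len(b):
                    continue
                try:
                    est = me.ng86(me.CodonPairAlignment(
                        a, b, f"{genes[i]}|{genes[j]}"), ds_max=config.ds_max)
                except ValueError:
                    continue
                if math.isnan(est.omega) or est.saturated:
                    continue
                for g in (genes[i], genes[j]):
                    best[g] = max(best.get(g, -math.inf), est.omega)
        for g, om in best.items():
            out[g] = me.percentile_rank(om, reference)
    return out


def run_discovery(config: AnalysisConfig,
                  dataset_dir: str | Path) -> CandidateReport:
    """Execute the full discovery chain on one dataset directory."""
    d = Path(dataset_dir)
    stage = "load"
    try:
        matrix_a = read_expression_table(d / "expression_A.tsv")
        matrix_b = read_expression_table(d / "expression_B.tsv")
        proteins = read_fasta(d / "proteins.fasta", alphabet="aa")
        cds = read_fasta(d / "cds.fasta", alphabet="nt")
        ortho = read_ortholog_table(d / "ortholog_table.tsv")
        gmap = read_gene_order(d / "gene_order.tsv")
        domains = read_domain_counts(d / "domain_counts.tsv")
        pathway_map_df = pd.read_csv(d / "pathway_map.tsv", sep="\t")
        families = pd.read_csv(d / "families.tsv", sep="\t").fillna("")
        tree_files = sorted((d / "trees").glob("*.nwk"))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    cds_by_id = {r.id: r.residues for r in cds}
    tables: dict = {}

    stage = "expression"
    try:
        (calls_a, spec_a, matches_a, vcalls_a,
         vg_expr_a) = _species_venomics(matrix_a, d / "peptides_A.txt",
                                        proteins, config)
        (calls_b, spec_b, matches_b, vcalls_b,
         vg_expr_b) = _species_venomics(matrix_b, d / "peptides_B.txt",
                                        proteins, config)
        specific_a = sorted(g for g in matrix_a.gene_ids
                            if ortho.is_specific(g))
        specific_b = sorted(g for g in matrix_b.gene_ids
                            if ortho.is_specific(g))
        enrich_a = ec.specific_gene_enrichment(calls_a, specific_a,
                                               matrix_a.gene_ids)
        tables["enrichment_A"] = enrich_a.table
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "venomics"
    try:
        scatter_a = vn.venom_scatter(matrix_a, vcalls_a, spec_a.index,
                                     vg_expr_a, specific_a)
        scatter_b = vn.venom_scatter(matrix_b, vcalls_b, spec_b.index,
                                     vg_expr_b, specific_b)
        tables["scatter_A"] = scatter_a
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "molevol"
    try:
        estimates = []
        for ga, gb in sorted(ortho.pairs.items()):
            pair_id = ga[:-2] if ga.endswith("_A") else ga
            estimates.append(me.ng86(me.CodonPairAlignment(
                cds_by_id[ga], cds_by_id[gb], pair_id), ds_max=config.ds_max))
        retained = me.filter_saturated(estimates, ds_max=config.ds_max)
        reference = [e.omega for e in retained
                     if not (math.isnan(e.omega) or math.isinf(e.omega))]
        pmap: dict[str, list[str]] = {}
        for _, row in pathway_map_df.iterrows():
            pmap.setdefault(str(row["pathway"]), []).append(str(row["gene_id"]))
        scan = me.pathway_scan(retained, pmap,
                               min_genes=config.pathway_min_genes,
                               alpha=config.pathway_alpha,
                               conserved_eps=config.conserved_eps)
        omega_pct = _family_omegas(families, cds_by_id, config, reference)
        blocks = me.call_macro_synteny(gmap, ortho,
                                       min_block=config.min_block,
                                       max_gap=config.max_gap)
        tables["rates"] = pd.DataFrame(
            [vars(e) for e in estimates]).set_index("pair_id")
        tables["pathway_scan"] = scan.table
        tables["n_synteny_blocks"] = len(blocks)
        tables["n_genes_in_blocks"] = int(sum(b.n_genes for b in blocks))
        tables["n_saturated_removed"] = len(estimates) - len(retained)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "homology_search"
    search_state = None
    if config.run_homology_search and (d / "genome.fasta").exists() \
            and (d / "seeds.fasta").exists():
        try:
            genome = read_fasta(d / "genome.fasta", alphabet="nt")[0]
            seeds = read_fasta(d / "seeds.fasta", alphabet="aa")
            params = SearchParams(score_min=config.score_min,
                                  gap_open=config.gap_open,
                                  gap_extend=config.gap_extend,
                                  max_join_gap=config.max_join_gap,
                                  locus_min_len=config.locus_min_len,
                                  locus_max_len=config.locus_max_len,
                                  max_iter=config.max_iter)
            search_state = iterative_search(seeds, genome, params)
            tables["n_loci"] = len(search_state.loci)
            tables["search_iterations"] = search_state.n_iterations
            tables["search_converged"] = search_state.converged
            tables["loci"] = pd.DataFrame(
                [{"locus_id": l.locus_id, "start": l.start, "end": l.end,
                  "strand": l.strand, "score": l.score,
                  "iteration": l.discovery_iteration,
                  "identity": l.identity, "best_query": l.best_query}
                 for l in search_state.loci]).set_index("locus_id") \
                if search_state.loci else pd.DataFrame()
        except Exception as exc:
            raise StageError(stage, exc) from exc
    else:
        logger.warning("homology search skipped (disabled or no genome/seeds)")

    stage = "lgt"
    try:
        verdicts: dict[str, str] = {}
        verdict_rows = []
        for tf in tree_files:
            tree = read_newick_labeled(tf)
            v = lp.classify_lgt(tree, tree_id=tf.stem,
                                min_microbial_sister=config.min_microbial_sister)
            verdicts[tf.stem] = v.verdict
            verdict_rows.append({"tree_id": tf.stem, "verdict": v.verdict,
                                 "metazoan_monophyly": v.metazoan_monophyly,
                                 "n_metazoan_clades": v.n_metazoan_clades})
        tables["lgt_verdicts"] = (pd.DataFrame(verdict_rows)
                                  .set_index("tree_id")
                                  if verdict_rows else pd.DataFrame())
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "signatures"
    try:
        gc_modes = []
        if (d / "genome.fasta").exists():
            genome = read_fasta(d / "genome.fasta", alphabet="nt")[0]
            track = gs.gc_windows(genome, window=config.gc_window,
                                  step=config.gc_step)
            gc_modes = gs.gc_mode_summary(track,
                                          bandwidth=config.kde_bandwidth,
                                          min_separation=config.min_separation)
            tables["gc_modes"] = [
                {"location": m.location, "mass": m.mass} for m in gc_modes]
        expansion = {sp: gs.expansion_index(domains, sp)
                     for sp in ("A", "B") if sp in domains.counts.columns}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "integrate"
    try:
        candidates = vn.rank_lar_like(scatter_a,
                                      omega_percentiles=omega_pct,
                                      lgt_verdicts=verdicts,
                                      s_min=config.s_min, p_min=config.p_min)
        warm_flags = _warm_like_flags(families, ortho, expansion,
                                      {"A": (matrix_a, vcalls_a),
                                       "B": (matrix_b, vcalls_b)},
                                      config)
        evidence = {str(g): {k: (bool(v) if isinstance(v, (bool,)) else v)
                             for k, v in row.items()}
                    for g, row in scatter_a.iterrows()}
        for g in evidence:
            evidence[g]["pair_omega_percentile"] = omega_pct.get(g)
            evidence[g]["lgt_verdict"] = verdicts.get(g)
            for k, v in list(evidence[g].items()):
                if hasattr(v, "item"):
                    evidence[g][k] = v.item()
    except Exception as exc:
        raise StageError(stage, exc) from exc

    thresholds = {k: getattr(config, k) for k in
                  ("s_min", "p_min", "min_peptides", "ds_max",
                   "pathway_alpha", "score_min", "min_microbial_sister",
                   "family_min", "alpha_high_stage", "alpha_high_vg")}
    return CandidateReport(
        config_hash=config_hash(config),
        seed=config.seed,
        thresholds=thresholds,
        lar_candidates=[c.as_dict() for c in candidates],
        warm_flags=warm_flags,
        evidence=evidence,
        tables=tables,
    )


def _warm_like_flags(families: pd.DataFrame, ortho, expansion,
                     per_species, config) -> list[dict]:
    """Members of species-specific multi-copy families with a focal-
    exclusive domain, VP evidence, and a venom-shifted expression peak."""
    flags: list[dict] = []
    for _, row in families.iterrows():
        sp = str(row["species"])
        genes = [g for g in str(row["genes"]).split(",") if g]
        dom = str(row["domain_id"])
        if sp not in per_species or len(genes) < config.family_min:
            continue
        if not all(ortho.is_specific(g) for g in genes):
            continue
        if sp not in expansion or dom not in expansion[sp].table.index:
            continue
        if expansion[sp].table.at[dom, "expansion_index"] != "exclusive":
            continue
        matrix, vcalls = per_species[sp]
        present = [g for g in genes if g in matrix.values.index]
        if not present:
            continue
        tops = {g: str(matrix.values.loc[g].idxmax()) for g in present}
        modal = Counter(tops.values()).most_common(1)[0][0]
        for g in present:
            call = vcalls.get(g)
            if call is not None and call.is_vp and tops[g] != modal:
                flags.append({"family_id": str(row["family_id"]),
                              "gene_id": g, "species": sp,
                              "top_sample": tops[g],
                              "family_modal_sample": modal,
                              "domain_id": dom,
                              "n_peptides": call.n_peptides})
    flags.sort(key=lambda f: (f["family_id"], f["gene_id"]))
    return flags


def write_report(report: CandidateReport, outdir: str | Path) -> Path:
    """Write report.json (stable key order) plus TSV side tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True,
                  default=_json_default)
        fh.write("\n")
    for name, obj in report.tables.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.tsv", sep="\t")
    return path


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return str(obj)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
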