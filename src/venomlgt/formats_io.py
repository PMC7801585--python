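"""Readers and writers for the formats every pipeline stage touches.

Conventions used throughout the package:

* genomic coordinates are 0-based, half-open, with the strand recorded
  explicitly (BED convention);
* expression sample categories (developmental stage vs. venom gland) live in
  a YAML sidecar next to the TSV matrix, never encoded in sample names;
* gene-tree tips are labelled ``name|category`` with ``|`` reserved as the
  separator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "ParseError",
    "SequenceRecord",
    "ExpressionMatrix",
    "OrthologTable",
    "GeneOrderMap",
    "DomainCountTable",
    "TaxLabeledTree",
    "AnalysisConfig",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
    "write_expression_table",
    "read_newick_labeled",
    "write_newick_labeled",
    "load_config",
    "write_config",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_gene_order",
    "write_gene_order",
    "read_domain_counts",
    "write_domain_counts",
]


class ParseError(ValueError):
    """A named error for malformed input files."""


# IUPAC nucleotide ambiguity codes are legal; amino acids may carry X
# (unknown) and * (stop, produced by six-frame translation).
NT_ALPHABET = frozenset("ACGTURYSWKMBDHVN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

TIP_CATEGORIES = frozenset({"focal", "metazoan", "microbial", "outgroup"})


@dataclass(frozen=True)
class SequenceRecord:
    """A single FASTA record with a declared alphabet (``nt`` or ``aa``)."""

    id: str
    residues: str
    alphabet: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise ParseError(f"record {self.id!r}: empty sequence")
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ParseError(
                f"record {self.id!r}: residues {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    The id is the header token before the first whitespace; residues are
    upper-cased. Duplicate ids and residues outside the declared alphabet
    raise :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                alphabet=alphabet,
                description=desc,
            )
        )
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord]) -> None:
    """Write records wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


@dataclass
class ExpressionMatrix:
    """TPM values for genes (rows) across samples (columns).

    ``sample_meta`` maps each sample id to ``"stage"`` or ``"venom_gland"``;
    at most one sample carries the venom-gland category. ``stage_order``
    fixes the developmental ordering of stage samples.
    """

    values: pd.DataFrame
    sample_meta: dict[str, str]
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate gene id {dup!r}")
        if (self.values.values < 0).any():
            raise ParseError("negative TPM value")
        unknown = set(self.values.columns) - set(self.sample_meta)
        if unknown:
            raise ParseError(f"samples without metadata: {sorted(unknown)}")
        bad = {s: c for s, c in self.sample_meta.items()
               if c not in ("stage", "venom_gland")}
        if bad:
            raise ParseError(f"unknown sample categories: {bad}")
        vg = self.venom_gland_samples()
        if len(vg) > 1:
            raise ParseError(f"more than one venom-gland sample: {vg}")
        if not self.stage_order:
            self.stage_order = [s for s in self.values.columns
                                if self.sample_meta.get(s) == "stage"]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def venom_gland_samples(self) -> list[str]:
        return [s for s in self.values.columns
                if self.sample_meta.get(s) == "venom_gland"]

    @property
    def vg_sample(self) -> str:
        vg = self.venom_gland_samples()
        if not vg:
            raise KeyError("matrix has no venom-gland sample")
        return vg[0]

    @property
    def stage_samples(self) -> list[str]:
        return [s for s in self.values.columns
                if self.sample_meta.get(s) == "stage"]


def read_expression_table(
    path: str | Path,
    sample_meta: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes × samples TPM matrix from TSV.

    Sample categories come from ``sample_meta`` or, when omitted, from the
    YAML sidecar ``<stem>.meta.yaml`` next to the table (keys ``categories``
    and optional ``stage_order``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # manual parse so ragged rows are a named error, not silent NaN padding
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty expression table")
    header = lines[0].split("\t")
    samples = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}: ragged row starting {parts[0]!r}")
        gene_ids.append(parts[0])
        try:
            row = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value in row {parts[0]!r}") from exc
        rows.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        dup = next(g for g in gene_ids if gene_ids.count(g) > 1)
        raise ParseError(f"{path}: duplicated gene row {dup!r}")
    df = pd.DataFrame(rows, index=gene_ids, columns=samples, dtype=float)

    stage_order: list[str] = []
    if sample_meta is None:
        sidecar = path.with_suffix(".meta.yaml")
        if not sidecar.exists():
            raise ParseError(f"{path}: no sample metadata given and no sidecar "
                             f"{sidecar.name}")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        sample_meta = meta.get("categories", {})
        stage_order = list(meta.get("stage_order", []))
    return ExpressionMatrix(df, dict(sample_meta), stage_order)


def write_expression_table(path: str | Path, matrix: ExpressionMatrix) -> None:
    """Write the TSV matrix plus its YAML sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         float_format="%.6g")
    sidecar = path.with_suffix(".meta.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"categories": matrix.sample_meta, "stage_order": matrix.stage_order},
            fh, sort_keys=True,
        )


@dataclass
class OrthologTable:
    """One-to-one ortholog pairs between two species.

    Genes absent from the table are species-specific.
    """

    species_a: str
    species_b: str
    pairs: dict[str, str]  # geneA -> geneB

    def __post_init__(self) -> None:
        vals = list(self.pairs.values())
        if len(set(vals)) != len(vals):
            raise ParseError("ortholog mapping not injective on species B")

    @property
    def reverse(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs.items()}

    def is_specific(self, gene: str) -> bool:
        return gene not in self.pairs and gene not in self.reverse


def read_ortholog_table(path: str | Path) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns")
    a_col, b_col = df.columns[:2]
    pairs = dict(zip(df[a_col], df[b_col]))
    if len(pairs) != len(df):
        raise ParseError(f"{path}: duplicate species-A gene")
    return OrthologTable(species_a=a_col, species_b=b_col, pairs=pairs)


def write_ortholog_table(path: str | Path, table: OrthologTable) -> None:
    df = pd.DataFrame(sorted(table.pairs.items()),
                      columns=[table.species_a, table.species_b])
    df.to_csv(path, sep="\t", index=False)


@dataclass
class GeneOrderMap:
    """Per species: scaffold -> ordered list of (gene id, strand)."""

    orders: dict[str, dict[str, list[tuple[str, str]]]]

    def __post_init__(self) -> None:
        for sp, scaffolds in self.orders.items():
            seen: set[str] = set()
            for genes in scaffolds.values():
                for g, strand in genes:
                    if strand not in ("+", "-"):
                        raise ParseError(f"{sp}: bad strand {strand!r} for {g}")
                    if g in seen:
                        raise ParseError(f"{sp}: gene {g!r} appears twice")
                    seen.add(g)

    def species(self) -> list[str]:
        return sorted(self.orders)


def read_gene_order(path: str | Path) -> GeneOrderMap:
    """TSV columns: species, scaffold, position, gene_id, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    need = {"species", "scaffold", "position", "gene_id", "strand"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    orders: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for (sp, sc), grp in df.groupby(["species", "scaffold"], sort=True):
        grp = grp.sort_values("position")
        orders.setdefault(sp, {})[sc] = list(zip(grp["gene_id"], grp["strand"]))
    return GeneOrderMap(orders)


def write_gene_order(path: str | Path, gmap: GeneOrderMap) -> None:
    rows = []
    for sp in sorted(gmap.orders):
        for sc in sorted(gmap.orders[sp]):
            for pos, (g, strand) in enumerate(gmap.orders[sp][sc]):
                rows.append((sp, sc, pos, g, strand))
    pd.DataFrame(rows, columns=["species", "scaffold", "position",
                                "gene_id", "strand"]).to_csv(
        path, sep="\t", index=False)


@dataclass
class DomainCountTable:
    """Domain × species counts of annotated protein domains."""

    counts: pd.DataFrame  # index: domain id; columns: species

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ParseError("negative domain count")


def read_domain_counts(path: str | Path) -> DomainCountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DomainCountTable(df.astype(int))


def write_domain_counts(path: str | Path, table: DomainCountTable) -> None:
    table.counts.to_csv(path, sep="\t", index_label="domain_id")


@dataclass
class TaxLabeledTree:
    """A rooted gene tree whose tips carry taxonomy categories.

    Tips are labelled ``name|category`` with category one of focal,
    metazoan, microbial, outgroup. The tree is consumed rooted as given;
    no rerooting is attempted here.
    """

    tree: dendropy.Tree
    categories: dict[str, str]  # tip name -> category

    def __post_init__(self) -> None:
        tips = self.tip_names()
        if len(tips) < 3:
            raise ParseError("tree has fewer than 3 tips")
        missing = set(tips) - set(self.categories)
        if missing:
            raise ParseError(f"tips without category: {sorted(missing)}")
        bad = {n: c for n, c in self.categories.items() if c not in TIP_CATEGORIES}
        if bad:
            raise ParseError(f"unknown tip categories: {bad}")

    def tip_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def tips_of(self, category: str) -> list[str]:
        return [n for n, c in self.categories.items() if c == category]


def _parse_tip_label(label: str) -> tuple[str, str]:
    if "|" not in label:
        raise ParseError(f"tip label {label!r} lacks '|category' suffix")
    name, _, category = label.rpartition("|")
    if category not in TIP_CATEGORIES:
        raise ParseError(f"tip label {label!r}: unknown category {category!r}")
    return name, category


def read_newick_labeled(path_or_string: str | Path) -> TaxLabeledTree:
    """Read one rooted newick tree with ``name|category`` tip labels.

    A multifurcating root is flagged as an error rather than silently
    rerooted (rooting belongs upstream of this artifact).
    """
    text = str(path_or_string)
    if "(" not in text:  # a path, not a newick string
        p = Path(text)
        if not p.exists():
            raise FileNotFoundError(p)
        text = p.read_text()
    elif isinstance(path_or_string, Path):
        text = path_or_string.read_text()
    text = text.strip()
    if not text.endswith(";"):
        raise ParseError("newick string lacks terminating semicolon")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"newick parse failure: {exc}") from exc
    root_children = tree.seed_node.child_nodes()
    if len(root_children) != 2:
        raise ParseError(
            f"root has {len(root_children)} children; expected a rooted "
            "bifurcating root (input is unrooted or multifurcating at the root)"
        )
    categories: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        name, category = _parse_tip_label(leaf.taxon.label)
        leaf.taxon.label = name
        categories[name] = category
    if len(categories) != len(list(tree.leaf_node_iter())):
        raise ParseError("duplicate tip name after category stripping")
    tree.is_rooted = True
    return TaxLabeledTree(tree=tree, categories=categories)


def write_newick_labeled(path: str | Path, tree: TaxLabeledTree) -> None:
    clone = tree.tree.clone(depth=1)
    for leaf in clone.leaf_node_iter():
        leaf.taxon.label = f"{leaf.taxon.label}|{tree.categories[leaf.taxon.label]}"
    with open(path, "w") as fh:
        fh.write(clone.as_string(schema="newick", suppress_rooting=True)
                 .strip() + "\n")


# ---------------------------------------------------------------------------
# Analysis configuration


def _rng_range(lo: float, hi: float):
    return lambda v: lo <= v <= hi


@dataclass
class AnalysisConfig:
    """Every tunable threshold of the pipeline, with documented defaults.

    Unknown keys in a config file are rejected; ``defaulted_keys`` records
    which values came from defaults rather than the file.
    """

    seed: int = 0
    # expression classification
    n99_mode: str = "cumulative"        # or "percentile"
    alpha_high_stage: float = 0.01      # Z-test cutoff for stages
    alpha_high_vg: float = 0.05         # Z-test cutoff for the venom gland
    spec_index_mode: str = "share"      # or "tau"
    # venomics
    min_peptides: int = 3               # VP rule is strictly greater than this
    il_equivalence: bool = False
    s_min: float = 0.9                  # specialization floor for candidates
    p_min: float = 95.0                 # pair-omega percentile floor
    # molecular evolution
    ds_max: float = 2.0                 # dS saturation filter
    pathway_min_genes: int = 3
    pathway_alpha: float = 0.01
    conserved_eps: float = 0.02
    min_block: int = 3
    max_gap: int = 1
    # homology search
    score_min: float = 60.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    max_join_gap: int = 1000
    locus_min_len: int = 50             # aa, after merging
    locus_max_len: int = 2000
    max_iter: int = 10
    # LGT classification
    min_microbial_sister: float = 0.8
    # genome signatures
    gc_window: int = 10000
    gc_step: int = 10000
    kde_bandwidth: float = 0.02
    min_separation: float = 0.05
    # pipeline
    family_min: int = 2
    run_homology_search: bool = True
    defaulted_keys: tuple = ()

    _RANGES = {
        "alpha_high_stage": _rng_range(0.0, 1.0),
        "alpha_high_vg": _rng_range(0.0, 1.0),
        "pathway_alpha": _rng_range(0.0, 1.0),
        "s_min": _rng_range(0.0, 1.0),
        "p_min": _rng_range(0.0, 100.0),
        "ds_max": lambda v: v > 0,
        "conserved_eps": lambda v: v >= 0,
        "min_peptides": lambda v: v >= 0,
        "min_block": lambda v: v >= 1,
        "max_gap": lambda v: v >= 0,
        "score_min": lambda v: v > 0,
        "gap_open": lambda v: v >= 0,
        "gap_extend": lambda v: v >= 0,
        "max_join_gap": lambda v: v >= 0,
        "locus_min_len": lambda v: v >= 1,
        "locus_max_len": lambda v: v >= 1,
        "max_iter": lambda v: v >= 1,
        "min_microbial_sister": _rng_range(0.0, 1.0),
        "gc_window": lambda v: v >= 100,
        "gc_step": lambda v: v >= 1,
        "kde_bandwidth": lambda v: v > 0,
        "min_separation": lambda v: v >= 0,
        "family_min": lambda v: v >= 2,
        "n99_mode": lambda v: v in ("cumulative", "percentile"),
        "spec_index_mode": lambda v: v in ("share", "tau"),
    }

    def __post_init__(self) -> None:
        if self.locus_min_len > self.locus_max_len:
            raise ValueError("locus_min_len exceeds locus_max_len")
        for key, check in self._RANGES.items():
            val = getattr(self, key)
            if not check(val):
                raise ValueError(f"config key {key}={val!r} out of range")


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)
                  if f.name != "defaulted_keys"}


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load a YAML key-value config; missing keys take documented defaults.

    Unknown keys and out-of-range values raise; ``defaulted_keys`` records
    provenance.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a key-value mapping")
    data.update(overrides)
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    defaulted = tuple(sorted(_CONFIG_FIELDS - set(data)))
    try:
        return AnalysisConfig(defaulted_keys=defaulted, **data)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_config(path: str | Path, config: AnalysisConfig) -> None:
    data = {k: getattr(config, k) for k in sorted(_CONFIG_FIELDS)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
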