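"""Lateral-gene-transfer classification from taxonomy-labeled gene trees.

A gene is called LGT-derived when its tree conflicts with vertical
inheritance: the focal + metazoan tips are not monophyletic AND the sister
group of the focal clade is (mostly) microbial. Trees are consumed rooted
as given — rooting with bacterial outgroups happens upstream — and branch
lengths are ignored: the argument is purely topological.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import dendropy

from .formats_io import TaxLabeledTree

__all__ = [
    "LgtVerdict",
    "is_monophyletic",
    "focal_sister",
    "count_metazoan_clades",
    "classify_lgt",
]


def _leaf_categories(tree: TaxLabeledTree, node: dendropy.Node) -> list[str]:
    return [tree.categories[lf.taxon.label] for lf in node.leaf_iter()]


def _mrca(tree: TaxLabeledTree, tip_names: list[str]) -> dendropy.Node:
    taxa = [lf.taxon for lf in tree.tree.leaf_node_iter()
            if lf.taxon.label in set(tip_names)]
    if len(taxa) == 1:
        for lf in tree.tree.leaf_node_iter():
            if lf.taxon is taxa[0]:
                return lf
    return tree.tree.mrca(taxa=taxa)


def is_monophyletic(tree: TaxLabeledTree, category_set: Iterable[str]) -> bool:
    """True iff the smallest clade containing every tip of the given
    categories contains no tips of other categories."""
    cats = set(category_set)
    tips = [n for n, c in tree.categories.items() if c in cats]
    if not tips:
        raise ValueError(f"no tips of categories {sorted(cats)} in tree")
    node = _mrca(tree, tips)
    return all(c in cats for c in _leaf_categories(tree, node))


def focal_sister(tree: TaxLabeledTree) -> dict[str, float]:
    """Category composition (fractions summing to 1) of the sister group
    of the smallest clade containing all focal tips."""
    focal_tips = tree.tips_of("focal")
    if not focal_tips:
        raise ValueError("tree has no focal tips")
    node = _mrca(tree, focal_tips)
    if node is tree.tree.seed_node:
        raise ValueError("focal clade spans the whole tree; no sister group")
    parent = node.parent_node
    sibling_cats: list[str] = []
    for child in parent.child_nodes():
        if child is not node:
            sibling_cats.extend(_leaf_categories(tree, child))
    counts = Counter(sibling_cats)
    total = sum(counts.values())
    return {c: counts[c] / total for c in sorted(counts)}


def count_metazoan_clades(tree: TaxLabeledTree) -> int:
    """Number of maximal clades composed only of focal/metazoan tips that
    contain at least one metazoan tip — a lower bound on independent
    acquisition events."""
    animal = {"focal", "metazoan"}

    def cats(node):
        return _leaf_categories(tree, node)

    count = 0
    stack = [tree.tree.seed_node]
    while stack:
        node = stack.pop()
        c = cats(node)
        if set(c) <= animal:
            if "metazoan" in c:
                count += 1
            continue  # maximal animal clade; do not descend
        stack.extend(node.child_nodes())
    return count


@dataclass
class LgtVerdict:
    """Classification of one gene tree."""

    tree_id: str
    metazoan_monophyly: bool
    focal_sister_composition: dict[str, float]
    n_metazoan_clades: int
    verdict: str  # "vertical" | "lgt" | "ambiguous"
    notes: str = ""


def classify_lgt(tree: TaxLabeledTree,
                 tree_id: str = "",
                 min_microbial_sister: float = 0.8) -> LgtVerdict:
    """Classify a gene tree as vertical, LGT, or ambiguous.

    vertical: focal + metazoan tips are monophyletic.
    lgt: not monophyletic AND the focal clade's sister group is at least
    ``min_microbial_sister`` microbial.
    ambiguous: otherwise.
    """
    if not tree.tips_of("focal"):
        raise ValueError("tree has no focal tips")
    if not tree.tips_of("microbial"):
        raise ValueError("tree has no microbial tips")
    mono = is_monophyletic(tree, {"focal", "metazoan"})
    sister = focal_sister(tree)
    n_clades = count_metazoan_clades(tree)
    microbial_frac = sister.get("microbial", 0.0)
    if mono:
        verdict = "vertical"
        notes = "focal+metazoan monophyletic"
    elif microbial_frac >= min_microbial_sister:
        verdict = "lgt"
        notes = (f"gene/species tree conflict; focal sister "
                 f"{microbial_frac:.0%} microbial")
    else:
        verdict = "ambiguous"
        notes = (f"conflict but focal sister only "
                 f"{microbial_frac:.0%} microbial")
    return LgtVerdict(tree_id=tree_id, metazoan_monophyly=mono,
                      focal_sister_composition=sister,
                      n_metazoan_clades=n_clades,
                      verdict=verdict, notes=notes)
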