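"""Clade extraction from support-annotated trees, or direct clade tables.

Candidate clades are maximal monophyletic groups meeting a branch-support
threshold (strictly greater, default 0.8) and a minimum leaf count
(default 10). Accepted clades are labeled with Roman numerals in
depth-first pre-order; leaves outside every accepted clade stay unassigned
(orphans). Because published clade choices also weigh taxonomy, which no
algorithm can reproduce, a hand-made clade table is accepted as an
alternative input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .errors import CladeError, IdentityError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10
DEFAULT_MIN_SUPPORT = 0.8


def roman(n: int) -> str:
    """Roman numeral for n >= 1 (clade labels I, II, III, ...)."""
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, sym in vals:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


@dataclass
class PhyloTree:
    """Rooted tree with unique leaf labels and optional internal supports."""

    tree: dendropy.Tree
    has_any_support: bool

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass
class CladeAssignment:
    """Mapping sequence id -> clade label; ids absent from the map are orphans."""

    assignment: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.assignment.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def members(self, label: str) -> list[str]:
        return [i for i, lab in self.assignment.items() if lab == label]

    def restrict(self, ids: list[str]) -> "CladeAssignment":
        keep = set(ids)
        return CladeAssignment({i: lab for i, lab in self.assignment.items() if i in keep})


def _node_support(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def read_newick(path: str | Path) -> PhyloTree:
    """Read a Newick tree with branch supports as internal node labels.

    Plain Newick carries no explicit rootedness flag; the file's root is
    taken at face value. An explicit ``[&U]`` (unrooted) annotation is
    rejected since clade extraction needs a rooted topology.
    """
    text = Path(path).read_text()
    if "[&U]" in text:
        raise CladeError("tree is explicitly unrooted ([&U]); a rooted tree is required")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
            raise IdentityError(f"duplicate leaf labels in tree: {exc}") from exc
        raise CladeError(f"malformed Newick in {path}: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise IdentityError(f"duplicate leaf labels in tree: {sorted(dupes)}")
    has_support = any(
        _node_support(nd) is not None
        for nd in tree.preorder_internal_node_iter()
    )
    return PhyloTree(tree=tree, has_any_support=has_support)


def extract_clades(
    ptree: PhyloTree,
    min_size: int = DEFAULT_MIN_SIZE,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> CladeAssignment:
    """Extract maximal monophyletic clades above the support/size thresholds.

    Traversal is root-down (pre-order); the first node whose support is
    strictly greater than ``min_support`` and whose leaf count is at least
    ``min_size`` is accepted as a clade and not descended into, which yields
    pairwise-disjoint maximal clades. Support exactly at the threshold is
    rejected. In a tree without any support annotation, missing supports
    count as 1.0 (a curated tree); in a partially annotated tree they count
    as 0.0 (conservative).
    """
    if min_size < 2:
        raise CladeError(f"min_size must be >= 2, got {min_size}")
    missing_default = 1.0 if not ptree.has_any_support else 0.0
    logger.info("missing internal supports treated as %.1f", missing_default)

    assignment: dict[str, str] = {}
    n_found = 0

    def visit(node: dendropy.Node, is_root: bool) -> None:
        nonlocal n_found
        if node.is_leaf():
            return
        support = _node_support(node)
        if support is None:
            # the root of the whole tree is not a candidate clade
            support = 0.0 if is_root else missing_default
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if not is_root and support > min_support and len(leaves) >= min_size:
            n_found += 1
            label = roman(n_found)
            for lf in leaves:
                assignment[lf] = label
            return  # maximality: do not descend into an accepted clade
        for child in node.child_nodes():
            visit(child, is_root=False)

    visit(ptree.tree.seed_node, is_root=True)
    return CladeAssignment(assignment)


def read_clade_table(path: str | Path) -> CladeAssignment:
    """Read a two-column TSV (sequence id, clade label), no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise CladeError(f"clade table must have 2 columns, found {df.shape[1]}")
    assignment: dict[str, str] = {}
    for sid, lab in df.itertuples(index=False):
        if sid in assignment and assignment[sid] != lab:
            raise CladeError(
                f"conflicting clade labels for {sid!r}: "
                f"{assignment[sid]!r} vs {lab!r}"
            )
        assignment[sid] = lab
    return CladeAssignment(assignment)


def write_clade_table(clades: CladeAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in clades.assignment.items():
            fh.write(f"{sid}\t{lab}\n")
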