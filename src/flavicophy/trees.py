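"""Rooted binary trees and virus-host association tables.

The whole package works on strictly binary, rooted, leaf-labeled trees:
reconciliation assigns one event per internal node, which is only well
defined when every divergence is resolved.  Polytomies are therefore
rejected at parse time rather than silently resolved.

Newick parsing is delegated to dendropy; validation and the lightweight
:class:`PhyloTree` container used throughout the package are defined here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd

__all__ = [
    "TreeError",
    "TreeNode",
    "PhyloTree",
    "AssociationMap",
    "parse_newick",
    "write_newick",
    "load_associations",
    "build_host_tree",
    "prune_to_group",
]


class TreeError(ValueError):
    """Malformed tree, association table, or nesting specification."""


class TreeNode:
    """A node of a rooted binary tree.

    Leaves carry a non-empty ``label``; internal nodes carry exactly two
    children.  ``length`` is the branch length to the parent (may be None).
    """

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label=None, children=None, length=None):
        self.label = label
        self.children = list(children) if children else []
        self.parent = None
        self.length = length
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r})" if self.is_leaf else f"TreeNode(<{len(self.children)}>)"


class PhyloTree:
    """A validated rooted, strictly binary, leaf-labeled phylogeny."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        seen = set()
        n_leaves = 0
        n_internal = 0
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label: {node.label!r}")
                seen.add(node.label)
                n_leaves += 1
            else:
                if len(node.children) != 2:
                    inside = ",".join(sorted(_leaf_labels_below(node))[:6])
                    raise TreeError(
                        f"non-binary node with {len(node.children)} children "
                        f"(clade containing: {inside})"
                    )
                n_internal += 1
        if n_leaves < 2:
            raise TreeError("tree must have at least 2 leaves")
        # n leaves => n-1 internal nodes is implied by the binary check,
        # kept as an integrity assertion.
        assert n_internal == n_leaves - 1

    # -- traversal -------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- topology comparison ---------------------------------------------
    def clade_sets(self) -> set[frozenset]:
        """The set of leaf-label bipartitions below each node (rooted clades)."""
        clades = {}
        out = set()
        for node in self.postorder():
            if node.is_leaf:
                clades[id(node)] = frozenset([node.label])
            else:
                clades[id(node)] = frozenset().union(
                    *(clades[id(c)] for c in node.children)
                )
            out.add(clades[id(node)])
        return out

    def same_topology(self, other: "PhyloTree") -> bool:
        """Label-respecting isomorphism of rooted topologies."""
        return self.clade_sets() == other.clade_sets()

    def copy(self) -> "PhyloTree":
        return parse_newick(write_newick(self))

    def __repr__(self):
        return f"PhyloTree({self.n_leaves} leaves)"


def _leaf_labels_below(node: TreeNode) -> list[str]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label or "?")
        stack.extend(n.children)
    return out


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted, ';'-terminated newick statement.

    Branch lengths are preserved; polytomies and duplicate leaf labels are
    rejected with a :class:`TreeError`.
    """
    if not text.strip().endswith(";"):
        raise TreeError("newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(label=label, length=dnode.edge.length)
        kids = [convert(c) for c in dnode.child_nodes()]
        node = TreeNode(children=kids, length=dnode.edge.length)
        return node

    root = convert(dtree.seed_node)
    # collapse a degenerate single-child root produced by e.g. "((A,B));"
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    return PhyloTree(root)


def _fmt_length(x) -> str:
    return "" if x is None else f":{x:.6g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize to newick; branch lengths written to 6 significant digits."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}{_fmt_length(node.length)}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){_fmt_length(node.length)}"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationMap:
    """Many-to-one map from virus strain labels to host species labels."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        viruses = [v for v, _ in self.records]
        if len(set(viruses)) != len(viruses):
            dup = sorted({v for v in viruses if viruses.count(v) > 1})
            raise TreeError(f"duplicate virus strain(s): {', '.join(dup)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationMap":
        return cls(tuple((str(v).strip(), str(h).strip()) for v, h in pairs))

    def host_of(self, virus: str) -> str:
        return self.as_dict()[virus]

    def as_dict(self) -> dict[str, str]:
        return dict(self.records)

    @property
    def virus_labels(self) -> list[str]:
        return [v for v, _ in self.records]

    @property
    def host_labels(self) -> list[str]:
        """Distinct host species, in first-appearance order."""
        seen = []
        for _, h in self.records:
            if h not in seen:
                seen.append(h)
        return seen

    def restrict(self, viruses: Iterable[str]) -> "AssociationMap":
        keep = set(viruses)
        return AssociationMap(tuple(r for r in self.records if r[0] in keep))

    def __len__(self):
        return len(self.records)


def load_associations(source) -> AssociationMap:
    """Load a TSV with header columns ``virus_strain`` and ``host_species``.

    ``source`` may be a path or a file-like object.  Labels are stripped of
    surrounding whitespace but otherwise treated as opaque, case-sensitive
    strings.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in ("virus_strain", "host_species"):
        if col not in df.columns:
            raise TreeError(f"association table missing column {col!r}")
    df = df.dropna(subset=["virus_strain", "host_species"])
    if len(df) == 0:
        raise TreeError("association table has no data rows")
    return AssociationMap.from_pairs(
        zip(df["virus_strain"].str.strip(), df["host_species"].str.strip())
    )


# ---------------------------------------------------------------------------
# declarative host topology
# ---------------------------------------------------------------------------

def build_host_tree(spec) -> PhyloTree:
    """Build a host topology from a nested specification.

    ``spec`` is a nested sequence of species names, e.g.
    ``(("Culex_pipiens", "Culex_quinquefasciatus"), "Culex_tritaeniorhynchus")``.
    Every nesting level must be binary; a species listed twice is an error.
    The host tree carries no branch lengths (reconciliation is topology-only).
    """

    def build(node_spec) -> TreeNode:
        if isinstance(node_spec, str):
            return TreeNode(label=node_spec)
        node_spec = list(node_spec)
        if len(node_spec) != 2:
            raise TreeError(
                f"nesting specification must be binary, got {len(node_spec)} entries"
            )
        return TreeNode(children=[build(s) for s in node_spec])

    tree = PhyloTree(build(spec))
    return tree


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_to_group(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``keep``, with degree-2 internal nodes suppressed.

    When a suppressed node separates two retained branch lengths, the lengths
    are summed so path lengths among kept leaves are preserved.
    """
    keep = set(keep)
    labels = set(tree.leaf_labels())
    if not keep <= labels:
        missing = sorted(keep - labels)
        raise TreeError(f"labels not in tree: {', '.join(missing)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 leaves to prune to")

    def build(node: TreeNode):
        if node.is_leaf:
            if node.label in keep:
                return TreeNode(label=node.label, length=node.length)
            return None
        kids = [build(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if child.length is not None or node.length is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        return TreeNode(children=kids, length=node.length)

    root = build(tree.root)
    root.length = None
    root.parent = None
    return PhyloTree(root)
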