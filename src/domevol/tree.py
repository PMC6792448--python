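"""Rooted species trees: parsing, validation, clade queries.

The reconstruction downstream is topology-only, so branch lengths and
support values are parsed and preserved for re-serialisation but never
interpreted. Internal nodes without a Newick label receive stable
auto-assigned identifiers (``N`` + preorder index) so that reports are
reproducible run to run. Polytomies are retained as given; Dollo
reconstruction is well defined on them and arbitrary resolution would
fabricate branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "RootedTree",
    "CladeDefinition",
    "TreeValidationError",
    "NewickParseError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "mrca",
    "resolve_clades",
    "read_clade_tsv",
    "read_clade_yaml",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass(frozen=True)
class CladeDefinition:
    """A named ancestor, defined extensionally by a list of member tips.

    ``resolved_node`` is the MRCA of ``member_tips`` on the tree the
    definition was resolved against.
    """

    name: str
    member_tips: tuple[str, ...]
    resolved_node: str


class RootedTree:
    """A rooted phylogeny with uniquely named tips.

    Node identifiers are strings: tips are identified by their taxon
    name; internal nodes by auto-assigned preorder ids ``N0, N1, ...``
    (``N0`` is the root). Original internal Newick labels, if any, are
    kept in :attr:`internal_labels`. Polytomies are permitted.

    Parameters
    ----------
    children :
        Mapping node id -> ordered child ids. Tips map to empty tuples
        or are simply absent.
    root :
        Id of the root node.
    internal_labels :
        Optional mapping internal node id -> original label.
    branch_lengths :
        Optional mapping node id -> length of the branch entering it.
    """

    def __init__(
        self,
        children: Mapping[str, Sequence[str]],
        root: str,
        internal_labels: Mapping[str, str] | None = None,
        branch_lengths: Mapping[str, float] | None = None,
    ) -> None:
        self.root = root
        self._children: dict[str, tuple[str, ...]] = {
            n: tuple(c) for n, c in children.items()
        }
        self._parent: dict[str, str] = {}
        for node, kids in self._children.items():
            for child in kids:
                if child in self._parent:
                    raise TreeValidationError(
                        f"node {child!r} has more than one parent"
                    )
                self._parent[child] = node
        self.internal_labels: dict[str, str] = dict(internal_labels or {})
        self.branch_lengths: dict[str, float] = dict(branch_lengths or {})
        self._validate()
        self._preorder: tuple[str, ...] = tuple(self._iter_preorder())
        self._tipset_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if self.root in self._parent:
            raise TreeValidationError("root must not have a parent")
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise TreeValidationError(f"cycle detected at node {node!r}")
            seen.add(node)
            stack.extend(self.children(node))
        orphans = (set(self._children) | set(self._parent) | {self.root}) - seen
        if orphans:
            raise TreeValidationError(
                f"disconnected nodes: {sorted(orphans)}"
            )
        tips = [n for n in seen if not self.children(n)]
        for t in tips:
            if not t:
                raise TreeValidationError("empty tip name")
        if len(set(tips)) != len(tips):  # defensive; dict keys enforce this
            raise TreeValidationError("duplicate tip names")

    # -- basic queries --------------------------------------------------------

    def children(self, node: str) -> tuple[str, ...]:
        return self._children.get(node, ())

    def parent(self, node: str) -> str | None:
        """Parent id, or None for the root."""
        return self._parent.get(node)

    def is_tip(self, node: str) -> bool:
        return not self.children(node)

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node ids in preorder (root first)."""
        return self._preorder

    @property
    def tips(self) -> tuple[str, ...]:
        """Tip names in preorder (left-to-right as written)."""
        return tuple(n for n in self._preorder if self.is_tip(n))

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self._preorder if not self.is_tip(n))

    def _iter_preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children(node)))

    def preorder(self) -> Iterator[str]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[str]:
        # reversed preorder: every node appears after all its descendants
        return reversed(self._preorder)

    def tip_set(self, node: str) -> frozenset[str]:
        """Frozenset of tip names in the clade subtended by ``node``."""
        cached = self._tipset_cache.get(node)
        if cached is not None:
            return cached
        for n in reversed(self._preorder):  # postorder: children first
            if n in self._tipset_cache:
                continue
            if self.is_tip(n):
                self._tipset_cache[n] = frozenset((n,))
            else:
                acc: set[str] = set()
                for c in self.children(n):
                    acc |= self._tipset_cache[c]
                self._tipset_cache[n] = frozenset(acc)
        return self._tipset_cache[node]

    def ancestors(self, node: str) -> Iterator[str]:
        """Ancestors of ``node`` from its parent up to the root."""
        p = self.parent(node)
        while p is not None:
            yield p
            p = self.parent(p)

    def is_descendant(self, node: str, ancestor: str) -> bool:
        """True if ``node`` is ``ancestor`` itself or lies below it."""
        return node == ancestor or ancestor in set(self.ancestors(node))

    def mrca(self, taxa: Iterable[str]) -> str:
        return mrca(self, taxa)

    def label_of(self, node: str) -> str:
        """Display label: taxon name for tips, original or auto id otherwise."""
        if self.is_tip(node):
            return node
        return self.internal_labels.get(node, node)

    def __contains__(self, node: str) -> bool:
        return node in set(self._preorder)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return (
            self.root == other.root
            and self._children == other._children
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RootedTree({len(self.tips)} tips, "
            f"{len(self.internal_nodes)} internal nodes)"
        )


# -- Newick I/O ---------------------------------------------------------------


def parse_newick(text: str) -> RootedTree:
    """Parse a single Newick tree into a :class:`RootedTree`.

    Quoted labels are un-quoted; branch lengths are preserved but not
    interpreted downstream. Duplicate tip labels raise
    :class:`TreeValidationError` naming the offending label. An unrooted
    trifurcation at the base is accepted as a root polytomy.
    """
    if not text.strip():
        raise NewickParseError("empty Newick string")
    _check_parentheses(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicate labels checked here
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' by end of input (length {len(text)})"
        )


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    leaves = list(dtree.leaf_node_iter())
    names = [lf.taxon.label if lf.taxon else (lf.label or "") for lf in leaves]
    seen: set[str] = set()
    for name in names:
        if not name:
            raise TreeValidationError("tip with empty label")
        if name in seen:
            raise TreeValidationError(f"duplicate tip label: {name!r}")
        seen.add(name)

    children: dict[str, list[str]] = {}
    internal_labels: dict[str, str] = {}
    branch_lengths: dict[str, float] = {}
    ids: dict[int, str] = {}
    counter = 0
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            nid = node.taxon.label if node.taxon else node.label
        else:
            nid = f"N{counter}"
            counter += 1
            if node.label:
                internal_labels[nid] = node.label
        ids[id(node)] = nid
        if node.edge.length is not None and node.parent_node is not None:
            branch_lengths[nid] = float(node.edge.length)
        if node.parent_node is not None:
            children.setdefault(ids[id(node.parent_node)], []).append(nid)
        children.setdefault(nid, [])
    root_id = ids[id(dtree.seed_node)]
    return RootedTree(children, root_id, internal_labels, branch_lengths)


def write_newick(tree: RootedTree, include_internal_labels: bool = True) -> str:
    """Serialise a tree to a Newick string (terminated with ``;``)."""

    def render(node: str) -> str:
        if tree.is_tip(node):
            out = _quote_if_needed(node)
        else:
            inner = ",".join(render(c) for c in tree.children(node))
            label = tree.internal_labels.get(node, "")
            out = f"({inner})" + (
                _quote_if_needed(label) if include_internal_labels and label else ""
            )
        bl = tree.branch_lengths.get(node)
        if bl is not None:
            out += f":{bl:g}"
        return out

    return render(tree.root) + ";"


_NEWICK_SPECIALS = set("()[]{}:;,= \t\n'")


def _quote_if_needed(label: str) -> str:
    if any(ch in _NEWICK_SPECIALS for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(path) -> RootedTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# -- clade queries ------------------------------------------------------------


def mrca(tree: RootedTree, taxa: Iterable[str]) -> str:
    """Most recent common ancestor of a set of taxon names.

    The MRCA of a single taxon is the tip itself.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxa must be non-empty")
    all_tips = set(tree.tips)
    unknown = taxa - all_tips
    if unknown:
        raise KeyError(f"unknown taxon: {sorted(unknown)[0]!r}")
    if len(taxa) == 1:
        return next(iter(taxa))
    # Walk rootward from an arbitrary member until the clade covers all taxa.
    node = next(iter(taxa))
    while not taxa <= tree.tip_set(node):
        parent = tree.parent(node)
        assert parent is not None, "root clade must contain all tips"
        node = parent
    return node


def resolve_clades(
    tree: RootedTree, defs: Sequence[tuple[str, Sequence[str]]]
) -> list[CladeDefinition]:
    """Resolve (name, member_tips) pairs to MRCA nodes, in the given order."""
    out: list[CladeDefinition] = []
    for name, members in defs:
        members = tuple(members)
        if not members:
            raise ValueError(f"clade {name!r} has an empty member list")
        out.append(CladeDefinition(name, members, mrca(tree, members)))
    return out


def read_clade_tsv(path) -> list[tuple[str, tuple[str, ...]]]:
    """Read clade definitions from a two-column TSV.

    Column 1 is the clade name, column 2 a comma-separated tip list.
    Lines starting with ``#`` are comments.
    """
    defs: list[tuple[str, tuple[str, ...]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(parts)}"
                )
            name, tips = parts
            members = tuple(t.strip() for t in tips.split(",") if t.strip())
            defs.append((name, members))
    return defs


def read_clade_yaml(path) -> list[tuple[str, tuple[str, ...]]]:
    """Read clade definitions from YAML: ``{name: [tip, tip, ...], ...}``."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of name -> tip list")
    return [(str(name), tuple(map(str, tips))) for name, tips in data.items()]
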