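"""Dollo-parsimony reconstruction of domain gain and loss.

Under Dollo parsimony each character (protein domain) is gained exactly
once and may subsequently be lost any number of times, irreversibly.
On a rooted tree the unique minimal-loss reconstruction places the gain
at the MRCA of the possessing tips; a node below the gain is ancestrally
present iff its clade contains at least one possessing tip; and one loss
event is charged to the branch entering the topmost absent node of each
maximal lost subtree. This module implements that reconstruction, the
per-node gain/loss/content tallies, and an exhaustive brute-force oracle
used to verify minimality on small trees.

The per-node tallies obey the conservation identity

    content(n) = content(parent(n)) - losses(n) + gains(n)

for every non-root node, with ``content(root) = gains(root)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .matrix import PresenceMatrix
from .tree import RootedTree, parse_newick, write_newick

__all__ = [
    "DomainHistory",
    "GainLossSummary",
    "AncestralReconstruction",
    "reconstruct_domain",
    "reconstruct_all",
    "brute_force_oracle",
    "stem_content",
    "enumerate_rooted_topologies",
    "write_reconstruction",
]


@dataclass(frozen=True)
class DomainHistory:
    """Dollo history of one domain: where gained, where lost, where present."""

    domain: str
    gain_node: str
    loss_branches: frozenset[str]  # child nodes whose incoming branch lost it
    present_nodes: frozenset[str]

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


@dataclass
class GainLossSummary:
    """Per-node event tallies over a set of domain histories.

    ``gains[n]`` counts domains gained at node ``n``; ``losses[n]``
    counts domains lost on the branch entering ``n``; ``content[n]`` is
    the number of domains reconstructed present at ``n``.
    """

    tree: RootedTree
    gains: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)
    content: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_histories(
        cls, tree: RootedTree, histories: Iterable[DomainHistory]
    ) -> "GainLossSummary":
        gains = {n: 0 for n in tree.nodes}
        losses = {n: 0 for n in tree.nodes}
        content = {n: 0 for n in tree.nodes}
        for h in histories:
            gains[h.gain_node] += 1
            for b in h.loss_branches:
                losses[b] += 1
            for n in h.present_nodes:
                content[n] += 1
        return cls(tree, gains, losses, content)

    def check_conservation(self) -> None:
        """Assert the content bookkeeping identity at every node."""
        tree = self.tree
        root = tree.root
        if self.content[root] != self.gains[root]:
            raise AssertionError(
                f"root content {self.content[root]} != root gains "
                f"{self.gains[root]}"
            )
        if self.losses[root] != 0:
            raise AssertionError("root has no incoming branch; losses must be 0")
        for n in tree.nodes:
            if n == root:
                continue
            parent = tree.parent(n)
            expected = self.content[parent] - self.losses[n] + self.gains[n]
            if self.content[n] != expected:
                raise AssertionError(
                    f"conservation violated at {n}: content {self.content[n]} "
                    f"!= {self.content[parent]} - {self.losses[n]} "
                    f"+ {self.gains[n]}"
                )


@dataclass
class AncestralReconstruction:
    """Full reconstruction: per-domain histories plus per-node tallies."""

    tree: RootedTree
    histories: list[DomainHistory]
    summary: GainLossSummary
    skipped: list[str]

    def history_of(self, domain: str) -> DomainHistory:
        for h in self.histories:
            if h.domain == domain:
                return h
        raise KeyError(domain)

    def domains_gained_at(self, node: str) -> list[str]:
        return [h.domain for h in self.histories if h.gain_node == node]

    def domains_lost_at(self, node: str) -> list[str]:
        """Domains lost on the branch entering ``node``."""
        return [h.domain for h in self.histories if node in h.loss_branches]


def reconstruct_domain(
    tree: RootedTree, possessing_tips: Iterable[str], domain: str = ""
) -> DomainHistory:
    """Dollo-optimal history of one domain from its tip presence pattern.

    The gain sits at the MRCA of the possessing tips (the tip itself for
    a single-taxon domain). A descendant of the gain node is present iff
    its clade retains at least one possessing tip; each maximal absent
    subtree hanging off the present set is charged one loss on its stem
    branch.
    """
    possessing = frozenset(possessing_tips)
    if not possessing:
        raise ValueError(
            f"domain {domain!r}: possessing tip set is empty; "
            "all-absent domains must be excluded by the caller"
        )
    gain = tree.mrca(possessing)
    present: set[str] = set()
    losses: set[str] = set()
    stack = [gain]
    while stack:
        node = stack.pop()
        present.add(node)
        for child in tree.children(node):
            if tree.tip_set(child) & possessing:
                stack.append(child)
            else:
                losses.add(child)
    return DomainHistory(
        domain=domain,
        gain_node=gain,
        loss_branches=frozenset(losses),
        present_nodes=frozenset(present),
    )


def reconstruct_all(
    tree: RootedTree,
    matrix: PresenceMatrix,
    prune_missing: bool = False,
    allow_absent_tips: bool = False,
) -> AncestralReconstruction:
    """Reconstruct every domain in the matrix on the tree.

    Matrix taxa must equal the tree's tips. A matrix taxon absent from
    the tree is an error unless ``prune_missing`` drops its row; a tree
    tip absent from the matrix is an error unless ``allow_absent_tips``
    treats it as possessing nothing. Domains present in no tip are
    skipped and listed in ``skipped``.
    """
    tree_tips = set(tree.tips)
    matrix_taxa = set(matrix.taxa)
    extra = matrix_taxa - tree_tips
    if extra:
        if prune_missing:
            keep = [t for t in matrix.taxa if t in tree_tips]
            matrix = PresenceMatrix(matrix.counts.loc[keep])
        else:
            raise ValueError(
                f"matrix taxon {sorted(extra)[0]!r} is not a tip of the tree "
                "(pass prune_missing=True to drop it)"
            )
    missing = tree_tips - set(matrix.taxa)
    if missing and not allow_absent_tips:
        raise ValueError(
            f"tree tip {sorted(missing)[0]!r} has no matrix row "
            "(pass allow_absent_tips=True to treat it as all-absent)"
        )
    histories: list[DomainHistory] = []
    skipped: list[str] = []
    presence = matrix.presence
    for domain in matrix.domains:
        col = presence[domain]
        possessing = frozenset(col.index[col])
        if not possessing:
            skipped.append(domain)
            continue
        histories.append(reconstruct_domain(tree, possessing, domain))
    summary = GainLossSummary.from_histories(tree, histories)
    summary.check_conservation()
    return AncestralReconstruction(tree, histories, summary, skipped)


def brute_force_oracle(
    tree: RootedTree, possessing_tips: Iterable[str]
) -> tuple[int, str]:
    """Exhaustive minimal-loss search for a single-gain history.

    Enumerates every assignment of present/absent to the internal nodes
    (tip states fixed by the pattern) that contains exactly one gain —
    either the root being present or a single absent-parent/present-child
    branch — and returns ``(min_losses, gain_node)`` of a minimising
    assignment. Ties on the loss count are broken in favour of the
    rootmost gain node, which is the canonical Dollo placement.

    Only intended for verification: refuses trees with more than 12
    internal nodes.
    """
    possessing = frozenset(possessing_tips)
    if not possessing:
        raise ValueError("possessing tip set is empty")
    internal = tree.internal_nodes
    if len(internal) > 12:
        raise ValueError(
            f"tree has {len(internal)} internal nodes; the exhaustive "
            "oracle is limited to 12"
        )
    tips = tree.tips
    unknown = possessing - set(tips)
    if unknown:
        raise KeyError(f"unknown taxon: {sorted(unknown)[0]!r}")

    best: tuple[int, int, str] | None = None  # (losses, depth of gain, node)
    depth = {n: sum(1 for _ in tree.ancestors(n)) for n in tree.nodes}
    non_root = [n for n in tree.nodes if n != tree.root]
    for bits in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, bits))
        for t in tips:
            state[t] = 1 if t in possessing else 0
        gains = [n for n in non_root if state[n] and not state[tree.parent(n)]]
        if state[tree.root]:
            gains.append(tree.root)
        if len(gains) != 1:
            continue
        losses = sum(
            1 for n in non_root if not state[n] and state[tree.parent(n)]
        )
        gain = gains[0]
        key = (losses, depth[gain], gain)
        if best is None or key < best:
            best = key
    assert best is not None, "full-presence assignment always qualifies"
    return best[0], best[2]


def stem_content(
    parent_content: int, stem_losses: int, stem_gains: int
) -> int:
    """Domain content at a node from its parent's content and the
    events on the connecting stem branch:
    ``content(n) = content(parent) - losses(n) + gains(n)``."""
    return parent_content - stem_losses + stem_gains


def enumerate_rooted_topologies(tips: Sequence[str]) -> list[RootedTree]:
    """All distinct rooted binary topologies on the given labelled tips.

    There are (2n-3)!! of them; used to verify the reconstruction
    exhaustively on small n. Trees are built by inserting each tip in
    turn on every branch (including above the current root).
    """
    tips = list(tips)
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")

    def insert(shape, tip):
        out = [(shape, tip)]
        if isinstance(shape, tuple):
            left, right = shape
            out += [(l2, right) for l2 in insert(left, tip)]
            out += [(left, r2) for r2 in insert(right, tip)]
        return out

    shapes = [(tips[0], tips[1])]
    for tip in tips[2:]:
        shapes = [s2 for s in shapes for s2 in insert(s, tip)]

    def to_newick(shape) -> str:
        if isinstance(shape, tuple):
            return f"({to_newick(shape[0])},{to_newick(shape[1])})"
        return shape

    return [parse_newick(to_newick(s) + ";") for s in shapes]


def write_reconstruction(
    reconstruction: AncestralReconstruction, out_dir
) -> dict[str, Path]:
    """Emit the reconstruction as three re-parseable text artifacts.

    ``node_summary.tsv`` — per-node gains/losses/content;
    ``domain_histories.tsv`` — per-domain gain node and loss branches;
    ``annotated_tree.nwk`` — the tree with ``name|+G-L`` internal labels.
    Returns the paths keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = reconstruction.tree
    summary = reconstruction.summary

    node_path = out / "node_summary.tsv"
    with open(node_path, "w") as fh:
        fh.write("node\tlabel\tis_tip\tgains\tlosses\tcontent\n")
        for n in tree.nodes:
            fh.write(
                f"{n}\t{tree.label_of(n)}\t{int(tree.is_tip(n))}\t"
                f"{summary.gains[n]}\t{summary.losses[n]}\t"
                f"{summary.content[n]}\n"
            )

    hist_path = out / "domain_histories.tsv"
    with open(hist_path, "w") as fh:
        fh.write("domain\tgain_node\tn_losses\tloss_branches\n")
        for h in reconstruction.histories:
            branches = ",".join(sorted(h.loss_branches))
            fh.write(f"{h.domain}\t{h.gain_node}\t{h.n_losses}\t{branches}\n")

    annotated = RootedTree(
        {n: tree.children(n) for n in tree.nodes},
        tree.root,
        internal_labels={
            n: (
                f"{tree.label_of(n)}|+{summary.gains[n]}-{summary.losses[n]}"
            )
            for n in tree.internal_nodes
        },
        branch_lengths=tree.branch_lengths,
    )
    tree_path = out / "annotated_tree.nwk"
    tree_path.write_text(write_newick(annotated) + "\n")

    skipped_path = out / "skipped_domains.txt"
    skipped_path.write_text(
        "".join(f"{d}\n" for d in reconstruction.skipped)
    )
    return {
        "node_summary": node_path,
        "domain_histories": hist_path,
        "annotated_tree": tree_path,
        "skipped_domains": skipped_path,
    }
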