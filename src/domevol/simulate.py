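"""Synthetic trees, Dollo-process domain histories, and fixture files.

The generator emulates the inputs of the full analysis with known
ground truth: a random species tree, domains that originate at chosen
(or uniformly drawn) nodes and are lost irreversibly along branches at
a constant per-branch probability, decoy domains flagged as
prokaryote-prevalent, and completeness records. An optional HGT-like
violation mode places a second, independent gain in a clade disjoint
from the first, breaking the single-origin assumption on purpose so the
reconstruction's bias under violation can be probed.

Loss events are sampled per branch in pre-order below the gain, so
irreversibility is structural: once a lineage loses a domain nothing
below it can regain it. Every emitted domain is conditioned on
surviving in at least one tip; all-absent draws are re-drawn and the
redraw count is reported so users can gauge the ascertainment this
conditioning induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .matrix import PresenceMatrix, write_prevalence_tsv
from .tree import RootedTree, write_newick

__all__ = [
    "SimulationConfig",
    "DomainTruth",
    "SimulationTruth",
    "simulate_yule_tree",
    "simulate_domain_evolution",
    "emit_fixture_set",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative process.

    ``gain_placement`` is either ``"uniform"`` (every node, tips
    included, equally likely to host the gain) or an explicit sequence
    of node ids sampled uniformly. ``hgt_rate`` is the probability a
    domain receives a second, independent gain in a disjoint clade.
    ``decoy_prokaryotic_fraction`` of domains are flagged as decoys and
    given prevalence 0.96 in the emitted table (others 0.10).
    """

    n_tips: int = 30
    n_domains: int = 500
    loss_probability: float = 0.2
    gain_placement: str | Sequence[str] = "uniform"
    hgt_rate: float = 0.0
    decoy_prokaryotic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        for name in ("loss_probability", "hgt_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 <= self.decoy_prokaryotic_fraction <= 1.0:
            raise ValueError("decoy_prokaryotic_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DomainTruth:
    """Ground truth for one simulated domain."""

    domain: str
    gain_nodes: tuple[str, ...]  # one entry, or two in HGT violation mode
    loss_branches: frozenset[str]
    tip_pattern: frozenset[str]
    is_decoy: bool


@dataclass
class SimulationTruth:
    """Event log of a whole simulation."""

    tree: RootedTree
    domains: list[DomainTruth]
    redraws: int  # all-absent outcomes re-drawn (ascertainment log)
    config: SimulationConfig

    def truth_of(self, domain: str) -> DomainTruth:
        for d in self.domains:
            if d.domain == domain:
                return d
        raise KeyError(domain)


def simulate_yule_tree(n_tips: int, seed: int) -> RootedTree:
    """Pure-birth topology: repeatedly split a uniformly chosen tip.

    Deterministic for a fixed seed. Tips are named T001..T{n}. Branch
    lengths are not assigned; the downstream reconstruction is
    topology-only.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_tips)))
    root = "N0"
    counter = 1
    children: dict[str, list[str]] = {root: []}
    # start from a cherry below the root
    active: list[str] = []
    for _ in range(2):
        leaf = f"L{counter}"
        counter += 1
        children[root].append(leaf)
        children[leaf] = []
        active.append(leaf)
    while len(active) < n_tips:
        idx = int(rng.integers(len(active)))
        leaf = active[idx]
        for _ in range(2):
            child = f"L{counter}"
            counter += 1
            children[leaf].append(child)
            children[child] = []
            active.append(child)
        active.remove(leaf)
    # rename: leaves get taxon names in left-to-right order, internals N#
    order: list[str] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children[node]))
    mapping: dict[str, str] = {}
    tip_i = 0
    int_i = 0
    for node in order:
        if children[node]:
            mapping[node] = f"N{int_i}"
            int_i += 1
        else:
            tip_i += 1
            mapping[node] = f"T{tip_i:0{width}d}"
    renamed = {
        mapping[n]: [mapping[c] for c in kids] for n, kids in children.items()
    }
    return RootedTree(renamed, mapping[root])


def _sample_domain(
    tree: RootedTree,
    rng: np.random.Generator,
    loss_probability: float,
    gain_pool: Sequence[str],
) -> tuple[str, frozenset[str], frozenset[str]]:
    """One gain + pre-order loss walk; returns (gain, losses, tips)."""
    gain = gain_pool[int(rng.integers(len(gain_pool)))]
    losses: set[str] = set()
    present_tips: set[str] = set()
    stack = [gain]
    while stack:
        node = stack.pop()
        if tree.is_tip(node):
            present_tips.add(node)
        for child in tree.children(node):
            if rng.random() < loss_probability:
                losses.add(child)  # nothing below can regain: stop here
            else:
                stack.append(child)
    return gain, frozenset(losses), frozenset(present_tips)


def simulate_domain_evolution(
    tree: RootedTree, config: SimulationConfig
) -> tuple[PresenceMatrix, SimulationTruth]:
    """Sample domain histories on the tree and return the tip matrix
    plus the ground-truth event log.

    Counts in the matrix are 0/1 (the generative process models
    presence, not copy number). Domains whose draw leaves no possessing
    tip are re-drawn; the number of redraws is recorded.
    """
    rng = np.random.default_rng(config.seed)
    if config.gain_placement == "uniform":
        gain_pool: tuple[str, ...] = tree.nodes
    else:
        gain_pool = tuple(config.gain_placement)
        unknown = set(gain_pool) - set(tree.nodes)
        if unknown:
            raise KeyError(f"gain node {sorted(unknown)[0]!r} not in tree")
        if not gain_pool:
            raise ValueError("explicit gain_placement list is empty")

    n_decoys = int(round(config.decoy_prokaryotic_fraction * config.n_domains))
    width = max(4, len(str(config.n_domains)))
    truths: list[DomainTruth] = []
    redraws = 0
    tips = tree.tips
    patterns = np.zeros((len(tips), config.n_domains), dtype=int)
    tip_index = {t: i for i, t in enumerate(tips)}
    for j in range(config.n_domains):
        while True:
            gain, losses, pattern = _sample_domain(
                tree, rng, config.loss_probability, gain_pool
            )
            gains = (gain,)
            if config.hgt_rate and rng.random() < config.hgt_rate:
                first_clade = tree.tip_set(gain)
                disjoint = [
                    n for n in tree.nodes
                    if not (tree.tip_set(n) & first_clade)
                ]
                if disjoint:
                    g2 = disjoint[int(rng.integers(len(disjoint)))]
                    _, losses2, pattern2 = _sample_domain(
                        tree, rng, config.loss_probability, [g2]
                    )
                    gains = (gain, g2)
                    losses = losses | losses2
                    pattern = pattern | pattern2
            if pattern:
                break
            redraws += 1
        name = f"D{j + 1:0{width}d}"
        truths.append(
            DomainTruth(
                domain=name,
                gain_nodes=gains,
                loss_branches=losses,
                tip_pattern=pattern,
                is_decoy=j < n_decoys,
            )
        )
        for t in pattern:
            patterns[tip_index[t], j] = 1
    names = [t.domain for t in truths]
    frame = pd.DataFrame(
        patterns, index=pd.Index(tips, name="taxon"), columns=names
    )
    matrix = PresenceMatrix(frame)
    return matrix, SimulationTruth(tree, truths, redraws, config)


def _pfamscan_lines(taxon: str, counts: pd.Series) -> str:
    """Fabricate pfam_scan-dialect lines realising one taxon's counts."""
    lines = [
        "# pfam_scan.pl, synthetic annotation generated by domevol",
        "# <seq id> <alignment start> <alignment end> <envelope start> "
        "<envelope end> <hmm acc> <hmm name> <type> <hmm start> <hmm end> "
        "<hmm length> <bit score> <E-value> <significance> <clan>",
    ]
    seq_i = 0
    for j, (domain, count) in enumerate(counts.items()):
        for copy in range(int(count)):
            seq_i += 1
            acc = f"PF9{j % 10000:04d}.1"
            lines.append(
                f"{taxon}_g{seq_i:05d} 10 110 8 112 {acc} {domain} "
                f"Domain 1 100 100 150.0 1e-10 1 No_clan"
            )
    return "\n".join(lines) + "\n"


def emit_fixture_set(
    tree: RootedTree,
    matrix: PresenceMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
    out_dir,
) -> dict[str, Path]:
    """Write a complete, parseable input set realising the simulation.

    Emits the tree (Newick), one pfam_scan-dialect annotation file per
    taxon (``<taxon>.pfam.tsv``), a prevalence table (decoys 0.96,
    others 0.10), clade definitions for a nested ancestor series along
    the root's first-child lineage, a completeness table (one exact
    record plus two degraded ones), and the truth log as JSON. The
    files round-trip through the parsing modules to reproduce the
    matrix exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tree_path = out / "species_tree.nwk"
    tree_path.write_text(write_newick(tree) + "\n")
    paths["tree"] = tree_path

    ann_dir = out / "annotations"
    ann_dir.mkdir(exist_ok=True)
    for taxon in matrix.taxa:
        p = ann_dir / f"{taxon}.pfam.tsv"
        p.write_text(_pfamscan_lines(taxon, matrix.counts.loc[taxon]))
    paths["annotations"] = ann_dir

    decoys = {t.domain for t in truth.domains if t.is_decoy}
    prevalence = {
        d: (0.96 if d in decoys else 0.10) for d in matrix.domains
    }
    prev_path = out / "prokaryotic_prevalence.tsv"
    write_prevalence_tsv(prevalence, prev_path)
    paths["prevalence"] = prev_path

    clade_path = out / "clades.tsv"
    with open(clade_path, "w") as fh:
        fh.write("# clade_name\tcomma-separated tips\n")
        node = tree.root
        level = 0
        while not tree.is_tip(node):
            tips = sorted(tree.tip_set(node))
            fh.write(f"C{level}\t{','.join(tips)}\n")
            node = tree.children(node)[0]
            level += 1
    paths["clades"] = clade_path

    comp_path = out / "completeness.tsv"
    taxa = list(matrix.taxa)
    degraded = [
        (taxa[0], 10.0, 50.0, 50.0, 2000, 1400),
        (taxa[min(1, len(taxa) - 1)], 7.25, 13.5, 14.1, 2518, 1763),
    ]
    with open(comp_path, "w") as fh:
        fh.write(
            "taxon\tassembly_mb\tbusco_pct\tcegma_pct\t"
            "annotated_genes\tdomain_bearing_genes\n"
        )
        exact = taxa[-1]
        fh.write(f"{exact}\t40.0\t100\t100\t10000\t7000\n")
        for taxon, mb, b, c, genes, bearing in degraded:
            fh.write(f"{taxon}\t{mb}\t{b}\t{c}\t{genes}\t{bearing}\n")
    paths["completeness"] = comp_path

    truth_path = out / "truth.json"
    truth_payload = {
        "config": {
            "n_tips": config.n_tips,
            "n_domains": config.n_domains,
            "loss_probability": config.loss_probability,
            "hgt_rate": config.hgt_rate,
            "decoy_prokaryotic_fraction": config.decoy_prokaryotic_fraction,
            "seed": config.seed,
        },
        "redraws": truth.redraws,
        "domains": [
            {
                "domain": t.domain,
                "gain_nodes": list(t.gain_nodes),
                "loss_branches": sorted(t.loss_branches),
                "tip_pattern": sorted(t.tip_pattern),
                "is_decoy": t.is_decoy,
            }
            for t in truth.domains
        ],
    }
    truth_path.write_text(json.dumps(truth_payload, indent=1) + "\n")
    paths["truth"] = truth_path
    return paths
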