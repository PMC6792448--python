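"""Retention-probability statistics for domains gained at named ancestors.

The retention probability of a domain in a clade is k/n: the number of
extant species of the clade possessing the domain divided by the number
of species of the clade considered. Incomplete genomes (e.g. fragmented
single-cell assemblies) are handled through an exclusion list and enter
neither k nor n, since their missing data would deflate the statistic.

Threshold conventions: "over 70%" is strict (p > 0.70); "half or more"
is non-strict (p >= 0.50). The median of an even-sized list is the mean
of the central pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dollo import AncestralReconstruction
from .matrix import PresenceMatrix
from .tree import CladeDefinition

__all__ = [
    "RetentionTable",
    "retention_probability",
    "retention_for_origin",
    "count_above_threshold",
    "lost_domain_retention_summary",
    "group_mean_domain_count",
    "write_retention_tsv",
    "retention_histogram",
]


@dataclass
class RetentionTable:
    """Rows of (domain, origin, clade, k, n, p) with p = k/n exactly."""

    rows: pd.DataFrame  # columns: domain, origin, clade, k, n, p

    COLUMNS = ("domain", "origin", "clade", "k", "n", "p")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"retention table missing columns: {missing}")
        if len(self.rows):
            k = self.rows["k"].to_numpy()
            n = self.rows["n"].to_numpy()
            p = self.rows["p"].to_numpy()
            if ((k < 0) | (k > n)).any():
                raise ValueError("retention table requires 0 <= k <= n")
            if not np.array_equal(p, k / n):
                raise ValueError("retention table requires p = k/n exactly")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def p(self) -> np.ndarray:
        return self.rows["p"].to_numpy()

    @classmethod
    def empty(cls) -> "RetentionTable":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))


def retention_probability(
    matrix: PresenceMatrix,
    domain: str,
    clade_tips: Iterable[str],
    excluded_taxa: Iterable[str] = (),
) -> tuple[int, int, float]:
    """(k, n, p) for one domain in one clade.

    n counts the clade's taxa after exclusions; k counts those
    possessing the domain; p = k/n.
    """
    if domain not in set(matrix.domains):
        raise KeyError(f"domain {domain!r} not in matrix")
    effective = set(clade_tips) - set(excluded_taxa)
    if not effective:
        raise ValueError("clade is empty after exclusions")
    unknown = effective - set(matrix.taxa)
    if unknown:
        raise KeyError(f"taxon {sorted(unknown)[0]!r} not in matrix")
    possessing = matrix.possessing_taxa(domain)
    n = len(effective)
    k = len(effective & possessing)
    return k, n, k / n


def retention_for_origin(
    matrix: PresenceMatrix,
    reconstruction: AncestralReconstruction,
    origin_clade: CladeDefinition,
    target_clade: CladeDefinition,
    excluded_taxa: Iterable[str] = (),
) -> RetentionTable:
    """Retention of every domain gained at ``origin_clade``'s ancestor,
    measured in ``target_clade``'s extant species.

    Rows are sorted by p descending, ties broken by domain name.
    """
    origin_node = origin_clade.resolved_node
    gained = reconstruction.domains_gained_at(origin_node)
    excluded = set(excluded_taxa)
    records = []
    for domain in gained:
        k, n, p = retention_probability(
            matrix, domain, target_clade.member_tips, excluded
        )
        records.append(
            dict(
                domain=domain,
                origin=origin_clade.name,
                clade=target_clade.name,
                k=k,
                n=n,
                p=p,
            )
        )
    if not records:
        return RetentionTable.empty()
    frame = pd.DataFrame.from_records(records)
    frame = frame.sort_values(
        ["p", "domain"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return RetentionTable(frame)


def count_above_threshold(
    table: RetentionTable, threshold: float, strict: bool = True
) -> int:
    """Rows with p > threshold (strict) or p >= threshold (non-strict)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not len(table):
        return 0
    p = table.p
    return int((p > threshold).sum() if strict else (p >= threshold).sum())


def lost_domain_retention_summary(
    matrix: PresenceMatrix,
    reconstruction: AncestralReconstruction,
    lost_at: str,
    background_tips: Iterable[str],
    excluded_taxa: Iterable[str] = (),
) -> tuple[float, int, RetentionTable]:
    """How well domains lost on the branch entering ``lost_at`` survive
    elsewhere.

    For every domain lost on that stem branch, retention is measured in
    ``background_tips`` (e.g. the non-metazoan eukaryotes). Returns the
    median p, the count with p >= 0.5, and the full table. An empty
    summary (nan median, zero count) is returned when the node has no
    losses.
    """
    lost = reconstruction.domains_lost_at(lost_at)
    if not lost:
        return float("nan"), 0, RetentionTable.empty()
    excluded = set(excluded_taxa)
    records = []
    for domain in lost:
        k, n, p = retention_probability(matrix, domain, background_tips, excluded)
        records.append(
            dict(domain=domain, origin=lost_at, clade="background", k=k, n=n, p=p)
        )
    frame = pd.DataFrame.from_records(records)
    frame = frame.sort_values(
        ["p", "domain"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table = RetentionTable(frame)
    median_p = float(np.median(table.p))
    count_ge_half = count_above_threshold(table, 0.5, strict=False)
    return median_p, count_ge_half, table


def group_mean_domain_count(
    matrix: PresenceMatrix,
    domain_set: Sequence[str],
    group_tips: Iterable[str],
) -> float:
    """Mean number of domains from ``domain_set`` present per taxon of a
    group (full precision; callers round for display)."""
    group = list(dict.fromkeys(group_tips))
    if not group:
        raise ValueError("group is empty")
    if not domain_set:
        raise ValueError("domain set is empty")
    domains = list(dict.fromkeys(domain_set))
    unknown = set(domains) - set(matrix.domains)
    if unknown:
        raise KeyError(f"domain {sorted(unknown)[0]!r} not in matrix")
    sub = matrix.presence.loc[group, domains]
    return float(sub.sum(axis=1).mean())


# -- exports ------------------------------------------------------------------


def write_retention_tsv(table: RetentionTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def retention_histogram(
    table: RetentionTable, n_bins: int = 10
) -> pd.DataFrame:
    """Bin the p distribution into equal-width bins on [0, 1].

    Returns a frame with bin_left, bin_right, count; the final bin is
    right-inclusive so p = 1 is counted.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(table.p, bins=edges) if len(table) else (
        np.zeros(n_bins, dtype=int),
        edges,
    )
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def summary_json(
    path,
    *,
    medians: Mapping[str, float] | None = None,
    threshold_counts: Mapping[str, int] | None = None,
) -> None:
    """Write a small JSON summary of medians and threshold counts."""
    payload = {
        "medians": dict(medians or {}),
        "threshold_counts": dict(threshold_counts or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
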