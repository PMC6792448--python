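"""Genome-size and gene-count extrapolation for single-cell assemblies.

A single-cell amplified genome (SAG) recovers only part of the genome.
Given the assembly length L (Mb) and the BUSCO and CEGMA completeness
percentages (complete + fragmented, 0-100 scale), the full genome size
is extrapolated as

    size = L / C,    C = (busco_pct + cegma_pct) / 200

i.e. the assembly scaled to 100% of the mean completeness. The total
gene count is extrapolated from the number of predicted proteins that
carry at least one Pfam domain (a conservative, contamination-robust
proxy for real genes), divided by the fraction of proteins expected to
carry a domain (default 0.70, from the two reference choanoflagellate
genomes) and by C:

    genes = round( domain_bearing / pfam_fraction / C )

Both extrapolations assume benchmark genes are distributed homogeneously
along the genome; the report repeats the caveats that fragmented and
complete hits are pooled and that gene predictors under-detect
fragmented genes, so estimates are indicative only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CompletenessRecord",
    "estimate_genome_size",
    "estimate_gene_count",
    "completeness_report",
    "read_completeness_tsv",
    "write_completeness_report",
    "CAVEATS",
]

DEFAULT_PFAM_FRACTION = 0.70

CAVEATS = (
    "Estimates assume core eukaryotic benchmark genes are homogeneously "
    "distributed along the genome; complete and fragmented BUSCO/CEGMA "
    "hits are pooled; gene predictors under-detect fragmented genes, so "
    "completeness is itself underestimated. k-mer based size estimation "
    "is not applicable to single-cell assemblies because amplification "
    "biases coverage. Interpret all extrapolations cautiously."
)


@dataclass(frozen=True)
class CompletenessRecord:
    """Completeness metrics for one assembly.

    Percentages are on the 0-100 scale, as reported by the benchmark
    tools; values above 100 are rejected to guard against accidentally
    passing fractions and percentages mixed.
    """

    taxon: str
    assembly_length: float  # megabases
    busco_pct: float
    cegma_pct: float
    annotated_genes: int = 0
    domain_bearing_genes: int = 0
    pfam_fraction: float = DEFAULT_PFAM_FRACTION

    def __post_init__(self) -> None:
        if self.assembly_length <= 0:
            raise ValueError(
                f"{self.taxon}: assembly length must be > 0 Mb"
            )
        for label, pct in (("busco", self.busco_pct), ("cegma", self.cegma_pct)):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(
                    f"{self.taxon}: {label} percentage {pct} outside [0, 100] "
                    "(percentages are on the 0-100 scale)"
                )
        if not 0.0 < self.pfam_fraction <= 1.0:
            raise ValueError(
                f"{self.taxon}: pfam_fraction must be in (0, 1]"
            )
        if self.annotated_genes < 0 or self.domain_bearing_genes < 0:
            raise ValueError(f"{self.taxon}: gene counts must be >= 0")
        if self.domain_bearing_genes > self.annotated_genes:
            raise ValueError(
                f"{self.taxon}: domain-bearing genes "
                f"({self.domain_bearing_genes}) exceed annotated genes "
                f"({self.annotated_genes})"
            )

    @property
    def mean_completeness(self) -> float:
        """C = mean of the two completeness metrics, as a fraction."""
        return (self.busco_pct + self.cegma_pct) / 200.0


def estimate_genome_size(record: CompletenessRecord) -> float:
    """Extrapolated genome size in Mb, at full precision.

    Display convention is one decimal; callers round. Raises when both
    completeness metrics are zero, since the assembly fraction is then
    unknown and the extrapolation undefined.
    """
    c = record.mean_completeness
    if c <= 0:
        raise ValueError(
            f"{record.taxon}: both completeness metrics are zero; genome "
            "size cannot be extrapolated from a 0% assembly fraction"
        )
    return record.assembly_length / c


def estimate_gene_count(record: CompletenessRecord) -> int:
    """Extrapolated total gene count, rounded half away from zero.

    Zero domain-bearing genes yields 0 (nothing to extrapolate from).
    """
    if record.domain_bearing_genes == 0:
        import warnings

        warnings.warn(
            f"{record.taxon}: no domain-bearing genes; estimated gene "
            "count is 0",
            stacklevel=2,
        )
        return 0
    c = record.mean_completeness
    if c <= 0:
        raise ValueError(
            f"{record.taxon}: both completeness metrics are zero; gene "
            "count cannot be extrapolated"
        )
    raw = record.domain_bearing_genes / record.pfam_fraction / c
    return int(math.floor(raw + 0.5))  # half away from zero (raw > 0 here)


def completeness_report(records: Sequence[CompletenessRecord]) -> pd.DataFrame:
    """Per-taxon extrapolation table.

    Columns: taxon, assembly_mb, mean_completeness_pct, estimated
    genome size (Mb, 1 decimal for display), annotated genes, estimated
    total genes. The caveat block is attached as ``frame.attrs['caveats']``
    and written alongside by :func:`write_completeness_report`.
    """
    rows = []
    for rec in records:
        size = estimate_genome_size(rec)
        genes = (
            estimate_gene_count(rec) if rec.domain_bearing_genes else 0
        )
        rows.append(
            dict(
                taxon=rec.taxon,
                assembly_mb=rec.assembly_length,
                mean_completeness_pct=round(100 * rec.mean_completeness, 2),
                estimated_genome_mb=round(size, 1),
                annotated_genes=rec.annotated_genes,
                estimated_total_genes=genes,
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "assembly_mb",
            "mean_completeness_pct",
            "estimated_genome_mb",
            "annotated_genes",
            "estimated_total_genes",
        ],
    )
    frame.attrs["caveats"] = CAVEATS
    return frame


def read_completeness_tsv(path, pfam_fraction: float = DEFAULT_PFAM_FRACTION
                          ) -> list[CompletenessRecord]:
    """Read completeness records from TSV with columns: taxon,
    assembly_mb, busco_pct, cegma_pct, annotated_genes,
    domain_bearing_genes (an optional pfam_fraction column overrides
    the default)."""
    frame = pd.read_csv(path, sep="\t")
    required = {
        "taxon", "assembly_mb", "busco_pct", "cegma_pct",
        "annotated_genes", "domain_bearing_genes",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            CompletenessRecord(
                taxon=str(row["taxon"]),
                assembly_length=float(row["assembly_mb"]),
                busco_pct=float(row["busco_pct"]),
                cegma_pct=float(row["cegma_pct"]),
                annotated_genes=int(row["annotated_genes"]),
                domain_bearing_genes=int(row["domain_bearing_genes"]),
                pfam_fraction=float(row.get("pfam_fraction", pfam_fraction))
                if "pfam_fraction" in frame.columns
                else pfam_fraction,
            )
        )
    return records


def write_completeness_report(records: Sequence[CompletenessRecord], path
                              ) -> pd.DataFrame:
    """Write the report TSV (with the caveat block as trailing comment
    lines) and return the frame."""
    frame = completeness_report(records)
    with open(path, "w") as fh:
        frame.to_csv(fh, sep="\t", index=False)
        fh.write("# caveats: " + CAVEATS + "\n")
    return frame
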