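"""Taxa x Pfam-domain occurrence matrices.

Builds the per-taxon domain count matrix from ``pfam_scan`` output
files, applies the prokaryotic-prevalence contamination filter, and
round-trips matrices through TSV. Counts are retained for reporting;
the ancestral reconstruction consumes only the binary presence view
(count > 0), since gain/loss events are presence/absence events.

A pandas ``DataFrame`` (taxa rows, domain columns, integer cells)
backs the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainAnnotationRecord",
    "PresenceMatrix",
    "PfamScanFormatError",
    "MatrixFormatError",
    "parse_pfamscan",
    "read_pfamscan",
    "build_matrix",
    "filter_prokaryotic",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_prevalence_tsv",
    "write_prevalence_tsv",
]


class PfamScanFormatError(ValueError):
    """Raised on a malformed pfam_scan data line."""


class MatrixFormatError(ValueError):
    """Raised on a malformed matrix TSV."""


@dataclass(frozen=True)
class DomainAnnotationRecord:
    """One significant-or-not pfam_scan hit of a domain on a sequence."""

    sequence_id: str
    domain_accession: str
    domain_name: str
    evalue: float
    significant: bool

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        if not self.domain_name:
            raise ValueError("empty domain name")


class PresenceMatrix:
    """Taxa x domain occurrence counts with a binary presence view.

    Attributes
    ----------
    counts :
        ``DataFrame`` of non-negative integers; index is taxa, columns
        are domain names, both unique and order-preserving.
    """

    def __init__(self, counts: pd.DataFrame) -> None:
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate taxon: {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise MatrixFormatError(f"duplicate domain: {dup!r}")
        arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise MatrixFormatError("negative count in matrix")
        self.counts = counts.astype(int) if counts.size else counts

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean view: exactly the positivity indicator of counts."""
        return self.counts > 0

    def possessing_taxa(self, domain: str) -> frozenset[str]:
        """Taxa with at least one copy of ``domain``."""
        col = self.presence[domain]
        return frozenset(col.index[col])

    def has(self, taxon: str, domain: str) -> bool:
        return bool(self.counts.at[taxon, domain] > 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PresenceMatrix({len(self.taxa)} taxa x {len(self.domains)} domains)"


# -- pfam_scan parsing --------------------------------------------------------

# Standard pfam_scan column order; >= 15 whitespace-delimited columns:
# seq id, aln start, aln end, env start, env end, hmm acc, hmm name, type,
# hmm start, hmm end, hmm length, bit score, E-value, significance, clan
_MIN_COLUMNS = 15
_COL_SEQ, _COL_ACC, _COL_NAME, _COL_EVALUE, _COL_SIG = 0, 5, 6, 12, 13


def parse_pfamscan(stream: IO[str] | str) -> list[DomainAnnotationRecord]:
    """Parse pfam_scan-format text into annotation records.

    Lines starting with ``#`` and blank lines are skipped. A data line
    with fewer than 15 columns or a non-numeric E-value raises
    :class:`PfamScanFormatError` naming the line number. An empty file
    yields an empty list.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    records: list[DomainAnnotationRecord] = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split()
        if len(cols) < _MIN_COLUMNS:
            raise PfamScanFormatError(
                f"line {lineno}: expected >= {_MIN_COLUMNS} columns, "
                f"got {len(cols)}"
            )
        try:
            evalue = float(cols[_COL_EVALUE])
        except ValueError as exc:
            raise PfamScanFormatError(
                f"line {lineno}: non-numeric E-value {cols[_COL_EVALUE]!r}"
            ) from exc
        records.append(
            DomainAnnotationRecord(
                sequence_id=cols[_COL_SEQ],
                domain_accession=cols[_COL_ACC],
                domain_name=cols[_COL_NAME],
                evalue=evalue,
                significant=cols[_COL_SIG] == "1",
            )
        )
    return records


def read_pfamscan(path) -> list[DomainAnnotationRecord]:
    with open(path) as fh:
        try:
            return parse_pfamscan(fh)
        except PfamScanFormatError as exc:
            raise PfamScanFormatError(f"{path}: {exc}") from exc


# -- matrix assembly ----------------------------------------------------------


def build_matrix(
    annotations: Mapping[str, Sequence[DomainAnnotationRecord]],
    significant_only: bool = True,
    evalue_max: float | None = None,
) -> PresenceMatrix:
    """Assemble the taxa x domain count matrix.

    ``counts[taxon, domain]`` is the number of hits of the domain
    across all sequences of the taxon. The domain universe is the union
    over taxa; a taxon with no (retained) hits keeps a row of zeros.
    Hit retention defaults to the pfam_scan significance flag; an
    optional E-value ceiling can be applied as well.
    """
    taxa = list(annotations)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon names in annotation mapping")
    domain_order: list[str] = []
    seen: set[str] = set()
    tallies: dict[str, dict[str, int]] = {}
    for taxon, records in annotations.items():
        tally: dict[str, int] = {}
        for rec in records:
            if significant_only and not rec.significant:
                continue
            if evalue_max is not None and rec.evalue > evalue_max:
                continue
            tally[rec.domain_name] = tally.get(rec.domain_name, 0) + 1
            if rec.domain_name not in seen:
                seen.add(rec.domain_name)
                domain_order.append(rec.domain_name)
        tallies[taxon] = tally
    domain_order.sort()  # input-order independence
    data = np.zeros((len(taxa), len(domain_order)), dtype=int)
    col = {d: j for j, d in enumerate(domain_order)}
    for i, taxon in enumerate(taxa):
        for d, c in tallies[taxon].items():
            data[i, col[d]] = c
    frame = pd.DataFrame(data, index=pd.Index(taxa, name="taxon"),
                         columns=domain_order)
    return PresenceMatrix(frame)


# -- prokaryotic-prevalence filter --------------------------------------------


def filter_prokaryotic(
    matrix: PresenceMatrix,
    prevalence: Mapping[str, float],
    threshold: float = 0.95,
) -> tuple[PresenceMatrix, list[str]]:
    """Remove domains prevalent in prokaryotes (contamination/HGT noise).

    A domain is removed when its prokaryotic fraction is >= ``threshold``
    (boundary inclusive). Domains absent from the prevalence table are
    kept and reported via a warning. Column order of survivors is
    preserved. Returns ``(filtered_matrix, removed_domains)``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    for d, frac in prevalence.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(
                f"prevalence for {d!r} out of [0, 1]: {frac}"
            )
    removed = [
        d for d in matrix.domains
        if d in prevalence and prevalence[d] >= threshold
    ]
    missing = [d for d in matrix.domains if d not in prevalence]
    if missing:
        warnings.warn(
            f"{len(missing)} domain(s) missing from the prevalence table "
            f"were kept: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    kept = [d for d in matrix.domains if d not in set(removed)]
    return PresenceMatrix(matrix.counts[kept]), removed


# -- TSV I/O ------------------------------------------------------------------


def write_matrix_tsv(matrix: PresenceMatrix, path) -> None:
    """Write the count matrix as TSV: header of domain names, first
    column taxon names."""
    matrix.counts.to_csv(path, sep="\t", index_label="taxon")


def read_matrix_tsv(path) -> PresenceMatrix:
    """Read a matrix TSV; lossless inverse of :func:`write_matrix_tsv`."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise MatrixFormatError(f"{path}: empty file (no header)") from exc
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise MatrixFormatError(f"{path}: duplicate taxon row {dup!r}")
    cells = frame.to_numpy()
    rows, cols = np.where(pd.isna(cells)) if cells.size else ([], [])
    if len(rows):
        raise MatrixFormatError(
            f"{path}: ragged/missing cell at data row {rows[0] + 1}"
        )
    try:
        counts = frame.astype(int)
    except ValueError as exc:
        for i, row in enumerate(cells, 1):
            for v in row:
                try:
                    int(v)
                except (TypeError, ValueError):
                    raise MatrixFormatError(
                        f"{path}: non-integer cell {v!r} at data row {i}"
                    ) from exc
        raise
    return PresenceMatrix(counts)


def read_prevalence_tsv(path) -> dict[str, float]:
    """Read a two-column TSV mapping domain name -> prokaryotic fraction."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: expected 2 columns"
                )
            name, frac = parts
            if name == "domain":  # optional header
                continue
            try:
                out[name] = float(frac)
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: non-numeric fraction {frac!r}"
                ) from exc
    return out


def write_prevalence_tsv(prevalence: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("domain\tprokaryotic_fraction\n")
        for name, frac in prevalence.items():
            fh.write(f"{name}\t{frac:g}\n")
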