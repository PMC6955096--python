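"""Consensus building, pairwise identity, and provirus coordinate bookkeeping.

Covers the genomic housekeeping around endogenous retrovirus (ERV)
annotation: a majority-rule nucleotide consensus with IUPAC ambiguity codes
on ties, mean pairwise identity between aligned ERV copies, parsing of
contig coordinate tokens in the ``c628,049`` / ``<c892`` / ``1 (start)``
dialect, and arithmetic validation of feature tables under the 1-based
fully-closed coordinate convention used on both strands.
"""

from __future__ import annotations

import csv
import itertools
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "ConsensusSequence",
    "Coordinate",
    "GenomicFeature",
    "read_alignment",
    "build_consensus",
    "write_consensus",
    "mean_pairwise_identity",
    "parse_coordinate",
    "feature_length",
    "read_feature_table",
    "validate_feature_table",
    "write_validation_report",
]

logger = logging.getLogger(__name__)

#: IUPAC nucleotide code for every non-empty subset of {A, C, G, T}.
IUPAC_CODES: dict[frozenset[str], str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_BASES = frozenset("ACGT")
_GAP = "-"


@dataclass(frozen=True)
class ConsensusSequence:
    """A consensus string plus the per-emitted-column base counts behind it."""

    sequence: str
    profile: tuple[Mapping[str, int], ...]
    dropped_columns: tuple[int, ...]  # 0-based indices of alignment columns


def read_alignment(path: str | Path, format: str = "fasta") -> MultipleSeqAlignment:
    """Read an alignment; rows must be equal length with unique ids."""
    alignment = AlignIO.read(str(path), format)
    ids = [rec.id for rec in alignment]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sequence ids in alignment")
    return alignment


def build_consensus(alignment: MultipleSeqAlignment) -> ConsensusSequence:
    """Majority-rule consensus; ties among bases yield the IUPAC ambiguity code.

    Per column: only unambiguous bases (A/C/G/T, case-insensitive) are
    counted — N and ambiguity codes are ignored.  A column is emitted only
    when bases outnumber gaps ('-'); a base-vs-gap tie resolves to the base.
    The majority base is emitted; on a count tie among k bases the IUPAC
    code for exactly that base set is emitted.  Columns with no countable
    character, or with gaps in the majority, are dropped (logged).
    """
    if len(alignment) == 0:
        raise ValueError("cannot build a consensus from an empty alignment")
    n_col = alignment.get_alignment_length()
    out: list[str] = []
    profile: list[dict[str, int]] = []
    dropped: list[int] = []
    for col in range(n_col):
        column = alignment[:, col].upper()
        counts = {b: column.count(b) for b in "ACGT"}
        n_bases = sum(counts.values())
        n_gaps = column.count(_GAP)
        if n_bases == 0:
            dropped.append(col)
            logger.warning("column %d has no countable base; dropped", col + 1)
            continue
        if n_gaps > n_bases:  # gap majority: no consensus position exists
            dropped.append(col)
            continue
        top = max(counts.values())
        winners = frozenset(b for b, c in counts.items() if c == top)
        out.append(IUPAC_CODES[winners])
        profile.append(counts)
    return ConsensusSequence(
        sequence="".join(out),
        profile=tuple(profile),
        dropped_columns=tuple(dropped),
    )


def write_consensus(
    consensus: ConsensusSequence, path: str | Path, name: str = "consensus"
) -> None:
    record = SeqRecord(Seq(consensus.sequence), id=name, description="")
    SeqIO.write([record], str(path), "fasta")


def mean_pairwise_identity(
    alignment: MultipleSeqAlignment,
    *,
    count_gap_mismatches: bool = False,
) -> float:
    """Mean percent identity over all unordered row pairs.

    Default convention: a column is compared only when both rows carry an
    unambiguous base (A/C/G/T); gaps, N and ambiguity codes skip the column.
    With ``count_gap_mismatches`` a base-vs-gap column counts as a compared
    mismatch (columns gapped in both rows are still skipped).  Pairs with no
    comparable column are dropped with a warning.
    """
    if len(alignment) < 2:
        raise ValueError("mean pairwise identity needs >= 2 rows")
    identities: list[float] = []
    rows = [str(rec.seq).upper() for rec in alignment]
    ids = [rec.id for rec in alignment]
    for (i, a), (j, b) in itertools.combinations(enumerate(rows), 2):
        matches = compared = 0
        for x, y in zip(a, b):
            x_base, y_base = x in _BASES, y in _BASES
            if x_base and y_base:
                compared += 1
                matches += x == y
            elif count_gap_mismatches and (
                (x_base and y == _GAP) or (y_base and x == _GAP)
            ):
                compared += 1
        if compared == 0:
            logger.warning(
                "pair (%s, %s) has no comparable column; dropped", ids[i], ids[j]
            )
            continue
        identities.append(matches / compared)
    if not identities:
        raise ValueError("no pair had any comparable column")
    return 100.0 * sum(identities) / len(identities)


# ---------------------------------------------------------------------------
# Coordinates and features
# ---------------------------------------------------------------------------

_COORD_RE = re.compile(
    r"^\s*(?P<partial>[<>])?\s*(?P<comp>c)?\s*(?P<digits>\d{1,3}(?:,\d{3})*|\d+)"
    r"\s*(?:\((?P<boundary>start|end)\))?\s*$"
)


@dataclass(frozen=True)
class Coordinate:
    """One parsed coordinate token from a feature table."""

    position: int
    complement: bool
    partial: bool
    boundary: str | None = None  # "start" | "end" when the token marks a contig edge


def parse_coordinate(token: str | int) -> Coordinate:
    """Parse a contig coordinate token.

    Accepts plain integers, thousands separators, a leading ``c`` for the
    complement strand, ``<``/``>`` for partial (truncated) ends, and
    trailing ``(start)``/``(end)`` contig-boundary annotations — e.g.
    ``c23,912``, ``<c892``, ``1 (start)``.
    """
    if isinstance(token, int):
        return Coordinate(position=token, complement=False, partial=False)
    match = _COORD_RE.match(token)
    if match is None:
        raise ValueError(f"unparseable coordinate token {token!r}")
    position = int(match["digits"].replace(",", ""))
    if position < 1:
        raise ValueError(f"coordinate must be >= 1, got {token!r}")
    return Coordinate(
        position=position,
        complement=match["comp"] is not None,
        partial=match["partial"] is not None,
        boundary=match["boundary"],
    )


def feature_length(start: int, end: int) -> int:
    """Inclusive span length |start - end| + 1 (1-based, fully closed, any strand)."""
    if start < 1 or end < 1:
        raise ValueError("coordinates are 1-based; start and end must be >= 1")
    return abs(start - end) + 1


@dataclass(frozen=True)
class GenomicFeature:
    """A row of a provirus feature table, with the length as printed."""

    contig_accession: str
    name: str
    start: Coordinate
    end: Coordinate
    printed_length: int | None
    kind: str = ""  # solo-LTR | LTR | gag | pol | env | acc | RE | ...

    @property
    def complement(self) -> bool:
        return self.start.complement or self.end.complement

    @property
    def partial(self) -> bool:
        return self.start.partial or self.end.partial

    @property
    def computed_length(self) -> int:
        return feature_length(self.start.position, self.end.position)


def read_feature_table(path: str | Path) -> list[GenomicFeature]:
    """Read a TSV feature table (columns contig, name, start, end, length, element)."""
    features: list[GenomicFeature] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"contig", "name", "start", "end", "length"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing feature column(s) {sorted(missing)}")
        for row in reader:
            printed = row["length"].strip().lstrip("<>")
            features.append(
                GenomicFeature(
                    contig_accession=row["contig"],
                    name=row["name"],
                    start=parse_coordinate(row["start"]),
                    end=parse_coordinate(row["end"]),
                    printed_length=int(printed.replace(",", "")) if printed else None,
                    kind=row.get("element", ""),
                )
            )
    return features


def validate_feature_table(features: Sequence[GenomicFeature]) -> list[dict]:
    """Check printed against computed lengths for non-partial spans.

    Returns one report row per feature with status ``pass``, ``flagged``
    (printed != computed — reported, never corrected) or ``partial``
    (truncated span, length not checkable).
    """
    report: list[dict] = []
    for feat in features:
        computed = feat.computed_length
        if feat.partial:
            status = "partial"
        elif feat.printed_length is None:
            status = "pass"
        elif feat.printed_length == computed:
            status = "pass"
        else:
            status = "flagged"
        report.append(
            {
                "contig": feat.contig_accession,
                "name": feat.name,
                "start": feat.start.position,
                "end": feat.end.position,
                "strand": "-" if feat.complement else "+",
                "printed_length": feat.printed_length,
                "computed_length": computed,
                "status": status,
            }
        )
    return report


def write_validation_report(report: Sequence[Mapping], path: str | Path) -> None:
    fieldnames = [
        "contig",
        "name",
        "start",
        "end",
        "strand",
        "printed_length",
        "computed_length",
        "status",
    ]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in report:
            writer.writerow(row)
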