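"""Shared domain types, coordinate conventions and file formats.

All in-memory coordinates are 0-based half-open; every on-disk format
(GFF3, the tabular match format) is 1-based inclusive.  Strand is carried
on the *subject* interval of a :class:`Match`; the query is always ``+``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("teforge")

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSet(dict):
    """Mapping of sequence id -> upper-case nucleotide string (A/C/G/T/N).

    A plain dict subclass so that standard mapping idioms apply; ``lengths``
    is derived rather than stored.
    """

    @property
    def lengths(self) -> dict:
        return {name: len(s) for name, s in self.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.values())


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end}) on {self.seq_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Overlap in bp with ``other`` (0 if different sequences)."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "Interval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class Match:
    """One local pairwise alignment between two genomic intervals.

    The atom of repeat discovery.  ``identity`` is a percentage in (0, 100];
    ``score`` is in arbitrary units (number of matching columns here).
    A match and its mirror (query/subject swapped) describe the same
    alignment and are treated as redundant duplicates.
    """

    id: int
    query: Interval
    subject: Interval
    identity: float
    score: float
    e_value: Optional[float] = None

    @property
    def query_length(self) -> int:
        return len(self.query)

    @property
    def subject_length(self) -> int:
        return len(self.subject)

    def mirror_key(self):
        a = (self.query.seq_id, self.query.start, self.query.end)
        b = (self.subject.seq_id, self.subject.start, self.subject.end)
        return (min(a, b), max(a, b), self.subject.strand)


@dataclass
class Chain:
    """An ordered set of matches joined by dynamic programming.

    Represents one fragmented TE copy: members are collinear on query and
    subject, non-overlapping on the query beyond a small tolerance.
    """

    members: list = field(default_factory=list)

    @property
    def cumulative_length(self) -> int:
        return sum(m.query_length for m in self.members)

    @property
    def span(self) -> int:
        return self.members[-1].query.end - self.members[0].query.start

    @property
    def score(self) -> float:
        return sum(m.score for m in self.members)

    @property
    def query_interval(self) -> Interval:
        first, last = self.members[0], self.members[-1]
        return Interval(first.query.seq_id, first.query.start, last.query.end, "+")

    @property
    def subject_interval(self) -> Interval:
        starts = [m.subject.start for m in self.members]
        ends = [m.subject.end for m in self.members]
        sub = self.members[0].subject
        return Interval(sub.seq_id, min(starts), max(ends), sub.strand)

    @property
    def strand(self) -> str:
        return self.members[0].subject.strand


@dataclass
class Feature:
    """A GFF3-serialisable feature."""

    interval: Interval
    type: str
    attributes: dict = field(default_factory=dict)
    source: str = "teforge"
    score: Optional[float] = None
    parent: Optional[str] = None


def read_fasta(path) -> GenomeSet:
    """Read a (multi-)FASTA file into a :class:`GenomeSet`.

    Residues are upper-cased; characters outside A/C/G/T/N are mapped to N
    with a logged warning.  Duplicate ids and empty files are errors.
    """
    genome = GenomeSet()
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not set(seq) <= VALID_BASES:
            n_mapped += sum(c not in VALID_BASES for c in seq)
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    if n_mapped:
        log.warning("mapped %d non-ACGTN residues to N while reading %s", n_mapped, path)
    return genome


def write_fasta(seqs: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features: Iterable[Feature], path, sequence_lengths: Optional[dict] = None) -> None:
    """Write features as GFF3 (1-based inclusive), deterministically ordered
    by (seq_id, start, end, type).  Intervals outside the sequence bounds
    (when ``sequence_lengths`` is given) raise an error.
    """
    feats = list(features)
    if sequence_lengths is not None:
        for f in feats:
            L = sequence_lengths.get(f.interval.seq_id)
            if L is not None and f.interval.end > L:
                raise ValueError(
                    f"feature {f.type} [{f.interval.start},{f.interval.end}) "
                    f"outside sequence {f.interval.seq_id} (length {L})"
                )
    feats.sort(key=lambda f: (f.interval.seq_id, f.interval.start, f.interval.end, f.type))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if sequence_lengths:
            for name in sorted(sequence_lengths):
                fh.write(f"##sequence-region {name} 1 {sequence_lengths[name]}\n")
        for f in feats:
            attrs = dict(f.attributes)
            if f.parent is not None:
                attrs["Parent"] = f.parent
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                "\t".join(
                    [
                        f.interval.seq_id,
                        f.source,
                        f.type,
                        str(f.interval.start + 1),
                        str(f.interval.end),
                        score,
                        f.interval.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list:
    """Minimal GFF3 reader returning :class:`Feature` objects (0-based half-open)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, source, ftype, start, end, score, strand, _, attrs = cols
            attributes = {}
            if attrs != ".":
                for item in attrs.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attributes[k] = v
            feats.append(
                Feature(
                    interval=Interval(seq_id, int(start) - 1, int(end), strand if strand in "+-" else "+"),
                    type=ftype,
                    attributes=attributes,
                    source=source,
                    score=None if score == "." else float(score),
                    parent=attributes.get("Parent"),
                )
            )
    return feats


MATCH_COLUMNS = [
    "query.id",
    "q.start",
    "q.end",
    "subject.id",
    "s.start",
    "s.end",
    "identity",
    "score",
    "e_value",
]


def write_match_table(matches: Iterable[Match], path) -> None:
    """Write matches as a 9-column TSV, 1-based inclusive on disk.

    Subject strand is encoded the usual tabular way: a minus-strand subject
    has its start and end columns swapped (start > end).
    """
    rows = []
    for m in matches:
        if m.subject.strand == "+":
            s_start, s_end = m.subject.start + 1, m.subject.end
        else:
            s_start, s_end = m.subject.end, m.subject.start + 1
        rows.append(
            (
                m.query.seq_id,
                m.query.start + 1,
                m.query.end,
                m.subject.seq_id,
                s_start,
                s_end,
                round(m.identity, 2),
                round(m.score, 2),
                "" if m.e_value is None else m.e_value,
            )
        )
    pd.DataFrame(rows, columns=MATCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_match_table(path) -> list:
    """Read a match TSV back into :class:`Match` objects.

    Mirror duplicates (the same alignment reported with query and subject
    swapped) are removed on read, keeping the first occurrence.  Malformed
    rows raise an error naming the line number.
    """
    matches = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MATCH_COLUMNS:
            raise ValueError(f"unexpected match-table header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                qid, qs, qe, sid, ss, se = cols[0], int(cols[1]), int(cols[2]), cols[3], int(cols[4]), int(cols[5])
                identity, score = float(cols[6]), float(cols[7])
                e_value = float(cols[8]) if cols[8] not in ("", "nan") else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            m = Match(
                id=len(matches),
                query=Interval(qid, qs - 1, qe, "+"),
                subject=Interval(sid, ss - 1, se, strand),
                identity=identity,
                score=score,
                e_value=e_value,
            )
            key = m.mirror_key()
            if key in seen:
                continue
            seen.add(key)
            matches.append(m)
    return matches
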