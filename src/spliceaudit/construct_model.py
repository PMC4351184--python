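"""Domain types and I/O for expression constructs.

A :class:`Construct` is an ordered list of role-labelled DNA segments
(promoter, ORF, tag, linker, UTR, intron, exon, polyA, ...) together with
reading-frame anchors (``orf_start``, ``intended_stop``) and the splice
sites the designer *intended* (annotated donors/acceptors, normally derived
from canonical GT...AG introns).  Assembling a construct concatenates its
segments and yields a coordinate map from the flat sequence back to
segments.

Coordinate convention: 0-based, half-open intervals everywhere in code;
1-based fully-closed coordinates appear only in human-readable reports.
Constructs are single-stranded, sense orientation (the mRNA strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DnaSeq",
    "SegmentRole",
    "Segment",
    "Construct",
    "CoordinateMap",
    "AmbiguousBaseWarning",
    "ConstructError",
    "read_fasta",
    "write_fasta",
    "read_construct_spec",
    "write_construct_spec",
    "write_bed",
    "assemble",
    "reverse_complement",
]

# IUPAC one-letter ambiguity codes beyond ACGTN; collapsed to N on ingest.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
_VALID = set("ACGTN")


class AmbiguousBaseWarning(UserWarning):
    """Raised when non-ACGTN IUPAC letters are collapsed to N."""


class ConstructError(ValueError):
    """Invalid construct specification or violated construct invariant."""


class DnaSeq(str):
    """An uppercase DNA string over {A,C,G,T,N}.

    Input is normalized on construction: lowercase is uppercased, U becomes
    T (RNA input is accepted), and any other IUPAC ambiguity letter
    collapses to N with an :class:`AmbiguousBaseWarning`.  Characters
    outside the IUPAC nucleotide alphabet raise ``ValueError``; empty
    sequences are rejected.
    """

    def __new__(cls, bases: str) -> "DnaSeq":
        if isinstance(bases, DnaSeq):
            return bases
        s = str(bases).upper().replace("U", "T")
        if not s:
            raise ValueError("empty DNA sequence")
        if not set(s) <= _VALID:
            bad = set(s) - _VALID
            if not bad <= _IUPAC_AMBIGUOUS:
                raise ValueError(
                    f"illegal characters in DNA sequence: {sorted(bad - _IUPAC_AMBIGUOUS)}"
                )
            warnings.warn(
                f"ambiguity codes {sorted(bad)} collapsed to N",
                AmbiguousBaseWarning,
                stacklevel=2,
            )
            s = "".join(c if c in _VALID else "N" for c in s)
        return str.__new__(cls, s)


def reverse_complement(seq: str) -> DnaSeq:
    return DnaSeq(str(Seq(str(seq)).reverse_complement()))


class SegmentRole(str, Enum):
    PROMOTER = "promoter"
    ORF = "orf"
    TAG = "tag"
    LINKER = "linker"
    UTR = "utr"
    INTRON = "intron"
    EXON = "exon"
    POLYA = "polyA"
    ITR = "itr"
    OTHER = "other"


# roles accepted case-insensitively on read
_ROLE_BY_VALUE = {r.value.lower(): r for r in SegmentRole}


@dataclass(frozen=True)
class Segment:
    """One building block of a construct.

    ``canonical`` marks an intron whose boundaries are design-guaranteed
    GT...AG; annotated donor/acceptor sites are derived from such introns.
    """

    label: str
    role: SegmentRole
    seq: DnaSeq
    canonical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", DnaSeq(self.seq))
        if self.canonical:
            if self.role is not SegmentRole.INTRON:
                raise ConstructError(
                    f"segment {self.label!r}: 'canonical' flag only applies to introns"
                )
            if not (self.seq.startswith("GT") and self.seq.endswith("AG")):
                raise ConstructError(
                    f"canonical intron {self.label!r} must start GT and end AG "
                    f"(got {self.seq[:2]}...{self.seq[-2:]})"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CoordinateMap:
    """Half-open (start, end) interval per segment, tiling [0, total)."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev = 0
        for label, start, end in self.intervals:
            if start != prev or end <= start:
                raise ConstructError("coordinate map intervals must tile [0, total)")
            prev = end

    @property
    def total(self) -> int:
        return self.intervals[-1][2] if self.intervals else 0

    def to_segment(self, pos: int) -> tuple[str, int]:
        """Map an assembled position to (segment label, offset in segment)."""
        if not 0 <= pos < self.total:
            raise IndexError(f"position {pos} outside [0, {self.total})")
        for label, start, end in self.intervals:
            if start <= pos < end:
                return label, pos - start
        raise AssertionError("unreachable: intervals tile the sequence")

    def to_global(self, label: str, offset: int) -> int:
        """Map (segment label, offset) back to an assembled position."""
        for lab, start, end in self.intervals:
            if lab == label:
                if not 0 <= offset < end - start:
                    raise IndexError(f"offset {offset} outside segment {label!r}")
                return start + offset
        raise KeyError(f"no segment labelled {label!r}")

    def interval(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.intervals:
            if lab == label:
                return start, end
        raise KeyError(f"no segment labelled {label!r}")

    def segment_at(self, pos: int) -> str:
        return self.to_segment(pos)[0]


@dataclass(frozen=True)
class Construct:
    """An ordered, role-labelled transgene/vector design.

    ``orf_start`` is the 0-based offset of the first translated nucleotide
    in the assembled sequence; ``intended_stop`` is the offset of the first
    nucleotide of the intended stop codon.  ``annotated_donors`` point at
    the G of a GT dinucleotide (first intronic nt); ``annotated_acceptors``
    point at the first exonic nt after an intronic AG.
    """

    name: str
    segments: tuple[Segment, ...]
    orf_start: int
    intended_stop: int
    annotated_donors: tuple[int, ...] = ()
    annotated_acceptors: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "annotated_donors", tuple(self.annotated_donors))
        object.__setattr__(self, "annotated_acceptors", tuple(self.annotated_acceptors))
        if not self.segments:
            raise ConstructError("construct needs at least one segment")
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise ConstructError("segment labels must be unique within a construct")
        seq = "".join(s.seq for s in self.segments)
        n = len(seq)
        if not 0 <= self.orf_start < self.intended_stop < n:
            raise ConstructError(
                f"need 0 <= orf_start({self.orf_start}) < intended_stop"
                f"({self.intended_stop}) < length({n})"
            )
        if (self.intended_stop - self.orf_start) % 3 != 0:
            raise ConstructError("ORF span (orf_start..intended_stop) not divisible by 3")
        for cut in self.annotated_donors:
            if not 0 <= cut <= n - 2 or seq[cut : cut + 2] != "GT":
                raise ConstructError(f"annotated donor at {cut} is not the G of a GT")
        for cut in self.annotated_acceptors:
            if not 2 <= cut <= n or seq[cut - 2 : cut] != "AG":
                raise ConstructError(f"annotated acceptor at {cut} not preceded by AG")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.segments)

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(f"no segment labelled {label!r}")


def assemble(construct: Construct) -> tuple[DnaSeq, CoordinateMap]:
    """Concatenate segments and return (sequence, coordinate map)."""
    parts = []
    intervals = []
    pos = 0
    for seg in construct.segments:
        parts.append(str(seg.seq))
        intervals.append((seg.label, pos, pos + len(seg)))
        pos += len(seg)
    return DnaSeq("".join(parts)), CoordinateMap(tuple(intervals))


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[tuple[str, DnaSeq]]:
    """Read a FASTA file into (id, normalized sequence) pairs, in file order.

    Duplicate record ids and empty files are errors; ambiguity codes other
    than N collapse to N with a warning (see :class:`DnaSeq`).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record ids {dup}")
    return [(r.id, DnaSeq(str(r.seq))) for r in records]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 60-column wrapped."""
    seqrecords = [
        SeqRecord(Seq(str(seq)), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# Construct spec TSV
#
# Format: optional "#key=value" metadata lines (name, orf_start,
# intended_stop), then a header row "label role sequence flags".  The
# sequence column is either a literal sequence or "@file.fasta:id"
# referencing a record in a FASTA file (relative to the spec's directory).
# Flags (comma-separated): "canonical"; "donor@K" / "acceptor@K" add an
# explicit annotated site at segment-relative offset K.


def read_construct_spec(path: str | Path) -> Construct:
    """Parse a construct spec TSV into a validated :class:`Construct`.

    ``orf_start`` defaults to the start of the first ``orf`` segment;
    ``intended_stop`` defaults to the first in-frame stop codon downstream
    of ``orf_start`` in the assembled sequence.  Annotated donors/acceptors
    are derived from canonical intron boundaries plus explicit
    ``donor@K``/``acceptor@K`` flags.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip().lower() for c in cells]
            required = {"label", "role", "sequence"}
            if not required <= set(header):
                raise ConstructError(
                    f"{path}: header must contain columns {sorted(required)}"
                )
            continue
        rows.append(cells)
    if header is None or not rows:
        raise ConstructError(f"{path}: no segment rows")

    col = {name: i for i, name in enumerate(header)}
    segments: list[Segment] = []
    explicit_donors: list[tuple[str, int]] = []
    explicit_acceptors: list[tuple[str, int]] = []
    for cells in rows:
        cells = cells + [""] * (len(header) - len(cells))
        label = cells[col["label"]].strip()
        role_raw = cells[col["role"]].strip().lower()
        if role_raw not in _ROLE_BY_VALUE:
            raise ConstructError(f"{path}: unknown segment role {role_raw!r}")
        seq_field = cells[col["sequence"]].strip()
        if seq_field.startswith("@"):
            ref, _, rec_id = seq_field[1:].partition(":")
            fasta = {rid: s for rid, s in read_fasta(path.parent / ref)}
            if rec_id not in fasta:
                raise ConstructError(f"{path}: no record {rec_id!r} in {ref}")
            seq = fasta[rec_id]
        else:
            seq = DnaSeq(seq_field)
        flags = (
            [f.strip() for f in cells[col["flags"]].split(",") if f.strip()]
            if "flags" in col
            else []
        )
        canonical = "canonical" in flags
        for f in flags:
            if f.startswith("donor@"):
                explicit_donors.append((label, int(f.split("@", 1)[1])))
            elif f.startswith("acceptor@"):
                explicit_acceptors.append((label, int(f.split("@", 1)[1])))
            elif f != "canonical":
                raise ConstructError(f"{path}: unknown flag {f!r}")
        segments.append(Segment(label, _ROLE_BY_VALUE[role_raw], seq, canonical))

    # build coordinates to resolve anchors and derived sites
    pos = 0
    starts: dict[str, int] = {}
    for seg in segments:
        starts[seg.label] = pos
        pos += len(seg)
    seq_all = "".join(s.seq for s in segments)

    if "orf_start" in meta:
        orf_start = int(meta["orf_start"])
    else:
        orf_segs = [s for s in segments if s.role is SegmentRole.ORF]
        if not orf_segs:
            raise ConstructError(f"{path}: no orf segment and no orf_start metadata")
        orf_start = starts[orf_segs[0].label]

    if "intended_stop" in meta:
        intended_stop = int(meta["intended_stop"])
    else:
        intended_stop = _first_inframe_stop(seq_all, orf_start)
        if intended_stop is None:
            raise ConstructError(f"{path}: no in-frame stop downstream of orf_start")

    donors = [starts[lab] + off for lab, off in explicit_donors]
    acceptors = [starts[lab] + off for lab, off in explicit_acceptors]
    for seg in segments:
        if seg.canonical:
            donors.append(starts[seg.label])
            acceptors.append(starts[seg.label] + len(seg))

    return Construct(
        name=meta.get("name", path.stem),
        segments=tuple(segments),
        orf_start=orf_start,
        intended_stop=intended_stop,
        annotated_donors=tuple(sorted(set(donors))),
        annotated_acceptors=tuple(sorted(set(acceptors))),
    )


_STOPS = ("TAA", "TAG", "TGA")


def _first_inframe_stop(seq: str, start: int) -> int | None:
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            return i
    return None


def write_construct_spec(construct: Construct, path: str | Path) -> None:
    """Write a construct spec TSV that round-trips through
    :func:`read_construct_spec` (field-level equality)."""
    _, cmap = assemble(construct)
    starts = {lab: s for lab, s, _ in cmap.intervals}
    derived_donors = set()
    derived_acceptors = set()
    for seg in construct.segments:
        if seg.canonical:
            s, e = cmap.interval(seg.label)
            derived_donors.add(s)
            derived_acceptors.add(e)
    lines = [
        f"# name={construct.name}",
        f"# orf_start={construct.orf_start}",
        f"# intended_stop={construct.intended_stop}",
        "label\trole\tsequence\tflags",
    ]
    for seg in construct.segments:
        flags = ["canonical"] if seg.canonical else []
        s0 = starts[seg.label]
        for cut in construct.annotated_donors:
            if cut not in derived_donors and s0 <= cut < s0 + len(seg):
                flags.append(f"donor@{cut - s0}")
        for cut in construct.annotated_acceptors:
            if cut not in derived_acceptors and s0 < cut <= s0 + len(seg):
                flags.append(f"acceptor@{cut - s0}")
        lines.append(f"{seg.label}\t{seg.role.value}\t{seg.seq}\t{','.join(flags)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(construct: Construct, path: str | Path) -> None:
    """Emit segment intervals as BED (0-based half-open) on the assembled
    sequence, for genome-browser-style inspection."""
    _, cmap = assemble(construct)
    with open(path, "w") as fh:
        for label, start, end in cmap.intervals:
            fh.write(f"{construct.name}\t{start}\t{end}\t{label}\n")
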