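"""Reading-frame operations: stop stripping, in-frame tag fusion, translation.

Epitope tagging a CDS means removing its stop codon, appending the tag's
coding sequence in frame, and adding a fresh stop.  The 10 nt spanning the
CDS–tag junction (3 CDS nt + 7 tag nt by default) are where fusion-created
splice donors arise, so :class:`FusionResult` carries that window
explicitly.

Only the standard genetic code is used (expression constructs); stop codons
are TAA, TAG, TGA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from Bio.Data import CodonTable

from .construct_model import DnaSeq

__all__ = [
    "STOP_CODONS",
    "CODON_TABLE",
    "TagSpec",
    "FusionResult",
    "Translation",
    "V5_METHODS",
    "V5_CANONICAL",
    "TAGS",
    "strip_stop",
    "fuse_tag",
    "translate",
    "read_tagspecs",
    "write_tagspecs",
]

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA


class Translation(NamedTuple):
    """A protein string plus whether a stop codon was actually reached.

    ``stopped`` is False for ragged ends (sequence ran out before a stop;
    a trailing partial codon of <3 nt is ignored).
    """

    protein: str
    stopped: bool


@dataclass(frozen=True)
class TagSpec:
    """An epitope tag's coding sequence plus the stop codon appended after it.

    ``coding`` must be a multiple of 3 with no internal in-frame stop.
    """

    name: str
    coding: DnaSeq
    default_stop: str = "TGA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coding", DnaSeq(self.coding))
        if len(self.coding) % 3 != 0:
            raise ValueError(f"tag {self.name!r}: coding length not a multiple of 3")
        for i in range(0, len(self.coding), 3):
            if self.coding[i : i + 3] in STOP_CODONS:
                raise ValueError(
                    f"tag {self.name!r}: internal stop codon at codon {i // 3}"
                )
        if self.default_stop not in STOP_CODONS:
            raise ValueError(f"tag {self.name!r}: {self.default_stop!r} is not a stop codon")

    @property
    def peptide(self) -> str:
        return translate(DnaSeq(self.coding + self.default_stop), 0).protein


# The V5 tag is shipped in two flavours.  "V5_methods" is the 42-mer used
# verbatim for the transcriptome-wide fusion screen (ends ...TCT AGC, ...DSS);
# "V5_canonical" ends ...TCT ACG (...DST), matching the canonical V5 epitope
# GKPIPNPLLGLDST, and together with a TGA stop carries the BsaAI site
# TACGTG across the tag/stop boundary.  Both share the GGTAAGCCT 5' end that
# creates the junction splice donor, so donor behaviour is identical.
V5_METHODS = TagSpec("V5_methods", DnaSeq("GGTAAGCCTATCCCTAACCCTCTCCTCGGTCTCGATTCTAGC"))
V5_CANONICAL = TagSpec("V5_canonical", DnaSeq("GGTAAGCCTATCCCTAACCCTCTCCTCGGTCTCGATTCTACG"))

TAGS: dict[str, TagSpec] = {t.name: t for t in (V5_METHODS, V5_CANONICAL)}


@dataclass(frozen=True)
class FusionResult:
    """Outcome of fusing a tag to a stop-stripped CDS.

    ``junction_offset`` is the 0-based offset of the first tag nucleotide in
    ``fused_cds`` (equal to the stripped CDS length); ``window`` spans the
    junction (last 3 CDS nt + first ``window_size``−3 tag nt).
    """

    fused_cds: DnaSeq
    junction_offset: int
    window: DnaSeq


class FrameError(ValueError):
    """Reading-frame violation (missing/misplaced stop, frame shift)."""


def strip_stop(cds: DnaSeq) -> DnaSeq:
    """Remove the terminal stop codon of an in-frame CDS.

    Raises :class:`FrameError` if the length is not a multiple of 3, the
    final codon is not a stop, or an internal in-frame stop exists (the
    offending codon index is reported).
    """
    cds = DnaSeq(cds)
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not a multiple of 3")
    if cds[-3:] not in STOP_CODONS:
        raise FrameError(f"no terminal stop codon (final codon {cds[-3:]})")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            raise FrameError(f"internal stop codon {cds[i:i+3]} at codon index {i // 3}")
    return DnaSeq(cds[:-3])


def fuse_tag(
    cds_nostop: DnaSeq,
    tag: TagSpec,
    linker: DnaSeq | None = None,
    window_size: int = 10,
) -> FusionResult:
    """Fuse ``tag`` in frame to the 3' end of a stop-stripped CDS.

    The fused CDS is ``cds + tag.coding + tag.default_stop``; an optional
    ``linker`` is appended *after* the stop (it becomes 3' UTR, as when
    linker sequence joins a tag to downstream genomic elements).  The
    junction window is the ``window_size``-mer starting 3 nt before the
    junction (default 10: 3 CDS nt + 7 tag nt, covering both the 8-mer
    donor definition and 10-mer junction search strings).
    """
    cds_nostop = DnaSeq(cds_nostop)
    if len(cds_nostop) % 3 != 0:
        raise FrameError(f"CDS length {len(cds_nostop)} not a multiple of 3")
    if window_size < 4:
        raise ValueError("window_size must be at least 4")
    fused = DnaSeq(cds_nostop + tag.coding + tag.default_stop + (linker or ""))
    junction = len(cds_nostop)
    window = DnaSeq(fused[max(0, junction - 3) : junction - 3 + window_size])
    return FusionResult(fused_cds=fused, junction_offset=junction, window=window)


def translate(seq: DnaSeq, start: int = 0) -> Translation:
    """Translate from ``start`` to the first in-frame stop (stop excluded).

    Returns ``Translation(protein, stopped)``; ``stopped`` is False when the
    sequence ends before any stop codon (trailing <3 nt ignored).  An N (or
    any ambiguity) inside the translated span raises ``ValueError``.
    """
    seq = DnaSeq(seq)
    if not 0 <= start < len(seq):
        raise IndexError(f"start {start} outside sequence of length {len(seq)}")
    aas: list[str] = []
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            return Translation("".join(aas), True)
        if "N" in codon:
            raise ValueError(f"ambiguous base in codon {codon} at offset {i}")
        aas.append(CODON_TABLE[codon])
    return Translation("".join(aas), False)


# ---------------------------------------------------------------------------
# TagSpec TSV I/O (columns: name, coding, stop)


def read_tagspecs(path: str | Path) -> dict[str, TagSpec]:
    tags: dict[str, TagSpec] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if cells[0].lower() == "name":
            continue
        name, coding = cells[0], cells[1]
        stop = cells[2] if len(cells) > 2 and cells[2] else "TGA"
        tags[name] = TagSpec(name, DnaSeq(coding), stop)
    if not tags:
        raise ValueError(f"{path}: no tag definitions")
    return tags


def write_tagspecs(tags: dict[str, TagSpec] | list[TagSpec], path: str | Path) -> None:
    items = list(tags.values()) if isinstance(tags, dict) else list(tags)
    lines = ["name\tcoding\tstop"]
    lines += [f"{t.name}\t{t.coding}\t{t.default_stop}" for t in items]
    Path(path).write_text("\n".join(lines) + "\n")
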