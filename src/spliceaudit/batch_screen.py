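"""Transcriptome-wide tag-fusion junction screen.

For every CDS in a library (e.g. a CCDS-style multi-FASTA), strip the stop
codon, fuse the tag in frame, and ask whether the fusion junction creates a
splice-donor signal.  Two classification modes are shipped because the two
natural definitions of "junction donor" differ in how many CDS nucleotides
they involve:

- ``methods-10mer`` (default): the junction 10-mer (last CDS nt + first
  9 tag nt) is compared literally against AGGTAAGCCT (consensus class) and
  TGGTAAGCCT (DUX4-like class).  With a GGTAAGCCT... tag this depends only
  on the CDS's final nucleotide.
- ``minimal-8mer``: the junction 8-mer (last 2 CDS nt + first 6 tag nt,
  since the donor GT sits inside a V5-type tag's first GGT codon) is
  classified by the tiered donor scanner; CONSENSUS tier -> consensus class
  (terminal dinucleotide AA or CA for a V5-type tag), and the literal
  TTGGTAAG window -> DUX4-like class (terminal dinucleotide TT).

Invalid CDSs (no terminal stop, internal stop, ambiguity codes, frame
violations) are recorded with a ``skipped_reason`` and counted, never
silently dropped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .construct_model import DnaSeq, read_fasta
from .donor_scan import DonorTier, classify_window
from .orf_tools import STOP_CODONS, TagSpec, V5_METHODS

__all__ = [
    "ScreenClass",
    "ScreenRecord",
    "ScreenSummary",
    "MODES",
    "classify_junction",
    "run_screen",
    "write_records_tsv",
    "summary_to_json",
]

MODES = ("methods-10mer", "minimal-8mer")

_CONSENSUS_10MER = "AGGTAAGCCT"
_DUX4_10MER = "TGGTAAGCCT"
_DUX4_8MER = "TTGGTAAG"


class ScreenClass(str, Enum):
    CONSENSUS_JUNCTION = "CONSENSUS_JUNCTION"
    DUX4_LIKE_JUNCTION = "DUX4_LIKE_JUNCTION"
    NONE = "NONE"


@dataclass(frozen=True)
class ScreenRecord:
    transcript_id: str
    terminal_dinucleotide: str
    junction10: str
    klass: ScreenClass
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


@dataclass(frozen=True)
class ScreenSummary:
    n_total: int
    n_screened: int
    n_skipped: int
    counts: dict[str, int]
    fractions: dict[str, float]


def _validate_cds(cds: str) -> str | None:
    if set(cds) - set("ACGT"):
        return "non-ACGT"
    if len(cds) % 3 != 0:
        return "length not multiple of 3"
    if len(cds) < 6:
        return "too short"
    if cds[-3:] not in STOP_CODONS:
        return "no terminal stop"
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return "internal stop"
    return None


def classify_junction(
    cds: DnaSeq,
    tag: TagSpec = V5_METHODS,
    mode: str = "methods-10mer",
    transcript_id: str = "",
) -> ScreenRecord:
    """Classify the donor signal a tag fusion would create on one CDS."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if mode == "methods-10mer" and not str(tag.coding).startswith("GGTAAGCCT"):
        warnings.warn(
            f"mode 'methods-10mer' search strings assume a tag starting "
            f"GGTAAGCCT (V5-like); tag {tag.name!r} starts {tag.coding[:9]}",
            stacklevel=2,
        )
    cds = str(DnaSeq(cds))
    reason = _validate_cds(cds)
    if reason is not None:
        return ScreenRecord(transcript_id, "", "", ScreenClass.NONE, reason)
    stripped = cds[:-3]
    dinuc = stripped[-2:]
    junction10 = stripped[-1] + str(tag.coding)[:9]
    if mode == "methods-10mer":
        if junction10 == _CONSENSUS_10MER:
            klass = ScreenClass.CONSENSUS_JUNCTION
        elif junction10 == _DUX4_10MER:
            klass = ScreenClass.DUX4_LIKE_JUNCTION
        else:
            klass = ScreenClass.NONE
    else:  # minimal-8mer: the donor GT sits inside the tag's GGT, so the
        # window is the terminal CDS dinucleotide + the tag's first 6 nt
        window8 = stripped[-2:] + str(tag.coding)[:6]
        tier = classify_window(window8) if len(window8) == 8 else None
        if tier == DonorTier.CONSENSUS:
            klass = ScreenClass.CONSENSUS_JUNCTION
        elif window8 == _DUX4_8MER:
            klass = ScreenClass.DUX4_LIKE_JUNCTION
        else:
            klass = ScreenClass.NONE
    return ScreenRecord(transcript_id, dinuc, junction10, klass, None)


def run_screen(
    cds_source: str | Path | Iterable[tuple[str, DnaSeq]],
    tag: TagSpec = V5_METHODS,
    mode: str = "methods-10mer",
) -> tuple[list[ScreenRecord], ScreenSummary]:
    """Screen a whole CDS library; returns per-transcript records plus a
    summary with exact class counts and fractions of screened transcripts."""
    if isinstance(cds_source, (str, Path)):
        records_in = read_fasta(cds_source)
    else:
        records_in = list(cds_source)
    if not records_in:
        raise ValueError("empty CDS input")
    records = [
        classify_junction(seq, tag=tag, mode=mode, transcript_id=rid)
        for rid, seq in records_in
    ]
    screened = [r for r in records if not r.skipped]
    counts = {k.value: 0 for k in ScreenClass}
    for r in screened:
        counts[r.klass.value] += 1
    n_screened = len(screened)
    fractions = {
        k: (c / n_screened if n_screened else 0.0) for k, c in counts.items()
    }
    summary = ScreenSummary(
        n_total=len(records),
        n_screened=n_screened,
        n_skipped=len(records) - n_screened,
        counts=counts,
        fractions=fractions,
    )
    return records, summary


def write_records_tsv(records: Sequence[ScreenRecord], path: str | Path) -> None:
    lines = ["transcript_id\tterminal_dinucleotide\tjunction10\tclass\tskipped_reason"]
    for r in records:
        lines.append(
            f"{r.transcript_id}\t{r.terminal_dinucleotide}\t{r.junction10}\t"
            f"{r.klass.value}\t{r.skipped_reason or ''}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def summary_to_json(summary: ScreenSummary, path: str | Path | None = None) -> str:
    payload = {
        "n_total": summary.n_total,
        "n_screened": summary.n_screened,
        "n_skipped": summary.n_skipped,
        "counts": summary.counts,
        "fractions": summary.fractions,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
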