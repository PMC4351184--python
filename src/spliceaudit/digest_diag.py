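"""Restriction-digest prediction for mis-splicing diagnostics.

A tag that carries a restriction site doubles as a splicing reporter: the
correctly spliced product cuts, while a mis-spliced product that lost the
tag is digest-resistant and runs as a single band.  This module finds IUPAC
recognition sites on linear sense-strand sequences and predicts fragment
patterns, so such assays can be designed before going near a gel.

BsaAI ships in two flavours: the literal site TACGTG and the enzyme's
accepted degenerate site YACGTR (both blunt, cutting after the third
nucleotide).  Reports should name which was used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .construct_model import DnaSeq

__all__ = [
    "IUPAC",
    "RecognitionSite",
    "DigestResult",
    "BSAAI_PAPER",
    "BSAAI_IUPAC",
    "ENZYMES",
    "find_sites",
    "digest_linear",
    "virtual_gel",
    "read_enzymes_tsv",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RecognitionSite:
    """An enzyme's recognition pattern (IUPAC) and cleavage offset.

    ``cut_offset`` is nucleotides from pattern start to the cleavage point;
    None defaults to the blunt midpoint (len // 2).
    """

    name: str
    pattern: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC letters {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)
        off = len(pat) // 2 if self.cut_offset is None else self.cut_offset
        if not 0 <= off <= len(pat):
            raise ValueError(f"{self.name}: cut_offset {off} outside pattern")
        object.__setattr__(self, "cut_offset", off)

    @property
    def regex(self) -> str:
        return "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.pattern
        )


BSAAI_PAPER = RecognitionSite("BsaAI_paper", "TACGTG", 3)
BSAAI_IUPAC = RecognitionSite("BsaAI_iupac", "YACGTR", 3)

ENZYMES: dict[str, RecognitionSite] = {
    e.name: e for e in (BSAAI_PAPER, BSAAI_IUPAC)
}


@dataclass(frozen=True)
class DigestResult:
    """Cut positions (sorted, 0-based) and 5'->3' fragment lengths."""

    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def find_sites(seq: DnaSeq, site: RecognitionSite) -> list[int]:
    """0-based start offsets of every (possibly overlapping) sense-strand
    match of the recognition pattern."""
    s = str(DnaSeq(seq))
    rx = re.compile(f"(?=({site.regex}))")
    return [m.start() for m in rx.finditer(s)]


def digest_linear(
    seq: DnaSeq, sites: RecognitionSite | Sequence[RecognitionSite]
) -> DigestResult:
    """Cleave a linear sequence at every recognition site's cut point.

    Fragments are reported 5'->3' and always sum to the input length; cut
    points falling exactly on a sequence boundary are ignored (they produce
    no fragment).
    """
    s = str(DnaSeq(seq))
    if isinstance(sites, RecognitionSite):
        sites = [sites]
    cuts = sorted(
        {
            start + site.cut_offset
            for site in sites
            for start in find_sites(DnaSeq(s), site)
            if 0 < start + site.cut_offset < len(s)
        }
    )
    bounds = [0, *cuts, len(s)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(cut_positions=tuple(cuts), fragment_lengths=fragments)


def virtual_gel(fragments: Iterable[int], width: int = 40) -> str:
    """Crude text rendering of a digest lane: one band per fragment size,
    largest first (no electrophoretic-mobility modeling)."""
    sizes = sorted(fragments, reverse=True)
    if not sizes:
        return "(no fragments)"
    top = sizes[0]
    lines = []
    for size in sizes:
        bar = "=" * max(1, round(width * size / top))
        lines.append(f"{size:>8} bp |{bar}")
    return "\n".join(lines)


def read_enzymes_tsv(path: str | Path) -> dict[str, RecognitionSite]:
    """Enzyme definitions TSV: name, IUPAC pattern, optional cut_offset."""
    enzymes: dict[str, RecognitionSite] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if cells[0].lower() == "name":
            continue
        name, pattern = cells[0], cells[1]
        off = int(cells[2]) if len(cells) > 2 and cells[2] else None
        enzymes[name] = RecognitionSite(name, pattern, off)
    if not enzymes:
        raise ValueError(f"{path}: no enzyme definitions")
    return enzymes
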