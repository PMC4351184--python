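"""Deterministic synthetic constructs and CDS sets for testing and demos.

The real vector studied in this problem domain (a muscular-dystrophy gene
cassette: promoter, 424-codon ORF ending in a leucine CTT codon, a V5 tag,
40 nt of linker, an 11-nt exon-1 3' UTR, two small canonical introns with
untranslated exons 2/3, and a polyA signal) is not publicly printed in
full, so these generators reproduce its *geometry* on a uniform-random
background: the tag fusion creates the TTGGTAAG junction donor, a second
GGTAAG donor sits in the linker 47 nt before the exon-1 3' end, and the
first in-frame stop along the mis-spliced path lies exactly 168 nt
downstream of the ORF–tag junction — so junction mis-splicing appends
168/3 − 1 = 55 missense residues to the 424-residue native protein (479
total).

Backgrounds are drawn uniformly over ACGT and rejected (not masked) until
the assembled sequence contains no unintended donor at MINIMAL tier or
above and no unintended recognition sites, so downstream scans stay honest.
All generators are deterministic per seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .construct_model import Construct, DnaSeq, Segment, SegmentRole, write_fasta
from .construct_model import assemble
from .digest_diag import BSAAI_IUPAC, find_sites
from .donor_scan import DonorTier, scan_donors
from .orf_tools import STOP_CODONS, TagSpec, V5_METHODS

__all__ = [
    "ModelConstructParams",
    "FixtureError",
    "NONSTOP_CODONS",
    "make_model_construct",
    "make_repaired_construct",
    "make_random_cds_set",
    "repaired_tag",
]

#: the 61 sense codons, sorted (stop codons excluded)
NONSTOP_CODONS: tuple[str, ...] = tuple(
    sorted(
        "".join(c)
        for c in itertools.product("ACGT", repeat=3)
        if "".join(c) not in STOP_CODONS
    )
)

_DINUCS: tuple[str, ...] = tuple(
    sorted("".join(d) for d in itertools.product("ACGT", repeat=2))
)


class FixtureError(RuntimeError):
    """Fixture generation failed (infeasible parameters or rejection-
    sampling exhaustion)."""


@dataclass(frozen=True)
class ModelConstructParams:
    """Geometry of the model tagged-transgene construct.

    ``exon3_stop_offset`` is measured along the mis-spliced mature mRNA,
    from the ORF–tag junction to the first in-frame stop, *including* the
    stop codon's 3 nt (168 nt -> 55 appended residues).  It must be a
    multiple of 3 and exceed ``exon2_len`` + 3 so the stop lands in exon 3.
    """

    native_orf_codons: int = 424
    final_codon: str = "CTT"
    tag: TagSpec = V5_METHODS
    linker_len: int = 40
    exon1_utr_len: int = 11
    intron1_len: int = 200
    intron2_len: int = 150
    exon2_len: int = 100
    exon3_len: int = 120
    exon3_stop_offset: int = 168
    promoter_len: int = 60
    polya_len: int = 30
    linker_donor_upstream_of_exon1_end: int = 47
    include_linker_donor: bool = True
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if self.exon3_stop_offset % 3 != 0:
            raise FixtureError("exon3_stop_offset must be a multiple of 3")
        if not str(self.tag.coding).startswith("GGT"):
            raise FixtureError(
                "the model geometry assumes a GGT-initial (V5-style) tag: the "
                "junction donor GT sits inside the tag's first codon"
            )
        # the junction splice retains the tag's first G, so the missense
        # path is G + exon2 + head of exon3; the stop must land in exon 3
        head_len = self.exon3_stop_offset - 1 - self.exon2_len
        if head_len < 3:
            raise FixtureError("stop must land in exon 3 (exon2 too long)")
        if head_len > self.exon3_len:
            raise FixtureError("exon3_len too short to hold the planted stop")
        if self.final_codon in STOP_CODONS or len(self.final_codon) != 3:
            raise FixtureError("final_codon must be a sense codon")
        if self.native_orf_codons < 3:
            raise FixtureError("need at least 3 ORF codons")
        c = self.linker_len + self.exon1_utr_len - self.linker_donor_upstream_of_exon1_end
        if self.include_linker_donor and not (1 <= c and c + 5 <= self.linker_len):
            raise FixtureError(
                "linker donor position falls outside the linker; adjust "
                "linker_len/exon1_utr_len/linker_donor_upstream_of_exon1_end"
            )
        if min(self.intron1_len, self.intron2_len) < 6:
            raise FixtureError("introns must be at least 6 nt")


def repaired_tag(tag: TagSpec) -> TagSpec:
    """The tag with its first codon's wobble position set to G (GGT -> GGG
    style), destroying the GT the fusion junction would otherwise expose."""
    coding = str(tag.coding)
    if not coding.startswith("GGT"):
        raise FixtureError(
            f"tag {tag.name!r} does not start GGT; no wobble repair template"
        )
    return TagSpec(tag.name + "_repaired", DnaSeq("GGG" + coding[3:]), tag.default_stop)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _build_attempt(params: ModelConstructParams, rng: np.random.Generator, repaired: bool) -> Construct:
    p = params
    tag = repaired_tag(p.tag) if repaired else p.tag
    orf = "ATG" + _random_codons(rng, p.native_orf_codons - 2) + p.final_codon
    tag_seg = str(tag.coding) + tag.default_stop

    linker = list(_random_bases(rng, p.linker_len))
    if p.include_linker_donor:
        c = p.linker_len + p.exon1_utr_len - p.linker_donor_upstream_of_exon1_end
        linker[c - 1 : c + 5] = "GGTAAG"
    linker = "".join(linker)

    utr = _random_bases(rng, p.exon1_utr_len)
    intron1 = "GT" + _random_bases(rng, p.intron1_len - 4) + "AG"
    intron2 = "GT" + _random_bases(rng, p.intron2_len - 4) + "AG"

    # The mis-spliced reading path runs: tag's retained first G, then exon 2,
    # then the head of exon 3, ending at a planted stop exactly
    # exon3_stop_offset nt past the ORF-tag junction.  Its first codon starts
    # with that G (never a stop; stops all begin with T), the rest are sense
    # codons, then TGA.
    n_missense = (p.exon3_stop_offset - 3) // 3
    path = "G" + _random_bases(rng, 2) + _random_codons(rng, n_missense - 1) + "TGA"
    exon2 = path[1 : 1 + p.exon2_len]
    exon3_head = path[1 + p.exon2_len :]
    exon3 = exon3_head + _random_bases(rng, p.exon3_len - len(exon3_head))

    promoter = _random_bases(rng, p.promoter_len)
    polya = "ATTAAA" + _random_bases(rng, p.polya_len - 6)

    segments = (
        Segment("promoter", SegmentRole.PROMOTER, DnaSeq(promoter)),
        Segment("orf", SegmentRole.ORF, DnaSeq(orf)),
        Segment("tag", SegmentRole.TAG, DnaSeq(tag_seg)),
        Segment("linker", SegmentRole.LINKER, DnaSeq(linker)),
        Segment("exon1_utr", SegmentRole.UTR, DnaSeq(utr)),
        Segment("intron1", SegmentRole.INTRON, DnaSeq(intron1), canonical=True),
        Segment("exon2", SegmentRole.EXON, DnaSeq(exon2)),
        Segment("intron2", SegmentRole.INTRON, DnaSeq(intron2), canonical=True),
        Segment("exon3", SegmentRole.EXON, DnaSeq(exon3)),
        Segment("polyA", SegmentRole.POLYA, DnaSeq(polya)),
    )
    offsets = {}
    pos = 0
    for seg in segments:
        offsets[seg.label] = pos
        pos += len(seg)
    name = "model_d4z4_repaired" if repaired else "model_d4z4"
    return Construct(
        name=name,
        segments=segments,
        orf_start=offsets["orf"],
        intended_stop=offsets["tag"] + len(tag.coding),
        annotated_donors=(offsets["intron1"], offsets["intron2"]),
        annotated_acceptors=(offsets["exon2"], offsets["exon3"]),
    )


def _expected_donor_cuts(construct: Construct, params: ModelConstructParams, repaired: bool) -> set[int]:
    _, cmap = assemble(construct)
    expected: set[int] = set()
    if not repaired:
        expected.add(cmap.interval("tag")[0] + 1)  # the GT of the tag's GGT
    if params.include_linker_donor:
        c = params.linker_len + params.exon1_utr_len - params.linker_donor_upstream_of_exon1_end
        expected.add(cmap.interval("linker")[0] + c)
    return expected


def _acceptable(construct: Construct, params: ModelConstructParams, repaired: bool) -> bool:
    seq, cmap = assemble(construct)
    found = {s.cut for s in scan_donors(seq, DonorTier.MINIMAL)}
    if found != _expected_donor_cuts(construct, params, repaired):
        return False
    # recognition sites (degenerate superset) may occur only inside the tag
    tag_lo, tag_hi = cmap.interval("tag")
    for start in find_sites(seq, BSAAI_IUPAC):
        if not (tag_lo <= start and start + len(BSAAI_IUPAC.pattern) <= tag_hi):
            return False
    return True


def _make(params: ModelConstructParams, repaired: bool) -> Construct:
    rng = np.random.default_rng(params.seed)
    for _ in range(params.max_attempts):
        construct = _build_attempt(params, rng, repaired)
        if _acceptable(construct, params, repaired):
            return construct
    raise FixtureError(
        f"no acceptable construct in {params.max_attempts} attempts "
        f"(seed {params.seed})"
    )


def make_model_construct(params: ModelConstructParams | None = None) -> Construct:
    """The model tagged construct: junction donor TTGGTAAG present, linker
    donor present (unless disabled), two annotated canonical introns, and a
    first in-frame stop on the mis-spliced path exactly
    ``exon3_stop_offset`` nt past the junction."""
    return _make(params or ModelConstructParams(), repaired=False)


def make_repaired_construct(params: ModelConstructParams | None = None) -> Construct:
    """The wobble-repaired construct: the tag's first codon is GGG, so the
    junction donor is gone; the linker donor (47 nt before the exon-1 3'
    end by default) remains unless ``include_linker_donor`` is False."""
    return _make(params or ModelConstructParams(), repaired=True)


def make_random_cds_set(
    n: int,
    terminal_dinuc_distribution: dict[str, float] | None = None,
    length_range: tuple[int, int] = (30, 300),
    seed: int = 0,
    out_path: str | Path | None = None,
) -> list[tuple[str, DnaSeq]]:
    """``n`` synthetic CDSs with controlled terminal-dinucleotide composition.

    Each CDS starts ATG, contains no internal in-frame stop, ends with a
    sense codon whose final two nucleotides are drawn from
    ``terminal_dinuc_distribution`` (uniform over the 16 dinucleotides by
    default), and carries a terminal TAA stop.  Lengths (nt, including the
    stop) are drawn uniformly from ``length_range`` rounded down to
    multiples of 3.  Deterministic per seed; ``out_path`` optionally writes
    the set as multi-FASTA (byte-identical across runs for a fixed seed).
    """
    if terminal_dinuc_distribution is None:
        probs = np.full(16, 1 / 16)
    else:
        missing = set(terminal_dinuc_distribution) - set(_DINUCS)
        if missing:
            raise ValueError(f"unknown dinucleotides {sorted(missing)}")
        probs = np.array(
            [terminal_dinuc_distribution.get(d, 0.0) for d in _DINUCS], dtype=float
        )
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("terminal dinucleotide distribution must sum to 1")
    lo, hi = length_range
    lo_c, hi_c = lo // 3, hi // 3
    if lo_c < 4 or hi_c < lo_c:
        raise FixtureError("length_range infeasible: need at least 12 nt (4 codons)")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, DnaSeq]] = []
    for i in range(n):
        n_codons = int(rng.integers(lo_c, hi_c + 1))  # incl. ATG, terminal, stop
        dinuc = _DINUCS[int(rng.choice(16, p=probs))]
        allowed_first = [b for b in "ACGT" if b + dinuc not in STOP_CODONS]
        first = allowed_first[int(rng.integers(0, len(allowed_first)))]
        body = _random_codons(rng, n_codons - 3)
        cds = "ATG" + body + first + dinuc + "TAA"
        out.append((f"cds_{i:05d}", DnaSeq(cds)))
    if out_path is not None:
        write_fasta(out, out_path)
    return out
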