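"""Tiered detection of splice-donor (and heuristic acceptor) signals.

Donors are classified by exact pattern matching of the 8-mer context around
the exon|intron cut (3 exonic + 5 intronic nt), in four nested tiers:

    CONSENSUS     (A/C)AGGTAAG   the minimal consensus donor
    GGTAAG_CLASS  NNGGTAAG       e.g. the TTGGTAAG site a V5 fusion creates
    MINIMAL       NNNGTAAG       bare GTAAG intron start
    CORE          NNNGT          any GT (reported only on request; floods)

Each tier's pattern contains the next ('CONSENSUS' sites are also
'GGTAAG_CLASS' matches, and so on); ``classify_window`` returns the highest
tier that matches.  No positional weighting or trained model is applied:
sites are defined purely by these observed/consensus patterns, though a
user-supplied position-weight matrix can be layered on top via
:func:`score_pwm` (no default matrix is shipped).

Windows containing N never match, and windows truncated by sequence ends
never match (a donor needs its full 8-mer context to be classified).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from .construct_model import Construct, DnaSeq, assemble

__all__ = [
    "DonorTier",
    "DonorSite",
    "AcceptorSite",
    "classify_window",
    "scan_donors",
    "scan_acceptors",
    "annotated_donor_sites",
    "annotated_acceptor_sites",
    "donor_report_rows",
    "score_pwm",
]


class DonorTier(IntEnum):
    """Nested donor-signal tiers; larger is stronger/more specific."""

    CORE = 1
    MINIMAL = 2
    GGTAAG_CLASS = 3
    CONSENSUS = 4


@dataclass(frozen=True, order=True)
class DonorSite:
    """A donor signal.  ``cut`` is the 0-based offset of the first intronic
    nucleotide (the G of GT); ``context8`` is the 8-mer [cut-3, cut+5)."""

    cut: int
    tier: DonorTier
    context8: str

    def __post_init__(self) -> None:
        if len(self.context8) != 8 or self.context8[3:5] != "GT":
            raise ValueError(f"donor context {self.context8!r} lacks GT at [3:5)")


@dataclass(frozen=True, order=True)
class AcceptorSite:
    """An acceptor.  ``cut`` is the 0-based offset of the first exonic
    nucleotide, i.e. the position immediately after the intronic AG."""

    cut: int
    source: str = "annotated"  # "annotated" | "scanned"


def classify_window(w: str) -> DonorTier | None:
    """Classify an 8-mer donor window; None if no tier matches.

    The putative cut sits at offset 3 (``w[3:5]`` must be GT for any tier).
    Any N in the window disqualifies it entirely.
    """
    if len(w) != 8:
        raise ValueError(f"donor window must be 8 nt, got {len(w)}")
    w = str(w).upper()
    bad = set(w) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal characters in window: {sorted(bad)}")
    if "N" in w:
        return None
    if w[3:5] != "GT":
        return None
    if w[1:] == "AGGTAAG" and w[0] in "AC":
        return DonorTier.CONSENSUS
    if w[2:] == "GGTAAG":
        return DonorTier.GGTAAG_CLASS
    if w[3:] == "GTAAG":
        return DonorTier.MINIMAL
    return DonorTier.CORE


def scan_donors(
    seq: DnaSeq,
    min_tier: DonorTier = DonorTier.MINIMAL,
    region: tuple[int, int] | None = None,
) -> list[DonorSite]:
    """All donor sites of tier >= ``min_tier``, sorted by ascending cut.

    ``region`` restricts the cut position to a half-open interval.  Cuts
    whose 8-mer context would be truncated by a sequence end are never
    reported.
    """
    seq = str(DnaSeq(seq))
    lo, hi = region if region is not None else (0, len(seq))
    lo = max(lo, 3)
    hi = min(hi, len(seq) - 4)  # cut is exclusive of hi; cut+5 must fit
    sites: list[DonorSite] = []
    find = seq.find
    # candidate cuts are exactly the GT positions; jump between them
    cut = find("GT", lo)
    while 0 <= cut < hi:
        if cut >= lo:
            w = seq[cut - 3 : cut + 5]
            tier = classify_window(w)
            if tier is not None and tier >= min_tier:
                sites.append(DonorSite(cut=cut, tier=tier, context8=w))
        cut = find("GT", cut + 1)
    return sites


def scan_acceptors(
    seq: DnaSeq, min_pyrimidines: int = 12, window: int = 20
) -> list[AcceptorSite]:
    """Heuristic acceptor scan: AG dinucleotides preceded by a pyrimidine-
    rich tract (>= ``min_pyrimidines`` C/T within the preceding ``window``
    nt).  Off by default in higher-level workflows — constructs normally
    carry annotated acceptors — but available for unannotated sequence.
    """
    seq = str(DnaSeq(seq))
    sites: list[AcceptorSite] = []
    for i in range(len(seq) - 1):
        if seq[i : i + 2] == "AG":
            tract = seq[max(0, i - window) : i]
            if sum(c in "CT" for c in tract) >= min_pyrimidines:
                sites.append(AcceptorSite(cut=i + 2, source="scanned"))
    return sites


def annotated_donor_sites(construct: Construct, seq: DnaSeq | None = None) -> list[DonorSite]:
    """DonorSite objects for the construct's annotated donors.

    Tier comes from classifying the real 8-mer context (a designed intron
    boundary may still be a weak signal); an annotated donor whose context
    is truncated or classifies below CORE is floored at CORE.
    """
    if seq is None:
        seq, _ = assemble(construct)
    sites = []
    for cut in construct.annotated_donors:
        left = str(seq[max(0, cut - 3) : cut]).rjust(3, "N")
        right = str(seq[cut : cut + 5]).ljust(5, "N")
        w = left + right
        tier = classify_window(w) or DonorTier.CORE
        sites.append(DonorSite(cut=cut, tier=tier, context8=w))
    return sorted(sites)


def annotated_acceptor_sites(construct: Construct) -> list[AcceptorSite]:
    return [AcceptorSite(cut=c, source="annotated") for c in sorted(construct.annotated_acceptors)]


def donor_report_rows(
    name: str, sites: Sequence[DonorSite], cmap=None
) -> list[dict[str, object]]:
    """TSV-ready rows: 0- and 1-based cut, tier, context, segment label."""
    rows = []
    for s in sites:
        rows.append(
            {
                "construct": name,
                "cut0": s.cut,
                "cut1": s.cut + 1,
                "tier": s.tier.name,
                "context8": s.context8,
                "segment": cmap.segment_at(s.cut) if cmap is not None else "",
            }
        )
    return rows


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def score_pwm(seq: DnaSeq, pwm: np.ndarray, threshold: float) -> list[tuple[int, float]]:
    """Optional log-odds PWM scan (4 x L matrix, rows A/C/G/T).

    Returns (offset, score) for every window scoring >= ``threshold``.
    Provided for users with their own trained donor matrices; the package
    ships none.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("PWM must have 4 rows (A, C, G, T)")
    L = pwm.shape[1]
    seq = str(DnaSeq(seq))
    out = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if "N" in window:
            continue
        score = sum(pwm[_BASE_INDEX[b], j] for j, b in enumerate(window))
        if score >= threshold:
            out.append((i, float(score)))
    return out
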