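"""Splice-isoform enumeration and protein-consequence calling.

Given donor and acceptor sites on an assembled construct, this module
enumerates every donor–acceptor-consistent set of splice events (each donor
and acceptor used at most once, removed intervals pairwise disjoint), builds
the mature mRNA of each isoform with provenance back to construct
coordinates, and classifies the translated product against the *intended*
fusion protein — the translation of the isoform carrying exactly the
annotated intron events.

The tool deliberately enumerates rather than predicts: which donor a
spliceosome prefers is an empirical question, so isoforms are ranked by
donor tier (stronger first) and event count instead of a quantitative
splice-strength model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .construct_model import Construct, DnaSeq, assemble
from .donor_scan import (
    AcceptorSite,
    DonorSite,
    DonorTier,
    annotated_acceptor_sites,
    annotated_donor_sites,
)
from .orf_tools import TagSpec, translate

__all__ = [
    "SpliceEvent",
    "Isoform",
    "ConsequenceClass",
    "ProteinConsequence",
    "SpliceError",
    "EnumerationCapError",
    "apply_splice",
    "enumerate_isoforms",
    "intended_isoform",
    "map_to_mature",
    "call_consequence",
    "rank_isoforms",
]


class SpliceError(ValueError):
    """Invalid splice event set (overlap, bad boundaries)."""


class EnumerationCapError(RuntimeError):
    """Isoform enumeration exceeded the configured hard cap."""


@dataclass(frozen=True)
class SpliceEvent:
    """One intron-removal event: [donor.cut, acceptor.cut) is excised."""

    donor: DonorSite
    acceptor: AcceptorSite

    def __post_init__(self) -> None:
        if self.donor.cut >= self.acceptor.cut:
            raise SpliceError(
                f"donor cut {self.donor.cut} must precede acceptor cut {self.acceptor.cut}"
            )

    @property
    def removed(self) -> tuple[int, int]:
        return (self.donor.cut, self.acceptor.cut)

    @property
    def length(self) -> int:
        return self.acceptor.cut - self.donor.cut


@dataclass(frozen=True)
class Isoform:
    """A mature mRNA plus provenance intervals on the source construct."""

    events: tuple[SpliceEvent, ...]
    mature: DnaSeq
    provenance: tuple[tuple[int, int], ...]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def id_string(self) -> str:
        if not self.events:
            return "unspliced"
        return "+".join(f"d{e.donor.cut}a{e.acceptor.cut}" for e in self.events)


def apply_splice(seq: DnaSeq, events: Iterable[SpliceEvent]) -> Isoform:
    """Excise the events' removed intervals and record retained intervals.

    Events must be pairwise non-overlapping.  Each removed interval should
    obey the GT...AG rule; a violation raises :class:`SpliceError` unless
    the donor is only CORE tier, in which case a warning is emitted (bare
    GT donors are speculative by nature).
    """
    seq = DnaSeq(seq)
    evs = sorted(events, key=lambda e: e.removed)
    for a, b in itertools.pairwise(evs):
        if a.acceptor.cut > b.donor.cut:
            raise SpliceError(
                f"overlapping events: removed {a.removed} and {b.removed}"
            )
    for e in evs:
        d, a = e.removed
        if a > len(seq):
            raise SpliceError(f"event {e.removed} beyond sequence end {len(seq)}")
        if seq[d : d + 2] != "GT" or seq[a - 2 : a] != "AG":
            msg = (
                f"removed interval [{d},{a}) is {seq[d:d+2]}...{seq[a-2:a]}, "
                "not GT...AG"
            )
            if e.donor.tier == DonorTier.CORE:
                warnings.warn(msg, stacklevel=2)
            else:
                raise SpliceError(msg)
    retained: list[tuple[int, int]] = []
    pos = 0
    for e in evs:
        d, a = e.removed
        if pos < d:
            retained.append((pos, d))
        pos = a
    if pos < len(seq):
        retained.append((pos, len(seq)))
    mature = DnaSeq("".join(str(seq[s:e]) for s, e in retained)) if retained else None
    if mature is None:
        raise SpliceError("splicing removed the entire sequence")
    return Isoform(events=tuple(evs), mature=mature, provenance=tuple(retained))


def _compatible(events: Sequence[SpliceEvent]) -> bool:
    donors = [e.donor.cut for e in events]
    acceptors = [e.acceptor.cut for e in events]
    if len(set(donors)) != len(donors) or len(set(acceptors)) != len(acceptors):
        return False
    ivs = sorted(e.removed for e in events)
    return all(a[1] <= b[0] for a, b in itertools.pairwise(ivs))


def enumerate_isoforms(
    construct_or_seq: Construct | DnaSeq,
    donors: Sequence[DonorSite],
    acceptors: Sequence[AcceptorSite],
    max_events: int = 3,
    cap: int = 10_000,
) -> list[Isoform]:
    """All isoforms reachable with <= ``max_events`` compatible events.

    Compatible means: donor strictly before acceptor within each event, each
    donor/acceptor consumed at most once, removed intervals pairwise
    disjoint.  The unspliced isoform is always included.  Isoforms are
    deduplicated by mature sequence and returned in deterministic order
    (event count, then removed-interval tuple).  Exceeding ``cap`` distinct
    isoforms raises :class:`EnumerationCapError` — never silent truncation.
    Re-splicing of mature products is not modeled.
    """
    if isinstance(construct_or_seq, Construct):
        seq, _ = assemble(construct_or_seq)
    else:
        seq = DnaSeq(construct_or_seq)
    candidates = [
        SpliceEvent(d, a) for d in donors for a in acceptors if d.cut < a.cut
    ]
    candidates.sort(key=lambda e: e.removed)
    isoforms: list[Isoform] = []
    seen: set[str] = set()
    for k in range(0, max_events + 1):
        layer: list[Isoform] = []
        for combo in itertools.combinations(candidates, k):
            if not _compatible(combo):
                continue
            iso = apply_splice(seq, combo)
            if iso.mature not in seen:
                seen.add(str(iso.mature))
                layer.append(iso)
                if len(seen) > cap:
                    raise EnumerationCapError(
                        f"more than {cap} distinct isoforms; raise the cap "
                        "explicitly or reduce donors/acceptors"
                    )
        layer.sort(key=lambda i: tuple(e.removed for e in i.events))
        isoforms.extend(layer)
    return isoforms


def intended_isoform(construct: Construct, seq: DnaSeq | None = None) -> Isoform:
    """The isoform carrying exactly the annotated intron events."""
    if seq is None:
        seq, _ = assemble(construct)
    donors = annotated_donor_sites(construct, seq)
    acceptors = annotated_acceptor_sites(construct)
    if len(donors) != len(acceptors):
        raise SpliceError(
            f"{len(donors)} annotated donors vs {len(acceptors)} acceptors; "
            "cannot pair introns"
        )
    events = [SpliceEvent(d, a) for d, a in zip(donors, acceptors)]
    return apply_splice(seq, events)


def map_to_mature(isoform: Isoform, pos: int) -> int | None:
    """Map a construct coordinate onto the mature mRNA; None if spliced out."""
    offset = 0
    for s, e in isoform.provenance:
        if s <= pos < e:
            return offset + (pos - s)
        offset += e - s
    return None


class ConsequenceClass(str, Enum):
    INTENDED = "INTENDED"
    UTR_ONLY = "UTR_ONLY"
    TAG_LOST_EXTENDED = "TAG_LOST_EXTENDED"
    EXTENDED = "EXTENDED"
    TRUNCATED = "TRUNCATED"
    NO_STOP = "NO_STOP"
    ORF_START_LOST = "ORF_START_LOST"


@dataclass(frozen=True)
class ProteinConsequence:
    """Classification of an isoform's translation vs the intended fusion.

    ``native_retained`` counts intended untagged-ORF residues preserved at
    the N-terminus; ``appended_missense`` counts residues translated beyond
    them (for extension classes ``total_length = native_retained +
    appended_missense``); ``tag_retained`` says whether the tag peptide
    survives anywhere in the product.
    """

    klass: ConsequenceClass
    native_retained: int
    appended_missense: int
    total_length: int
    tag_retained: bool


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def call_consequence(
    isoform: Isoform, construct: Construct, tag: TagSpec
) -> ProteinConsequence:
    """Classify the protein an isoform encodes, relative to the intended
    tagged fusion protein.

    The intended protein is the translation (from ``orf_start``) of the
    isoform containing exactly the annotated intron events.  Classes:

    - INTENDED: identical protein *and* identical mature mRNA.
    - UTR_ONLY: identical protein, mRNA altered only outside the CDS.
    - TAG_LOST_EXTENDED: untagged native ORF intact, tag peptide absent,
      missense extension appended (the hallmark of junction-donor
      mis-splicing).
    - EXTENDED: intended protein intact but read-through appended.
    - TRUNCATED: intended protein cut short (includes tag-only loss).
    - NO_STOP: translation ran off the mature mRNA without a stop.
    - ORF_START_LOST: splicing removed the start of the ORF itself.
    """
    seq, _ = assemble(construct)
    intended = intended_isoform(construct, seq)
    ipos = map_to_mature(intended, construct.orf_start)
    assert ipos is not None, "annotated events removed orf_start"
    intended_tr = translate(intended.mature, ipos)
    intended_prot = intended_tr.protein
    tag_pep = tag.peptide
    if intended_prot.endswith(tag_pep):
        native = intended_prot[: len(intended_prot) - len(tag_pep)]
    else:  # untagged or unusual construct: the whole product is "native"
        native = intended_prot

    opos = map_to_mature(isoform, construct.orf_start)
    if opos is None:
        return ProteinConsequence(
            ConsequenceClass.ORF_START_LOST, 0, 0, 0, tag_retained=False
        )
    tr = translate(isoform.mature, opos)
    obs = tr.protein
    tag_retained = tag_pep in obs
    prefix = _common_prefix_len(obs, native)

    if not tr.stopped:
        klass = ConsequenceClass.NO_STOP
        native_retained = prefix
        appended = len(obs) - native_retained
    elif obs == intended_prot:
        identical_mrna = isoform.mature == intended.mature
        klass = ConsequenceClass.INTENDED if identical_mrna else ConsequenceClass.UTR_ONLY
        native_retained = len(native)
        appended = 0
    elif obs.startswith(native) and len(obs) > len(native):
        native_retained = len(native)
        appended = len(obs) - native_retained
        klass = (
            ConsequenceClass.EXTENDED
            if tag_retained
            else ConsequenceClass.TAG_LOST_EXTENDED
        )
    else:
        klass = ConsequenceClass.TRUNCATED
        native_retained = prefix
        appended = 0
    return ProteinConsequence(
        klass=klass,
        native_retained=native_retained,
        appended_missense=appended,
        total_length=len(obs),
        tag_retained=tag_retained,
    )


def rank_isoforms(isoforms: Sequence[Isoform]) -> list[Isoform]:
    """Plausibility ranking: strongest donor tier first, then fewer events,
    then position.  The unspliced isoform ranks by its absence of donors
    (tier 0), i.e. last among single-candidate sets."""
    def key(iso: Isoform):
        top = max((e.donor.tier for e in iso.events), default=0)
        return (-int(top), iso.n_events, tuple(e.removed for e in iso.events))

    return sorted(isoforms, key=key)
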