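"""Synonymous codon repair of cryptic splice donors.

A donor that a tag fusion creates inside a coding region can usually be
destroyed without touching the protein: mutate a wobble position of a codon
overlapping the donor 8-mer (the archetype is GGT -> GGG at the first
glycine codon of a V5 tag, which removes the invariant GT while keeping the
glycine).  :func:`suggest_repairs` evaluates every synonymous variant of
every codon overlapping the donor window, discards any that fails to lower
the donor tier or that creates a *new* donor nearby, and returns the rest
sorted wobble-first (fewest nucleotides changed).

Every emitted suggestion is verified translation-preserving by actually
translating, not by codon-table reasoning alone.  Because a repaired
construct can still harbour other functional donors (e.g. in linker
sequence downstream of the stop), :func:`verify_repair` re-audits the whole
sequence, reporting all donors lost and gained.
"""

from __future__ import annotations

from dataclasses import dataclass

from .construct_model import DnaSeq
from .donor_scan import DonorSite, DonorTier, classify_window, scan_donors
from .orf_tools import CODON_TABLE, STOP_CODONS, translate

__all__ = [
    "RepairSuggestion",
    "RepairReport",
    "RepairError",
    "SYNONYMOUS",
    "suggest_repairs",
    "apply_suggestion",
    "verify_repair",
]


class RepairError(ValueError):
    pass


def _synonym_table() -> dict[str, tuple[str, ...]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in CODON_TABLE.items():
        by_aa.setdefault(aa, []).append(codon)
    table: dict[str, tuple[str, ...]] = {}
    for codon, aa in CODON_TABLE.items():
        table[codon] = tuple(sorted(c for c in by_aa[aa] if c != codon))
    for stop in STOP_CODONS:
        table[stop] = tuple(sorted(s for s in STOP_CODONS if s != stop))
    return table


#: codon -> synonymous alternatives (stops are synonyms of stops)
SYNONYMOUS: dict[str, tuple[str, ...]] = _synonym_table()


@dataclass(frozen=True)
class RepairSuggestion:
    """One candidate edit that weakens/destroys a donor.

    For in-frame repairs ``codon_index`` indexes codons of the fused CDS and
    old/new are 3-mers encoding the same residue.  For non-coding sites
    (``coding=False``, e.g. a donor in a linker/UTR) the edit is an
    unconstrained single-nucleotide change: ``codon_index`` is the
    nucleotide offset and old/new are single bases.
    """

    codon_index: int
    old_codon: str
    new_codon: str
    residue: str
    tier_before: DonorTier
    tier_after: DonorTier | None
    n_changes: int
    coding: bool = True
    new_sites: tuple[DonorSite, ...] = ()


@dataclass(frozen=True)
class RepairReport:
    """Whole-sequence before/after audit of a repair."""

    protein_preserved: bool
    donors_lost: tuple[DonorSite, ...]
    donors_gained: tuple[DonorSite, ...]


def _tier_at(seq: str, cut: int) -> DonorTier | None:
    if cut < 3 or cut + 5 > len(seq):
        return None
    return classify_window(seq[cut - 3 : cut + 5])


def _new_sites(
    original: str, edited: str, cut: int, flank: int, min_tier: DonorTier
) -> tuple[DonorSite, ...]:
    """Donors >= min_tier present near the repaired cut in the edited
    sequence but absent (at that cut) in the original."""
    lo, hi = max(0, cut - 3 - flank), min(len(edited), cut + 5 + flank)
    before = {(s.cut, s.tier) for s in scan_donors(DnaSeq(original), min_tier, (lo, hi))}
    after = scan_donors(DnaSeq(edited), min_tier, (lo, hi))
    return tuple(s for s in after if (s.cut, s.tier) not in before and s.cut != cut)


def suggest_repairs(
    fused_cds: DnaSeq,
    site: DonorSite,
    flank: int = 30,
    coding_end: int | None = None,
) -> list[RepairSuggestion]:
    """Synonymous edits that lower (or erase) the tier of ``site``.

    ``fused_cds`` is assumed to be in frame 0; ``coding_end`` bounds the
    coding span (default: whole sequence).  Every codon overlapping the
    donor 8-mer [cut-3, cut+5) is tried with every synonymous alternative;
    a variant is kept only if the donor tier at ``site.cut`` drops strictly
    (or vanishes), the translation is unchanged (verified by translating),
    and no new donor >= MINIMAL appears within ``flank`` nt of the window.
    Suggestions are sorted by (fewest nt changed, tier-erased first,
    5'-most codon, new codon); an empty list means no synonymous escape
    exists (e.g. a donor pinned by Met/Trp codons).

    If the site lies outside the coding span the repair is unconstrained:
    single-nucleotide edits within the donor's GT/GTAAG core are returned
    with ``coding=False``.
    """
    seq = str(DnaSeq(fused_cds))
    cut = site.cut
    end = len(seq) if coding_end is None else coding_end
    tier_before = _tier_at(seq, cut)
    if tier_before is None:
        raise RepairError(f"no donor signal at cut {cut}; nothing to repair")

    if cut + 2 > end:  # GT not (fully) inside the coding span
        return _noncoding_repairs(seq, site, flank, tier_before)

    suggestions: list[RepairSuggestion] = []
    first_codon = max(0, (cut - 3) // 3)
    last_codon = min((end // 3) - 1, (cut + 4) // 3)
    for ci in range(first_codon, last_codon + 1):
        old = seq[ci * 3 : ci * 3 + 3]
        residue = CODON_TABLE.get(old, "*")
        for new in SYNONYMOUS.get(old, ()):
            edited = seq[: ci * 3] + new + seq[ci * 3 + 3 :]
            tier_after = _tier_at(edited, cut)
            if tier_after is not None and (
                tier_before is None or tier_after >= tier_before
            ):
                continue
            if translate(DnaSeq(edited), 0) != translate(DnaSeq(seq), 0):
                continue  # belt and braces: never trust the table alone
            created = _new_sites(seq, edited, cut, flank, DonorTier.MINIMAL)
            if created:
                continue
            suggestions.append(
                RepairSuggestion(
                    codon_index=ci,
                    old_codon=old,
                    new_codon=new,
                    residue=residue,
                    tier_before=tier_before,
                    tier_after=tier_after,
                    n_changes=sum(a != b for a, b in zip(old, new)),
                    coding=True,
                    new_sites=(),
                )
            )
    suggestions.sort(
        key=lambda s: (
            s.n_changes,
            0 if s.tier_after is None else 1,
            s.codon_index,
            s.new_codon,
        )
    )
    return suggestions


def _noncoding_repairs(
    seq: str, site: DonorSite, flank: int, tier_before: DonorTier
) -> list[RepairSuggestion]:
    cut = site.cut
    suggestions = []
    core_len = 5 if tier_before >= DonorTier.MINIMAL else 2
    for pos in range(cut, min(cut + core_len, len(seq))):
        old = seq[pos]
        for new in "ACGT":
            if new == old:
                continue
            edited = seq[:pos] + new + seq[pos + 1 :]
            tier_after = _tier_at(edited, cut)
            if tier_after is not None and tier_after >= tier_before:
                continue
            if _new_sites(seq, edited, cut, flank, DonorTier.MINIMAL):
                continue
            suggestions.append(
                RepairSuggestion(
                    codon_index=pos,
                    old_codon=old,
                    new_codon=new,
                    residue="-",
                    tier_before=tier_before,
                    tier_after=tier_after,
                    n_changes=1,
                    coding=False,
                )
            )
    suggestions.sort(
        key=lambda s: (0 if s.tier_after is None else 1, s.codon_index, s.new_codon)
    )
    return suggestions


def apply_suggestion(seq: DnaSeq, suggestion: RepairSuggestion) -> DnaSeq:
    s = str(DnaSeq(seq))
    if suggestion.coding:
        i = suggestion.codon_index * 3
        if s[i : i + 3] != suggestion.old_codon:
            raise RepairError(
                f"codon {suggestion.codon_index} is {s[i:i+3]}, expected "
                f"{suggestion.old_codon}"
            )
        return DnaSeq(s[:i] + suggestion.new_codon + s[i + 3 :])
    i = suggestion.codon_index
    if s[i] != suggestion.old_codon:
        raise RepairError(f"base at {i} is {s[i]}, expected {suggestion.old_codon}")
    return DnaSeq(s[:i] + suggestion.new_codon + s[i + 1 :])


def verify_repair(
    original: DnaSeq,
    repaired: DnaSeq,
    orf_start: int,
    min_tier: DonorTier = DonorTier.MINIMAL,
) -> RepairReport:
    """Whole-sequence audit of an edit: the translation from ``orf_start``
    must be identical (hard failure otherwise), and all donor sites lost and
    gained anywhere in the sequence are reported — a repaired junction can
    still leave, or newly expose, donors elsewhere."""
    original, repaired = DnaSeq(original), DnaSeq(repaired)
    if len(original) != len(repaired):
        raise RepairError("original and repaired sequences differ in length")
    if translate(original, orf_start) != translate(repaired, orf_start):
        raise RepairError("repair changed the translated protein")
    before = {(s.cut, s.tier): s for s in scan_donors(original, min_tier)}
    after = {(s.cut, s.tier): s for s in scan_donors(repaired, min_tier)}
    lost = tuple(before[k] for k in sorted(before.keys() - after.keys()))
    gained = tuple(after[k] for k in sorted(after.keys() - before.keys()))
    return RepairReport(protein_preserved=True, donors_lost=lost, donors_gained=gained)
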