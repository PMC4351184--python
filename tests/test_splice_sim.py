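"""Isoform enumeration, provenance, and protein-consequence calling."""

import itertools

import numpy as np
import pytest

from spliceaudit.construct_model import DnaSeq, assemble
from spliceaudit.donor_scan import (
    AcceptorSite,
    DonorSite,
    DonorTier,
    annotated_acceptor_sites,
    annotated_donor_sites,
    scan_donors,
)
from spliceaudit.orf_tools import V5_METHODS
from spliceaudit.splice_sim import (
    ConsequenceClass,
    EnumerationCapError,
    SpliceError,
    SpliceEvent,
    apply_splice,
    call_consequence,
    enumerate_isoforms,
    intended_isoform,
    map_to_mature,
    rank_isoforms,
)

from conftest import random_dna


def _donor(seq: str, cut: int) -> DonorSite:
    w = seq[cut - 3 : cut + 5]
    return DonorSite(cut=cut, tier=DonorTier.CORE, context8=w)


def _mk_seq_with(donor_cuts, acceptor_cuts, length=200, seed=0):
    """Random sequence with GT planted at each donor cut and AG before each
    acceptor cut."""
    rng = np.random.default_rng(seed)
    s = list(str(random_dna(rng, length)))
    for c in donor_cuts:
        s[c], s[c + 1] = "G", "T"
    for c in acceptor_cuts:
        s[c - 2], s[c - 1] = "A", "G"
    seq = "".join(s)
    donors = [_donor(seq, c) for c in donor_cuts]
    acceptors = [AcceptorSite(cut=c, source="annotated") for c in acceptor_cuts]
    return DnaSeq(seq), donors, acceptors


def brute_force_isoforms(seq, donors, acceptors, max_events):
    """Independent subset-enumeration oracle: distinct mature sequences."""
    events = [(d, a) for d in donors for a in acceptors if d.cut < a.cut]
    matures = set()
    for k in range(0, max_events + 1):
        for combo in itertools.combinations(events, k):
            cuts_d = [d.cut for d, _ in combo]
            cuts_a = [a.cut for _, a in combo]
            if len(set(cuts_d)) != k or len(set(cuts_a)) != k:
                continue
            ivs = sorted((d.cut, a.cut) for d, a in combo)
            if any(x[1] > y[0] for x, y in zip(ivs, ivs[1:])):
                continue
            mature, pos = [], 0
            for s, e in ivs:
                mature.append(seq[pos:s])
                pos = e
            mature.append(seq[pos:])
            matures.add("".join(mature))
    return matures


class TestApplySplice:
    def test_no_events_is_identity(self):
        seq = random_dna(np.random.default_rng(0), 50)
        iso = apply_splice(seq, [])
        assert iso.mature == seq and iso.provenance == ((0, 50),)

    def test_interval_arithmetic(self):
        seq, donors, acceptors = _mk_seq_with([40], [70], length=100)
        iso = apply_splice(seq, [SpliceEvent(donors[0], acceptors[0])])
        assert len(iso.mature) == 70
        assert iso.provenance == ((0, 40), (70, 100))
        assert iso.mature == seq[:40] + seq[70:]

    def test_overlapping_events_rejected(self):
        seq, donors, acceptors = _mk_seq_with([40, 60], [80, 120], length=200)
        with pytest.raises(SpliceError, match="overlap"):
            apply_splice(
                seq,
                [
                    SpliceEvent(donors[0], acceptors[1]),
                    SpliceEvent(donors[1], acceptors[0]),
                ],
            )

    def test_non_gt_ag_interval_warns_for_core_donor(self):
        seq = DnaSeq("A" * 20 + "GTCCC" + "A" * 20)  # GT at 20, no AG end
        donor = _donor(str(seq), 20)
        acc = AcceptorSite(cut=30, source="annotated")  # seq[28:30] = AA
        with pytest.warns(UserWarning, match="not GT...AG"):
            apply_splice(seq, [SpliceEvent(donor, acc)])

    def test_model_fixture_junction_splice_joins_leucine_to_exon2(self, model_construct):
        """Junction donor -> intron-1 acceptor plus the annotated intron-2
        event joins the ORF's terminal CTT (+ the tag's retained G) to exon
        2, then exon 2 to exon 3 — checked by explicit index arithmetic."""
        seq, cmap = assemble(model_construct)
        tag_lo, _ = cmap.interval("tag")
        e2_lo, e2_hi = cmap.interval("exon2")
        e3_lo, _ = cmap.interval("exon3")
        i2_lo, i2_hi = cmap.interval("intron2")
        junction = next(s for s in scan_donors(seq) if s.cut == tag_lo + 1)
        acc = annotated_acceptor_sites(model_construct)
        d2 = next(d for d in annotated_donor_sites(model_construct, seq) if d.cut == i2_lo)
        iso = apply_splice(seq, [SpliceEvent(junction, acc[0]), SpliceEvent(d2, acc[1])])
        # manual oracle: retained = [0, tag_lo+1) + [e2_lo, i2_lo) + [i2_hi, end)
        expected = seq[: tag_lo + 1] + seq[e2_lo:i2_lo] + seq[i2_hi:]
        assert iso.mature == expected
        orf_lo, orf_hi = cmap.interval("orf")
        assert seq[orf_hi - 3 : orf_hi] == "CTT"
        j = map_to_mature(iso, orf_hi - 3)
        assert iso.mature[j : j + 4] == "CTTG"  # Leu codon + retained tag G

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_and_provenance_concatenation(self, seed):
        seq, donors, acceptors = _mk_seq_with(
            [30, 90], [60, 140], length=200, seed=seed
        )
        for iso in enumerate_isoforms(seq, donors, acceptors, max_events=2):
            removed = sum(e.length for e in iso.events)
            assert len(seq) == len(iso.mature) + removed
            assert "".join(str(seq[s:e]) for s, e in iso.provenance) == iso.mature


class TestEnumerateIsoforms:
    def test_one_donor_one_acceptor(self):
        seq, donors, acceptors = _mk_seq_with([40], [70])
        isoforms = enumerate_isoforms(seq, donors, acceptors, max_events=1)
        assert len(isoforms) == 2  # unspliced + spliced

    def test_two_donors_before_one_acceptor(self):
        seq, donors, acceptors = _mk_seq_with([30, 50], [90])
        isoforms = enumerate_isoforms(seq, donors, acceptors, max_events=1)
        assert len(isoforms) == 3

    @pytest.mark.parametrize("nd,na", [(1, 1), (2, 2), (3, 2), (4, 3)])
    @pytest.mark.parametrize("seed", range(3))
    def test_equals_bruteforce_subset_enumeration(self, nd, na, seed):
        rng = np.random.default_rng(1000 * nd + 10 * na + seed)
        length = 400
        # keep planted GT/AG signals at least 8 nt apart so none clobber each other
        cuts = sorted(rng.choice(np.arange(10, length - 10, 8), nd + na, replace=False))
        labels = list("d" * nd + "a" * na)
        rng.shuffle(labels)
        donor_cuts = [int(c) for c, l in zip(cuts, labels) if l == "d"]
        acceptor_cuts = [int(c) for c, l in zip(cuts, labels) if l == "a"]
        if not donor_cuts or not acceptor_cuts:
            pytest.skip("degenerate assignment")
        seq, donors, acceptors = _mk_seq_with(donor_cuts, acceptor_cuts, length, seed)
        got = {str(i.mature) for i in enumerate_isoforms(seq, donors, acceptors, 3)}
        assert got == brute_force_isoforms(str(seq), donors, acceptors, 3)

    def test_model_fixture_contains_both_observed_products(self, model_construct):
        """Enumeration over scanned+annotated donors reproduces both
        empirically observed products: the tag-deleted transcript and the
        full-length transcript spliced at the linker donor."""
        seq, cmap = assemble(model_construct)
        donors = {s.cut: s for s in annotated_donor_sites(model_construct, seq)}
        for s in scan_donors(seq):
            donors.setdefault(s.cut, s)
        acceptors = annotated_acceptor_sites(model_construct)
        isoforms = enumerate_isoforms(seq, sorted(donors.values()), acceptors, 3)
        tag_lo, _ = cmap.interval("tag")
        link_lo, _ = cmap.interval("linker")
        e2_lo, _ = cmap.interval("exon2")
        i2_lo, i2_hi = cmap.interval("intron2")
        tag_deleted = seq[: tag_lo + 1] + seq[e2_lo:i2_lo] + seq[i2_hi:]
        linker_spliced = seq[: link_lo + 4] + seq[e2_lo:i2_lo] + seq[i2_hi:]
        matures = {str(i.mature) for i in isoforms}
        assert str(tag_deleted) in matures
        assert str(linker_spliced) in matures

    def test_unspliced_always_first_and_order_deterministic(self):
        seq, donors, acceptors = _mk_seq_with([30, 50], [90, 150])
        a = enumerate_isoforms(seq, donors, acceptors, 2)
        b = enumerate_isoforms(seq, donors, acceptors, 2)
        assert [i.id_string() for i in a] == [i.id_string() for i in b]
        assert a[0].events == ()

    def test_cap_exceeded_raises(self):
        seq, donors, acceptors = _mk_seq_with(
            list(range(10, 50, 4)), list(range(100, 180, 4)), length=200
        )
        with pytest.raises(EnumerationCapError):
            enumerate_isoforms(seq, donors, acceptors, max_events=3, cap=50)


class TestCallConsequence:
    def test_annotated_events_isoform_is_intended(self, model_construct):
        iso = intended_isoform(model_construct)
        cons = call_consequence(iso, model_construct, V5_METHODS)
        assert cons.klass is ConsequenceClass.INTENDED
        assert cons.appended_missense == 0
        assert cons.tag_retained

    def test_junction_missplice_appends_55_residues_total_479(self, model_construct):
        """The fixture's junction-donor mis-splice: 424 native residues +
        55 missense (stop 168 nt past the junction) = 479 total, tag lost."""
        seq, cmap = assemble(model_construct)
        tag_lo, _ = cmap.interval("tag")
        junction = next(s for s in scan_donors(seq) if s.cut == tag_lo + 1)
        acc = annotated_acceptor_sites(model_construct)
        d2 = annotated_donor_sites(model_construct, seq)[1]
        iso = apply_splice(seq, [SpliceEvent(junction, acc[0]), SpliceEvent(d2, acc[1])])
        cons = call_consequence(iso, model_construct, V5_METHODS)
        assert cons.klass is ConsequenceClass.TAG_LOST_EXTENDED
        assert cons.native_retained == 424
        assert cons.appended_missense == 55
        assert cons.total_length == 479
        assert not cons.tag_retained

    def test_repaired_fixture_linker_splice_is_utr_only(self, repaired_construct):
        """Splicing at the linker donor (47 nt before the exon-1 3' end,
        downstream of the stop) leaves the protein intact: UTR_ONLY."""
        seq, cmap = assemble(repaired_construct)
        link_lo, _ = cmap.interval("linker")
        linker_site = next(s for s in scan_donors(seq) if s.cut == link_lo + 4)
        acc = annotated_acceptor_sites(repaired_construct)
        d2 = annotated_donor_sites(repaired_construct, seq)[1]
        iso = apply_splice(
            seq, [SpliceEvent(linker_site, acc[0]), SpliceEvent(d2, acc[1])]
        )
        cons = call_consequence(iso, repaired_construct, V5_METHODS)
        assert cons.klass is ConsequenceClass.UTR_ONLY
        assert cons.tag_retained
        assert cons.total_length == 438  # 424 native + 14 tag residues

    def test_orf_start_lost_reported_distinctly(self, model_construct):
        seq, cmap = assemble(model_construct)
        # a synthetic event removing the promoter and ORF start
        prom_lo, prom_hi = cmap.interval("promoter")
        gt = str(seq).find("GT")
        assert 0 <= gt < prom_hi  # fixture promoter is random: expect a GT
        donor = DonorSite(
            cut=gt,
            tier=DonorTier.CORE,
            context8=("NNN" + str(seq[: gt + 5]))[-8:] if gt < 3 else str(seq[gt - 3 : gt + 5]),
        )
        acc = annotated_acceptor_sites(model_construct)[0]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iso = apply_splice(seq, [SpliceEvent(donor, acc)])
        cons = call_consequence(iso, model_construct, V5_METHODS)
        assert cons.klass is ConsequenceClass.ORF_START_LOST


class TestRankIsoforms:
    def test_stronger_donor_tier_ranks_first(self, model_construct):
        seq, cmap = assemble(model_construct)
        donors = {s.cut: s for s in annotated_donor_sites(model_construct, seq)}
        for s in scan_donors(seq):
            donors.setdefault(s.cut, s)
        acceptors = annotated_acceptor_sites(model_construct)
        ranked = rank_isoforms(enumerate_isoforms(seq, sorted(donors.values()), acceptors, 2))
        top = ranked[0]
        assert top.events  # unspliced never outranks a GGTAAG-class splice
        assert max(e.donor.tier for e in top.events) == DonorTier.GGTAAG_CLASS
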