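# Methods

## Scope and model

`spliceaudit` models one concrete, empirically documented failure mode of
expression constructs: an in-frame 3′ epitope-tag fusion creates a
functional splice donor at the CDS–tag junction, and any downstream splice
acceptor (e.g. from natural 3′ genomic elements retained in the construct)
lets the cell excise the tag and stop codon from the pre-mRNA. The package
treats the construct as a single-stranded, sense-orientation, linear
sequence — the pre-mRNA the transcribing cell sees. Reverse-strand signals,
circular topology, trans-splicing and recursive splicing of mature products
are out of scope.

## Donor model: tiered exact patterns, not a trained score

Donor signals are classified from the 8-mer context around the exon|intron
cut (3 exonic + 5 intronic nt) into four nested tiers:

| tier | pattern | meaning |
|---|---|---|
| CONSENSUS | `(A/C)AGGTAAG` | minimal consensus donor |
| GGTAAG_CLASS | `NNGGTAAG` | the class a V5-type fusion creates (`TTGGTAAG`) |
| MINIMAL | `NNNGTAAG` | bare GTAAG intron start |
| CORE | `NNNGT...` | any GT; reported only on request |

This is deliberately not a position-weight matrix or neural-network score:
the phenomenon being audited is defined by observed functional sites and the
printed consensus, and shipping invented weights would imply quantitative
confidence the tool does not have. A user-supplied log-odds PWM can be
layered on via `donor_scan.score_pwm`; no default matrix is shipped.
Windows containing N never match (ambiguity disqualifies rather than
wildcards), and windows truncated by sequence ends never match — a donor
needs its full context. Default reporting tier is MINIMAL; CORE floods
output on random sequence (one GT per ~16 nt) and must be requested
explicitly.

Acceptors are normally *annotated* (derived from canonical GT...AG introns
declared in the construct spec); a heuristic polypyrimidine-tract scanner
(`scan_acceptors`, AG preceded by ≥ 12 C/T in 20 nt by default) exists for
unannotated sequence but is off in all default workflows, because acceptor
prediction from primary sequence is far less reliable than donor pattern
matching and the audit's job is conservative enumeration against known
acceptors.

## Isoform enumeration and consequence calling

`enumerate_isoforms` generates every event set of ≤ `max_events` (default 3)
splices in which each donor and acceptor is used at most once, donor
precedes acceptor, and removed intervals are pairwise disjoint, then
deduplicates by mature sequence. The unspliced isoform is always included.
Exceeding the hard cap (10,000 isoforms) is an explicit error, never silent
truncation. The tool enumerates rather than predicts: which donor a
spliceosome prefers was established empirically in the motivating work, and
no quantitative splice-strength model is available, so isoforms are *ranked*
(strongest donor tier, then fewest events) instead of scored.

Protein consequences are called against the *intended* product — the
translation of the isoform carrying exactly the annotated intron events —
with classes INTENDED, UTR_ONLY (same protein, different mRNA), 
TAG_LOST_EXTENDED (native ORF intact, tag peptide absent, missense
extension; the hallmark failure), EXTENDED, TRUNCATED, NO_STOP, and
ORF_START_LOST (splicing removed the ORF start; reported distinctly rather
than folded into NO_STOP). For extension classes,
`total_length = native_retained + appended_missense`, where
`appended_missense` counts all residues past the untagged native ORF.

## Synonymous repair

`suggest_repairs` evaluates every synonymous variant of every codon
overlapping the donor 8-mer. A variant is emitted only if (a) the donor tier
at the repaired cut drops strictly or vanishes, (b) the full translation is
unchanged — checked by translating, never by codon-table reasoning alone —
and (c) no new donor ≥ MINIMAL appears within ±30 nt (configurable flank).
Suggestions sort wobble-first (fewest nucleotides changed), then
donor-erased before donor-weakened, then 5′-most codon, then alphabetically
by new codon, making the list deterministic. Donors outside the coding span
(linker/UTR) are unconstrained; they get single-nucleotide edits flagged
`coding=False`. Because a repaired junction can leave other functional
donors elsewhere (the motivating repair did — a linker donor took over,
harmlessly, downstream of the stop), `verify_repair` re-audits the entire
sequence and reports every donor lost and gained.

## Library screen

`batch_screen` reproduces the transcriptome-scale question "how many CDSs
would create a donor when V5-tagged?" Two junction definitions are shipped
because they genuinely differ and the historical record is ambiguous about
which was used:

- **methods-10mer** (default): literal comparison of the junction 10-mer
  (last CDS nt + first 9 tag nt) against `AGGTAAGCCT` / `TGGTAAGCCT`. For a
  V5-type tag this depends only on the final CDS nucleotide, so uniform
  composition predicts 1/4 consensus-class and 1/4 DUX4-like.
- **minimal-8mer**: tier classification of the junction 8-mer (last 2 CDS nt
  + first 6 tag nt). Consensus class requires terminal dinucleotide AA/CA
  (expected 2/16 under uniform composition); the DUX4-like class is the
  literal `TTGGTAAG` (terminal TT, 1/16).

Real CDS libraries are neither uniform nor version-stable, so the shipped
tests assert the analytic expectations on synthetic uniform-composition
libraries (99% binomial interval at n = 10,000) rather than any particular
database snapshot. Invalid CDSs (no terminal stop, internal stop, ambiguity
codes, frame violations) are counted with reasons, never dropped.

## Digest diagnostics

`digest_diag` matches IUPAC recognition patterns on the sense strand
(overlapping matches all reported) and cleaves linear sequences at each
site's cut offset; fragments always sum to the input length. BsaAI ships
twice: `BsaAI_paper` is the literal `TACGTG` as historically printed,
`BsaAI_iupac` is the enzyme's accepted degenerate site `YACGTR` (both blunt,
cut after nt 3); reports name the definition used. Electrophoretic mobility
is not modeled — the tool predicts fragment sizes, not gel positions.

## Synthetic fixtures: what they emulate and what they do not

The full sequence of the motivating vector is not printed in any public
text, so `fixtures` reproduces its *geometry* exactly and its sequence
content synthetically:

- 424-codon native ORF starting ATG and ending the leucine codon `CTT`;
- V5 tag + TGA stop (TGA chosen because it is the natural stop following
  `...CTT` in the modeled gene, and because with the canonical `...ACG`
  V5 flavour it completes the tag-resident `TACGTG` BsaAI site);
- 40-nt linker with a second `GGTAAG` donor whose cut falls 47 nt before
  the exon-1 3′ end (linker offset 4 at defaults);
- 11-nt exon-1 UTR; two canonical GT...AG introns (200/150 nt) flanking a
  100-nt exon 2; an exon 3 whose first in-frame stop on the mis-spliced
  path sits exactly 168 nt past the ORF–tag junction (the junction splice
  retains the tag's first G, so the missense path is G + exon 2 + exon-3
  head, and appended residues = 168/3 − 1 = 55); and a polyA segment
  beginning with the non-canonical signal `ATTAAA`.
- Segment lengths the source geometry does not fix (60-nt promoter, 120-nt
  exon 3, 30-nt polyA) were chosen once as small-but-realistic placeholders
  and are parameters, not constants.

Backgrounds are uniform over ACGT, and whole assemblies are
rejection-sampled (not masked) until they contain *only* the planted donors
at tier ≥ MINIMAL and no recognition sites outside the tag, so scanner
results on fixtures are exact by construction. The natural intron donors
are left as bare-GT (CORE-tier) signals, mirroring the observation that the
natural exon-1 donor is the weakest site in the system. Everything is
deterministic per seed (numpy `default_rng`).

What fixtures do **not** emulate: real promoter/ORF base composition and
codon usage, RACE adaptor chemistry, splice-strength differences beyond the
tier ordering, and the true vector sequence. Tests passing on fixtures
therefore demonstrate the *logic* of detection, simulation, repair and
digest prediction under controlled composition — not recall on arbitrary
genomic sequence, where additional weak donors will be reported and must be
triaged by the user.

## Numerical and interface conventions

Coordinates are 0-based half-open internally; 1-based closed only in
human-readable reports. Stop codons are TAA/TAG/TGA, standard genetic code
only (expression constructs). FASTA is 60-column wrapped; lowercase and U
are normalized on ingest, other IUPAC ambiguity codes collapse to N with a
warning, and non-IUPAC characters are errors. Two V5 flavours ship because
printed sources disagree on the tag's last codon (`...TCT AGC`, peptide
...DSS, used verbatim for the screen default; `...TCT ACG`, ...DST,
matching the canonical epitope and carrying the BsaAI site): their shared
5′ end makes junction behaviour identical, and no attempt is made to guess
which was intended — both are available as `V5_methods` and `V5_canonical`.

## Problem sizes used in the shipped checks

Oracle-equivalence checks run the scanner and site-finder against
brute-force regex/IUPAC oracles on 100 random 10-kb sequences, the window
classifier exhaustively over all 4^8 windows, isoform enumeration against
subset enumeration on all donor/acceptor counts up to 4×3, digest
conservation on 1,000 random inputs, and the screen composition check on
10,000 synthetic CDSs. These sizes were picked so the whole suite settles
in seconds while leaving the combinatorial spaces fully covered where
exhaustion is feasible (the 8-mer classifier, the 16 terminal
dinucleotides).

## Known limitations

- Donor detection is pattern-based; a site matching no tier can still be
  used by a spliceosome, and a GGTAAG-class site can be silent. The tool
  over-reports by design and cannot rank true usage.
- Acceptor discovery is heuristic and off by default; constructs without
  annotated introns get no acceptors and hence no isoforms beyond the
  unspliced one.
- Consequence calling assumes frame-0 translation from `orf_start` and the
  standard code; internal ribosome entry, frameshifting and non-AUG starts
  are not modeled.
- Repair only considers single-codon synonymous edits (plus single-base
  edits outside coding sequence); donors pinned by Met/Trp codons yield an
  empty suggestion list with a diagnostic rather than multi-codon recoding.
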