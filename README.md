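# spliceaudit

Vet expression constructs for cryptic splice donors created by in-frame
epitope-tag fusions — before the construct goes into cells, vectors, or
animals.

## The problem

Expression constructs increasingly carry natural genomic elements
(untranslated exons, small introns, native polyA signals) downstream of the
cDNA, and epitope tags fused in frame to the ORF's 3′ end. Those two design
choices can interact badly. The V5 tag's coding sequence begins
`GGT AAG ...`; fused after a leucine codon (`...CTT`), the junction reads
**`TTGGTAAG`** — one mismatch away from the minimal splice-donor consensus
**`(A/C)AGGTAAG`**. If any functional splice acceptor lies downstream, the
spliceosome can use the fusion-created donor and excise the tag *and the
stop codon* from the mRNA. Translation then runs on into sequence that was
never meant to be coding: in the motivating case, a 424-residue protein
gained 55 missense residues (479 aa total, first in-frame stop 168 nt past
the junction) and lost its function. The fix was a single wobble edit:
mutating the tag's first glycine codon `GGT → GGG` keeps the glycine but
destroys the invariant GT.

`spliceaudit` turns that failure mode into a checklist:

- **detect** donor signals with a tiered exact-pattern scanner
  (`CONSENSUS (A/C)AGGTAAG ⊃ GGTAAG-class NNGGTAAG ⊃ MINIMAL GTAAG ⊃ CORE GT`);
- **simulate** every donor–acceptor-consistent splice isoform and classify
  each protein product (intended / UTR-only / tag-lost-extended / extended /
  truncated / no-stop);
- **repair** donors with synonymous codon edits, verified by translation and
  re-scanned for newly created donors;
- **screen** whole CDS libraries (e.g. CCDS-style FASTA) for tag-fusion
  junctions that create donors;
- **predict diagnostic digests**: a tag-resident restriction site (BsaAI
  `TACGTG` in V5) makes correctly spliced products cut while tag-deleted
  mis-spliced products run as a single resistant band.

## Worked example

Everything runs on deterministic synthetic fixtures that reproduce the
geometry of the motivating vector (no downloads needed):

```python
from spliceaudit import *
from spliceaudit.donor_scan import annotated_donor_sites, annotated_acceptor_sites

construct = make_model_construct(ModelConstructParams(seed=1))
seq, cmap = assemble(construct)

for site in scan_donors(seq):
    print(f"donor at {site.cut} ({cmap.segment_at(site.cut)}): "
          f"{site.context8} [{site.tier.name}]")

junction = scan_donors(seq)[0]
acceptors = annotated_acceptor_sites(construct)
intron2 = annotated_donor_sites(construct, seq)[1]
iso = apply_splice(seq, [SpliceEvent(junction, acceptors[0]),
                         SpliceEvent(intron2, acceptors[1])])
cons = call_consequence(iso, construct, V5_METHODS)
print(f"consequence: {cons.klass.value}, native={cons.native_retained}, "
      f"appended={cons.appended_missense}, total={cons.total_length} aa")
```

prints

```
donor at 1333 (tag): TTGGTAAG [GGTAAG_CLASS]
donor at 1381 (linker): TCGGTAAG [GGTAAG_CLASS]
consequence: TAG_LOST_EXTENDED, native=424, appended=55, total=479 aa
```

Read: the scanner finds the fusion-created junction donor (`TTGGTAAG`,
inside the tag segment) plus a second donor in the linker. Splicing from the
junction donor to the intron-1 acceptor (with intron 2 also removed)
deletes the tag and stop; the consequence caller reports the full native
protein (424 aa) extended by 55 missense residues to 479 aa — the tag is
gone from the product.

Repair is one call:

```python
fused = fuse_tag(DnaSeq("ATG" + "GCA"*8 + "CTT"), V5_METHODS)
print(fused.window)                                   # CTTGGTAAGC
site = scan_donors(fused.fused_cds)[0]
for s in suggest_repairs(fused.fused_cds, site)[:3]:
    print(s.old_codon, "->", s.new_codon, s.residue, s.tier_after)
```

Every suggestion is a synonymous edit (here `GGT → GGA/GGC/GGG`, all
glycine) that removes the donor and creates no new one nearby;
`verify_repair` re-audits the whole sequence for donors lost and gained.

The same pipeline is scriptable from a shell:

```bash
spliceaudit fixtures --model --seed 1 --out-dir fx
spliceaudit simulate --spec fx/model_d4z4.tsv --out-dir sim
spliceaudit repair   --spec fx/model_d4z4.tsv --out-dir rep
spliceaudit screen   --cds my_cds_library.fasta --mode minimal-8mer --out-dir scr
spliceaudit digest   --fasta sim/isoforms.fasta --gel --out-dir dig
```

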