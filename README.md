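# pseudocasp

Gene-structure forensics for pseudogene detection, built around the
evolutionary anatomy of primate caspase-16: splice-phase computation,
ortholog-guided frameshift and premature-stop detection, exon-skipping
frame-rescue evaluation, rescue-ORF mapping, catalytic-dyad conservation
checks, and intragenic domain-duplication detection with exon attribution
— plus a synthetic caspase-16-like locus generator with known truth, so
every stage is testable without downloading anything.

## Who this is for

Molecular evolution researchers asking *how* a gene died: a candidate
pseudogene and an intact ortholog go in; out comes the disabling lesion,
its reading-frame consequence, whether any single-exon-skip isoform or
internal start codon could rescue a product, whether the catalytic
residues survive, and a verdict (`intact` / `pseudogene` /
`truncated_coding`) with the evidence chain. A second analysis detects
intra-protein domain duplication (a prodomain that is a degenerate copy
of the protein's own catalytic domain) by off-diagonal self-alignment
with permutation significance, attributes it to exons, and corroborates
it with splice-phase signatures.

## The core quantities

For a gene with exons *e₁…eₙ* and coding lengths *cᵢ*, the **end phase**
of exon *k* is `(Σᵢ≤k cᵢ) mod 3`; a junction interrupts a codon after
that many nucleotides. Skipping exon *k* restores the reading frame iff
the phases flanking the new junction match — equivalently `cₖ ≡ 0
(mod 3)` — and no frame-shifting lesion remains outside it. A
frame-shifting indel of length *L* (`L mod 3 ≠ 0`) shifts all downstream
codons; the premature stop is the first stop triplet in the shifted
reading, reported as the number of complete triplets downstream of the
disrupted codon (stop inclusive). Alignment is Needleman–Wunsch /
Smith–Waterman with Gotoh affine gaps (cost `open + (L−1)·extend`),
implemented from scratch and verified against exhaustive enumeration;
duplication significance is a composition-preserving residue-shuffle
permutation test.

## Worked example

Generate a disabled gene with known truth and analyse it:

```bash
pseudocasp synth --seed 1 --scenario human-casp16p --out demo/
pseudocasp forensics \
    --gene demo/query_gene.gff3 --genome demo/query_locus.fasta \
    --ortholog-cds demo/ortholog_cds.fasta \
    --ortholog-protein demo/ortholog_protein.fasta \
    --ref-his 227 --ref-cys 286 --domain-start 197 --domain-end 416
```

prints

```
gene CASP16LIKE: PSEUDOGENE
  CDS identity to ortholog: 99.92%
  deletion of 1 nt after reference position 298 (frame shift 1)
  - frameshift (deletion of 1 nt after reference position 298) with premature stop 6 triplets downstream; truncated product of 105 aa
  - no single-exon skip restores the reading frame: skip exon 3 joins end phase 0 to start phase 1
  - rescue ORF starts at reference residue 270, inside the catalytic domain (197-416): incomplete domain
```

Reading the output: a single-nucleotide deletion in exon 3 shifts the
reading frame and terminates translation at the 6th triplet downstream,
truncating the 416-residue protein to 105 residues. Skipping exon 3
would remove the lesion, but exon 2 ends in splicing phase 0 while exon 4
begins in phase 1, so the exon-2/exon-4 junction is itself out of frame.
The only ATG in frame with the catalytic domain sits in exon 7 and its
ORF maps inside the catalytic-domain window (residues 197–416 of the
intact ortholog), so no complete protease domain can be made: the gene is
a pseudogene. The same chain is available as a library call
(`pseudocasp.run_forensics`) returning a structured report with JSON
serialization.

The duplication analysis on the same protein:

```python
>>> import pseudocasp as pc
>>> seq, model, truth = pc.generate_caspase16_like_locus(1)
>>> hits = pc.self_compare(truth.derived_protein, n_permutations=1000, seed=1)
>>> hits, table = pc.map_exon_homology(hits, model, truth.derived_protein)
>>> h = hits[0]
>>> h.query_span, h.subject_span, round(h.identity_pct, 1), h.empirical_p
((7, 195), (203, 415), 61.4, 0.000999000999000999)
>>> h.query_exons, h.subject_exons
((2, 3, 4, 5), (6, 7, 10, 11))
```

The protein's N-terminal region (exons 2–5) is a significantly similar,
degenerate copy of its catalytic domain (exons 6–7 and 10–11, with the
linker exons 8–9 bridged by a gap) — the prodomain arose by duplication
of the exons encoding the catalytic domain.

## Layout

| module | contents |
|---|---|
| `pseudocasp.sequence_core` | sequence types, FASTA I/O, conceptual translation |
| `pseudocasp.gene_models` | exon/CDS models, splice phases, transcript assembly, GFF3 I/O, synteny check |
| `pseudocasp.pairwise_align` | affine-gap global/local alignment, percent identity, indel calling |
| `pseudocasp.pseudogene_forensics` | PTC location, exon-skip evaluation, rescue ORFs, dyad check, classification |
| `pseudocasp.domain_duplication` | self-comparison, permutation test, exon attribution, phase signatures |
| `pseudocasp.synthetic_data` | truth-manifest locus generator, lesion scenarios, ortholog divergence |

See `docs/methods.md` for conventions, algorithms, design decisions and
limitations. The package operates on standard FASTA and GFF3; real loci
(e.g. the caspase-16 region of any annotated primate assembly) can be
analysed by supplying the gene model, genomic sequence, and an intact
ortholog CDS/protein to `pseudocasp forensics`.
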