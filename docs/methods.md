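# Methods

`pseudocasp` is a gene-structure forensics toolkit for a specific class of
molecular-evolution question: given a candidate pseudogene and an intact
ortholog, reconstruct *how* the gene lost its coding capacity — where the
disabling lesion sits, what it does to the reading frame, whether any
alternative-splicing isoform or internal start codon could rescue a
functional product, and whether the residues required for catalysis
survive. A second component detects intragenic domain duplication — a
protein whose N-terminal region is a degenerate copy of its own C-terminal
domain — and attributes the duplication to exons, supported by
splice-phase signatures. The motivating system is the primate caspase-16
gene (an 11-exon caspase whose prodomain arose by duplication of the
exons encoding the catalytic domain, and which was inactivated in one
lineage by a single-nucleotide deletion), but every analysis is generic
over gene models.

## Coordinate and phase conventions

* Internal coordinates are 0-based half-open; everything file-facing and
  report-facing is 1-based inclusive (GenBank/GFF3 convention).
* The **end phase** of an exon is the cumulative coding length through
  that exon, mod 3. End phase 0 means the exon's last nucleotide is the
  third position of a codon; start phase 1 means one nucleotide of the
  interrupted codon lies upstream. The GFF3 `phase` column (nucleotides
  to the next codon start) equals `(3 − start_phase) % 3`; tabular output
  reports both to avoid ambiguity.
* Exon ordinals are 1-based in transcription order.

## Conceptual translation

Translation uses the standard genetic code only (the genes in scope are
nuclear); codons containing `N` yield `X`. Translation-to-stop products
never contain `*`; full-window conceptual translations (used for
catalytic-residue checks on damaged genes) render internal stops as `X`.
The translation length law `3·(len(peptide) + stop_found) + trailing_nt =
translated nt` is enforced and property-tested. Ambiguity codes other
than `N` are rejected at parse time to keep translation deterministic.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment with the
Gotoh three-state affine-gap recursion is implemented in-package (the DP
fill is a numba kernel; traceback re-derives predecessors in Python). A
gap of length L costs `gap_open + (L−1)·gap_extend`. Default scoring
follows the common tools' conventions: nucleotide +2/−3 with gaps 5/2,
protein BLOSUM62 with gaps 11/1; all parameters are configurable. The
traceback tie-break is fixed (diagonal, then gap-in-b, then gap-in-a), so
results are deterministic. Scores are held in float64 (float32 for very
large problems); with integer-valued parameters they are exact.

Correctness is checked against brute-force enumeration of *all*
alignments (global: every 2-letter sequence pair to length 6; local: every
pair to length 5 plus sampled pairs to length 8), an oracle that shares no
code with the DP.

**Known limitation.** When co-optimal alignments exist, the deterministic
traceback is not symmetric under swapping the inputs, so percent identity
(which depends on the chosen alignment) is guaranteed swap-invariant only
when the optimum is unique — always the case for the high-identity
comparisons this package targets. The optimal *score* is always
symmetric.

Indel calling merges maximal gap-column runs into events positioned on a
designated reference sequence and left-aligns each event through repeat
runs (the same normalization the synthetic generator applies to its truth
records, so coordinates are comparable). A substitution immediately
adjacent to an indel can make two gap placements co-optimal; exact
coordinate recovery is therefore benchmarked on indel-only divergence
runs, and mixed runs are exercised at fixed seeds.

## Pseudogene forensics

The forensic chain compares the query CDS to an intact ortholog CDS
(global alignment → indel events with the ortholog as the coordinate
reference), then:

* **Premature stop location.** The query transcript is translated from
  the annotated start; the first stop after the first frame-shifting
  event is the PTC. `codons_downstream_to_stop` counts complete triplets
  strictly after the codon disrupted by the event, with the stop triplet
  counted as the terminating ordinal. Truncation lengths count the
  initiator methionine as residue 1 and exclude the stop. A premature
  stop with no frameshift (a nonsense substitution) is reported with no
  causal indel; compensating indels whose translation reaches the
  annotated terminal stop raise "no premature stop".
* **Exon-skip evaluation.** Phases are computed from the *pre-lesion*
  coding lengths (query lengths corrected by the called indels), i.e. in
  the conserved ortholog frame — this is what makes "exon 2 ends in phase
  0, exon 4 begins in phase 1" a property of the gene architecture rather
  than of the broken query reading. A skip restores the frame iff the
  flanking phases match (equivalently, the skipped exon's pre-lesion
  coding length is ≡ 0 mod 3) and no frame-shifting event remains outside
  the skipped exon. Each verdict is cross-validated by conceptual
  translation of the skip isoform; the two can legitimately differ in two
  corners, which the verdict definition resolves as follows: (a) a
  substitution-created stop is invisible to frame arithmetic (the
  translation oracle catches it; a warning is emitted); (b) skipping a
  *different* exon whose length cancels the lesion's shift lets
  translation read through a garbled middle stretch to the terminal stop
  — `frame_restored` stays False because the lesion remains. Only
  single-exon skips are evaluated by default; multi-exon enumeration is
  available behind a flag.
* **Rescue ORF.** The spliced transcript is scanned 3′ of the premature
  stop for ATG codons in the ortholog-defined downstream frame (the frame
  is identified empirically as the one whose conceptual translation of
  the post-stop region aligns best to the reference protein). The
  earliest such ATG is translated to the next stop and mapped onto the
  reference protein with a *local* alignment — the ORF is a fragment of
  the reference, and a strict global alignment with penalized end gaps
  would misplace short fragments. For an intact gene the annotated CDS is
  returned with reference start 1.
* **Catalytic dyad.** Alignment-anchored, not motif-based: the reference
  His/Cys positions are mapped through a global protein alignment and a
  position is reported only when the aligned query residue is H
  (respectively C). For frameshifted queries the check runs on a
  frame-corrected conceptual translation (deleted stretches re-inserted
  as N → X, insertions removed), so intact dyad codons downstream of a
  lesion are still recognized as intact sequence.
* **Classification.** `intact` = no premature stop and dyad conserved.
  `pseudogene` = a premature stop that no single-exon skip repairs
  (repair requires restoring the frame *and* removing the lesion) and
  that no rescue ORF starting upstream of the catalytic-domain window can
  bypass — or loss of the dyad. Everything else is `truncated_coding`.
  The catalytic-domain window is an input parameter (its endpoints are
  assembly-specific); the rescue ORF "precludes a complete domain" when
  it starts strictly inside that window.

## Domain duplication

Self-comparison runs Smith–Waterman on the protein against itself
restricted to the strict upper triangle of the matrix, which excludes the
trivial self-diagonal; hits must have non-overlapping query/subject spans
(a split-point rescan resolves the rare overlapping path). Hits shorter
than `min_len` (default 20 residues) are discarded. Hit identity is
reported over aligned residue pairs (gap columns excluded), so a
duplication bridged by an internal deletion — such as a prodomain copy
that never contained the linker — can still be 100% identical.

Significance is a composition-preserving residue-shuffling permutation
test (default 1000 permutations, seed required): the statistic is the
best upper-triangle self-alignment score, and `empirical_p` uses the
standard conservative estimator `(1+g)/(n+1)`. Because alignment scores
are discrete, that estimator is stochastically slightly above uniform
under the null; `permutation_pvalue(..., randomized=True)` provides the
exactly-uniform randomized-tie construction used for distributional
calibration.

Exon attribution intersects a hit's aligned columns with the per-exon
peptide segmentation (junction-spanning codons belong to the exon
contributing ≥ 2 of 3 nucleotides, so segments tile the protein exactly
once). An exon enters the correspondence only if its aligned columns are
**self-supporting**: at least `min_columns` (default 4) aligned pairs
whose summed substitution score exceeds the two gap openings that
excising the segment would cost. This keeps out exons merely crossed by
the alignment path — a handful of chance columns across a linker can be
cheaper than a longer gap without constituting homology.

Phase-signature comparison computes, per gene pair, the longest common
subsequence of coding-junction end phases with an aligned junction
listing — the sequence-free line of evidence for exon origin, since
duplicated exons carry their junction phases with them.

## Synthetic data

The generator builds an ancestral 8-exon caspase-1-like gene (leader
exon, two prodomain exons, two large-subunit exons, one linker exon, two
small-subunit exons) and derives an 11-exon caspase-16-like gene by the
duplication plan *large+small exons copied 5′-ward as a new prodomain,
linker duplicated in place*. Defaults (coding lengths 198/130/127/133 for
the duplicated block, 36 nt linker) are chosen so that exon 2 ends in
phase 0 and exon 4 begins in phase 1 — the junction asymmetry that makes
the exon-3 skip fail — and so that the duplicated block preserves its
phase subsequence. Coding sequence is drawn uniformly from the 61 sense
codons (no codon-usage bias is modelled), noncoding sequence at a
configurable GC content, introns are GT…AG. The catalytic His/Cys sit in
fixed pentapeptide contexts in the large-subunit exons (derived-protein
residues 227 and 286 under the defaults); at nonzero copy divergence the
copy's dyad is knocked out, matching the degenerate-prodomain biology.
Copy divergence substitutes the stated fraction of the copy's codons with
sense codons for different residues; at divergence 0 the copy is exact
(block-boundary bases are pinned so the copy translates identically to
the catalytic domain around the linker gap).

At nonzero divergence the generator also primes the canonical lesion
anatomy: deleting the nucleotide after coding position 100 of exon 3
meets its first out-of-frame stop exactly in the 6th downstream triplet
(truncating the product to 105 residues, measured from Met = residue 1),
the deleted base differs from its left neighbour so the left-aligned
indel call has a single canonical coordinate, and the only downstream
in-frame ATG is planted in exon 7. All edits provably keep the in-frame
reading stop-free (a forced middle-position C can never create a stop).
Named lesion scenarios (`human-casp16p`, `in-frame-deletion`,
`dyad-knockout`, `stop-substitution`, `compensated-double-indel`) record
their expected consequences in the truth manifest by *direct simulation*
— conceptual translation of the lesioned gene and its skip isoforms, ATG
scanning in the terminal-stop frame — independently of the
alignment-based pipeline the scenarios are used to test. Everything is
deterministic under the seed; regeneration is byte-identical.

Ortholog divergence applies per-site substitutions (always to a different
base, so expected identity is exactly `100·(1−p_sub)`) and non-overlapping
indels of length 1–3 with left-aligned truth coordinates; supplied
intervals (e.g. dyad codons) are never mutated.

The random gene models used by the frame-law suites have arbitrary-phase
junctions and are resampled when a single-exon skip would create a stop
codon in the chimeric junction codon: the frame law concerns reading-frame
arithmetic, and incidental stop creation at an artificial junction is
outside its domain. Models are generated on the plus strand and reflected
onto the minus strand after lesioning (lesions are expressed in
plus-strand coordinates).

**What passing tests do and do not show.** The generator emulates gene
architecture, frame arithmetic and controlled sequence divergence; it does
not model codon-usage or substitution-rate heterogeneity, splice-site
sequence signals, alignment-confounding repeats, or sequencing error.
Results on synthetic loci validate the logic of the pipeline, not its
robustness to annotation errors or low-complexity sequence in real
genomes.

## Problem sizes

The default verification suite uses: exhaustive alignment enumeration to
length 6 (global) / 5 (local) with sampled pairs to length 8; 1000 random
gene models for the frame law; 100 generator seeds at 40% copy divergence
for duplication recovery; 500 null proteins × 200 permutations for
p-value calibration; and 10 kb sequences at 2% substitution divergence
for ortholog identity and indel recovery.
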