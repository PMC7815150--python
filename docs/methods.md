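# Methods

## Problem and model

Insect olfactory receptors (ORs) sit in tandem genomic arrays and diverge
quickly, so homology evidence arrives as many redundant spliced
protein-to-genome alignments per locus, often fragmented where a real
intron exceeded the aligner's intron cap, and with fragment boundaries
wrongly extended into introns. `orannot` models annotation as a
deterministic reduction of that alignment set:

* **Coverage and islands.** For each scaffold a per-base counter counts
  covering *exon segments* (introns inside an alignment contribute
  nothing). Maximal runs of positive count are islands. Exon-only coverage
  is what keeps a chimeric alignment that spans two neighbouring genes from
  fusing their islands: the intergenic gap it jumps carries no exon
  evidence. A consequence is that one multi-exon gene produces one island
  per exon cluster; islands are locus *candidates*, and gene integrity is
  restored by the best-query step, which groups all fragments of the
  winning query across the scaffold.
* **Best query.** Per island the supporting alignment with maximal aligner
  score wins; ties break by query id (lexicographic) then leftmost start,
  purely for determinism. Only winning queries' alignments proceed.
* **Congruence.** Two same-query fragments can belong to one gene iff they
  are on the same strand, their target order matches their query order for
  that strand, and their query spans are not nested. Sorted fragments are
  greedily chained while congruent; each chain becomes one candidate model.
* **Stitching.** For adjacent fragments overlapping by k aa, the upstream
  fragment's last exon ends with the 3k-nt image of the overlap residues
  and the downstream fragment's first exon starts with another image of the
  same residues. Every donor offset d ∈ {0,…,3k} (nucleotide granularity,
  so phase-1/2 introns are representable) splits the overlap as d upstream
  + (3k−d) downstream nucleotides. A candidate is valid when the upstream
  cut is immediately followed by `gt`, the downstream cut immediately
  preceded by `ag` (both on the coding strand), the implied intron is ≥ 30
  nt, and neither exon is emptied. Valid candidates are scored by summed
  BLOSUM62 similarity between the translated 3k-nt window and the query's
  overlap residues; the maximum wins, ties to the leftmost donor. If no
  candidate is valid the junction stays open and the fragments are reported
  as separate models flagged `unstitched_junction`. Minus-strand chains are
  processed in reverse-complement coordinates and mapped back, so the
  splice motifs and translation are always evaluated on the coding strand.
* **Isoform rule.** Two models whose regions overlap are both kept
  (putative isoforms / duplicated exons) when the overlap is below 20 % of
  *both* models' regions; otherwise the better model wins by completeness,
  protein length, non-pseudogenous status, then START presence. For models
  of the same query the overlap fraction is computed on query residue
  spans; for different queries, on shared exonic bases.
* **Refinement (optional).** Each P1 model's span, extended per side by
  min(span length, 6000 nt) — 6000 being an empirical insect intergenic
  distance — can be handed with its query to an external GeneWise-class
  predictor. The adapter is a subprocess contract (`exe target.fa
  query.fa`, GFF-style rows out); any failure degrades to P1-only. An
  overlapping P1/P2 pair (shared exonic bases, same strand) resolves by the
  same ranking, exact ties to P2.
* **Finalization.** If the CDS does not begin with ATG, the nearest
  in-frame upstream ATG within 20 codons is taken, provided no in-frame
  stop intervenes (minimal extension; the window size is the convention,
  the nearest-ATG tie-break is this package's choice). If the CDS does not
  end with a stop, the first stop codon within 20 downstream codons extends
  the last exon; the search never crosses a scaffold end. Internal `*` in
  the translation flags `inframe_stop`; CDS length ≢ 0 (mod 3), or indel
  arithmetic already seen in the alignment, flags `frameshift`. Completeness
  is purely a length rule: protein (excluding terminal stop) ≥ 300 aa by
  default. Names encode location, strand, serial and flags:
  `scaf1:8549-12325(+)OR2-NTE-PSE-P` (`NTE` no start, `PSE` pseudogenous,
  `P` partial). Finalization only extends or labels; it never shortens.

## Evaluation semantics

The evaluator mirrors transcript-accuracy practice: at **base** level TP =
exonic bases shared on the same strand; at **exon** level unique exon
intervals are matched one-to-one — internal boundaries exact, a
transcript-terminal free end may deviate by ≤ e nt (default e = 10) — with
the one-to-one assignment computed as a maximum bipartite matching, which
makes TP counts symmetric under prediction/reference swap; at **locus**
level transcripts are clustered by exonic overlap and a reference locus is
TP when some predicted transcript fully matches one of its transcripts
(identical intron chain, terminal ends within e). Because one predicted
locus can match two reference loci, precision uses the predicted-side
match count. Missed/novel exons and loci are zero-overlap counts.
Percentages are rounded half-up to one decimal.

## Synthetic data

The generator emulates the input regime the pipeline is designed for:
random-background scaffolds (uniform ACGT) with tandem, ATG-initiated,
stop-terminated genes of 4–9 exons (the Hymenopteran OR exon-count range),
25–60 aa exons, `gt…ag` introns of 40–1500 nt (respecting the ≤ 2000 nt
cap), 300–1000 nt intergenic gaps, and ~30 % minus-strand genes. Redundancy
comes from decoy queries (mutated copies, 10 % substitutions, always
scoring below the self alignment); fragmentation splits a gene's alignment
at one intron with a k-aa query overlap, each boundary extended ~3k/2 nt
into the intron, exactly the wrong-extension pathology. Pseudogenes get one
internal in-frame stop or a 1-nt frameshift; the alignment for a frameshift
carries per-exon segment triples whose target arithmetic is not a whole
number of codons, as a real aligner's indel annotation would.

For fragmented junctions the intron's splice-scan windows are filled with C
runs, so the true `gt`/`ag` pair is provably the only valid candidate in
the enumeration window; this makes exact-recovery tests well-posed without
a rejection-sampling loop. What the simulator does **not** emulate:
realistic base composition (isochores, repeats), sequencing/assembly error,
alignment noise beyond boundary jitter, non-canonical splice sites, or
overlapping genes. Passing tests therefore demonstrate the correctness of
the reduction and stitching logic under its stated assumptions, not
robustness to noisy real alignments.

Problem sizes used by the test suite: 5 scaffolds × 4 genes for end-to-end
runs, 10 × 4 for pseudogene flagging, two 5 × 4 runs (40 junctions) for
fragment repair, and 200 random toy annotation pairs for the evaluator
oracle — all chosen so every check completes in seconds while still
exercising multi-scaffold, both-strand, multi-exon structure.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `min_complete_len` | 300 | aa | completeness cutoff on protein length |
| `max_extension` | 6000 | nt | per-side cap on locus extension before refinement |
| `terminal_search_window` | 20 | codons | START/STOP search range beyond alignment ends |
| `isoform_overlap_frac` | 0.20 | fraction | keep-both threshold of the isoform rule |
| `eval_tolerance_e` | 10 | nt | terminal-exon free-end tolerance in evaluation |
| `min_intron` | 30 | nt | smallest intron a stitched junction may create |

The per-side extension rule min(hit length, cap) is the simplest monotone
reading of "extension depends on hit length"; the 30-nt intron floor is a
biological minimum below which a junction is treated as a frameshift
artifact rather than an intron.

## Numerical and degenerate-input choices

All internal coordinates are 0-based half-open on the forward strand;
conversion happens only at format boundaries (GFF 1-based inclusive, BED
0-based half-open), and query (protein) coordinates stay 1-based inclusive.
Candidate scoring uses Biopython's BLOSUM62 with −4 for residues outside
the matrix alphabet. Empty inputs are legal everywhere (empty alignment
file → no models; all-zero coverage → no islands; zero-gene simulation →
valid empty bundle). A gene record with an exon outside its span is skipped
with a warning; a malformed GFF line is a hard parse error naming the line.
Evaluator denominators of zero yield 0.0 %.

## Known limitations

* Only canonical `gt…ag` junctions are considered when stitching; `gc…ag`
  and other minor splice classes are out of scope.
* The isoform rule can suppress a genuine second copy if the *same* query
  wins two overlapping, non-congruent alignments at one locus with high
  query overlap — inherent to query-overlap-based de-duplication.
* Exon-only coverage means single-exon evidence at both ends of a long
  intron relies on the congruence chain, not the island, to be united.
* The external refiner contract is deliberately minimal; rich refiner
  output (frameshift annotations, UTRs) is not interpreted.
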