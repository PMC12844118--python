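# Methods

## Scope and model of the phenomenon

Ectopic gene conversion is the unidirectional transfer of sequence from a
donor locus to a highly similar non-allelic acceptor, homogenizing the
pair while leaving the donor unchanged.  When a block of genes is
duplicated proximally on a chromosome before a speciation, both daughter
species inherit the paralogous arms, and conversion in either lineage can
recursively re-homogenize them.  The observable signatures this package
detects are: paralog pairs far more similar than their age (topology
flips in homologous gene quartets), homogenized tracts bounded by
hypermutated flanks with small-to-large deletions, genes split into
tandem daughters by introduced stop codons, elevated synonymous
divergence of the affected region between species, and excess gene loss.

Inference is deliberately restricted to what a two-genome + outgroup
comparison can support.  In particular the donor/acceptor direction of a
conversion is *not* called: after homogenization the two copies are
indistinguishable on sequence alone, so verdicts name only the converted
lineage.

## Quartet topology test

A quartet joins two within-species paralogs (identity ≥
`paralog_min_identity`, default 0.80; separation ≤
`max_paralog_separation`, default 50 genes) with their
collinearity-assigned orthologs, plus the best-hit outgroup CDS.  The
five sequences are star-aligned through the first paralog (pairwise
global alignments merged on reference coordinates — adequate at quartet
scale where all members are near-full-length homologs; a progressive
multiple aligner would add cost without changing the distances
materially).  Pairwise Jukes–Cantor distances over gap-free columns feed
Saitou–Nei neighbor joining with a deterministic lexicographic tie-break;
NJ is exact in the additive limit, and the tree is consumed only for its
topology, which is why a likelihood method was not used.  After rooting
at the outgroup, sister-pair structure maps to the verdict
(`converted_in_A` / `_in_B` / `_in_both` / `none` / `ambiguous`).  Two
guards temper the topology signal:

* a sister pair must sit behind an internal branch of positive length, so
  arbitrary resolutions of zero-signal (all-identical) inputs are
  ambiguous rather than spuriously "converted";
* a converted verdict requires the converted lineage's paralog identity
  to reach `conversion_min_identity` (default 0.92, the homology level
  below which conversion is not considered competent; typical recent
  conversions sit above 0.95).

Support is the fraction of site-bootstrap replicates (default 100,
seeded) reproducing the point verdict; alignments shorter than 10 columns
report support as undefined.

## Tract delineation

Converted tracts are delineated on the paralog alignment by sliding
windows (50 columns, step 10; gap columns count as mismatches).  Windows
at identity ≥ `tract_min_identity` (0.95) seed candidate runs whose
boundaries are refined to the exact first/last matching column.  Runs of
≥ `min_del_run` (5) columns gapped in exactly one row become `deleted`
segments.  Remaining intervals with paralog identity <
`flank_max_identity` (0.70) — and, when ortholog alignments are supplied,
ortholog identity below the converted-region background — are
`mutated_flank`; the rest are `unclassified`.  Segments tile the
alignment exactly.  Segment contrasts use Pearson's 2×2 chi-square (1 df,
no continuity correction, matching the extreme p-values such contrasts
produce on long segments) with Fisher's exact test substituted whenever
an expected cell is below 5 (short flanks of a few bp would otherwise
invalidate the approximation); the method used is recorded.

## Stop-codon split detection

A candidate split is an intact-ORF "mother" gene in one genome whose
counterpart region in the other genome is annotated as ≥ 2 consecutive
genes, each of which fits inside the mother under a semi-global (infix)
edit-distance screen (edlib; normalized distance ≤ 1 −
`split_min_identity`, default 0.7), jointly covering ≥ 50% of the mother.
The tandem region is globally aligned to the mother and translated in the
mother's frame *as projected through the alignment*: target bases are
consumed in triplets, and indels of length ≢ 0 (mod 3) shift the frame
exactly as translation would experience them.  Internal stops strictly
before the mother's terminal codon are reported with the frame offset at
which they were read; a stop read in frame 0 is a point-mutation stop
even if the alignment contains compensating gap pairs elsewhere, and any
stop read in a shifted frame classifies the event as frameshift.  The
split alignment uses stiffened gap penalties (open −10, extend −4 against
match +2 / mismatch −3): at 25–30% divergence the ordinary scoring admits
spurious 1–2 bp compensating gap pairs that jitter the projected frame by
one codon.

## Ks / Ka estimation (Nei–Gojobori)

Coding pairs are codon-aligned by globally aligning their translations
(BLOSUM62, gap open −11 / extend −1) and back-projecting the gaps, so
alignment gaps are always frame-preserving.  Codon columns with a gap, an
ambiguity base, or a stop are dropped; any codon containing N is excluded
because fractional site counting is undefined on ambiguity codes.
Synonymous site fractions per codon count, for each position, the
proportion of the three single-base changes that preserve the amino acid
under the standard genetic code, with changes to stop codons counted
nonsynonymous (the classic convention); site totals are averaged over the
two sequences.  Differences per codon pair are averaged over all
orderings of the differing positions, excluding pathways through stops
(if all are excluded, all steps count as nonsynonymous and the pair is
flagged).  pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected; a log
argument ≤ 0 flags saturation instead of emitting infinities.  Pairs with
fewer than `min_codons` (default 10) usable codons are flagged short with
rates suppressed.

Region contrasts use Welch's unequal-variance t (two-sided) on per-pair
Ks, with the fold reported to 2 decimals.  Region-scope loss rates are
conventionally printed to 1 decimal and genome-scope rates (orphans /
total genes) to 2.

## Homology search and collinearity

Default alignment weights are the classic blastn scheme (match +2,
mismatch −3, gap open −5, extend −2).  This matters: with gap residues
cheaper than mismatches, a global alignment of *unrelated* sequences of
different lengths can reach > 80% gap-free identity by tunnelling through
gaps, so homolog filtering additionally requires a positive alignment
score.  The k-mer prefilter (k = 11, ≥ 2 shared k-mers) passes ortholog
pairs down to roughly 65–70% identity while excluding almost all
unrelated pairs; it replaces the role an E-value-thresholded BLAST search
plays at genome scale.  Chaining works in gene-rank coordinates (robust
to intergenic length variation, the natural coordinates of a gene-level
dotplot): sparse dynamic programming finds maximal chains in same and
inverted orientation (score = Σ anchor scores − gap_penalty · rank gaps),
and non-overlapping blocks are extracted greedily by descending chain
score — simple, deterministic, and adequate at gene-level resolution.
Ortholog pairs are block anchors, with conflicts resolved toward the
higher-scoring block; genes anchored in no block are orphans and feed the
loss-rate calculation.

## The simulator

The generator instantiates the scenario end-to-end and is the package's
benchmark instrument; every draw flows from one integer seed and
identical parameters give byte-identical files.

* **Ancestor** — one chromosome; background genes flank a contiguous
  region of `n_genes_region` genes (default 12).  Genes are clean
  single-exon ORFs of 150–300 codons (uniform sense codons) separated by
  200–400 bp intergenic spacers — compact, fungal-like gene density at a
  size where a full scan runs in seconds.
* **Duplication** — the block `dup_block_span` (default the region's
  first four genes) is copied immediately downstream of the region
  (capped at the next gene so the copy always lands in intergenic
  sequence), by default inverted, putting arm-2 genes on the minus strand
  in reversed order.
* **Divergence** — Jukes–Cantor substitutions (per-site Poisson event
  counts, uniform base choice) on a shared post-duplication ancestral
  branch (`dup_branch_sub_rate`, 0.02/site) and then independently on
  each lineage branch (`branch_sub_rate`, 0.033/site).  Genes in the
  affected region mutate at `region_rate_multiplier` (default 3.5×) the
  background rate, calibrated so background ortholog Ks ≈ 0.066 and
  affected-region Ks ≈ 0.23 — the regime of interest.  Substitutions that
  would create an internal stop, or touch the start/terminal codon, are
  rejected so every non-split gene stays a valid ORF; only deliberate
  split events disrupt frames.  The outgroup is the pre-duplication
  ancestral gene set diverged at `outgroup_sub_rate` (0.05/site).
* **Conversion** — an instantaneous unidirectional copy of the donor
  arm's tract over the acceptor arm (donor unchanged), after the
  substitution pass; tracts are codon-snapped and keep clear of
  start/stop codons.  Both arms' tract flanks (140 bp, the scale of the
  observed hypermutated patches) then receive independent elevated
  substitutions (`flank_mut_rate` 0.5/site, driving flank identity toward
  ~40%), and the acceptor's flanks receive log-uniform deletions over
  3–700 bp (the observed 4 bp to ~700 bp range), snapped in-gene to codon
  multiples and never removing the tract itself.
* **Splits** — point mode mutates roughly evenly spaced internal codons
  to stops; frameshift mode deletes 4 bp at a codon boundary and locates
  the first stop reached in the shifted reading frame (positions are
  resampled until one exists at a re-annotatable location).  Daughters
  are the maximal inter-stop segments of ≥ 30 codons (a floor that avoids
  annotating micro-genes), replacing the mother annotation; truth records
  carry the stop offsets in the projected-frame convention the detector
  uses.
* **Loss** — per-gene Bernoulli with elevated probability in the region
  (defaults 0.25 vs 0.02); the annotation is removed and, with
  probability 0.5, the DNA too.  Coordinates in all bookkeeping are
  shifted through every deletion, so truth coordinates are valid in the
  emitted genomes.

What the generator does **not** emulate: introns and alternative
transcripts, codon-usage and GC bias, transition/transversion bias,
population-level variation, transposable elements, and conversion
donor/acceptor asymmetries.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the modeled scenario, not
performance on real annotation noise or repeat-rich genomes.

## Recovery experiments and their conditions

The `validation` module scores the pipeline against the truth table
(problem sizes chosen so the whole battery runs in about a minute):

* **Verdicts** — 13 genome pairs × 4 full-gene conversions (two per
  lineage): paralog identity ~100%, ortholog divergence ≥ 5%.
  Sensitivity and FDR are computed over ≥ 50 converted quartets.
* **Tracts** — 20 events converting the central half of a gene; called
  converted segments are compared to truth in acceptor-gene coordinates
  by Jaccard overlap.
* **Splits** — 20 events (10 point, 10 frameshift, both arms/strands);
  detection from either counterpart arm counts, and point-mode events
  must recover the exact stop offsets.
* **Ks contrast** — 20 replicates with a configured 3.5× region
  multiplier and no conversions (conversion events themselves add
  apparent ortholog divergence beyond the configured fold, so the rate
  recovery is tested in isolation); the ratio estimate aggregated over
  replicates is compared to the configured fold and Welch significance is
  counted per replicate.
* **Loss accounting** — 20 replicates with region losses and one split;
  the expected ancestral count is the number of post-duplication region
  genes observable in at least one lineage, since a gene lost
  independently in both descendants leaves no trace any reconstruction
  could count (the same "at least" logic applies to real data).

## Numerical and degenerate-input conventions

Alignment tie-breaks are deterministic (first alignment in the aligner's
canonical order; NJ joins break ties lexicographically; outgroup and
subject-rank ties break on gene id).  Saturated JC distances are capped
just inside the model domain and flagged rather than emitted as
infinities.  Negative NJ branch estimates are clamped to zero.  Welch's t
on two identical constant groups returns (0, 1) by contract.  Windows
longer than the alignment produce a single whole-alignment segment.
Empty gene sets propagate as empty results, not errors; malformed inputs
(overlapping CDS, out-of-bounds features, duplicate FASTA ids, invalid
rates) fail loudly with the offending field named.

## Known limitations

Gene-rank chaining assumes broadly conserved gene order; massive
rearrangement would fragment blocks and starve quartet detection.  The
star alignment degrades if quartet members differ grossly in length
(e.g. a quartet built directly on split daughters).  The k-mer prefilter
loses sensitivity below ~60–65% nucleotide identity, which bounds how old
a conversion the homology stage can see.  Split detection requires the
mother gene to survive intact in one genome.  FDR control relies on the
paralog identity floor; lowering `paralog_min_identity` far below 0.8
admits gap-tunnelled false paralog pairs on unrelated genes.
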