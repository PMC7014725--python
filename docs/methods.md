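# Methods

## Scope and data model

`tucast` infers bacterial transcription units (TUs) from three evidence
layers — junction sequence, stranded coverage/expression, and targeted
junction assays — and compares two unreplicated count libraries. All gene
coordinates are GFF3-style (1-based, inclusive); per-base tracks are
0-based numpy arrays; bedGraph output is 0-based half-open. The conversion
lives in one place (`tucast.trackio`). Genes are CDS features with an `ID`
attribute; a TU is an ordered, strand-consistent, genomically contiguous
run of genes.

## Translational coupling (stage 1)

For every adjacent co-directional gene pair whose coordinates overlap by
≥ 1 bp, the detector emits a link carrying the overlap length, the
sense-strand junction sequence spanning both the upstream stop codon and
the downstream start codon, and the number of nucleotides those codons
share. Interval arithmetic shows the codons can only share bases when the
overlap is ≤ 5 bp (the start codon occupies overlap positions 1–3, the
stop codon positions k−2…k); the canonical 4-bp case is the `ATGA`/`GTGA`
tetranucleotide with 2 shared bases. Because well-documented coupled pairs
with 8-bp overlaps exist (no codon sharing is geometrically possible
there), **coupling is defined by overlap length**: `coupled` iff
1 ≤ overlap ≤ `max_coupled_overlap` (default 12 bp; longer overlaps are
reported but treated as probable annotation artifacts). Codon sharing is
reported as an annotation, not used as the criterion. Maximal chains of
coupled genes become preliminary units; detection is strand-symmetric and
local to each junction.

## Boundary calling

A TSS is a step-up and a TTS a step-down of per-base depth in transcription
direction. At every position the detector compares mean depth over the
upstream and downstream windows (`window_bp` = 25): a call requires the
high side ≥ `min_depth` (5) and a ratio ≥ `min_ratio` (3) with a
pseudodepth of 0.5 in the denominator; calls of one kind within a window of
each other collapse to the maximum-score call. The minus strand is scanned
on the reversed track, so both kinds are defined in transcription
direction. This is a deliberate simplification of dedicated bacterial
transcript assemblers — sufficient for step-like tracks, and external calls
can be imported from TSV instead. Defaults recover every noise-free planted
step in the test suite with precision and recall 1.0.

## Boundary/FPKM merging (stage 2)

Junctions between adjacent co-directional genes are decided locally, using
the junction-adjacent genes (last gene of the upstream unit, first of the
downstream unit) rather than unit means, in a single pass:

1. different strand or contig → split;
2. FPKM ratio downstream/upstream ≥ `jump_factor` (default 4) → split,
   *even across a coupled link*: transcriptional read-through can only
   dilute downstream of the promoter, so a strong rising step is
   incompatible with co-transcription whatever the junction sequence says;
3. otherwise a coupled junction stays linked;
4. otherwise a start-type boundary in the transcription-sense intergenic
   gap (up to `boundary_slack` = 25 bp into the downstream gene, the
   detector's resolution) → split — **unless** the boundary sits at the
   upstream edge of a coupled unit that an FPKM jump interrupts
   internally, in which case the predicted start is treated as
   mislocalized (the expression step marks the true start inside the
   chain) and the junction merges;
5. otherwise merge: confidently when the downstream FPKM is degressive
   (declining, the expected within-unit profile) or within
   `similar_factor` (default 2), flagged low-confidence for a rise between
   `similar_factor` and `jump_factor`. Exact threshold ties resolve to
   split (conservative against over-merging).

"Much larger" is thus encoded as ≥ 4-fold and "not significantly
different" as within 2-fold; both knobs are parameters. The mislocalized-
boundary rule (4) is this package's formalization of how a start predicted
at the edge of an overlap chain should be reconciled with an expression
jump inside it; on the encoded lmb cluster it reproduces the documented
reading (merge lmbS|lmbO, split lmbZ|lmbN).

## Junction-evidence refinement (stage 3)

Evidence rows are adjacent co-directional gene pairs with a boolean
`detected` (an upstream transcript amplified from cDNA primed in the
downstream gene). Detection merges the two current units — it outranks
stage-2 splits, mirroring that a positive RT-PCR across a junction is
direct physical evidence of a shared transcript, whereas a predicted TSS is
model output. Non-detection confirms a split and never breaks a unit;
stage 3 never splits, so every stage-2 unit is contained in a stage-3
unit. The operation is idempotent. Units are then numbered TU1…TUn by
leftmost genomic coordinate and classed mono/bi/tri/tetra/penta-cistronic
by gene count.

Evidence trust order, highest first: junction evidence > FPKM jump >
coupling > start-boundary split > degressive/similar merge. (The jump sits
above coupling because of rule 2; it is the one place the coupled-links-
survive property yields, and the package reports such junctions with
reason `fpkm_jump_breaks_coupling`.)

## Quantification

FPKM = count · 10⁹ / (length_bp · total_fragments); counts may be
non-integral (normalized counts are accepted). FPKM is used only for
within-sample comparisons (stage-2 merging); between-condition fold changes
use readcounts directly. Mean per-base depth over a gene body serves as an
FPKM-scale proxy when only coverage is available. No between-sample
normalization (TMM, median-of-ratios) is applied: the two-library design
compares proportions of library totals.

## Two-library differential expression

log2FC = log2(count_mut / count_orig), deletion strain in the numerator.
There is no pseudocount: a zero count in either library leaves the fold
change undefined and the gene is classified `excluded` and listed
separately — the deleted gene itself (zero reads) is the canonical case,
and forcing it onto the volcano with a pseudocount would fabricate a fold
change. Significance is the pooled two-proportion z statistic with library
totals as denominators (totals default to column sums when not supplied;
for simulated data the configured library size is passed explicitly, since
column sums of a cluster-only matrix would renormalize the knockdown
away). An exact hypergeometric (Fisher) test is available as an
alternative and serves as the oracle in tests. Calls use |log2FC| > 1 and
raw p < 0.005; Benjamini–Hochberg q-values are emitted for information
only. Degenerate input (both proportions 0 or 1) returns p = 1.

Numerical note: against the exact hypergeometric test, the z-test's
two-sided p agrees in sign everywhere and in order of magnitude (−log10 p
within a factor of 2 across all counts ≤ 200 at totals 10⁴), but raw p
ratios are unbounded in the deep tail, where the normal approximation is
anticonservative relative to the exact tail probability. The property
tests therefore assert agreement on the log scale. Without replicates the
test ignores biological overdispersion and over-calls at moderate counts;
the fold-change band and the q-value column are the practical guards, and
the regulon report separates cluster from non-cluster calls.

## Synthetic-data generator

The generator emulates a regulator-deletion study of a highly expressed
BGC. Layout: a cluster contig built from a TU plan (strand, gene count per
unit) with intra-unit junctions coupled (4- or 8-bp stop–start overlaps
with real codons stamped at the junction) with probability
`coupled_fraction` = 0.6, intra-unit gaps of 15–80 bp, intergenic gaps of
150–400 bp, CDS lengths 300–1500 bp (multiples of 3); background genes sit
on a second contig as alternating-strand monocistrons. Defaults (chosen
once as the study conditions):

- `base_expression` = 2·10⁴ FPKM-scale for cluster units, lognormal spread
  σ = 0.5, `degression_factor` = 0.85 per step. A production-phase BGC
  dominates its transcriptome, and quantifying a 99.98% decline at library
  size 10⁶ requires original counts on the 10⁴ scale — fold changes of
  −log2FC ≈ 12 are only measurable at such depths.
- counts: negative binomial with `dispersion` = 0.1
  (var = μ + 0.1 μ²), `library_size` = 10⁶ fragments; `dispersion` = 0
  gives Poisson, `noise=False` gives rounded means exactly.
- deletion condition: per-gene declines drawn uniformly from
  `knockdown_range` = (93.71, 99.98)%, drawn once per configuration so
  both conditions share them; the deleted gene (default: first gene of the
  13th unit, a mid/late-cluster regulator position) is set to zero reads;
  1 planted up gene (log2FC ≈ +5.8) and 19 planted down genes (log2FC
  uniform in −[2.5, 5.4]) among the background, matching a regulator with
  a small trans-regulon.
- coverage: plateaus at each gene's FPKM level with read-through filling
  intra-unit gaps; optional Poisson noise.

Identical seed + config produce byte-identical FASTA/GFF3/bedGraph/TSV
output; all streams derive from `numpy.random.default_rng([seed, k])` with
fixed per-purpose offsets k. What the generator does **not** emulate:
read-level artifacts (mapping bias, rRNA carryover, fragment-length
effects), condition-dependent internal promoters, UTR structure beyond
step edges, and biological replicate variance. Passing tests on synthetic
data therefore demonstrate correctness of the inference logic under clean,
step-like signals, not robustness to the full noise spectrum of real
libraries.

## The encoded lmb cluster

`tucast.lmb` hard-codes the characterized evidence for the 29-ORF
lincomycin cluster: gene order, the seven overlap chains (including the
8-bp lmbIH–J junction and the AUGA lmbY–X junction), start-boundary
predictions upstream of lmbA, lmbB1, lmbE, the lmbG and lmbJ groups, lmbO,
lmbU and lmbY, an FPKM table, and the RT-PCR junction results. Coordinates,
standalone-gene strands and FPKM magnitudes are synthetic stand-ins (no
coordinates are published for this layout); only order, overlap lengths,
boundary placements, junction evidence and the qualitative expression
relations are contractual, and the documented 145-bp lmbU–lmbY gap is
used verbatim. Strands of the four standalone biosynthetic genes and the
resistance genes are chosen so their monocistronic status follows from
chromosomal arrangement (flanking strand changes), which is how such genes
are recognized in practice. Upstream boundary predictions reported as
"TTSs" at gene upstreams are recorded as start-type calls, which is what
their placement implies. Running the three stages on this fixture gives
17 → 17 → 15 units with composition 8 mono / 2 bi / 4 tri / 1 penta;
left-to-right numbering places the lmbU-Y-X tricistron at TU13 (figure
numbering in the source characterization orders the last three units
differently; the composition is what is asserted).

## Numerical and degenerate-input choices

- Boundary detector: pseudodepth 0.5 avoids division by zero; tracks
  shorter than twice the window warn and return no calls.
- FPKM ratios with a zero denominator: ∞ if the numerator is positive
  (split), 1 if both are zero (mergeable).
- Ties at `jump_factor` split; ties at the p threshold are
  not-significant (strict inequalities per the stated thresholds).
- Evidence on non-adjacent or opposite-strand pairs, unknown gene ids,
  duplicate gene ids, counts exceeding totals, and non-positive
  lengths/totals raise `InputError` (CLI exit code 2); violations of the
  partition invariants raise `InvariantError` (exit code 3).

## Known limitations

- The boundary detector is a step detector; it will fragment units with
  strong internal coverage structure and cannot resolve boundaries closer
  than its window.
- Stage 2's merge default (absent boundaries, non-jumping FPKM) assumes
  read-through; sparse boundary input therefore biases toward larger
  units — the boundary-dropout tests quantify exactly this degradation.
- The two-library test has no dispersion model; its p-values are honest
  only under the binomial sampling assumption. Replicated designs should
  use a count-model package instead.
- TU architecture is inferred for one condition; condition-dependent
  units (internal promoters switching) are out of scope.
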