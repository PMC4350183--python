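# Methods

## The question and the approach

A gene class can be underrepresented on a chromosome either because genes
left it after the chromosome formed, or because the chromosome assembled
from ancestral regions already poor in that class. `synmito` separates the
two signals with synteny: the regions of an outgroup genome homologous to
the focal chromosome stand in for the ancestral state, movement is read
from ortholog pairs that escape all syntenic regions, and density is
compared between the focal chromosome and its ancestral proxies.

## Orthology

Reciprocal best hit (rBBH) over two directed homology-hit tables
(BLAST `-outfmt 6`). Hits are screened at *e*-value `< 1e-10` (strict
inequality; the threshold is read as a bound). Candidates are ordered by
bitscore, with a deterministic tie cascade — e-value ascending, percent
identity descending, subject id lexicographic — chosen so results are
identical across platforms; the cascade beyond bitscore is a package
convention, as best-hit ties are otherwise ambiguous. The 30% identity
rule applies to the *top* hit only: a query whose best hit is too diverged
yields no ortholog rather than promoting a runner-up (a `strict` mode that
filters all hits is available but off by default). Pairs are kept only
when both genes sit on sequences usable for synteny ("placed"); which
sequence names count as placed is assembly metadata, supplied as a regex,
not code.

One caution discovered by property testing: tightening the e-value cutoff
does **not** monotonically shrink the pair set — removing a best hit can
promote a runner-up into a brand-new reciprocal pair. What does hold, and
is tested, is that pairs whose best hits survive the tighter cutoff are
preserved.

## Synteny blocks and merged regions

Anchors are ortholog pairs ranked by start-order on their chromosomes.
Within each chromosome pair, maximal chains strictly monotone in both
ranks (increasing/increasing = same orientation, increasing/decreasing =
inverted) with consecutive rank gaps ≤ 25 genes are extracted greedily by
a longest-chain dynamic program; chains of ≥ 5 anchors become blocks, and
each anchor belongs to at most one block. The ≥ 5 / ≤ 25 defaults mirror
MCScanX's documented defaults, and `read_collinearity` ingests real
MCScanX output when available. Chain score is anchor count rather than an
e-value-weighted score; downstream logic consumes only block membership
and spans, so the simplification does not propagate.

Blocks on one chromosome pair are sorted by genome-A start and merged
transitively into regions whenever the gap to the growing region's hull is
below 10 Mb **on both genomes**. Requiring both sides (the stricter of the
plausible readings of a one-genome rule) prevents chimeric regions that
would join distant genome-B segments through genome-A proximity alone.
Merging is idempotent. A gene belongs to a region when its midpoint falls
inside the region's interval — unambiguous for edge-straddling genes.

## Movement classification and the size null

An ortholog pair is *retained* when it anchors a block or both midpoints
lie inside corresponding intervals of one merged region; otherwise it is a
candidate movement, binned X→A / A→X / A→A by source (inside a
focal-syntenic region of genome B or not) and destination (focal
chromosome of genome A or not). Movements whose source chromosome carries
a focal-syntenic region but whose gene lies outside it are flagged
*ambiguous* (a partly syntenic contig may be mis-assembled rather than
truly non-syntenic); reports carry both the full tally and a sensitivity
tally without them.

With T observed movements, P(source=X) = the focal-syntenic fraction of
classified genome-B ortholog genes (all placed genome-B genes,
optionally), and P(target=X) = the focal chromosome's fraction of genome-A
base pairs:

    E[X→A] = T·p·(1−q)   E[A→X] = T·(1−p)·q   E[A→A] = T·(1−p)·(1−q)

The X→X mass T·p·q is excluded from the three-category table and the rest
rescaled to sum to T (proportional rescaling; the three-category layout
matches how such tables are conventionally reported). Observed vs
integer-rounded expected rows are compared with an exact 2×3
Freeman–Halton test: all tables with the given margins are enumerated and
the probabilities of tables no more probable than the observed one are
summed. Arithmetic is exact-integer, so the "no more probable" comparison
carries no floating-point tolerance. Expected counts must be pre-rounded
by the caller — exact tests are defined on integer tables, and the
rounding step is deliberately visible.

**Calibration caveat.** The observed-vs-expected construction conditions
on table margins although one row is deterministic. The test is therefore
strongly conservative: under multinomial sampling at the null proportions
(T = 150, 1,000 replicates) it rejects at α = 0.05 in well under 1% of
replicates, not 5%. Power against realistic effects is nonetheless high —
a 5× excess of off-focal movement at T ≈ 115 is detected end-to-end in
~96% of seeded simulations — but the p-values should be read as
conservative.

## Abundance bias

For a region of n genes with m class genes, expected = (n/total_genes) ·
total_class and bias = m/expected. Bias of the whole genome is exactly 1,
and expected counts are additive over any partition. CIs are percentile
bootstrap (10,000 resamples by default) over the region's genes with
genome totals fixed; resampling a boolean flag vector with replacement is
exactly a binomial draw on the region's class fraction, which is what the
implementation computes (vectorized). Percentile rather than BCa because
it is the simplest method consistent with resampling-with-replacement of
region genes; at the region sizes of interest (hundreds of genes) the
half-width agrees with the delta-method closed form
1.96·bias·√((1−p)/(n·p)) to within a few percent. Regions are compared
with a two-tailed 2×2 exact test on (observed, rounded-expected) counts —
this reading reproduces the published comparisons — and lineage-level
direction calls use the exact sign test p = 2·min(P(K≤k), P(K≥k)), K ~
Binomial(n, ½), capped at 1.

Class flags can come from a genome's own annotation or from orthology to
a flagged reference genome; both modes are supported and their Jaccard
overlap is reported, since electronic GO annotation in non-model genomes
is itself orthology-derived and the two sets differ in practice.

## Simulator

The generator's defaults are the study conditions: 8 chromosomes × 120
genes (≈ 960 genes — a desk-scale stand-in for a ~20,000-gene amniote
genome), class fraction 0.08 (the human mt-N proportion, 1,572/~20,000),
one gene per ~30 kb with exponential gene lengths (mean 3 kb) and
intergenic gaps (mean 27 kb), focal chromosome chr1 holding ~1/8 of genes
and base pairs (the human X is ~5% of the genome; 1/8 keeps per-category
counts informative at desk scale), 3 inversions and 1 translocation per
lineage, per-gene movement rate 0.01, hit identity ~ N(70, 10) truncated
to (30, 100] with 5% paralog noise. Per-chromosome class biases are
renormalized to gene-weighted mean 1 so the genome-wide fraction is
preserved. A single RNG stream seeded from the config is consumed in fixed
order (ancestor → lineage A → lineage B → hits), making every output
bit-reproducible.

What it emulates: conserved gene order broken by rearrangement, directed
single-gene traffic, chance per-chromosome class biases, assemblies whose
focal-syntenic material sits on "Ultra" contigs, and genes stranded on
tiny unplaced scaffolds. What it does not: sequence evolution, tandem
duplication, many-to-many homology, gene gain/loss, or realistic length
distributions — so green tests certify the inference machinery under the
stated statistical structure, not robustness to annotation error or
assembly artifacts in real genomes. Movement destinations are drawn in
proportion to chromosome gene content, which matches the analysis null
(base-pair share) only because simulated gene density is uniform; the two
would diverge if per-chromosome density were made heterogeneous.

## Numerical and design choices

- Coordinates are 0-based half-open internally; conversion only at IO.
- First-listed coordinates are used for genes with multiple placements.
- Strand is parsed and carried but unused by all statistics.
- Chain extraction ties break deterministically (smaller ranks first,
  blocks ordered by anchor count, then leftmost interval).
- Degenerate inputs: zero observed movements ⇒ p = 1; all-zero 2×2 ⇒
  p = 1; empty regions are rejected rather than given bias 0/0.
- The acceptance script sizes its simulations at 100 power replicates and
  1,000 null replicates of T = 150 movements, chosen to give binomial
  standard errors below one percentage point on the reported rates.

## Known limitations

- The movement exact test's conservatism (above) is a property of the
  published construction, reproduced faithfully.
- Greedy chain extraction guarantees each block is a maximum chain at its
  extraction step, not a globally optimal block partition.
- Percentile bootstrap CIs undercover slightly at small region sizes
  (tested coverage ≥ 90% for nominal 95% at n = 400).
- Expected-count rounding before the exact tests loses sub-integer
  information; it is required for exactness and matches how such tables
  are printed.
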