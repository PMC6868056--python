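# Methods

This note documents the models, defaults and numerical choices behind each
stage of `dhskit`, and what the synthetic-data validation does and does not
establish about real DNase I-seq data.

## Coordinates and interval arithmetic

All intervals are 0-based half-open (BED convention); GFF3 input (1-based
inclusive) is converted on read, and a gene's TSS is its strand-aware 5′ end
(`start` on +, `end − 1` on −). Merging follows `bedops -m`: overlapping
*and* abutting intervals coalesce (merge distance 0). Chromosome names match
by exact string equality — no `chr` prefix normalization, since synthetic
data controls its own naming and real inputs should be harmonized upstream.
Gene annotations keep only primary transcripts, keyed on the literal `.1`
suffix of the mRNA ID. Merge, subtraction and base counting are validated
against per-base boolean-array oracles on randomized toy chromosomes;
`total_bases` of a merged set equals the per-base union size by
construction.

## Quantification and normalization

Cut tracks are sparse per-base counts; tallying a DHS sums counts in
[start, end). Sample quality is normalized by the SPOT-style fraction: the
proportion of a sample's cleavages inside its 1% FDR hotspots, with counts
divided by that fraction. The low-signal filter removes DHSs whose mean
count across samples is ≤ 50 — applied to **raw** counts, because the
filter targets raw sequencing depth (roughly the bottom decile of signal),
not quality-adjusted values. Depth equalization is count-level binomial
thinning: each stored cleavage is kept independently with probability
target/total, so a position holding k cuts contributes k Bernoulli trials
and the expected total equals the target. This preserves the statistical
intent of read-level subsampling while operating on tracks, which are the
package's inputs.

## The cone classifier

For a two-sample comparison each union DHS sits at
(x, y) = (log10 cutsₐ, log10 cutsᵦ). The cone is bounded by
y = (1 − m)x + b and y = (1 + m)x − b with defaults m = 0.21, b = 0.9
(log10 units). A DHS is *activated* when y is strictly above both lines,
*deactivated* when strictly below both, otherwise *static*. Numerical
choices:

- **Closed cone**: points exactly on a boundary line are static
  (conservative calling).
- **Envelope past the crossing**: the lines cross at x = 2b/(2m) = b/m ≈
  4.286; beyond it the upper/lower envelopes of the two lines keep "inside
  the cone" meaning the band between them, so the dynamic region never
  inverts.
- **Minimum-cleavage gate**: a DHS can only be dynamic with more than 50
  **raw** cuts (log10(50) ≈ 1.69897) in at least one sample; the gate is
  evaluated before any logarithm, which also disposes of log10(0) — a zero
  count that passes the gate on the other axis maps to −∞ and is maximally
  dynamic.
- **Asymmetry**: the cone is intentionally not symmetric under swapping the
  samples (reflecting one line about y = x does not give the other); the
  printed line equations are preserved exactly rather than symmetrized.

The classifier is checked against a direct per-point evaluation of the two
line inequalities on 10⁴ random count pairs, and for monotonicity of the
label in the second count. It is a geometric caller, not a count-model test;
no negative-binomial testing is performed or implied.

## Annotation

Context is decided by the DHS midpoint, floor((start+end)/2). The TSS
context is the 400 bp window strictly 5′ of the TSS (the TSS base itself is
gene body); a midpoint inside a gene body is intragenic, not TSS, keeping
the two categories disjoint. A midpoint coinciding with several elements
(e.g. a transposon inside a gene) is tallied in **all** of them, so context
tallies may sum to more than the number of DHSs; finer intragenic splits
(5′UTR/CDS/3′UTR) are deliberately collapsed. Gene assignment is
proximity-based: the containing gene when intragenic, otherwise the nearest
gene on **each** side (up to two) with distance measured midpoint to nearest
gene-body edge and ties broken by lexicographic gene id. Two-sided flanking
assignment is essential: a single-nearest rule cannot produce more assigned
genes than dynamic DHSs, while observed landscapes routinely do. The
assignment deliberately ignores long-range (chromatin-contact) interactions.

## Enrichment

Overlap tests are upper-tail hypergeometric: with |set₁| = n₁, |set₂| = n₂
in a universe of N genes, expected overlap n₁n₂/N, fold = observed/expected,
p = P[X ≥ observed]. p-values are reported raw (per-test). Differential
expression uses an inclusive ratio threshold (t₂ ≥ fold·t₁ for up), with a
zero baseline counting as change and genes at zero in both timepoints
unchanged — a rule that only matters for synthetic data, as microarray
intensities never hit exact zero. Two counting modes exist: gene-level
(deduplicated sets) for set tests, and pair-level (`pair_enrichment`, the
observed pair count supplied by the caller) for DHS–gene-pair arithmetic.
The scipy implementation is verified against exact rational-arithmetic
enumeration on every universe of ≤ 25 genes to 10⁻¹², and its null
rejection rate is calibrated by simulation with independent random gene
sets at a realistic scale (universe of 28,775 genes, sets of 1,000–5,000):
at small set sizes the discrete test is visibly conservative, which is a
property of the statistic, not an implementation artifact.

## Landscape comparison

The high-confidence union merges each sample's *large* DHSs — its own
hotspots carrying more than 50 of its cuts, gated per sample **before**
merging. Unique hypersensitive bases use leave-one-out differencing:
unique_bp(s) = union bases of all samples − union bases without s, and the
unique fraction divides by the full union size. The saturation curve adds
samples by descending unique contribution and reports cumulative union bp;
its final value equals the full union by construction. These identities are
oracle-checked per base: Σ unique_bp + bases covered by ≥ 2 samples = union
bases.

Sample clustering uses 1 − Pearson correlation of log10(1 + count) column
vectors with average linkage. The metric and linkage are a design choice
(correlation distance matches the replicate-correlation framing of DNase
data) and are isolated behind the module surface. Bootstrap support of each
internal bipartition is the fraction of trees built from random
subsample-row subsets (default 100 trees × 10,000 DHSs, scaled to the data)
that contain the same **unrooted** bipartition, canonicalized as the side
not containing the first sample. With three samples there are no internal
bipartitions and the support map is empty. PCA removes DHSs overlapping an
exclusion mask (e.g. rDNA/NOR regions with anomalous signal), transforms to
log10(1 + count), centers each DHS row, and decomposes with a full SVD;
explained-variance fractions are non-increasing by construction, and a
constant matrix is rejected as degenerate.

## Synthetic landscapes

The generator emulates the statistical structure the pipeline assumes, not
the sequence level (no reads, no cutting-bias model):

- **Geometry**: planted DHSs of width 150–300 bp (matching typical DHS
  spans) placed without overlap on a proportional lattice with ≥ 2 kb
  jittered gaps — deterministic feasibility instead of rejection sampling;
  an infeasible request fails loudly.
- **Classes**: shared (open in every sample), sample-specific (open in one
  sample, background elsewhere), and dynamic between the two timepoint
  samples at a configurable fold change, split evenly between directions.
  Note that sample-specific DHSs are *also* genuinely dynamic between the
  timepoint pair; truth-based evaluations therefore score recovery on the
  planted dynamic class and false calls on the shared class only.
- **Counts**: per-DHS totals are Poisson (default) or negative-binomial
  (mean/size parameterization, for replicate overdispersion) around
  class-dependent means; defaults 500 cuts per open DHS, fold 4. Cut
  positions are multinomial-uniform within the DHS — every implemented
  statistic uses interval sums only, so per-base shape is irrelevant.
  Uniform background at 0.01 cuts/bp keeps the SPOT fraction below 1 so
  normalization is exercised.
- **Annotation**: one gene per inter-DHS gap (flanking both neighbors),
  alternating strand; every fifth gap also carries a transposon. Expression
  is flat at 100 units except that a gene whose dynamic neighbors are all
  activated goes 2-fold up at the second timepoint with probability
  `concordance_p` (all deactivated: 2-fold down); genes with conflicting
  dynamic neighbors stay unchanged.
- **Determinism**: one seed drives everything through named substreams;
  identical seeds give byte-identical bedGraph output.

**What passing synthetic tests does and does not show.** They demonstrate
the operations are implemented correctly (oracle equality), the classifier
recovers planted effects of the stated size at the stated depth (≥ 95%
recovery of 8-fold changes at 500-cut depth with ≤ 2% false calls among
shared DHSs), and the statistical machinery is calibrated. They do not
demonstrate performance on real chromatin: real DHS landscapes have
correlated backgrounds, width heterogeneity, copy-number artifacts
(centromeres, rDNA) and mappability structure the generator deliberately
omits — which is why masks and quality normalization exist as explicit,
inspectable stages.

## Problem sizes

The default validation suite runs on toy chromosomes (2 kb oracle toys;
0.3–1.6 Mb synthetic genomes with 200–600 planted DHSs; 2,000–5,000-row
matrices with 100 bootstrap trees on 1,000-row subsamples). These sizes were
chosen so the full suite and the reproduction script each complete in well
under a minute while keeping every estimate's sampling error far from the
acceptance margins; all operations scale to genome-size inputs (sorted
arrays and cumulative sums; nothing is quadratic in bases).

## Known limitations

- Peak calling, read alignment and count-model differential testing are out
  of scope by design; hotspot intervals and tracks are inputs.
- Flanking-gene assignment ignores long-range regulatory interactions and
  will misassign distal enhancers.
- The dendrogram metric/linkage and the PCA preprocessing are sensible
  defaults, not canon; both are exposed as code-level seams rather than
  hard-wired conventions.
- The cone classifier has no error model: it is a reproducible geometric
  rule whose thresholds (0.21, 0.9, 50) are fixed conventions, and its
  calls should be treated as candidate sets, not significance statements.
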