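# dhskit

Comparative analysis of DNase I-hypersensitive site (DHS) landscapes.

DNase I-seq marks regulatory DNA: open chromatin is hypersensitive to DNase I,
and per-base cleavage ("cut") counts quantify accessibility. Comparing cut
counts across samples — developmental timepoints, treatments, cell types —
identifies *dynamic* DHSs whose accessibility changes, the regulatory
correlates of differential gene expression. `dhskit` implements that
comparative pipeline for anyone with per-base cleavage tracks (bedGraph) and
called DHS/hotspot intervals (BED):

- **Union DHS construction** — merge per-sample DHS sets (`bedops -m`
  semantics: overlapping *and* abutting intervals coalesce) into a shared
  coordinate system, with exclusion masks (e.g. centromeres).
- **Quantification** — tally cuts per union DHS per sample; normalize for
  sample quality by the SPOT-style fraction (proportion of a sample's cuts
  inside its 1% FDR hotspots); drop low-signal DHSs (mean raw count ≤ 50);
  binomial depth thinning to equalize coverage.
- **Dynamic-DHS classification** — on the log10 cut-count scatter of two
  samples, a DHS with x = log10(cuts in A), y = log10(cuts in B) is dynamic
  when it falls outside the cone bounded by

  ```
  y = (1 − 0.21)·x + 0.9      and      y = (1 + 0.21)·x − 0.9
  ```

  and carries more than 50 raw cuts in at least one sample. Above the cone:
  *activated* (more accessible in B); below: *deactivated*.
- **Annotation** — genomic context of each DHS by its midpoint (TSS = 400 bp
  strand-aware window upstream of a transcription start site, intragenic,
  transposon, intergenic; overlapping elements are all tallied), and
  proximity assignment of DHSs to genes (containing gene, else the nearest
  gene on each side).
- **Expression integration** — hypergeometric tests of gene-set overlap.
  With n₁ genes near activated DHSs and n₂ genes ≥ 2-fold up-regulated in a
  universe of N genes, the expected overlap is n₁·n₂/N; the upper-tail
  p-value P[X ≥ observed] measures the excess, and fold enrichment is
  observed/expected. Includes the multi-DHS enrichment ladder (genes with
  ≥ 1, ≥ 2, ≥ 3 dynamic DHSs).
- **Landscape comparison** — high-confidence union of "large" DHSs (> 50
  cuts), per-sample unique hypersensitive bases by leave-one-out union
  differencing, saturation curves, bootstrap-supported sample dendrograms
  (1 − Pearson correlation of log10 counts, average linkage, support from
  trees on random DHS subsamples), and PCA of samples.
- **Synthetic landscapes** — a generator that plants shared, sample-specific
  and dynamic DHSs of known fold change with Poisson or negative-binomial
  noise, plus a toy gene annotation whose expression tracks the planted
  dynamics, so every stage can be validated against known truth.

## Worked example

```python
from dhskit import (LandscapeSpec, generate_landscape, generate_annotation,
                    DhsMatrix, call_dynamic, diff_expressed,
                    direction_concordance, genes_by_direction, pair_enrichment)

# a two-timepoint landscape: 200 shared DHSs, 20 private per sample,
# 50 dynamic at 4-fold change, Poisson noise around 500 cuts per DHS
spec = LandscapeSpec(n_dynamic_dhs=50, fold_change=4.0, seed=7)
profiles, truth = generate_landscape(spec)

matrix = DhsMatrix.from_samples(truth.intervals(), profiles)
calls, summary = call_dynamic(matrix, "t1", "t2")
print(f"dynamic DHSs: {summary['n_above']} activated, "
      f"{summary['n_below']} deactivated")

genes, tes, expr = generate_annotation(spec, truth, concordance_p=1.0)
up, down = diff_expressed(expr, "t1", "t2", fold=2)
by_dir = genes_by_direction(calls, genes)
universe = {g.gene_id for g in genes}
grid = direction_concordance(up, down, by_dir["activated"],
                             by_dir["deactivated"], universe)
res = grid[("up", "activated")]
print(f"up-regulated x activated: observed {res.observed}, "
      f"expected {res.expected:.1f}, fold {res.fold:.1f}, p = {res.p_value:.2e}")
```

prints

```
dynamic DHSs: 45 activated, 45 deactivated
up-regulated x activated: observed 43, expected 11.8, fold 3.6, p = 1.35e-29
```

90 DHSs are called dynamic between the timepoints: the 50 planted dynamic
DHSs (4-fold change, nearly all recovered) plus the 40 sample-private DHSs,
which genuinely differ between the pair. Genes next to activated DHSs are
3.6-fold enriched among up-regulated genes — far above the 11.8 expected by
chance — because the generator was asked for full concordance between
chromatin and expression direction.

The same arithmetic reproduces a classic back-of-envelope check: with 2,131
up-regulated genes and 3,269 genes near activated DHSs among 28,775 genes,
`pair_enrichment(2131, 3269, 28775, observed=586)` gives expected ≈ 242.1
pairs, a 2.4-fold excess at p < 10⁻²⁰.

## Command line

Every stage is also a `dhs` subcommand operating on plain-text files:

```bash
dhs simulate --spec spec.yaml --out sim/         # synthetic landscape + truth
dhs union --hotspots a.bed --hotspots b.bed --out union.bed
dhs quantify --dhs union.bed --track t1 sim/t1.bedGraph --track t2 sim/t2.bedGraph --out matrix.tsv
dhs dynamic --matrix matrix.tsv --a t1 --b t2 --out calls.tsv
dhs annotate --dhs union.bed --gff genes.gff3 --te te.bed --out contexts.tsv
dhs enrich --calls calls.tsv --gff genes.gff3 --expression expr.tsv --t1 t1 --t2 t2 --out grid.tsv
dhs timepoint --config run.yaml                  # the full two-sample analysis
dhs landscape --config run.yaml                  # the multi-sample analysis
```

All intermediates are TSV/BED/Newick; reruns with the same config and seed
are byte-identical.

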