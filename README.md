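# synmito

Synteny-based analysis of interchromosomal gene movement and gene-class
density bias, built around one comparative-genomics question: **is a gene
class scarce on a chromosome because selection moved its genes away after
the chromosome formed, or because the ancestral regions that built the
chromosome were already poor in that class?**

The motivating case is mitonuclear (mt-N) genes — nuclear genes whose
products are imported into mitochondria (GO:0005739) — which are
underrepresented on the therian mammal X chromosome. Because mitochondria
are maternally inherited while the X spends two-thirds of its time in
females, intergenomic conflict is one candidate explanation; chance bias on
the ancestral autosomes is the other. The package distinguishes the two by
locating the ancestral X-syntenic regions in an outgroup genome and asking
(i) whether mt-N orthologs moved on/off the X more than a size-based null
predicts, and (ii) whether mt-N density on the ancestral regions differs
from the X itself.

## What it computes

For genomes A (focal, X-bearing) and B (outgroup):

1. **Orthology** — one-to-one orthologs by reciprocal best BLAST hit
   (rBBH): hits filtered at *e* < 10⁻¹⁰, candidates ordered by bitscore, a
   pair counted only when both directions agree and the top hit's identity
   exceeds 30%.
2. **Synteny** — ortholog anchors ranked by gene order are chained into
   collinear blocks (≥ 5 anchors, gene-order gaps ≤ 25, both orientations);
   blocks on one chromosome pair closer than 10 Mb (on both genomes) are
   merged into syntenic regions. Regions on the focal chromosome identify
   the ancestral X-syntenic segments of genome B. MCScanX
   `.collinearity` files can be ingested in place of internal chaining.
3. **Movement** — an ortholog pair outside every merged region is a
   candidate movement, classified X→A / A→X / A→A by its source
   (focal-syntenic region of B) and destination (focal chromosome of A).
   Expected counts redistribute the same total with
   P(source = X) = the focal-syntenic share of genome-B ortholog genes and
   P(target = X) = the focal chromosome's share of genome-A base pairs;
   observed vs expected rows are compared with an exact 2×3
   (Freeman–Halton) test.
4. **Abundance** — for a region with *n* genes of which *m* are in the
   class,

   ```
   expected = (n / total_genes) · total_class_genes      bias = m / expected
   ```

   with a 10,000-resample percentile bootstrap CI, exact 2×2 tests between
   regions, and an exact two-tailed sign test across independent lineages.
5. **Simulator** — an ancestral genome evolves into two descendants by
   inversions, translocations and single-gene movements with a
   configurable direction bias, emitting BED/lengths/hit-table/GO-TSV
   inputs plus a JSON truth log, so every stage can be validated against
   known ground truth.

## Worked example

```python
>>> from synmito import fisher_exact_2x3, region_bias
>>> fisher_exact_2x3((0, 4, 132), (2, 4, 130))   # observed vs expected movements
0.6395121921624851
>>> res = region_bias("X", [True]*55 + [False]*765,
...                   total_mtn=1578, total_genes=20_000,
...                   n_boot=10_000, seed=17)
>>> round(res.bias, 2), round(res.ci_low, 2), round(res.ci_high, 2)
(0.85, 0.63, 1.07)
```

The first number says 136 observed mt-N movements binned (0, 4, 132) are
statistically indistinguishable (p ≈ 0.64) from the (2, 4, 130) expected
under chromosome size and content alone — no excess traffic off the X. The
second says a region carrying 55 class genes where 64.7 are expected has
bias 0.85 with a bootstrap CI spanning 1 — underrepresented, but not
significantly.

Narrative scripts in `examples/` walk each capability end to end
(`python examples/01_movement_tables.py`, …), and a thin CLI mirrors the
stages:

```sh
synmito simulate --seed 42 --outdir fixtures/
synmito run-all --config run.yaml --outdir report/
```

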