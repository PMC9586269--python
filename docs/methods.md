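# Methods

## The screening model

The screen targets genes expressed in exactly one tissue class out of a
small panel of bulk RNA-seq libraries. It assumes:

* counts are already summarized per gene (mapping is upstream and out of
  scope);
* library depth differences and gene-length differences are removed by
  RPKM, with the library total N(j) taken as the column sum of the count
  matrix — the standard proxy when the mapper's own "total mapped reads"
  figure is not carried along (the choice is recorded in the provenance
  of every normalization);
* tissue exclusivity is adequately captured by the shape of the raw RPKM
  profile. Correlation is computed on raw RPKM, not log-RPKM: the
  template is a 0/1 indicator, and on raw values r ≥ 0.99 demands that
  off-target expression be both small and uniform, which is exactly the
  exclusivity pattern sought. A log transform would reward genes with
  merely *proportionally* lower off-target expression.

The three filters are conjunctive and inclusive (≥). The fold change uses
the **maximum** over non-target libraries by default — the most stringent
reading of "target versus other samples", guaranteeing the ratio holds
against every individual library; the mean is available via
`fc_mode="mean"` for users who prefer the laxer contrast. With a single
target library, the "mean over target libraries" reduces to that
library's RPKM; with replicates it averages them.

### Pseudocount

FC is undefined for perfectly exclusive genes (denominator 0). Two
behaviours are provided: ε = 0 returns an explicit +∞ (serialized as
`inf`), and the default ε = 0.1 RPKM adds the pseudocount to both
numerator and denominator, turning an exclusive 10-RPKM gene into
FC = 101 while perturbing mid-range ratios by well under 5%. Note the
worked 5-gene example in the README is run at ε = 0, where the boundary
gene (10, 1, 2, 1) has FC exactly 10/2 = 5 and passes inclusively; at the
default ε = 0.1 its FC is 10.1/2.1 ≈ 4.81 and it fails — the pseudocount
is a genuine modelling choice, not a free constant.

### Undefined correlation

A profile with zero variance (constitutive or all-zero gene) has no
defined Pearson coefficient. Such genes cannot be tissue-exclusive, so
they fail the r filter (serialized as `NA`) instead of raising.

### Ordering

Screen records are sorted by (is_candidate desc, r desc, fold change
desc, gene_id asc), with undefined r after all defined values, so outputs
are byte-stable across runs and platforms.

## The simulator

The generator emulates the motivating study design: four single-library
conditions (`f-hl` = hind legs of sexual females, the target; `f-fl` =
front legs of sexual females; `af-hl` = hind legs of asexual females;
`m-hl` = hind legs of males), a genome of 20,918 gene models, and 21
genes planted exclusively in the target — 8 mevalonate-pathway genes,
6 iridoid-pathway genes and 7 mitochondrial transporters, with
annotations drawn from those pathways' enzyme classes so the triage
stage has realistic text to parse.

Counts are negative binomial with mean μ(g, j) = rpkm(g, j) · L(g) ·
N(j) / 10⁹, so intended expression is specified on the RPKM scale and
survives normalization in expectation. Defaults, and why:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 20,918 | the pea-aphid v3 gene-model count |
| `replicates_per_sample` | 1 | one pooled library per condition, as in the study design; r > 1 supported for power studies |
| `library_size_mean` | 2×10⁷ | ≈ 6 GB of PE150 reads per library |
| `library_size_cv` | 0.10 | log-normal depth variation typical of same-batch libraries |
| `nb_dispersion` (size k) | 5 | moderate bulk overdispersion; variance μ + μ²/k |
| `baseline_logmean_range` | (−2, 2) log₁₀ RPKM | background spans 0.01–100 RPKM, log-uniform |
| `gene_length_range` | 300–10,000 bp | uniform; spans typical mRNA lengths |
| spike target RPKM means | 200 / 150 / 100 | well above the RPKM ≥ 10 filter, CV 20% between genes |
| `leaky_fraction` | 0 | default fixture is truly exclusive; leaky genes get 10% of their target mean off-target (`leaky_level`), chosen to straddle the FC ≥ 5 boundary |

Randomness comes from `numpy.random.default_rng` (PCG64); the seed fully
determines every output, and the generator is named in each run's
provenance record.

### What the simulator does not model

Real libraries have correlated gene-gene structure, GC and length biases,
multimapping artefacts, and biological covariance between tissues; the
simulator's background genes are independent with a shared flat profile.
Passing the recovery tests therefore shows that the screen's logic is
correct and its false-positive behaviour under independent NB noise is
tiny — it does not certify false-positive rates on real tissue panels,
where shared biology (e.g. leg-specific but not sex-specific genes) is
the dominant confounder. Background annotations are drawn from a neutral
vocabulary without enzyme-class keywords, so class counts over spiked
candidates are exact; triage behaviour on misleading annotations is
exercised separately in the test suite.

## Triage

Candidate shortlisting in the source workflow combined annotation text
with curator judgment. Here it is formalized as ordered case-insensitive
substring matching: classes are tried in priority order and the first
match wins. "P450 reductase" precedes "cytochrome P450", which precedes
the generic "oxidase/reductase" list, so composite names resolve to the
most specific class. The map ships as an editable TSV
(`src/texscreen/data/keyword_map.tsv`); text matching alone is not
claimed to reproduce any particular curated shortlist.

## Evaluation

Positives are the `target_exclusive` genes; `leaky` genes count as
negatives, so a near-exclusive gene that passes the screen is a false
positive — the stringent reading of "exclusively expressed". Precision
and recall with empty denominators are reported as `NA`, never coerced.
The threshold sweep re-screens the same expression matrix at each grid
point; candidate counts are non-increasing in each threshold by
construction, and the tests assert it on randomized matrices as well.

## Numerical choices

* Pearson r is computed with a vectorized deviation-product formula in
  float64; tests cross-check it against `scipy.stats.pearsonr` to 1e-12
  relative, and the whole screen against a brute-force per-gene Python
  reference on 200 random matrices.
* RPKM satisfies Σ_g RPKM(g, j)·L(g) = 10⁹ exactly up to float error
  (asserted to 1e-6 relative; observed ~1e-14).
* On-disk RPKM is rounded to 4 decimals (configurable). The `pipeline`
  command screens the table *as written*, so running the stages by hand
  on each other's outputs is byte-identical to the pipeline.
* Problem sizes in the test suite and acceptance script (full 20,918-gene
  design, 10 seeds for the recovery study, 200 oracle matrices) keep the
  whole validation under a minute on one core while using the full-scale
  study design everywhere it matters.

## Known limitations

* No statistical test on r: the screen is a fixed-cutoff filter, as in
  the source workflow; with 4 libraries a correlation threshold has no
  meaningful sampling distribution anyway.
* Single-target-library designs give the template only one "1" entry;
  r ≥ 0.99 then mostly constrains the off-target spread. Multi-replicate
  targets are supported but the defaults do not exercise them.
* GFF3-derived lengths use the exon-interval union per gene (merged
  across transcripts) and fall back to the gene span when a gene has no
  exon features; isoform-specific effective lengths are out of scope.
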