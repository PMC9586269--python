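# texscreen

Tissue-exclusive expression screening for bulk RNA-seq count matrices.

Some genes matter precisely because they are expressed in exactly one
place. The motivating case is iridoid (nepetalactone) biosynthesis in the
pea aphid *Acyrthosiphon pisum*: the pathway's enzymes are active only in
the hind legs of sexual females, so candidate genes can be found by
screening a genome-scale count matrix for transcripts private to that one
tissue — no replicates, no differential-expression model, just a sharp
expression pattern. `texscreen` implements that screen as a tested,
reusable pipeline, together with a spike-in simulator that reproduces the
study design so every stage can be validated against known ground truth.

## The screen

Given read counts C(g, j) for gene g in library j and gene lengths L(g),
expression is normalized to RPKM:

    RPKM(g, j) = 10^9 · C(g, j) / (N(j) · L(g)),     N(j) = Σ_g C(g, j)

Each gene's RPKM profile **x** across libraries is compared with an
indicator template **t** (1 in target-tissue libraries, 0 elsewhere), and
a gene is a *candidate* when all three filters pass (inclusively):

* Pearson correlation  r(**x**, **t**) ≥ 0.99,
* mean target-library RPKM ≥ 10,
* fold change  FC = (mean target RPKM + ε) / (max non-target RPKM + ε) ≥ 5.

ε (default 0.1 RPKM) keeps FC finite for perfectly exclusive genes; with
ε = 0 an exclusive gene reports FC = ∞. Profiles with zero variance have
undefined r and fail the screen. Candidates are then triaged by ordered
keyword matching of their functional annotations into enzyme/transport
classes (prenyltransferase, phosphatase, P450 reductase, cytochrome P450,
oxidase/reductase, transporter).

The simulator draws a negative-binomial background (20,918 gene models, one
library per condition: `f-hl`*, `f-fl`, `af-hl`, `m-hl`) and plants 8
mevalonate-pathway, 6 iridoid-pathway and 7 transporter genes exclusively
in the target library `f-hl`, with truth labels for evaluation.

## Worked example

```bash
python analysis/01_simulate.py --seed 1   # results/fixture/
python analysis/02_normalize.py           # results/rpkm.tsv
python analysis/03_screen.py              # results/candidates.tsv
python analysis/04_triage.py              # results/triage.tsv, summary.tsv
python analysis/05_evaluate.py            # results/evaluation.tsv
python analysis/06_sweep.py               # results/sweep.tsv
```

With seed 1 this prints, in order: the design summary
(`21 genes spiked exclusive to f-hl: mevalonate=8, iridoid=6, transporter=7`),
then `22 candidates pass all three filters` — the 21 spiked genes plus one
background gene that fluctuated into an exclusive-looking pattern — then the
class table

```
IDS/prenyltransferase: 2    phosphatase: 1      P450 reductase: 1
cytochrome P450: 1          oxidase/reductase: 3  transporter: 7
unclassified: 7
```

and finally `precision=0.9545 recall=1.0000 background FPR=0.000048`:
every planted gene is recovered, and fewer than 1 in 20,000 background
genes slip through at the default thresholds. The sweep table shows the
filters behaving monotonically — e.g. tightening `fc_min` from 2 to 5
drops the candidate count from 46 to 22.

The same stages are available as one command-line tool:

```bash
texscreen pipeline --simulate --seed 1 --out-dir results/run1
texscreen normalize --counts counts.tsv --genes genes.tsv \
    --samples samples.tsv --out rpkm.tsv   # ... screen / triage / evaluate / sweep
```

Every pipeline run writes a `provenance.json` (effective config, seed,
tool version) sufficient to reproduce it exactly.

## Layout

* `src/texscreen/` — the library: `simulate`, `core` (I/O + RPKM),
  `screening`, `triage`, `evaluation`, `cli`.
* `analysis/` — numbered narrative drivers for the end-to-end analysis.
* `tests/` — pytest suite, including a brute-force reference screen used
  as an independent oracle.
* `docs/methods.md` — modelling and design notes.
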