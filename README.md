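# mitodlp

Joint single-cell analysis of mitochondrial and nuclear genomes for
amplification-free single-cell whole-genome sequencing (scWGS, DLP+-style),
where read-depth ratios are directly interpretable as copy number. The
package is aimed at analysts of single-cell cancer genomes who want to ask,
per cell: how many mtDNA copies does this cell carry, which heteroplasmic
mtDNA variants does it bear, which clone does it belong to, and does
heteroplasmy covary with mtDNA copy number?

Everything runs on a bundled synthetic-data generator that reproduces the
statistical structure of such experiments (clones with distinct
mtDNA-to-nuDNA ratios, whole-genome-doubled subpopulations, clone-specific
heteroplasmy, strand-split binomial read counts), so the full analysis is
testable without any controlled-access sequencing data.

## What it computes

**Copy number.** For each cell, with average ploidy the mean copy-number
state over 500-kb nuclear bins,

```
MNR = mtDNA depth / nuDNA depth        CN = MNR x average ploidy
```

MNR (the mtDNA-to-nuDNA ratio) is copies per average haploid nuclear
genome. Baseline (modal) ploidy labels cells diploid/tetraploid for
whole-genome-doubling (WGD) contrasts: CN should double with WGD while MNR
stays flat — stoichiometric homeostasis — and the percent MNR change
`100 x (median MNR_tet - median MNR_dip) / median MNR_dip` quantifies
departures.

**Variant genotyping.** Pileup-level strand counts pass a three-filter
stack: >= 2 alternate reads on each strand in pseudo-bulk; forward/reverse
per-cell heteroplasmy correlation R >= 0.2; exclusion of the homopolymer
blacklist regions 513–525 and 3105–3109. Per-cell heteroplasmy is the
strand-pooled alternate fraction.

**Clonal inference (MityBayes).** Alternate counts are binomial with
clone-specific heteroplasmy `P_kv`; the model maximizes the marginal MAP
objective `sum_c log sum_k pi_k prod_v Binom(a_cv | t_cv, P_kv) + log prior`
by EM (default) or gradient ascent, with an exhaustive-enumeration oracle
for small instances and BIC-based selection of the clone count. A fallback
hierarchical clustering of nuclear bin profiles (with an optional
UMAP+HDBSCAN adapter) provides the nuclear-clone cross-check.

**Association.** A stratified, weighted concordance statistic (Kendall-tau
style; strata are libraries, weights are library cell counts) links
heteroplasmy to copy number per variant, with an analytic normal z/p, a
permutation calibration oracle and Benjamini–Hochberg correction; ordinary
least squares regresses CN on cell diameter per library (slope in copies
per micron).

## Worked example

The numbered scripts under `analysis/` run the full study on the canonical
synthetic dataset and write tables under `results/`:

```
python analysis/01_simulate_dataset.py
python analysis/02_genotype_variants.py
python analysis/03_copy_number_wgd.py
python analysis/04_clonal_inference.py
python analysis/05_heteroplasmy_cn_association.py
python analysis/06_downsampling_stability.py
```

With the default seed, stage 02 prints the filter outcome for the six
planted variants, e.g.

```
quality gate (>= 0.75): kept 115 / dropped 5
variants: 6 called, 6 PASS
  m.1539G>T  pooled h=0.354 strand R=0.97  PASS
```

(pooled heteroplasmy ~0.35 because each variant lives in one of two equally
sized clones at heteroplasmy 0.4–0.9). Stage 03 shows the WGD contrast —
copy number roughly doubles while MNR does not move —

```
SIM01: CN log2FC=0.83 (p=9.2e-06), MNR change=-9.8% (p=0.78)
confounded pooled MNR change: +19.5%
  within clone A: -5.7%  (vanishes under stratification)
```

together with the confounding demonstration: a clone with sqrt(2)-fold
higher MNR that is mostly tetraploid creates an apparent +19.5% pooled
diploid-to-tetraploid MNR shift that disappears once the contrast is
stratified by clone. Stage 04 recovers the two clones from mtDNA variants
alone (BIC chooses K=2) and agrees perfectly with the nuclear-profile
clustering:

```
chosen K = 2
assignments: {'1': 58, '0': 57}
nuclear vs mtDNA clone agreement: ARI = 1.000
```

Stage 05 reports per-variant concordance (no variant is truly coupled to CN
in this simulation, so q-values are null) and the size regression, which
recovers the generative 24 copies per micron (`slope=24.2 copies/um`).
Stage 06 shows estimation stability under binomial depth downsampling: at
30% of the original 80x depth, per-cell CN still correlates at r=0.997 with
the full-depth estimates and 100% of PASS variants are retained.

The same pipeline is available as a CLI for one-shot runs:

```
mitodlp run --seed 0 --outdir run/
```

## Layout

```
src/mitodlp/        library: simulate, genotyping, copynum, mitybayes,
                    assoc, clones_nu, pipeline, cli
analysis/           numbered drivers for the canonical study
scripts/acceptance.py   headline-quantity recomputation
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     model descriptions, defaults, limitations
```
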