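# Methods

`mitodlp` re-creates, on synthetic data, the co-analysis of mitochondrial and
nuclear genomes that amplification-free single-cell whole-genome sequencing
(DLP+-style) makes possible: per-cell mtDNA copy number, heteroplasmic
variant genotyping, clonal inference from mtDNA variants, and association of
heteroplasmy with copy number. This note describes the models, the defaults
and why, what the synthetic generator does and does not emulate, and the
numerical choices.

## Copy number and MNR

Because the platform is amplification-free, depth ratios are interpretable
as copy number. For each cell

```
MNR = mtDNA read depth / nuDNA read depth            (copies per haploid genome)
CN  = MNR x average ploidy                           (copies per cell)
```

where *average ploidy* is the mean integer copy-number state over
500-kb-equivalent nuclear bins and *baseline ploidy* is the modal state
(ties broken toward the smaller state, which is conservative against
over-calling whole-genome doubling). Baseline ploidy defines the
diploid/tetraploid labels used in WGD contrasts; average ploidy enters the
CN formula. Both depths are mean per-base coverages, not read counts, so the
ratio is read-length independent. The identity `CN = MNR x average ploidy`
holds exactly for every emitted cell and is tested as such.

WGD contrasts report, per sample (or per library with
`stratify_by_library=True`): median CN and MNR per ploidy class, log2 CN
fold change, the percent MNR change
`100 x (median(MNR_tetraploid) - median(MNR_diploid)) / median(MNR_diploid)`,
and Wilcoxon rank-sum p-values (two-sided for CN; configurable, with
one-sided "greater" testing an MNR increase in tetraploid cells). Groups
need at least 20 cells per ploidy class by default; smaller groups are
skipped with a reason rather than silently dropped.

## Variant genotyping

Input is pileup-level strand-split allele counts per (cell, variant);
mapping quality > 20 and base quality > 20 are assumed upstream. Three
filters, each an independent predicate of the data (hence order-invariant):

* **strand support** — pseudo-bulk across quality-passing cells must have at
  least 2 alternate reads on each strand;
* **strand concordance** — per-cell forward and reverse heteroplasmy must
  correlate (Pearson R >= 0.2) across cells informative on both strands;
  fewer than 3 informative cells, or zero variance on either strand, fails
  conservatively with a reason code (the correlation is undefined there);
* **blacklist** — homopolymer repeat regions 513–525 and 3105–3109
  (1-based, both ends inclusive) are excluded; coordinates are 1-based on a
  circular contig.

Per-cell heteroplasmy is the strand-pooled alternate fraction
`(fwd_alt + rev_alt) / (fwd_total + rev_total)`, missing where the
denominator is zero. A variant is called homoplasmic when its median defined
heteroplasmy exceeds 0.95 — a deliberate operationalization, since
haplogroup-based germline classification is out of scope here.

Trinucleotide spectra are computed with circular wrap-around on the given
(L) strand and its reverse complement (H), each normalized by the frequency
of the context on that strand; de-normalizing recovers the substitution
totals, which is tested. Length heteroplasmy at a homopolymer anchor (the
m.302 poly-C tract being the motivating case) reports the reference-allele
fraction and major allele per cell, restricted to cells with at least 10
reads at the anchor.

## MityBayes clone model

Alternate counts are Binomial: `a_cv ~ Binom(t_cv, P_kv)` with clone-specific
heteroplasmy `P_kv`, and cells are exchangeable draws from clone fractions
`pi`. The fit maximizes the marginal MAP objective

```
sum_c log sum_k pi_k prod_v Binom(a_cv | t_cv, P_kv) + log Dir(pi; alpha) + sum log Beta(P_kv; a, b)
```

Defaults are flat priors (alpha = a = b = 1), exposed in `Priors`; `P` is
clipped to [1e-6, 1-1e-6] for stable logarithms. Two backends optimize the
same objective:

* **EM** (default): exactly monotone; MAP M-steps for `pi` and `P`.
* **Gradient** (`map_grad`): ascent on softmax(pi)/sigmoid(P) parameters
  with backtracking line search starting at step 0.1 — a point-mass (MAP)
  treatment of the latent parameters. Backtracking keeps the objective trace
  monotone, which a fixed-step adaptive optimizer would not guarantee; the
  backends agree on the partition and closely on the objective.

Both use 8 random restarts by default (seeds derived from the master seed)
and stop when the relative objective change drops below 1e-5. Assignment
probabilities are the responsibilities at the optimum; hard labels take the
argmax when it exceeds `min_prob` (default 0.9), else "unassigned", with
ties to the lowest clone index. Per-variant contribution weights are the
expected log-likelihood gain of clone-specific over pooled heteroplasmy,
rescaled to [0, 1]; constant variants score 0, clone-separating variants
score high.

`exact_posterior` is the test oracle: on instances up to 8 cells x 4
variants x 3 clones it enumerates every assignment; given an assignment the
likelihood factorizes over (clone, variant), so the heteroplasmy grid
(0.01 steps) is profiled exactly per entry. Clone fractions are profiled at
their MAP or held uniform. Raw assignment marginals are label-symmetric
under exchangeable priors (a single cell always gets uniform marginals), so
agreement with the mixture fit is checked on the label-invariant
co-assignment matrix P(z_i = z_j) and the MAP partition. One subtlety:
profiling `pi` per assignment concentrates no-data posteriors on
single-clone assignments (an empirical-Bayes artifact of maximizing instead
of integrating), so degenerate no-data comparisons use the uniform-`pi`
mode, where fit and oracle coincide exactly.

`select_k` scores each K by BIC, `-2 x data log-likelihood +
[(K-1) + K*V] x log(cells)`, and returns the full table so the choice can
be overridden — the clone-count prior is treated as user input, with BIC as
a default selector.

## Nuclear-profile clones

The standard embedding/density route (UMAP with min_dist 0, correlation
metric; HDBSCAN with cluster_selection_epsilon 0.2,
approx_min_span_tree False, gen_min_span_tree True) is an optional adapter,
since those algorithms are off-the-shelf. The default backend is
average-linkage hierarchical clustering on correlation distance, cut at a
requested clone count or a distance threshold. Correlation distance is
undefined for constant profiles; identical rows are placed at distance 0 and
constant-vs-different rows at distance 1. Cluster letters are assigned by
(size, then smallest member cell id), so labels are stable under cell-order
permutation. The nuclear/mtDNA cross-check reports a contingency table,
adjusted Rand index, and each nuclear clone's modal mtDNA clone.

## Concordance statistic

Within each stratum (sequencing library), all observation pairs are
classified by the sign of `(h_i - h_j)(y_i - y_j)`; ties contribute half.
With per-stratum concordance `c_s` and weights `w_s` (cells in the library):

```
c = sum_s w_s c_s / sum_s w_s           c_scaled = 2c - 1
Var0(c_s) = [2(2n_s + 5) / (9 n_s (n_s - 1))] / 4
z = (c - 1/2) / sqrt(sum_s w_s^2 Var0(c_s) / (sum_s w_s)^2)
```

with a two-tailed normal p-value. `c_scaled` equals Kendall's tau-a exactly
in a single tie-free stratum (tested against an O(n^2) brute-force oracle),
and is invariant to strictly monotone transforms of either variable. The
null variance is the Kendall null variance mapped to the concordance scale
and combined across strata with squared weights; a within-stratum
permutation test is the calibration oracle for it, and the type-I error at
alpha 0.05 is verified to sit near 0.05 under simulated independence.
Observation filters: alternate reads >= 10 per cell-variant observation (the
stricter per-cell reading), heteroplasmy strictly inside (0.05, 0.95) with
the endpoints retained, and a per-variant surviving range >= 0.15
(inclusive). Multiple testing uses Benjamini–Hochberg across variants;
the cell-size regression BH-adjusts across libraries.

## Synthetic data

The generator emulates, per cell: clone membership (categorical), WGD
(clone-specific probability; tetraploid cells are an exact doubling of the
clone's diploid bin profile), nuclear bin states (each clone carries its own
random one-state alterations in a configurable fraction of bins — a
single-clone simulation stays flat diploid — plus rare per-cell bin flips),
true CN = clone MNR x average ploidy x median-centred lognormal noise with
`sigma = sqrt(ln(1 + CV^2))` so the target CV (default 0.65) is met and
`clone_mnr` is the clone's median MNR, matching the median-based summaries
downstream. Depths follow: nuclear depth is Gamma around its mean (default
0.2x), mtDNA depth is `nu_depth x MNR`. Read counts per variant site are
Poisson with rate proportional to the cell's CN relative to the library
mean (default 80x at the mean, mirroring a deeply sequenced library);
alternate reads are Binomial(total, clone heteroplasmy) and each read lands
on a strand with probability 1/2, so strand counts are exchangeable and sum
exactly. Cell diameter is affine in CN (default 24 copies per micron) plus
Gaussian noise. Default clone MNR values are geometrically spaced from 378
(a diploid median of ~750 copies per cell); clone heteroplasmy defaults
assign each variant to one owner clone at heteroplasmy U(0.4, 0.9).

Deliberate omissions, hence what passing tests do not show about real data:
no read-level error model or NUMT contamination (the strand-artifact
injector is a caricature used for negative tests); bin states are truth-like
inputs, not segmentation outputs, so segmentation error is not represented;
quality scores are drawn, not derived from read features; diameter is a
deterministic function of CN plus noise, so within-library size correlations
are near 1 rather than the 0.3–0.5 typical of real libraries; doublets and
cell-cycle effects are absent.

## Problem sizes and determinism

All randomness flows from one master seed through named substreams
(`SeedSequence` on [seed, stage-hash]); reruns are byte-identical. The
bundled analyses use 120–3,000 cells and 2–10 variants — sizes at which
every stage completes in seconds on one CPU while Monte-Carlo error stays
small relative to the tested effects; the clone-recovery replicates use 200
cells x 10 variants x 3 clones at 50x, where assignment is near-perfect and
heteroplasmy RMSE is well under 0.05. One caveat is intrinsic: a
diploid/tetraploid contrast of group medians at 2,000 cells under CV 0.65
has a Monte-Carlo s.e. near 3.4%, so single-seed values of the MNR percent
change scatter by a few percent around zero even though the estimator is
unbiased under the homeostatic generator.

## Known limitations

* The concordance null variance ignores tie corrections; the permutation
  oracle shows calibration is unaffected at the tested sizes, but heavily
  tied data (e.g. discretized heteroplasmy) would warrant the permutation p.
* BIC-based clone-count selection assumes well-separated binomial clones;
  overdispersed (beta-binomial) counts would favor too many clones.
* The homoplasmy threshold stands in for haplogroup-based germline calling
  and will misclassify low-frequency germline variants as heteroplasmic.
* Circular-coordinate handling assumes a single contig; multi-contig
  references are not supported.
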