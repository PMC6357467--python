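# Methods

This note documents the statistical models implemented in `dmrkit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Differential methylation model

The unit of analysis is the destranded CpG: the two cytosines of a CpG
dyad are merged (counts summed, reported at the plus-strand coordinate)
before any statistics. The analysis-ready matrix keeps CpGs whose total
coverage is at least `min_coverage` (default 1) in every sample of every
group; the rule and threshold are configurable because published cohort
analyses rarely state theirs.

Group differences are **pooled proportions**, `Σmeth/Σtotal` within each
group, rather than means of per-sample proportions. At 5–15× coverage a
single sample's proportion at one CpG is extremely noisy (a 8× binomial);
pooling weights samples by the evidence they carry and is the stabler
choice at low coverage. The smoothing weight `w_i = sqrt(total coverage)`
tempers the same heteroscedasticity without letting a single deep CpG
dominate its window.

Smoothing is a windowed weighted mean (±500 bp default) that never crosses
an inter-CpG gap above `max_gap` (1000 bp default): CpG correlation decays
on the hundreds-of-bp scale and deserts of the CpG landscape should not
couple unrelated regions. An isolated CpG keeps its raw difference.

Candidate regions are maximal runs of ≥ `min_cpgs` (default 5) consecutive
CpGs with `|s_i| ≥ cutoff` (default 0.10) and constant sign, gaps ≤
`max_gap`. Region coordinates run from the first CpG to two bases past the
last (half-open, covering the final dyad). The area statistic `Σ s_i`
grows with both effect size and region extent, which matches the intuition
that long coherent shifts are stronger evidence than short spikes. The
reported percent difference is the pooled-proportion difference over the
region's CpGs; it is rounded to an integer only in BED/report output.

### Permutation inference

Group labels are permuted preserving group sizes; when the number of
distinct assignments is at most `n_perm` (default 1000) all are enumerated
exactly once (e.g. C(6,3)=20 for a 3 vs 3 comparison). For each permuted
labelling the pipeline re-runs smoothing **and segmentation** and collects
the areas of the permutation's own candidate regions. Two nulls follow:

- the pooled null (all permutation-detected areas across regions and
  permutations) gives the per-region empirical p — pooling stabilises
  tail estimates at desk scale;
- the per-permutation maximum |area| (0 for permutations with no
  candidate) gives the FWER by the max-statistic construction, which
  controls the probability of any false region genome-wide.

Re-detecting candidates inside each permutation, rather than re-scoring
the observed windows, is essential: observed candidates are selected
maxima, and comparing them against permuted areas at the same fixed
windows is anti-conservative. With re-detection, 20 signal-free synthetic
cohorts produced a false FWER hit in 1 of 20 runs (nominal 5%).

Ties count as exceedances and the add-one estimator is used, so no p-value
is ever zero and degenerate inputs (all samples identical) give p = FWER
= 1. BH q-values are computed over the pooled-null p-values. Direction
(hyper/hypo, case minus reference) is assigned after testing; all
statistics are two-sided.

## Consensus signatures

A disease-specific region must (i) separate cases from healthy controls,
(ii) overlap by ≥ 1 bp a same-direction region separating cases from
disease controls, and (iii) overlap no region (any direction) separating
disease controls from healthy controls. Direction agreement in (ii) is
required because hyper- and hypo-methylated counts are reported
separately; the ≥ 1 bp rule is the weakest overlap criterion and therefore
the most conservative exclusion in (iii). The case-vs-healthy record is
the representative; provenance keeps the partners. The enrichment
background is the anchor comparison's full candidate list minus the
consensus regions — the universe of regions the caller actually tested.
All interval logic is half-open: touching regions do not overlap.

## Enrichment

The enrichment unit is the region (≥ 1 bp overlap), not base pairs,
mirroring "fraction of regions overlapping a state" reporting. The 2×2
table (query vs background × overlap vs not) is tested with the two-sided
Fisher exact test; the odds ratio uses the Haldane–Anscombe 0.5 correction
only when a cell is zero, and output flags when it did. Gene-set overlap
uses the hypergeometric upper tail with the gene-model table as the
default universe; enrichment p-values are therefore universe-relative.
The cell-type screen reports (i) the fraction of DMRs at
cell-type-specific promoters and (ii) per-promoter Welch t-tests between
groups with the nominal p<0.05 rate — a near-nominal rate argues that
cell-composition shifts do not drive the signal.

## Gene annotation

Gene models are single-TSS records. Distance is measured from the nearest
region edge to the TSS point (0 when the region covers it), in kb at one
decimal, signed negative upstream with respect to gene strand. Position
categories: TSS if the region covers the TSS; otherwise the region
midpoint decides Exon/Intron inside the span (a region can straddle both;
one label is needed) or the strand-aware Upstream/Downstream side. The two
nearest genes are reported by default; ties break lexicographically.

## Phenotype classifier

Discrete AdaBoost (SAMME) over depth-1 trees, 100 rounds, learning rate
1.0, with missing features imputed by training means. Training is
two-stage: a full-feature fit ranks regions by importance, regions with
importance > 0 become the panel, and the final model is refit on the panel
— this is how a sequencing assay would be reduced to a targeted panel.
Micro-averaged precision (total correct over total predicted) is reported
because it is the only convention under which 9 of 10 correct yields 0.9
in a balanced binary test; AUC uses the ensemble margin with the hepatic
phenotype as positive class. Note that with tens of samples and thousands
of regions a single fortuitous feature can separate the training set, in
which case boosting stops early and the panel is small; noisier features
yield larger panels.

## Synthetic data: what it emulates

The generator reproduces the statistical skeleton of a low-coverage WGBS
case/control study:

- **CpG landscape**: geometric inter-CpG gaps (mean 200 bp) over toy
  chromosomes (two of 5 Mb by default — large enough for segmentation
  edge cases, small enough for desk-scale runs); bimodal baseline
  methylation (island-like blocks low ≈ 0.2, background high ≈ 0.8).
- **Counts**: coverage ~ negative binomial (mean 8×, dispersion 3,
  matching "relatively low coverage" cohort sequencing); per-sample
  methylation proportion ~ Beta with precision φ = 30 around the group
  mean (realistic inter-sample variance at this depth); methylated reads
  ~ Binomial. Methylated ≤ total holds by construction.
- **Planted regions**: signed shifts on the proportion scale, clipped to
  [0.01, 0.99], magnitudes bracketing the 10–40% differences reported for
  genome-wide-significant regions. The placement helper is
  baseline-aware — positive shifts go to low-methylation runs, negative
  to high-methylation runs — because a +0.3 shift on a 0.8 baseline would
  clip to +0.19 and no generator setting could then realise the nominal
  effect; biologically this mirrors hypermethylation of normally
  unmethylated regulatory regions.
- **Annotations**: the "enhancer-like" set is random intervals whose
  density gives a ~1 kb region a base overlap rate of 0.2, topped up so
  planted hypermethylated regions are covered at a configurable multiple
  of that rate (factor 1 = no preference); matched null sets carry no
  preference. Gene models are evenly spaced single-TSS genes with random
  strand and exon structure; the drug table includes one drug whose
  targets are the genes nearest the planted regions.
- **Covariates**: age/sex/BMI/fibrosis/inflammation/steatosis drawn
  independently of group by default (so association screens are null); a
  switch skews fibrosis in the case group for confounding power tests.
- **Region-level phenotype tables**: for classifier experiments, region
  percent methylation is drawn directly with beta precision 10 (~0.17 sd
  between subjects). This is deliberately noisier than φ = 30 per CpG:
  within a region one subject's CpGs are strongly correlated, so
  averaging CpGs does not shrink inter-individual variance, and DMR-level
  methylation typically varies by 10–20 points between subjects. Train
  and independent test cohorts share the same per-region means — a panel
  cannot transfer across unrelated feature definitions.

What it does **not** emulate: read-level data (FASTQ, bisulfite conversion
errors), non-CpG contexts, sex chromosomes and imprinting, linkage between
covariates and methylation (unless switched on), realistic chromatin
state geography, or inter-region correlation. Passing recovery tests on
this generator therefore demonstrates that the machinery is correct and
calibrated under the stated model, not that real cohorts of a given size
would yield the same power.

## Problem sizes and numerical conventions

Validation experiments run at: DMR recovery on 2 × 5 Mb, 10 vs 10, 1000
permutations; error control on twenty 2 Mb, 6 vs 6 null cohorts at 300
permutations; enrichment on twenty replicates of 120 planted regions vs
400 background regions; classifier on twenty seeds of 2860 regions
(44 informative), 20+20 train, 5+5 test. These sizes make the full
validation a couple of minutes on one CPU while keeping every test at the
cohort scale of the motivating studies.

Numerical conventions: PCA scores come from the SVD of the
sample-centered matrix, each component oriented so its largest-magnitude
loading is positive; missing region values impute to the region mean
(0 after centering). Bonferroni adjustment is `min(1, p·m)` with m = the
number of regions tested per covariate. Fibrosis stage is treated as
ordinal numeric in regressions. Every random draw in a pipeline run
derives from the single config seed; reruns are hash-identical.

## Known limitations

- Permutation inference needs exchangeability: with confounded covariates
  the FWER guarantee applies to the permutation null, not to the
  covariate-adjusted question (covariate-adjusted calling is out of
  scope; the association screen flags, it does not correct).
- The pooled empirical p borrows strength across regions; with few strong
  regions and many weak ones it is conservative for the weak ones.
- Enrichment p-values depend on the chosen background and universe;
  values are comparable within a run, not across studies.
- Small groups (3 vs 3) admit only 20 label assignments, so the smallest
  achievable FWER is 2/21 ≈ 0.095 — genome-wide significance is
  unreachable there by construction.
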