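# dmrkit

Differential methylation analysis for low-coverage whole-genome bisulfite
sequencing (WGBS) cohorts, built around the kind of case/control liver and
blood methylome studies used to characterise Wilson disease: region-level
differential methylation with permutation family-wise error control,
disease-specific consensus signatures, functional region-set and gene-set
enrichment, covariate and cell-type confound screens, and a boosted-stump
classifier that turns region methylation into a phenotype biomarker panel.

It is aimed at analysts who start from per-CpG cytosine reports (Bismark
style) plus a sample sheet, and who want every stage — from count matrix to
classifier — as plain, reproducible, individually testable steps. A
synthetic-data module generates complete cohorts with planted ground truth
so that every claim the pipeline makes can be checked against a known
answer.

## The statistics in brief

**DMR calling.** For CpG `i`, with pooled (coverage-weighted) group
proportions `p_A(i) = Σm_A/Σt_A` and `p_B(i)`, the raw difference
`d_i = p_A(i) − p_B(i)` is smoothed within ±`window` bp (never across gaps
larger than `max_gap`):

```
s_i = Σ_j w_j d_j / Σ_j w_j ,   w_j = sqrt(total coverage at CpG j)
```

Candidate regions are maximal same-sign runs of ≥ `min_cpgs` CpGs with
`|s_i| ≥ cutoff`; each is scored by its area `A_r = Σ_{i∈r} s_i`. Group
labels are then permuted (all distinct assignments enumerated when there
are few enough): each permutation re-runs smoothing and segmentation, the
detected null areas are pooled across permutations for the empirical
per-region p-value, and the per-permutation maximum `|A|` yields the
family-wise error rate (max-statistic, strong control):

```
p_r    = (1 + #{null |A| ≥ |A_r|}) / (1 + pool size)
FWER_r = (1 + #{perm max |A| ≥ |A_r|}) / (1 + n_perm)
```

with Benjamini–Hochberg q-values over `p_r`. Hypermethylated means higher
methylation in the case group.

**Consensus.** A region is disease-specific when it separates cases from
healthy controls, overlaps (≥ 1 bp) a same-direction region separating
cases from disease controls, and overlaps no region separating the two
control groups.

**Enrichment.** Region-unit Fisher exact tests of annotation overlap
(query vs background candidate regions), hypergeometric gene-set overlap,
transcription-factor co-occurrence counts, and a Welch-test screen of
cell-type-specific promoters for cell-composition confounding.

**Classifier.** Discrete AdaBoost (SAMME) over depth-1 trees on region
percent methylation; regions with feature importance > 0 form the panel
and the model is refit on the panel alone. Evaluation reports
micro-averaged precision (= accuracy for binary prediction) and ROC AUC of
the ensemble margins on an independent cohort.

## Worked example

```python
import numpy as np
from dmrkit import (
    SimulationConfig, simulate_cpg_landscape, plant_dmr_truth, simulate_cohort,
    call_dmrs, DMRCallingParams,
)
from dmrkit.simulate import choose_planted_regions

config = SimulationConfig(seed=42, n_per_group={"WD": 10, "HC": 10})  # 2 x 5 Mb
landscape = simulate_cpg_landscape(config)
specs = choose_planted_regions(landscape, 50, [0.3, -0.3], n_cpgs=10,
                               rng=np.random.default_rng(7))
truth = plant_dmr_truth(landscape, specs)
cohort = simulate_cohort(landscape, truth, config)

result = call_dmrs(cohort.matrix, cohort.sample_sheet, "WD", "HC",
                   DMRCallingParams(n_perm=1000, seed=5))
called = result.significant(0.05, "q")
print(len(result.candidates), "candidates,", len(called), "significant at q<0.05")
```

prints

```
51 candidates, 49 significant at q<0.05
```

— 50 regions with a ±0.30 methylation shift were planted; 49 of the 51
candidate regions pass q < 0.05, all of them overlap a planted region
(empirical FDR 0), and 49 of the 50 planted regions are recovered
(sensitivity 0.98). The same run from the shell:

```bash
dmrkit simulate --outdir sim --seed 42
dmrkit matrix --sheet sim/samples.tsv --out matrix.tsv
dmrkit call-dmrs --matrix matrix.tsv --sheet sim/samples.tsv \
    --groups WD,HC --perms 1000 --seed 5 --out dmrs.bed
```

The package also ships a reference table of 18 genome-wide-significant
Wilson disease liver DMRs (`dmrkit.consensus.load_reference_dmr_table()`),
used as a worked example for the significance filter: at FWER < 0.05 all
18 regions pass; at FWER < 0.02 exactly the 4 regions printed below that
threshold remain.

## Layout

- `dmrkit.simulate` — synthetic cohorts, annotations, gene models, truth sets
- `dmrkit.io` — cytosine reports, sample sheets, BED/bedGraph, count matrix
- `dmrkit.calling` — difference track, smoothing, segmentation, permutation test
- `dmrkit.consensus` — directional intersection/subtraction, significance filter
- `dmrkit.stats` — region tables, centering, PCA, covariate association
- `dmrkit.enrichment` — Fisher region enrichment, gene sets, promoter screen
- `dmrkit.annotation` — nearest-TSS assignment, position categories, drug targets
- `dmrkit.classify` — boosted-stump phenotype classifier
- `dmrkit.pipeline` / `dmrkit.cli` — config-driven orchestration, `dmrkit` CLI

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
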