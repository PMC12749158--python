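# Methods

This note documents the models, formulas, numerical choices and known
limitations behind `vasosyn`, in the order the pipeline applies them.

## Design and units

The unit of inference is the **paired set**: one animal's four samples
(CTRL, MET, HUM, ALL) from the same cell passage, treated in parallel. The
pairing key is (animal, cell type, passage); groups missing a condition are
dropped with a warning rather than erroring, to tolerate real-world sample
sheets. Expression is in **FPM** (fragments per million): count × 10⁶ /
library size, with library size defined as the per-sample column total of
the matrix at hand. Whether total mapped reads or assigned counts should be
the denominator is a genuinely open choice; the column total is used as the
self-contained default and an explicit library-size mapping can be supplied
instead.

## Variability-derived threshold

Per gene, CV = SD/mean of control-sample FPM using the n−1 sample standard
deviation (the small-n choice; with 4 controls the n-denominator would
understate variability). The |log₂FC| threshold is exactly 3 × the mean CV.
Genes with control mean FPM below `min_mean_fpm` (default 1) are excluded
from the CV average: at unexpressed genes the CV estimator degenerates to
0/0 noise that would otherwise dominate the mean. The triple DEG filter then
requires (i) FDR < 0.05 in both method columns, (ii) mean FPM ≥ 3 in at
least one group, (iii) |log₂FC| ≥ threshold — with ≥, so a gene exactly at
the threshold passes.

## Paired effects and the exclusion test

Per-set ratios stressor/control are summarized by their geometric mean; the
CI is built on the log₂ scale with the t-distribution (n−1 df) and
back-transformed. Ratios are strictly positive and fold-type effects are
multiplicative, which makes the log scale the natural home for a symmetric
interval; a bootstrap would need far more than 4 sets to be informative.
Significance = the CI excludes 1; at level 1−α this is exactly the two-sided
one-sample t-test on log-ratios. Pairs with a non-positive value are dropped
for that gene (with an audit count) rather than pseudocounted; a configurable
pseudocount (default 0) is available. Biomarker-panel genes are each tested
at α = 0.01 without multiplicity correction — each panel member is an
a-priori hypothesis, and the panel report counts genes affected in any
condition.

### The built-in genome-wide test

When external DESeq2/edgeR-style FDR columns are not supplied, both FDR
columns are filled by the built-in one-sample test on log₂ ratios with
Benjamini–Hochberg correction. With only ~4 paired sets, a plain per-gene t
has essentially no genome-wide power after FDR control (the df-3 null is so
heavy-tailed that even true two-fold effects rarely reach BH-adjusted
significance), and the genes it does select are exactly those whose variance
was underestimated — a selection artifact. The default test therefore
moderates variances across genes in the empirical-Bayes fashion standard for
small-n expression designs: per-gene variances are squeezed toward a prior
fitted by matching the moments of log s² to a scaled F-distribution, and the
t statistic uses the posterior variance with inflated degrees of freedom.
The plain per-gene test remains available (`moderated=False`). Effect
estimates, CIs and exclusion verdicts are never moderated — only the
genome-wide screening p-values.

## Synergy decomposition

Additive prediction and synergy index are exact identities on the log₂
scale: additive = met + hum, index = measured − additive. Per-gene
classification (none / metabolic / humoral / additive / synergistic up or
down) reuses the variability-derived threshold as the materiality cut for
the synergy index; this is an explicit formalization — the aggregate
comparisons (DEG counts, slopes) do not depend on it.

The scatter slope is **through-origin least squares**, β = Σxy/Σx², with
x = log₂FC(ALL) and y = log₂FC(single condition), over the ALL-condition DEG
set. Through-origin matches the interpretation "β ≈ 1 ⟺ equal effects":
with an intercept, a cloud of nulls plus a handful of concordant genes can
produce a slope near 1 for the wrong reason. Because x is an estimate, the
slope carries mild regression attenuation (selection on |x| and noise in x);
on simulated no-interaction data it lands near 0.93–0.95 rather than exactly
1. The attenuation is partially offset by the shared-control-sample
correlation between the two coordinates, which the paired design creates by
construction.

Set reconciliation: for a gene present in only one condition's DEG list, the
other condition's CI is checked for coverage of the first condition's point
estimate; coverage = "concordant" (the gene missed one list through filter
stringency, not through a different effect). This formalizes a narrative use
of CI limits and is the package's interpretation, documented as such.

The enrichment score E = (intersection/query)/(term/domain) is the plain
fold-enrichment ratio; no hypergeometric p-value is attached (out of scope).

## Phenotype readouts

- **Circularity** C = 4πA/P²; values marginally above 1 from discretized
  perimeters are clipped to 1 with a warning. Ellipse circularities use
  Ramanujan's perimeter approximation (relative error < 10⁻⁶ over the axis
  ratios involved). Cell objects are filtered to single-nucleus objects with
  area in [400, 4000] µm² before any shape statistics; per-sample medians
  are used because circularity is not normally distributed.
- **Contraction model**: an ellipse shortens its long axis by fraction s;
  the short axis responds per mode — 2-D area conserved (b/(1−s)), prolate
  3-D volume conserved (b/√(1−s), the default, matching an ellipsoidal cell
  body), or constant width. From a baseline circularity of 0.26 and 20%
  shortening the three modes give ≈0.39 / ≈0.35 / ≈0.32 after; the exact
  assumption behind an observed 0.26→0.37 change is not recoverable, so all
  three modes are exposed and none is presented as ground truth.
- **Cell-cycle gating**: the G1 mode m is the kernel-density maximum over
  the lower half of the DAPI-integral distribution; gates are m(1 ± w/2)
  and 2m(1 ± w/2) with window w = 0.3, S between, and nuclei outside the
  outer bounds excluded as debris/aggregates. The gate geometry is a
  robustness choice validated by simulation recovery (±3 points at n = 5000),
  not a published constant; w is configurable. Fewer than ~100 nuclei
  triggers a warning.
- **BrdU positivity**: threshold = 99th percentile of the negative-control
  red integrals (mean + 3 SD available as an alternative); by construction
  a null sample scores ≈1% positive.
- **Lipid score** = mean red intensity × mean red-object area × object
  count / nucleus count; compartment splitting assigns an object
  perinuclear when its centroid is within 5 µm of the nearest nucleus
  boundary, proxied by nucleus centroid + equivalent radius √(area/π).
- **OCR parameters**: NMOC = rotenone/antimycin minimum; BR = baseline −
  NMOC; PL = oligomycin minimum − NMOC; ATP-linked OCR = BR − PL (the
  standard mito-stress definition; source formulas conflate it with BR);
  maxOCR is reported both raw (FCCP maximum) and NMOC-corrected, with the
  utilization ratio BR/maxOCR using the corrected value. Two
  coupling-efficiency conventions disagree in the source material and both
  are reported: ((BR+NMOC)−(PL+NMOC))/(BR+NMOC) and ATP-OCR/BR. Baseline is
  the baseline-phase mean (robust to noise); inhibitor responses are phase
  extrema. Degenerate inputs (BR ≤ 0, PL > BR) are flagged, not erased.
- **Motility**: greedy mutual-nearest-neighbor linking between consecutive
  frames with a hard step cap — adequate for sparse nuclei at 2–3 h
  sampling, and deliberately simple; net displacement rate is
  √(Δx²+Δy²)/Δt (net, not path length).
- **Fluxes and rates**: glucose consumption and lactate production per mg
  protein; glycolytic index = lactate/(2×glucose), 1 for fully glycolytic
  disposal; caspase-type activity as protein-normalized slope between two
  reads; nuclear/perinuclear ratio after background subtraction, undefined
  (flagged) when the ring signal does not exceed background.

## The simulator and what passing tests show

`simulate_counts` draws negative-binomial counts (gamma–Poisson,
var = µ + φµ²) with per-gene log₂ baselines ~ N(5, 2²), lognormal animal
random effects, and condition means
baseline + animal + x_met·β + x_hum·β + x_met·x_hum·γ, scaled to a target
library size. Defaults are the study conditions: 4 animals × 4 conditions,
~10⁴ genes, dispersion φ = 0.05 and animal SD 0.1 log₂ — which lands the
average control CV near 0.21–0.24 and hence the derived threshold near
0.64–0.71. Effect fractions default to 15% metabolic, 10% humoral, 20%
synergistic at 1.0 log₂ units with random sign; knockout/endothelial
profiles zero the humoral and interaction terms, encoding the qualitative
biology as generative truth. Acceptance-scale runs use 10,000 genes — large
enough for stable BH behavior and slope estimates while keeping a full
pipeline run in seconds.

The simulator emulates the *statistical* structure (pairing, overdispersion,
animal effects, interaction), not the biology it abstracts: no
gene–gene correlation, no length/GC bias, no compositional coupling beyond
the library-size constraint, effect sizes at a point mass rather than a
continuum. Passing recovery tests therefore shows the estimators are
correct under the assumed model — not that the model captures everything in
real data.

`simulate_dapi` places G1 at the mode, G2 at twice the mode and an S bridge
uniform over [1.15m, 1.7m] — the region between the default gates. That
choice makes truth labels recoverable by the gating procedure and is a
fixture-design decision, not a claim about real S-phase DNA-content
distributions (which blend into both peaks). `simulate_ocr_trace` is the
exact forward model of the OCR parameter extraction (noise 0 inverts
exactly). `simulate_tracks` offers isotropic random-walk and straight-line
modes; only the directed mode has a deterministic expected displacement
rate.

## Determinism and numerics

Every generator is a pure function of config + seed (numpy `default_rng`).
Identical config and seed give byte-identical TSV outputs (fixed float
format `%.6g`; JSON metadata carries no timestamps). Zero-variance ratio
vectors yield zero-width CIs and a p-value of 0 or 1 by the sign of the
mean; all-zero expression drops a gene from effect estimation rather than
producing infinities. The moderated test falls back to the plain t when
fewer than 10 genes are available to fit the prior.

## Known limitations

- The built-in genome-wide test is a moderated one-sample location test on
  log-ratios; it does not model counts directly and is not a replacement
  for count-based GLMs when those outputs are available — the pipeline
  accepts their FDR columns as first-class inputs.
- Through-origin slopes are attenuated by estimation noise in x (see above);
  comparisons between profiles (synergistic vs not) are robust to this,
  absolute values carry a few percent of downward bias.
- The reconciliation rule (CI covers the other condition's point estimate)
  is one reasonable formalization; alternatives (CI overlap, equivalence
  testing) would shift the concordance fraction.
- Track linking is greedy and will swap identities for dense, fast-moving
  nuclei; it is intended for the sparse fields of the motility assay.
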