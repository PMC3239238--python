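# Methods

This note records the model, the numerical choices, and the design
decisions behind them, in the order the pipeline applies them.

## Reference model

**Input.** A genes × samples matrix of continuous log2-scale expression
values with a sample → class annotation. Values are taken as already
normalized and comparable across samples; no internal re-normalization is
performed (cross-platform harmonization is a preprocessing concern and out
of scope). Missing entries (NaN / `NA`) are allowed and excluded per
(gene, class) before fitting.

**Shared grid.** For each gene, one uniform evaluation grid of 512 points
spans `[min − 3·SD, max + 3·SD]` of the gene's pooled values across all
samples. All class densities for a gene live on this one grid, which is
what makes the uniqueness weight (an area between curves) well defined
point-by-point. 512 points resolve the curves to well below every tolerance
used here; the 3-SD pad keeps tail truncation negligible, so a value
outside the grid genuinely carries ~zero density for every class. A gene
whose pooled values are all identical has no spread to build a grid from
and is dropped (logged).

**Density estimator.** Per (gene, class): a Gaussian-kernel density with
Silverman's rule-of-thumb bandwidth `h = (4/3n)^(1/5)·sd`, floored at one
grid spacing. The floor also covers the degenerate all-values-equal class,
which becomes a one-bin-wide spike rather than an error. The KDE is
evaluated by linear binning onto the grid followed by FFT convolution with
the sampled kernel — the same scheme R's `density()` uses — and then
renormalized so the trapezoidal integral over the grid is exactly 1. The
binned evaluation agrees with a naive direct-sum KDE to ~1e-3 sup-norm
(tested), is deterministic, and makes full-cohort model builds and
leave-one-out rebuilds fast enough to be routine. A class contributes a
density only if it has at least `min_class_n = 6` non-missing values for
the gene (configurable; 6 is the smallest class size the method is meant
to support). Genes with fewer than two eligible classes are dropped: a
density with no competitor can neither score nor weigh anything.

**Serialization.** A model is one compressed archive of arrays (grids,
density tensor, per-pair sample counts, labels) plus JSON-encoded build
configuration. Round-trip is lossless to the bit.

## Scores

`tm(g,c) = f₍g,c₎(x₍g₎) / max f₍g,c₎`, linearly interpolated between grid
points; values outside the grid score 0 (with 3-SD padding this truncation
is negligible). Normalizing by the modal density maps "sits at the most
typical level for this class" to exactly 1, regardless of how concentrated
the class is.

`ts(g,c) = tm(g,c) − max₍c′≠c₎ tm(g,c′)` over the classes available for the
gene. This construction reproduces the intended endpoint semantics: +1 iff
the gene fits *c* perfectly and no other class at all; −1 iff it fits some
other class perfectly and *c* not at all; 0 when the evidence is
indeterminate; and at most one class per gene can be positive. Whether the
competitor should be the max, the mean, or a rank statistic is a genuinely
open choice; the max is the most conservative (it gives the smallest
positive scores) and is isolated behind `ts_score` so an alternative can be
swapped in without touching anything else. Masked entries (class absent for
the gene, or query value missing) propagate: downstream means run over
unmasked genes only, and a gene with fewer than two available classes is
fully masked.

## Uniqueness weight

`w(g,c)` is the trapezoidal integral of `f₍g,c₎ − max₍c′≠c₎ f₍g,c′₎` over
the grid points where `f₍g,c₎` is strictly the highest. Ties contribute
nothing — identical curves get exactly 0 — and the competitor is the
pointwise maximum of the other curves, whichever class supplies it at each
point. Results are clamped to [0, 1]; any clamp beyond 1e-6 would be an
internal error rather than floating-point dust. Against an independent
100×-finer quadrature on analytic Gaussian pairs the 512-point trapezoid
agrees to ~1e-5.

Note that with two essentially disjoint classes *both* get weight ≈ 1 —
each curve sits entirely above its near-zero competitor — so "at most one
dominant class per gene" is an empirical regularity of overlapping,
realistic references, not a theorem.

## Weighted similarity and classification

`S(c) = Σ ts·w / Σ w` over genes unmasked in both matrices. This is
algebraically identical to "multiply each ts-score by its weight, divide by
the class's mean weight, then average" (the form in which the weighting is
usually described); the ratio-of-sums form is used for numerical clarity,
and with all weights equal it reduces bit-for-bit to the plain mean
(the unweighted method). A class whose mean weight over usable genes is
below 1e-6 falls back to the unweighted mean and is flagged, rather than
dropped, so the ranking stays complete.

The prediction is the argmax of `S`; ties break lexicographically and are
flagged. Against a known truth label the call is graded **exact** (same
class), **similar** (same organ group per a user-supplied taxonomy — the
package does not hard-code any cancer taxonomy; defaults exist only for
the synthetic classes), **same_site** (the top class represents the
metastasis site and the runner-up is exact/similar), or **incorrect**.
Reliability tiers use the best-hit score with inclusive thresholds:
high ≥ 0.10, medium ≥ 0.05, low otherwise (configurable).

## Validation

**LOOCV.** Each sample is held out, its own class's densities are refit
without it, the gene-weight matrix is recomputed from the fold's densities
(a switch can freeze full-cohort weights for speed; recomputing is the
default since weights derive from densities), and the sample is scored and
graded. Samples whose class would fall below `min_class_n` members after
holdout are skipped with a logged reason. The per-gene evaluation grids are
pinned from the full cohort: the grid is evaluation scaffolding rather than
a fitted quantity, and pinning it makes the fold exactly equal to a
from-scratch rebuild on the same grids (asserted per-sample against such a
rebuild in the tests) while touching only one class per fold. Accepted
categories default to exact+similar, configurable to exact-only.

**Summaries.** Per-class sensitivity (`correct in c / truth c`) and
specificity (`1 − predicted-c among non-c / non-c`), with a total row
(overall accuracy; unweighted average sensitivity/specificity). The
accuracy-versus-score curve slides a window of width 0.1 in steps of 0.005
along the best-score axis, starting at the observed minimum score; empty
windows report a count of 0 and undefined accuracy. (Sliding over the score
axis rather than the rank-ordered sample list is a deliberate reading; the
rank-space alternative would weight windows by sample density instead.)
`threshold_accuracy` reports the fraction of samples at or above a score
threshold and the accuracy within them.

**Specific-gene retention.** For one class, genes with uniqueness weight
> 0.25 (the strongly class-specific tail) that are non-missing in every
query are tabulated by their *unweighted* ts-scores per query, with queries
ordered by descending weighted similarity to the class. Reading the table
left to right shows which class-specific genes a drifting metastasis has
retained or lost.

## Synthetic data

The generator emulates a class-structured expression compendium on the log2
scale: every gene has background `N(μ₀ = 8, σ = 1)` (a typical mid-range
log2 intensity; σ in these units makes effect sizes directly interpretable),
and each class owns a disjoint block of marker genes shifted by `+Δ·σ` in
that class only. Queries are drawn from a class's generative model and a
fraction *d* of their markers is redrawn from background ("drift"),
mimicking metastatic loss of origin-specific expression. Missing entries
can be inserted at a configurable rate. Everything is bit-reproducible from
the scenario seed, and marker/drift assignments are returned as ground
truth.

Named conditions:

- **easy** — K=8 classes, G=1000 genes, m=100 markers/class, n=30
  samples/class, Δ=3: well-separated, the parameter-recovery setting.
- **noisy** — easy plus 80% additional pure-background genes (G=1800) and
  Δ=1.5: the low-signal regime where gene weighting should earn its keep.
- **graded** — the easy reference, with query cohorts drawn at per-query
  drift uniform in [0, 1]: probes how the best-hit score calibrates
  correctness.

What the generator does *not* emulate: probe/batch effects, saturation,
heavy-tailed or multimodal within-class expression, correlated genes, and
class-imbalanced references. Passing tests on these cohorts therefore
demonstrate the correctness and internal consistency of the machinery and
its qualitative behavior (weighting helps when most genes are
uninformative; the score tracks correctness), not clinical accuracy on real
tumor compendia.

## Known limitations

- The tm/ts constructions follow the documented endpoint semantics but are
  this package's own formulations; they are isolated behind `tm_score` /
  `ts_score` so alternative definitions can be substituted.
- tm-scores are mode-normalized densities, not calibrated probabilities;
  no likelihood-ratio or p-value interpretation is offered.
- LOOCV cost scales with samples × genes; the FFT KDE keeps full rebuilds
  of cohorts in the few-hundred-sample, few-thousand-gene range in the
  minutes regime on one CPU, but far larger references would want frozen
  weights (`recompute_weights=False`) or a coarser grid.
- Accuracy categories beyond "exact" require a user-supplied taxonomy of
  organ groups and site representatives.
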