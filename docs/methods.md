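# Methods

This note documents the models behind `soilcd`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Calorimetry kinetics

A thermogram is the heat-flow record (mW) of one sealed soil ampoule held at
constant temperature. Flow is integrated by the trapezoid rule into
cumulative heat in joules (1 mW sustained for 1 h = 3.6 J). Negative
recorded flows — baseline dips left by the instrument's blank subtraction —
are retained in the integral; a spiked-minus-control delta below zero is a
meaningful outcome, not an artefact to clip.

Growth-driven heat release is modeled with the modified (Zwietering-style)
Gompertz curve,

    Q(t) = Q_max · exp(−exp((µ_max·e/Q_max)(λ − t) + 1)),

chosen because each parameter is directly interpretable: `Q_max` (J) is the
asymptotic total heat, `µ_max` (J/h) is exactly the maximum of the fitted
flow curve, and `λ` (h) is the lag/adaptation phase. Two quantities are
derived, never fitted: the time of peak activity `TTP = λ + Q_max/(e·µ_max)`
(where dQ/dt attains µ_max — a calculus identity of this parameterization,
asserted to 1e-6 relative in the tests), and the mean log-phase rate

    µ = (Q(TTP) − Q(λ)) / (TTP − λ) = Q_max(e⁻¹ − e^(−e)) / (TTP − λ),

a defined convention for the "growth rate" distinct from the maximal rate;
the closed form is used rather than numerical averaging.

**Fit target.** The model is fit to cumulative heat, not raw flow:
integration damps high-frequency instrument noise and makes the
least-squares problem much better conditioned. Fitting uses
`scipy.optimize.least_squares` with bounds (all parameters positive, lag
within the record) and multi-start initialization — `Q_max` from the final
observed heat, `µ_max` from the maximum finite-difference flow, and the lag
started at each of {0, time at 10% of final heat, the configured fallback
peak hour}. The lowest-RSS converged start wins; ties break to the smallest
lag. A curve whose final cumulative heat is not positive has no growth
signal and is reported unfit (converged = False) rather than forced.

**Peak detection.** For the P-subsample rule the flow is smoothed with a
centred moving average (default 5 points) and peaks below a prominence
floor (default 0.05 mW) are ignored; when nothing qualifies the sampling
time falls back to 37 h, the assay's prescribed default.

**Paired deltas.** Each spiked ampoule is compared to the control from the
same soil on their common time support, interpolating the coarser grid onto
the finer one; `delta_auc` is the cumulative-heat difference at the end of
that support, and the sample is activity-responsive iff it is strictly
positive. All deltas are exactly antisymmetric under role swap. The
cadmium immobilization ratio is implemented as the spiked/control
final-heat ratio; this is a clearly labelled proxy — the original index is
defined in instrument-specific prior work and its exact formula is not part
of this package's contract.

## Synthetic data

The generator exists so every downstream stage can be scored against known
ground truth. It emulates the *statistical structure* of a five-farm
rhizosphere survey and of the paired spiking assay, not the biology:

* **Field survey** (`simulate_field_experiment`): five farms at evenly
  spaced centres along a 0–4.3 mg/kg soil-Cd gradient, 16 plots
  (3/3/3/3/4), each plot jittered around its farm (sd 0.45 mg/kg) and each
  sample around its plot (sd 0.35 mg/kg), so Cd categories vary within as
  well as between farms; 14–20 samples per plot. Taxon log-abundance is
  `base (sd 1.0) + farm effect (sd 0.5) + sign · lfc · category ordinal`,
  with 13% positive and 15% negative responders at lfc 1.0 per category
  step, log-normal overdispersion (sd 0.5), and a multinomial draw at a
  library depth uniform in 2788–25083 reads. The responder effect acts on
  the category ordinal (0/1/2), not raw Cd, so generator and detector test
  the same contrast. Responder fractions and depth bounds are the study
  conditions; the effect size is chosen for detectability (the field study
  reports no responder effect sizes) and documented as such.
* **Thermogram pairs** (`simulate_thermogram_pair`): noiseless flow is the
  analytic Gompertz derivative; the spiked member carries an extended lag
  (Cd stress delays adaptation) and a scaled Q_max; additive Gaussian flow
  noise and linear drift are optional. Defaults: 80 h at 0.5 h sampling.
* **Assay timepoints** (`simulate_timepoint_counts`): S/P/E snapshots in
  both arms with log-linear trajectories; planted spiked-only responders, a
  disjoint "medium growth" set enriched identically in both arms, stable
  background taxa, 10 replicate subsamples per arm-timepoint (the printed
  assay scale). The trajectory form is a modeling choice; no functional
  form is prescribed by the design.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomic mis-assignment, phylogenetic correlation among taxa, spatial soil
chemistry, multi-peak thermograms from competing sub-populations, or
Dirichlet-style taxon covariance. Passing tests therefore demonstrate the
estimators' statistical behavior under the declared data-generating
process, not performance on raw reads.

## Differential abundance

Counts are compositions scaled by an unobserved per-sample sampling
fraction, so the estimator works on `log(count + 0.5)` and corrects two
distinct biases:

1. **Per-sample offsets** (library/sampling fraction): estimated by an
   alternating robust iteration — per-taxon group means of offset-corrected
   logs, then per-sample offset as the median residual. Two numerical
   details matter. Exact medians make the alternation settle into
   two-point cycles, so updates are damped 50/50. And the map is
   translation-invariant along per-group offset constants (a group-level
   constant is indistinguishable from the taxon means), so offsets are
   median-centred within each group every iteration; only the within-group
   component is identified, which is the correct division of labour because
   the between-group component is precisely the compositional bias handled
   next. Median (not mean) centring keeps one aberrant library from
   dragging its whole group. Convergence tolerance 1e-6, cap 100
   iterations; the returned offsets are mean-centred to sum to zero.
2. **Shared compositional bias**: a genuine shift in part of the community
   forces an equal-and-opposite apparent shift on every other taxon (the
   per-group log-normalizer). The bias is estimated as the median of the
   per-taxon contrast coefficients — consistent while most taxa are null,
   robust to ~50% contamination — and subtracted from every fold change.
   This replaces the reference method's E-M mixture with a transparent
   robust-centre estimate; its adequacy is checked statistically (null
   false-discovery control, planted-effect recall, invariance of fold
   changes to rescaling any single library by 10×).

Each remaining taxon (structural zeros — taxa entirely absent from one
group — are screened out first and reported separately) is tested by OLS
with `W = lfc/se` against a Student-t reference with the residual degrees
of freedom. The t reference matters for the small per-arm assay designs
(~10 residual dof), where a normal reference is visibly anticonservative;
at survey scale the two are indistinguishable. BH adjustment runs across
tested taxa; direction is assigned at q ≤ α (default 0.05).

**Contrast modes.** The default is a two-level dummy (reference vs
comparison, other samples dropped). For the field survey's high-vs-low
contrast adjusted for farm, the two-level design can be exactly collinear:
when Cd clusters strongly by farm, "low" may coincide with a single farm's
indicator. The ordinal mode (`ordinal_levels=('low','medium','high')`)
enters the category as a numeric score over all three levels, letting
medium-Cd samples bridge farms and identify the slope within covariate
levels; the reported fold change is the slope scaled by the
reference-to-comparison step (2 for low→high). Covariates enter as fixed
effects; no random effects are modeled.

Taxa can be aggregated to any rank (phylum … genus) by summing counts
within the truncated lineage before testing; aggregation is a pre-step, not
a separate model.

## Community statistics

* Chao1 uses the bias-corrected form `S + F1(F1−1)/(2(F2+1))`, defined even
  without doubletons; Shannon is in natural log.
* Bray–Curtis is computed on relative abundances by default (library sizes
  span an order of magnitude); a raw-count switch exists.
* Dunn's post hoc z-tests (pooled ranks, tie-corrected variance) are gated
  on a significant omnibus Kruskal–Wallis test, then BH-adjusted over all
  pairs; the compact-letter display letters the maximal cliques of the
  graph whose edges join groups with adjusted p > α.
* PERMANOVA uses the among/within decomposition of squared distances with
  `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)` (999 permutations by
  default); permutations can be restricted within strata so nested designs
  (plots within farms) never exchange labels across blocks. Whether the
  original analysis nested plot as strata or a fixed term is not
  documented; both modes are exposed.
* PCoA Gower-centres the squared distances; negative eigenvalues are
  dropped and their count and magnitude reported on the result, with no
  correction applied. CAP is implemented as distance-based RDA: PCoA axis
  scores are regressed on the constraint design (intercept always
  included), and the constrained axes are the principal components of the
  fitted values; rank-deficient constraints reduce the axis count.

## Response classification and accounting

Soil Cd maps to low/medium/high with left-closed bounds at 1 and 2 mg/kg,
so assignment is total and single-valued on [0, ∞) — the printed ranges
leave boundary membership ambiguous and a convention had to be fixed.
Composition responders are taxa with q ≤ α against the low-Cd reference;
activity responders are the set difference `enriched(spiked arm) −
enriched(control arm)` over the S→P/E course, where per-arm enrichment is a
significantly *positive* call in the P-vs-S or E-vs-S contrast (union rule
by default; intersection available). The direction of an activity call
comes from the spiked arm; the control arm contributes membership only.
Summaries report responsive/positive/negative/stable fractions over the
tested universe (structural zeros included in the denominator, since they
were observed but not estimable).

Core-taxon (Venn) partitions: a taxon occurs in a group iff its relative
abundance reaches the detection threshold (default 1/100) in at least the
prevalence fraction (default 0.001) of the group's samples; regions are the
frozensets of groups, and counts over regions partition the occurring taxa.

## Degenerate inputs and edge behavior

All-zero sample columns are rejected wherever relative abundance is needed
(they have no composition). All-zero taxa are structural zeros in every
group. A thermogram needs ≥ 2 points to integrate and ≥ 5 to fit. An
all-identical Kruskal–Wallis input has nothing to detect and returns
H = 0, p = 1. Identical thermogram pairs give exactly zero deltas and are
not activity-responsive (the criterion is strictly positive). A control
ampoule with zero final heat leaves the immobilization ratio undefined and
flagged rather than infinite.

## Problem sizes

Defaults throughout are the study-scale conditions: ~270-sample surveys
with 300 taxa, 80 h thermograms at 0.5 h sampling, 999 permutations,
25-replicate null/planted suites and 10-seed end-to-end runs. These sizes
were chosen so the statistical checks have power while the full suite and
the acceptance script each complete in seconds on one CPU.

## Known limitations

The differential-abundance estimator is not the published reference
implementation; its variance model is a per-taxon OLS and its bias
estimate a median, so its numbers will not match the reference package
cell-for-cell even when both control error rates. The median bias estimate
assumes fewer than half the taxa shift in one direction. Farm enters as a
fixed effect; with very few farms per Cd category the ordinal bridge
carries the identification and standard errors grow accordingly. The CAP
implementation is the distance-based-RDA flavour without the
discriminant-style axis-count cross-validation. Rarefaction is available
but off by default; depth-evening practice varies and the choice is left
to the user.
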