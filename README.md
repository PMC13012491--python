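# soilcd

Identification of cadmium-responsive soil bacteria from paired
isothermal-microcalorimetry (IMC) assays and 16S ASV count tables.

Heavy-metal contamination of agricultural soil — cadmium in cacao-growing
regions in particular — reshapes the soil bacterial community. `soilcd`
implements an integrated analysis for studies that combine two complementary
views of that response:

* **activity** — each soil sample is split into an unamended control ampoule
  and a CdCl₂-spiked ampoule, and heat flow (mW) is recorded continuously
  over an 80 h assay; extra heat in the spiked member marks activity
  attributable to Cd-responsive (Cd-tolerant) bacteria;
* **composition** — ASV count tables across a natural soil-Cd gradient
  (low/medium/high categories) are tested for differentially abundant taxa
  with a bias-corrected compositional model.

The package provides the kinetic model, the statistics, the set-logic
classification that merges the two evidence streams, and a synthetic-data
generator that reproduces the statistical structure of a five-farm
rhizosphere survey, so the whole pipeline is testable end to end without any
sequencing download.

## The models

**Microcalorimetry kinetics.** Heat flow is integrated to cumulative heat
Q(t) (1 mW·h = 3.6 J), which follows the modified Gompertz growth curve

```
Q(t) = Q_max · exp(−exp((µ_max·e/Q_max)·(λ − t) + 1))
```

with total heat `Q_max` (J), maximal heat-production rate `µ_max` (J/h) and
lag phase `λ` (h), fitted by multi-start nonlinear least squares. Derived
quantities follow in closed form: the time of peak activity
`TTP = λ + Q_max/(e·µ_max)`, the mean log-phase rate
`µ = Q_max(e⁻¹ − e^(−e))/(TTP − λ)`, and for each control/spiked pair the
delta cumulative heat (activity criterion: Δ > 0) and the spiked/control
final-heat ratio (a proxy for the Cd immobilization ratio `Cd_imm`).

**Differential abundance.** A from-scratch estimator in the ANCOM-BC
spirit: structural zeros are screened out, per-sample sampling-fraction
offsets are estimated by robust median iteration, each taxon's
`log(count + 0.5)` is regressed on the Cd contrast (optionally with farm as
a fixed covariate, or with the three Cd categories as an ordinal score),
and the shared compositional bias — the artefactual shift a real change in
part of the community imposes on every other taxon — is removed as the
median contrast coefficient before Benjamini–Hochberg correction.

**Community statistics.** Observed richness, bias-corrected Chao1 and
Shannon diversity; Kruskal–Wallis with Dunn's post hoc comparisons, BH
correction and compact-letter display; Bray–Curtis dissimilarities;
PERMANOVA by permutation (optionally restricted within strata for the
plot-within-farm design); PCoA and constrained PCoA (CAP).

**Response classification.** Composition responders are taxa with q ≤ α in
the high-vs-low contrast (low soil Cd as reference, 0–1 / 1–2 / 2+ mg/kg
categories). Activity responders follow the paired set logic: taxa enriched
over the S→P→E course of the assay in the spiked arm *and not* in the
control arm (both-arm enrichment is growth on the medium, not on Cd).
Core-taxon Venn partitions use a prevalence/detection occurrence rule.

## Worked example

```python
import numpy as np
from soilcd import (
    ThermoSimParams, simulate_thermogram_pair, integrate_heat,
    fit_gompertz, paired_delta, CommunitySimParams, simulate_field_experiment,
    Contrast, differential_abundance, assign_cd_category,
    classify_composition_responders,
)

# --- paired calorimetry: control vs Cd-spiked ampoule from one soil ---
params = ThermoSimParams(q_max=2.0, mu_max=0.1, lag=10.0,
                         spike_lag_extension=6.0, spike_qmax_multiplier=1.3,
                         noise_sd=0.002, seed=42)
control, spiked, truth = simulate_thermogram_pair(params)
fit_c = fit_gompertz(integrate_heat(control))
fit_s = fit_gompertz(integrate_heat(spiked))
d = paired_delta(spiked, fit_s, control, fit_c)
for name, fit in (("control", fit_c), ("spiked", fit_s)):
    print(f"{name}: Q_max={fit.q_max:.3f} J  mu_max={fit.mu_max:.4f} J/h  "
          f"lag={fit.lag:.2f} h  TTP={fit.ttp:.2f} h")
print(f"delta heat = {d.delta_auc:.3f} J  Cd_imm = {d.cd_imm:.3f}  "
      f"activity-responsive: {d.activity_responsive}")

# --- field survey: responders along the natural Cd gradient ---
table, meta, truth = simulate_field_experiment(CommunitySimParams(seed=1))
meta["cd_category"] = [assign_cd_category(c) for c in meta["cd_soil"]]
contrast = Contrast("cd_category", "low", "high", covariates=("farm",),
                    ordinal_levels=("low", "medium", "high"))
results = differential_abundance(table, meta, contrast)
calls, summary = classify_composition_responders(results)
print(f"{summary.n_responsive} of {summary.n_taxa_total} taxa responsive "
      f"({100*summary.fraction_responsive:.1f}%): "
      f"{100*summary.fraction_positive:.1f}% up, "
      f"{100*summary.fraction_negative:.1f}% down "
      f"(planted: {100*truth.responsive_fraction(table.n_taxa):.0f}%)")
```

Output:

```
control: Q_max=1.977 J  mu_max=0.1037 J/h  lag=10.19 h  TTP=17.20 h
spiked:  Q_max=2.609 J  mu_max=0.0984 J/h  lag=15.67 h  TTP=25.43 h
delta heat = 0.650 J  Cd_imm = 1.332  activity-responsive: True
86 of 300 taxa responsive (28.7%): 13.7% up, 15.0% down (planted: 28%)
```

The fitted kinetic parameters recover the generating values (the spiked
member shows the longer adaptation phase and larger total heat that Cd
stress produces); the positive delta heat classifies the sample's extra
activity as Cd-responsive. On the simulated survey the pipeline recovers
the planted 28% responder fraction (13% increasing, 15% decreasing) within
a percentage point.

The same stages are available as CLI subcommands for file-based runs:

```
soilcd simulate --seed 7 --out sim/
soilcd imc-fit --input sim/thermograms --out fit/
soilcd diversity --counts sim/counts.tsv --metadata sim/metadata.csv --out div/
soilcd diffabund --counts sim/counts.tsv --metadata sim/metadata.csv \
    --covariate farm --ordinal --out da/
soilcd respond --diffabund da/diffabund.tsv --out resp/
soilcd report --responsive resp/responsive_taxa.tsv \
    --counts sim/counts.tsv --metadata sim/metadata.csv --out rep/
```

Every output table carries a provenance header (stage, seed, config hash)
and identically seeded runs are byte-identical.

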