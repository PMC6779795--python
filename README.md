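# cortexdyn

Layer-resolved analysis of the long-term dynamics of cortical activity
patterns during multimodal memory formation.

## The problem

Chronic two-photon imaging of immediate-early-gene (IEG) reporter
fluorescence gives a day-by-day readout of the activity of thousands of
individually tracked cortical neurons while an animal cycles through
multimodal environments (home cage, conditioning boxes, enriched
environments, stimulus rigs) over weeks to months.  The scientific
question is how today's population pattern depends on the history of
past patterns — and whether that dependence differs between superficial
layers II/III and deep layer V, and between cortical locations.

`cortexdyn` frames this as tabular regression: for one cortical
location and laminar compartment, rows are neurons, features are each
neuron's activity on earlier scan days, and the label is its activity
on a target day.  A gradient-boosted decision-tree regressor with a
fixed reference configuration (10 leaves, minimum 1 sample per leaf,
learning rate 0.05, 93% feature and bagging fractions, l2 objective) is
fit with validation early stopping and scored against a shuffle null
that permutes neuron identities independently within each feature-day
column of the test set — preserving every day's activity distribution
while destroying each neuron's pairing with its own history.

Writing δ for the test mean-square error of the model and δ_s for the
MSE of the average of 20 predictions on shuffled features, the quality
statistics are

    δ_r = δ / δ_s          (relative error; 1 = shuffle level)
    κ   = exp(−δ_r) ∈ (0, 1]   (κ = e⁻¹ ≈ 0.368 = no signal)

On top of this engine the package implements four protocols:

- **Cross-location transfer** — train in location i, test in location
  j of the same compartment (always predicting the last scan day from
  all previous days, Day 0 excluded; train/valid/test sizes are 90%/10%
  /100% of the animal's minimum per-location neuron count).  κ(i, j)
  fills a location × location quality matrix M_κΛ per compartment; 10
  repeats are averaged (M̃), differenced across compartments
  (M_κ = M̃_II/III − M̃_V), symmetrized (M_s), and tested pair-by-pair
  with paired t-tests under Bonferroni correction.
- **Intra-location control** — the same prediction inside one
  population, guarded by a 10-group partition and a 350/50/100 split;
  locations under 500 neurons are excluded.
- **Prediction power** — per feature day D, the model's total split
  gain normalized to P_D = G_D / Σ G_D: the share of learned structure
  each historical day carries, fit on 90% of the neurons (80% train,
  10% validation).
- **Environment repeats** — for pairs of same-environment scan days
  (S_a, S_b) selected with a box-identity exclusion rule, predict S_b
  from S_a plus three neuron-shuffled early control days; average δ_r
  over 100 repetitions and over locations, then regress the mean and SD
  on the repeat interval Inv: δ̄_r = ρ_m·Inv + α_m, σ(δ_r) = ρ_s·Inv +
  α_s.  Positive ρ_m is the signature of memory decay.

Because cohorts of this kind are not publicly deposited, the package
ships a synthetic-cohort generator (`generate_cohort`) whose regimes —
shared recency-weighted history, location-specific lag dependence,
independent noise, plus decaying environment-specific patterns — give
every protocol a known ground truth to recover.

## Worked example

`python examples/02_cross_location_transfer.py` (3 locations, 500
neurons/panel; superficial layers shared-recency, deep layer
location-specific):

```
mean kappa, layers II/III (rows train, columns test):
[[  nan 0.895 0.907]
 [0.903   nan 0.907]
 [0.907 0.901   nan]]

mean kappa, layer V:
[[  nan 0.302 0.373]
 [0.833   nan 0.159]
 [0.553 0.277   nan]]

symmetrized difference M_s (positive = II/III transfers better):
[[  nan 0.331 0.444]
 [0.331   nan 0.686]
 [0.444 0.686   nan]]

pairs with worse deep-layer transfer: 6 (4 significant at Bonferroni alpha=0.01); better: 0 (0 significant)
```

Superficial-layer models transfer almost perfectly (κ ≈ 0.9 for every
ordered pair, far above the shuffle level e⁻¹ ≈ 0.368) because all
locations share one recency rule; deep-layer models mostly collapse
toward or below shuffle level in other locations because each location
keys on its own historical day.  Every M_s entry is positive, so the
contrast points the right way for all pairs.

`python examples/05_repeat_environment.py` adds the interval analysis:

```
  Inv   7 d (RA): mean delta_r = 0.139, sd across locations = 0.011
  Inv   9 d (RA): mean delta_r = 0.148, sd across locations = 0.019
  Inv  16 d (EE): mean delta_r = 0.178, sd across locations = 0.012
  Inv  17 d (RA): mean delta_r = 0.133, sd across locations = 0.015
  Inv  37 d (H): mean delta_r = 0.554, sd across locations = 0.054

linear fits: mean delta_r = 0.0144*Inv + -0.017 (R^2 = 0.88)
```

The generator decays environment-pattern fidelity at 0.015/day and the
fitted slope ρ_m = 0.0144/day recovers it: reactivation reliability
falls with the time since the previous exposure.

The other examples cover simulation + QC (`01`), the intra-location
control (`03`), prediction-power profiles (`04`), and the one-config
end-to-end pipeline with its JSON run manifest (`06`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's pipeline from scratch under the given seed —
simulating a two-regime cohort, applying QC, and running cross-location
transfer, the intra-location control, prediction-power profiling and
the environment-repeat regression end to end — and writes its result
JSON to `--out`.

## Layout

```
src/cortexdyn/
  data_model.py      panels, schedules, table I/O, QC rules
  synthetic.py       cohort generator with ground truth
  engine.py          boosted-tree core, shuffle null, δ/δ_s/δ_r/κ
  cross_location.py  transfer matrices and the layer contrast
  intra_location.py  10-group same-population control
  power.py           prediction-power profiles and comparisons
  repeat_env.py      repeat-pair selection, interval regression
  workbench.py       orchestration, run manifest
examples/            one narrative script per capability
docs/methods.md      model, assumptions, parameter choices, limitations
```
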