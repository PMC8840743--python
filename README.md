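# esiquant

Structure-free semi-quantification for non-targeted LC/ESI/HRMS.

Non-targeted screening of water samples by liquid chromatography /
electrospray ionization / high-resolution mass spectrometry detects far
more compounds than there are analytical standards for. Because
electrospray ionization efficiency varies by five to six orders of
magnitude between compounds, a peak area alone says almost nothing about
concentration — two compounds at the same concentration can differ in
signal by a factor of a million. `esiquant` is for analytical chemists
and environmental monitoring groups who need concentration *estimates*
for detected-but-unidentified features, accurate enough for risk-based
prioritization, without knowing the structures.

## The method

For each calibration standard and each of six measurement conditions
(positive/negative ESI × mobile-phase pH 2.7, 8.0, 10.0), the **response
factor** RF (M⁻¹) is the slope of the linear range of the calibration
curve, peak area vs molar concentration. Twelve descriptors available for
*any* detected feature — log₁₀ positive/negative peak-area ratio at each
pH, retention time at each pH, two retention-time differences, ion m/z,
sodium-adduct flag, negative-mode detection flag, nominal-mass parity —
feed one random-forest regressor per condition predicting log₁₀ RF.
Censored values are encoded as ±999 sentinels, which tree ensembles
handle natively. Concentrations then follow from

    c = A / RF_pred

and accuracy is scored by the symmetric fold error

    error = max(c_pred / c_actual, c_actual / c_pred) ≥ 1,

summarized by its mean, median, maximum and the fraction of datapoints
strictly below a factor of 10. Two baselines calibrate expectations: the
**equal-RF** baseline (geometric mean RF of all standards) and the
**closest-eluting** baseline (RF of the standard with the nearest
retention time). Fold-uncertainties from independent sources combine as
1 + √Σ(fᵢ−1)², so the larger factor always dominates.

A synthetic-data module generates dilution-series feature tables with
known ground-truth RFs (spanning >4 orders of magnitude, dual-polarity
detection, LOD censoring, log-normal area noise), so the whole chain is
testable without instrument data.

## Worked example

Run the full synthetic pipeline — simulate standards and unknowns,
calibrate RFs, build descriptors, train the six forests, quantify the
test compounds three ways, and score them:

```python
from esiquant.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(out_dir="demo", seed=1, n_train=150, n_test=50))
print(summary.to_string(index=False))
```

```
         method  mean_fold  median_fold    max_fold  frac_below_10    n
closest_eluting 334.205396    37.129026 2753.597668       0.312000  250
       equal_rf  48.906664    10.189381  524.374615       0.497222 1080
          model  28.092022     5.849322  819.661237       0.591667 1080
```

Each row is one quantification method, scored over every test datapoint
(one compound at one concentration in one condition). The trained model
set halves the equal-RF baseline's mean fold error and beats it clearly
on the median and on the fraction of datapoints within a factor of 10;
the closest-eluting baseline (applied in positive mode at pH 2.7, its
home setting) is an order of magnitude worse, because retention time
alone is a poor proxy for ionization efficiency. The exact figures vary
with the simulation seed — the fold-error mean is tail-heavy — but the
ordering is stable. All intermediate artifacts (feature tables,
calibrated RFs, descriptor tables, the model bundle, per-datapoint
evaluations) are written under `demo/`.

The same chain is available stage by stage from the shell:

```sh
esiquant simulate --n-compounds 100 --seed 1 --out-dir sim
esiquant calibrate --features sim/features.csv --standards sim/standards.csv --out rf.csv
esiquant featurize --features sim/features.csv --out desc.csv
esiquant train --descriptors desc.csv --rf rf.csv --out bundle.joblib
esiquant predict --bundle bundle.joblib --descriptors desc.csv \
    --features sim/features.csv --out pred.csv
esiquant evaluate --predictions pred.csv --truth sim/standards.csv \
    --out-evaluation eval.csv --out-summary summary.csv
```

And the uncertainty arithmetic for risk quotients:

```python
>>> from esiquant import combine_uncertainty_factors
>>> combine_uncertainty_factors([10, 10])   # two order-of-magnitude uncertainties
13.727922061357855
>>> combine_uncertainty_factors([10, 1.2])  # a 20% uncertainty is dominated
10.00222194794152
```

## Scope

No vendor raw-file parsing, peak picking or integration; input is an
aligned feature table (CSV). No structure-derived descriptors — that is
the complementary, structure-based approach this method deliberately
avoids. No matrix-effect correction and no cross-instrument model
transfer. See `docs/methods.md` for the model, parameter defaults, and
limitations.
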