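# Methods

## The problem

Non-targeted LC/ESI/HRMS screening detects thousands of features for which
no analytical standard exists, so peak areas cannot be converted to
concentrations the usual way. Electrospray ionization efficiency — and
with it the response factor RF, the slope of peak area versus molar
concentration — varies by five to six orders of magnitude between
compounds, so a raw area says almost nothing about amount. `esiquant`
implements a structure-free route around this: the RF of a feature is
predicted from quantities the instrument itself provides (retention times
at three mobile-phase pHs, the ratio of positive- to negative-mode peak
areas, the ion m/z, adduct behavior), and the concentration follows as

    c = A / RF_pred

with A the peak area. No molecular structure, candidate list or
physicochemical property calculation is needed.

## Calibration: RF as the slope of the linear range

For every standard and every (polarity, pH) condition, the dilution-series
points (c_i, A_i) are fit by ordinary least squares with a free intercept;
the RF is the fitted slope (M^-1). The intercept is fitted to absorb
baseline offsets but deliberately ignored at quantification time, where
c = A / RF assumes proportionality.

ESI calibration curves flatten at high concentration, and "linear range"
has no universal operational definition, so the package uses a
deterministic trimming rule. Sorted by concentration, while more than
three points remain the top point is dropped when either

* the full-fit R² falls below 0.99, or
* the top point's area deviates by more than 30 % from the value
  back-calculated from an OLS fit through the remaining points.

The second (leave-top-out) check is the one that actually catches
saturation: a saturated top point has so much leverage that raw-scale R²
can stay above 0.99 while the point sits at half the area the lower
points predict. The 30 % tolerance is deliberately looser than the ±20 %
back-calculation accuracy band used in targeted work, so that a noisy but
linear top point (≈10 % area CV) is almost never discarded; under the
simulator's default noise the false-trim rate is about 1 %. At least
three points are always retained; a non-positive fitted slope raises a
degenerate-calibration error rather than returning a meaningless RF.

## The 12 LC/MS descriptors

Per compound: log10 positive/negative area ratio at pH 2.7, 8.0, 10.0;
retention time at each pH (minutes); RT(8.0)−RT(2.7); RT(8.0)−RT(10.0);
ion m/z; sodium-adduct flag at pH 2.7; detected-in-negative-mode flag; and
the parity of the nominal ion mass (odd nominal mass suggests an odd
nitrogen count). Missing values are encoded as sentinels far outside the
continuous range (−999 when positive mode is undetected at that pH, +999
when negative mode is, −999 for missing RTs and RT differences): tree
ensembles split on such values directly, which keeps censored compounds in
the training set without imputation.

Choices the data leave open, fixed here once:

* the per-pH area ratio is the mean of per-dilution log ratios over
  dilutions detected in both modes (robust to LOD censoring at the series
  tails, invariant to the common concentration); if the two modes share no
  dilution, the ratio of mean detected areas is used;
* descriptor RTs prefer the positive-mode trace at each pH;
* the descriptor m/z is the positive-mode ion m/z when available,
  otherwise the negative-mode ion m/z plus two proton masses;
* a compound absent from both modes at one pH gets −999 for that pH's
  ratio and RT instead of an error, since it may be well characterized at
  the other pHs;
* parity is computed on the nominal (half-away-from-zero-rounded) mass of
  the detected ion.

## Models

One random-forest regressor per (polarity, pH) condition — six in total —
predicts log10 RF from the 12 descriptors. Forests have 500 trees;
`max_features` ∈ {4, 8, 12} and `min_samples_leaf` ∈ {1, 3} are tuned by
5-fold cross-validation on mean squared error. A condition is only
trained with at least 10 calibrated standards, and fails loudly otherwise.
All randomness derives from a single seed; per-condition seeds are
deterministic functions of it. Descriptor relevance is measured by
permutation importance (mean increase in squared error over repeated
column permutations). Because the three per-pH area ratios are strongly
correlated, permutation importance shares credit among them; rankings
should be read per-group, not per-column.

Two formula-defined baselines provide context:

* **equal-RF** — every compound gets the geometric mean RF of the
  training standards in its condition (the mean of log RFs,
  back-transformed);
* **closest-eluting** — every compound gets the RF of the training
  standard with the nearest mean retention time, ties broken toward the
  earlier-eluting standard. The pipeline applies it in positive mode at
  pH 2.7, its home setting; the function itself works for any condition.

For compounds ionizing in both modes there is also a one-variable linear
model: log10 RF_pos(pH 8.0) regressed on the pH-8.0 area ratio. Shallow
regression trees (`fit_interpretive_tree`) expose what the forests learn
as a serializable nested structure.

Interpolating ensembles regress toward the training mean: predictions
never leave the range of training log RFs, so the largest errors are
expected for compounds with extreme response factors.

## Quantification and scoring

Per-condition estimates c = A / RF_pred are aggregated per compound and
dilution into a (min, median, max) range over the available conditions;
the median of an even count is the arithmetic midpoint. Accuracy is the
symmetric fold error max(c_pred/c_act, c_act/c_pred), summarized by mean,
median, maximum, and the fraction of datapoints *strictly* below a factor
of 10; one datapoint is one compound × concentration × condition. The
fold-error mean has a heavy right tail — a single extreme-RF compound can
dominate it — so the median and the below-10 fraction are the more stable
summaries at small test-set sizes.

Independent multiplicative uncertainties (for instance a predicted
concentration and a predicted toxicity endpoint entering a risk quotient)
combine by quadrature of relative uncertainties: each factor f maps to
u = f − 1 and the total is 1 + sqrt(Σ u²). This rule is reconstructed
from its two known worked values — two factor-10 uncertainties combine to
≈13.7 ("a factor of 14"), and factor 10 with factor 1.2 gives ≈10.0 — and
both are pinned by tests; the larger uncertainty always dominates.

## The synthetic-data generator

`esiquant.simulate` generates feature tables with known ground truth so
every stage is testable without instrument data. Each compound carries
three latent traits: lipophilicity (drives retention), basicity and
acidity (drive the pH-dependent RT shift and the polarity offsets of the
RF). Defaults, chosen once to mirror realistic screening conditions:

| parameter | default | meaning |
|---|---|---|
| `n_compounds` | 200 | compounds per table |
| `log_rf_mean_pos` / `sd` | 15.5 / 1.2 | positive-mode log10 RF location/scale |
| `log_rf_mean_neg` / `sd` | 15.0 / 1.0 | negative-mode, centered near 10^15 |
| `frac_neg_detectable` | 0.5 | fraction ionizing in negative mode |
| `dilution_factors_train` | 1, 2, 4, 20, 40 | standards series |
| `dilution_factors_test` | 1, 2, 10, 20, 100 | test series |
| `conc_range_M` | 1.7e-6 – 2.4e-5 | undiluted standard concentrations |
| `noise_cv` | 0.1 | multiplicative (log-normal) area noise |
| `lod_area` | 1e4 | censoring threshold, cf. a 10,000-count minimum peak intensity |
| `rt_range` | 2 – 18 min | elution window within a 20-min gradient |
| `ph_trend_pos` | 0.5 | drop of positive-mode log RF from pH 2.7 to 10.0 |
| `rt_rf_coupling` | 0.3 | lipophilicity term in log RF (0 ⇒ RT ⊥ RF at pH 2.7) |

The generated RFs span >4 orders of magnitude across 200 compounds; the
log pos/neg area ratio correlates with positive-mode log RF with R² ≈
0.55, inside the 0.48–0.75 band such screening data show; retention time
correlates strongly with latent lipophilicity; compounds shifting to
longer retention at pH 10 (basic) tend to higher positive-mode RFs.
Areas are expected = c × 10^logRF times exp(N(0, noise_cv)); realized
areas below `lod_area` are emitted as not-detected rows, so censoring is
monotone in the threshold under a fixed seed. The magnitude of the
pH trend of the RF is exposed as a knob rather than fixed, since no
quantitative value is established for it.

What the generator does **not** emulate: chromatographic peak shapes and
integration error, isotope patterns, matrix effects (ion suppression or
enhancement), sample-preparation recovery, instrument-to-instrument RF
drift, and any structural relationship between descriptors beyond the
three latent traits. Passing tests therefore demonstrate correctness of
the pipeline's statistics and bookkeeping under a plausible generative
model — not field performance on real extracts.

## Numerical and design notes

* All logarithms are base 10.
* Split peaks: within a (compound, condition, dilution) group all k ≥ 2
  detected records merge to one (areas summed, RTs averaged) — the
  two-peak rule generalized to any k, conserving total area.
* The sodium-adduct flag is stored per record and reduced to a
  per-compound "any at pH 2.7" in the descriptors.
* Genuine log ratios lie within (−20, 20) under any realistic
  configuration, so ±999 sentinels cannot collide with real values.
* CSV numerics are written with `repr`, so read∘write round-trips
  bit-exactly; record order is canonicalized (compound, condition,
  dilution; positive before negative, ascending pH).
* Evaluation pipelines are deterministic end to end under a fixed seed;
  train/test realizations use separated RNG streams of one seed.
* The end-to-end demonstrations in the test suite use 150 training and 50
  test compounds with 250-tree forests, pooling datapoints over three
  replicate simulations when ordering claims are asserted, because the
  fold-error mean at a 50-compound test set is dominated by its largest
  outlier.

## Known limitations

* The RF trimming rule is a reconstruction; laboratories with their own
  linear-range conventions should expect small slope differences.
* Models transfer neither across instruments nor across chromatographic
  methods; descriptors are method-specific by construction.
* The uncertainty-combination rule treats the input fold-uncertainties as
  independent, symmetric relative errors; it is validated only against
  the two worked values above.
* Quantification ignores the calibration intercept; strongly nonzero
  baselines violate the c = A/RF assumption at low areas.
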