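# Methods

This note documents the models, numerical choices and limitations behind
`dendroprov`, in the order the pipeline runs them.

## Detrending spline

Raw ring widths mix an age/size trend with year-to-year climate signal.
Each series is divided by a smoothing-spline growth curve whose stiffness
is set in the frequency domain: for the roughness penalty
`λ ∫ s''(t)² dt` on annual data, the transfer function is
`U(ω) = 1 / (1 + λ ω⁴)`, so requiring 50% amplitude at wavelength `L`
gives `λ = (L / 2π)⁴`. With the default `L = 30` years the measured
response on 150-year sinusoid probes is 0.545 at 30 years (edge effects
raise the full-span value slightly above the asymptotic 0.5; the interior
value is 0.509), 0.991 at 100 years, and < 0.01 at 5 years. The relation
is verified by the probe tests rather than trusted. Detrending is by
division (ratio indices near 1, the conifer convention); a non-positive
fitted curve aborts with the offending year named — no silent clamping.
Zero widths (locally absent rings) become index 0 and stay in the series.

## Prewhitening

A first-order autoregression (ordinary least squares of `x_t` on
`x_{t−1}` with intercept) is removed and the residuals recentred to mean 1;
the first year, which has no predictor, is dropped. The order is fixed at
one by design, not AIC-selected. Note a statistical fact the tests
encode: perfectly white residuals of length ~200 still show sample lag-1
autocorrelation with standard deviation ≈ 0.07, so whiteness is asserted
on ensemble averages, not on single draws.

## Robust chronology

Per provenance × site and year, trees are averaged with an iterated Tukey
biweight (tuning radius 9 × MAD, ≤ 50 iterations, tolerance 1e-8; MAD = 0
falls back to the median). Sample depth is recorded per year. Descriptive
statistics: glk is scored 1 / 0.5 / 0 per year-to-year interval (same
direction / exactly one flat / opposite) and averaged over all
within-group tree pairs; MS is the mean absolute relative difference
`|2(x_{t+1} − x_t)/(x_{t+1} + x_t)|` with zero-sum pairs skipped; rbar is
the mean pairwise Pearson correlation over each pair's common period,
computed here on the prewhitened indices (the usual choice when the
chronology itself is prewhitened; computing it on detrended-only series
would raise the values slightly).

## Climate indices

Extraterrestrial radiation uses the standard daily solar-geometry formulas
evaluated at the mid-month representative day `J = int(30.4 m − 15)`;
latitudes beyond ±66.5° are rejected rather than given polar-day handling.
Hargreaves PET needs only temperature and `R_a`, which is why it suits
station-poor trial sites; monthly PET is the daily value times the
(non-leap) month length, floored at zero. CWB is `P − PET` exactly, month
by month.

SPEI-k sums `D = P − PET` over backward k-month windows and fits, per
calendar month over the full provided record (the calibration period), a
three-parameter log-logistic distribution by unbiased probability-weighted
moments `w_s = E[X(1−F)^s]`; non-exceedance probabilities map to standard
normal deviates. Left-skewed month samples — which arise when drought
years thin the summer tail — are fitted on the reflected sample with the
probit negated, preserving monotonicity in `D` and the calibration
property (per-month mean ≈ 0, s.d. ≈ 1, verified on 50 simulated years).
Probabilities are clipped to `[1/(4n), 1 − 1/(4n)]` so the probit stays
finite. The first k−1 months are undefined. The fit is cross-checked
against scipy's log-logistic (`fisk`) parametrization in the tests.

The annual aridity index is pluggable because the trial literature uses
several un-reconciled formulas; the default is de Martonne
`P / (T + 10)`, recorded in the output metadata. The 19 bioclim variables
use all 12 wrap-around three-month quarters (December–January wraps),
first-window tie-breaks, sample standard deviations (bio4 = s.d. × 100),
and the literal CV for bio15 (undefined, not stabilized, at zero mean
precipitation). PDSI is validated as an external input only — computing it
requires a water-balance accounting model that is out of scope.

## Pairwise PCGA

The tree × year index matrix over the common overlap (each tree centred on
its own mean — indices are already variance-comparable, centring removes
residual level differences) is decomposed by SVD; each tree's loadings on
the first two components give a polar angle, and trees are ranked by
angle. PCA signs are fixed by orienting both components so their mean
loading is positive, which resolves the reflection ambiguity of the polar
coordinates; the rank-sum test is applied to the gradient *ranks*, making
the result invariant to monotone transforms of the angle (for untied data
this is equivalent to testing the angles themselves). Ties in angle break
by stable series order. A matrix with no positive-variance component is
rejected; a rank-one matrix (all trees identical) is legal and yields
equal angles.

For every unordered provenance pair, a separate PCGA is run on just those
two provenances' trees, then the two groups' ranks are compared with a
Wilcoxon rank-sum test (exact enumeration for combined n ≤ 12 without
ties, otherwise the normal approximation with tie and continuity
corrections; all-identical input returns p = 1 with a warning).
Provenances with fewer than 4 trees are excluded with a warning. No
multiplicity correction is applied across the 45 pairs — the matrix is
meant to be read as a raw significance map. The differentiation score is
the fraction of pairs with p < α; simulated exchangeable nulls put its
per-pair false-positive rate at ~4–5% at α = 0.05 through the entire
chain.

## Pointer years

Cropper values standardize each index within a centred 5-year window using
the sample (n−1) standard deviation; edge years without a full window are
undefined rather than computed on truncated windows (avoids edge bias),
as are zero-spread windows. Intensity classes are strict thresholds
|C| > 1 / 1.28 / 1.645. A provenance flags a pointer year when ≥ 65% of
assessable trees (at least 5, a floor chosen to avoid tiny denominators)
show a same-sign event; the year's intensity is the highest class still
met by that share. Common pointer years need ≥ 6 provenances agreeing in
sign. Because the window statistics travel with the series, a sustained
multi-year depression re-normalizes the local mean and is *not* flagged in
its interior — an intended property of the metric, demonstrated by the
engineered-depression fixtures.

## Clustering and ordination

Chronologies are truncated to their common period and clustered on
Euclidean distances under single, complete, UPGMA and Ward linkages (Ward
in the minimum-variance form with heights on the distance scale, since
"Ward" is ambiguous across toolkits; the tests pin it to the
Lance–Williams recurrence). The linkage with the highest agglomerative
coefficient — `1 − mean_i(first-merge height of i / final height)` — is
selected, and the cluster count comes from the Mojena rule: cut before the
first fusion exceeding `mean + c · s.d.` of fusion heights, default
`c = 1.25` (the value recommended in the follow-up literature),
`k = 1` when nothing exceeds. Bioclim PCA standardizes variables to zero
mean and unit variance (eigenvalues then sum to the number of retained
variables), drops zero-variance or undefined variables with a warning, and
orients each component so its largest-magnitude variable correlation is
positive. Score signs are convention-dependent; only magnitudes and
relative positions are interpretable.

## Synthetic trial generator

The generator emulates the structure the analysis assumes, not any
particular forest. Monthly climate: temperature normals plus a year-level
Gaussian anomaly (default s.d. 0.8 °C) with a fixed ±5 °C diurnal
half-range; precipitation gamma-distributed around monthly normals
(CV 0.30–0.35); drought years drawn with site-specific frequency
(0.08 mild, 0.25 dry) impose a 40–50% May–August precipitation cut and a
+1.5 °C summer bump. Ring width for tree t of provenance p in year y:

    log w = log A(age) + min((1−m)·s_p(y) + m·u(y), u(y) + 3(1−m))
            + tree effect + noise

with `A(age) = baseline · exp(−0.03 · age) + 0.3` mm, `s_p` the
provenance's standardized response to the 24 z-scored monthly covariates
(12 temperature + 12 precipitation), `u` the standardized May–August water
balance of the site, signal scale 0.25 in log units, lognormal tree effect
(s.d. 0.10) and year × tree noise (s.d. 0.15), and widths rounded to the
0.01 mm measurement grid. The `min()` is a hard Liebig ceiling: at
marginality m = 1 it coincides with the blend and every tree carries the
water-limited signal exactly; at m = 0 it sits 3 log-units above the
signal and never binds. One master seed spawns per-tree substreams, so
each tree's draws are reproducible from its recorded seed independent of
ordering.

Default provenance responses share a summer-moisture component (weight
0.8) plus an independent random direction (weight 0.6), making provenances
correlated but distinguishable; effect sizes are this package's choice —
the trial literature quantifies none — and were fixed once at values that
give the pairwise test high power (≥ 0.8 observed) at 15 trees per
provenance on a mild site. What the generator does *not* emulate: spatial
block effects, mortality and bark-beetle outbreaks, stand competition,
age-dependent climate sensitivity, and measurement/crossdating error
beyond rounding. Passing tests therefore certify the statistical machinery
and its operating characteristics under the stated generative model, not
the biology of any particular trial.

## Problem sizes

Tests and the acceptance script run the canned scenarios at 10 provenances
× 15 trees × 40 years (the standard trial design), the null calibration at
2 × 15 × 34 years over 300–500 replicates, and the marginality sweep over
a 5-point grid averaged across 10–20 seeds — sizes chosen so the whole
suite completes in a few minutes on one core while keeping Monte-Carlo
error well inside the asserted bands.

## Known limitations

* The spline's 50%-cutoff calibration is asymptotic; the measured full-span
  response at the cutoff is ~0.545 because the spline relaxes at the
  boundaries. Interior behaviour matches theory.
* SPEI calibrated on short records (< 30 years) has noticeably noisy
  per-month parameters; the 20-year floor is a hard minimum, not a
  recommendation.
* rbar on prewhitened series is not numerically comparable to values
  computed on detrended-only series.
* The rank-one PCGA case gives all trees equal angles; the subsequent
  rank-sum test then correctly reports p = 1 rather than failing.
* `aridity_index` implements de Martonne only; other formulas can be added
  behind the same interface.
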