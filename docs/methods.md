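# Methods

## Model

`betaclock` treats age prediction as discrete maximum-likelihood estimation
over an integer age grid a ∈ {0, …, 100}. A trained reference holds, for
each selected CpG site j, the expected beta value μ_j(a) and its standard
deviation σ_j(a). For a sample with observed beta values x_j, the
log-likelihood of age a is the sum of per-site log-densities; the predicted
age is the grid argmax. No prior over ages is applied (equivalently, a flat
prior: the normalized exp(L − logsumexp L) is available as a posterior for
diagnostics via `AgeLikelihoodProfile.posterior()`).

Two per-site density families are supported.

* **normal** (default): N(μ_j(a), σ_j(a)) on the beta scale.
* **beta**: Beta(α, β) with moment-matched shapes
  α = μ(μ(1−μ) − σ²)/σ², β = (1−μ)(μ(1−μ) − σ²)/σ². A Beta law only exists
  for σ² < μ(1−μ); since the variance floor can violate this near μ → 0 or
  1, variances are clipped to `feasibility_fraction` (0.99) of the bound
  before the shapes are computed, and observations are clipped into
  [`x_eps`, 1 − `x_eps`] (1e−6) so boundary beta values keep a finite
  log-density. Densities are evaluated through log-gamma, never raw gamma.
  On moderate-noise synthetic data the two families' predictions differ by
  ≤ 1 year in the median, so the simpler normal family is the default.

### Training

1. **Selection.** Spearman ρ (average ranks for ties, pairwise-complete
   observations, undefined below 3 usable pairs) between methylation and
   age for every site; screen at |ρ| ≥ `min_abs_rho` (0.60); keep the
   `n_sites` (16) largest |ρ|, ties broken by site ID so selection is
   order-invariant.
2. **Trend.** Per selected site, LOWESS — tricube-weighted local linear
   regression whose window holds the nearest τ fraction of points
   (τ = 0.7, `statsmodels` backend, no robustifying iterations by
   default) — fitted to (age, beta) pairs. Grid values come from linear
   interpolation between the fitted values at observed ages, constant
   beyond the observed range, clipped to [0, 1].
3. **Variance.** Same-age samples act as technical replicates: integer-age
   bins with ≥ `min_bin_size` (3) values contribute (mean, unbiased
   variance); a LOWESS (same τ) of variance against bin mean gives a
   smoothed variance-versus-methylation curve, interpolated in methylation
   space and clamped outside its support. σ_j(a) = √max(v(μ_j(a)),
   `sigma_floor`²), with `sigma_floor` = 0.01 preventing degenerate spike
   likelihoods when a bin's variance is ~0 (one bin: flat pooled variance;
   two bins: linear interpolation, since LOWESS needs three points).
4. **Two-stage.** Stage 1 trains on everyone. Stage 2 splits training
   samples at real age ≤ cutoff into junior/senior cohorts (each at least
   `min_cohort_size` = 30 samples), re-ranks sites *within the stage-1
   screened set* per cohort, and builds a reference per cohort. The cutoff
   is either fixed (canonically 25) or scanned over 10–30: per candidate,
   cohort models are retrained and full two-stage predictions of a held-out
   validation set are scored; the candidate with the smallest |MBE| wins
   (ties → smallest). |MBE| rather than signed MBE is minimized because a
   large negative bias is no better than a small positive one.
   Sex-specific training simply runs the whole pipeline per sex.

### Prediction

The stage-1 estimate routes each sample (≤ routing threshold → junior,
else senior; the threshold equals the training cutoff) and the routed
cohort model produces the final age. Sites absent or missing in a sample
drop out of the likelihood sum (intersection semantics — never
imputation); `n_sites_used` is reported so callers can filter. A sample
sharing no site with the needed reference is recorded as failed without
stopping the batch. Misrouted samples are accepted as-is; there is no
iterative re-routing.

**Tie-breaking.** The argmax resolves exact likelihood ties toward the
youngest age, with one refinement: ties are first restricted to ages inside
the reference's observed training range. This matters for cohort models.
A senior reference trained on ages 26–100 is constant-extrapolated over
0–25, so those 26 grid ages are *exactly* tied whenever a sample looks
younger than the senior boundary; a plain youngest-age rule would emit age
0 (errors of −20 to −30 years for ~6% of samples in our piecewise
simulations), systematically drag the MBE negative, and push the cutoff
scan toward degenerate small cutoffs. Restricting tied maxima to the
training range sends such samples to the cohort boundary instead, which is
the informative answer; for a full-range reference the rule is identical to
plain youngest-age.

## Synthetic data

`simulate_dataset` emulates the structure of a large blood-methylome
compilation: integer ages uniform on [0, 100] (newborns to centenarians),
balanced sexes, and a beta matrix with `n_informative` monotone
age-tracking sites among age-independent background sites.

* **Curve families.** Informative sites follow
  μ(a) = b + s·t(a): `logarithmic` t = log(1+a)/log(1+a_max) (saturating —
  fast change in childhood, default), `linear`, or `piecewise` (two linear
  segments joined at `changepoint_age` = 25, with `junior_fraction` = 0.6
  of the amplitude spent below the changepoint, so the junior slope is
  steeper). Amplitudes |s| ~ U(0.3, 0.6) with random sign, baselines drawn
  so curves stay inside [0.02, 0.98] — the span of strong age-CpGs such as
  the ELOVL2 promoter, which covers roughly half the beta scale over a
  lifetime.
* **Noise.** Truncated Gaussian on the beta scale (or moment-matched Beta
  draws) with variance v(μ) = `noise_scale`²·(1 + 4μ(1−μ)) when
  `heteroscedastic` — largest at intermediate methylation, as observed on
  arrays. The default `noise_scale` = 0.03 is a plausible stand-in for
  residual inter-individual spread at strong clock sites, not a calibration
  to any cohort.
* **Extras.** Optional additive sex offset on a random 25% of informative
  sites (males), and uniform missingness at `missing_rate`.

Every dataset carries a `GroundTruth` able to evaluate the noise-free
curves exactly; `simulate_like` draws fresh cohorts under the same curves
for train/test designs. The generator does **not** emulate probe-level
intensity artifacts, batch effects, or cell-composition heterogeneity, so
green tests show the estimator recovers the model it assumes — not that the
model captures every property of real arrays.

### What the generator implies for accuracy claims

With purely logarithmic curves the senior decades are nearly flat
(slope ∝ 1/(1+a)), so at `noise_scale` 0.03 even an oracle that knows the
true curves has MAE ≈ 4 years over a 0–100 test population — the grid MLE
is information-limited there, and LOWESS curvature bias (≈ ½ f″ μ₂(K) h²,
with the window h ≈ 35 years at τ = 0.7) adds a further systematic shift of
up to several years at young ages, where the shift-to-slope ratio is
independent of the curve amplitude. Noise-free recovery is therefore exact
under linear curves (verified: 100/100 test samples) but not under
logarithmic ones; accuracy statements in the test-suite are made per curve
family for this reason. The piecewise family, whose senior segment keeps a
nonzero slope, is the regime where the two-stage refinement shows its
intended behavior (cutoff selected near the changepoint, junior MAE
roughly halved, bias reduced several-fold).

## Evaluation

MAE, RMSE, MBE (= mean(predicted − real); positive means over-prediction)
and R² = 1 − SS_res/SS_tot against real ages (NaN when the real ages have
zero variance). Cohort-level metrics group by *real* age at the model's
cutoff; routing, by contrast, uses the *predicted* stage-1 age — these
differ for misrouted samples. k-fold cross-validation (default k = 10)
attaches folds to sorted sample IDs so reports are invariant to row order;
with cutoff scanning enabled, the scan runs on an inner 20% validation
split of each fold's training part, never on the held-out fold. The
penalized baselines minimize (1/2n)‖y − Xβ‖² + λ(r‖β‖₁ + ((1−r)/2)‖β‖²)
(λ = 0.01; r = 1 is the LASSO, r = 0.72 the canonical elastic net), with
per-site training-mean imputation — baselines only; the clock itself never
imputes.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `tau` | 0.7 | LOWESS window fraction (trend and variance fits) |
| `n_sites` | 16 | sites per reference matrix |
| `min_abs_rho` | 0.60 | Spearman screening threshold |
| `family` | normal | per-site likelihood family |
| `sigma_floor` | 0.01 | lower bound on σ (beta-value scale) |
| `min_bin_size` | 3 | replicates per age bin for a variance estimate |
| `min_cohort_size` | 30 | smallest trainable cohort |
| cutoff scan | 10–30 | candidate junior/senior cutoffs, |MBE|-selected |

## Known limitations

* Point predictions only; the grid posterior is exposed but uncalibrated.
* Constant extrapolation outside the training age range means the clock
  cannot distinguish ages beyond the oldest/youngest training sample.
* Variance estimation leans on same-age replicates; sparse age bins fall
  back to pooled variance, and τ for the variance fit is assumed equal to
  the trend τ.
* The senior cohort's near-flat saturating sites are information-poor;
  no amount of smoothing recovers accuracy the data do not contain.
* Problem sizes in the test-suite and acceptance script (≈2000 training
  samples, ≤100 sites) are chosen so the full pipeline, including the
  21-candidate cutoff scan, retrains in seconds.
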