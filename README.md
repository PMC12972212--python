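# betaclock

A two-stage maximum-likelihood epigenetic clock for microarray
DNA-methylation data.

Epigenetic clocks predict chronological age from CpG methylation. Most are
penalized linear regressions, which assume methylation drifts linearly with
age — an assumption that fails in childhood and adolescence, where many
age-associated CpG sites change rapidly and then saturate. `betaclock`
implements a nonparametric alternative for Illumina 450K-style beta values
(methylation fractions in [0, 1]):

1. **Site selection.** Rank CpG sites by the Spearman correlation ρ between
   methylation and age (robust to monotone nonlinearity), screen at
   |ρ| ≥ 0.60, and keep the top 16.
2. **Reference curves.** For each selected site, fit a LOWESS curve
   (tricube-weighted local linear regression, smoothing fraction τ = 0.7) of
   methylation against age and read it out on an integer age grid 0–100,
   giving μ_j(a). Same-age samples are treated as technical replicates: each
   integer-age bin contributes its (mean methylation, variance) pair, and a
   second LOWESS of variance against methylation level yields a
   heteroscedastic noise model σ_j²(a) = v(μ_j(a)).
3. **Maximum-likelihood age.** For a sample with beta values x_j, the
   log-likelihood of age a is

   L(a) = Σ_j log p(x_j | μ_j(a), σ_j(a)),

   summed over the reference sites present in the sample (missing sites
   simply drop out). p is a normal density by default, or a Beta density
   with moment-matched shapes α = μ(−μ² + μ − σ²)/σ² and
   β = (μ − 1)(μ² − μ + σ²)/σ² — the two give nearly identical predictions.
   The predicted age is argmax L(a) over the grid.
4. **Two-stage refinement.** Because young and old methylomes follow
   different dynamics, the clock is trained twice: once on everyone
   (stage 1), then separately on a *junior* (age ≤ cutoff) and *senior*
   (age > cutoff) cohort, each with its own re-selected sites and curves.
   At prediction time the stage-1 estimate routes each sample (≤ cutoff →
   junior model, otherwise senior) and the routed cohort model produces the
   final age. The cutoff is chosen by scanning 10–30 and keeping the value
   with the smallest validation mean bias error (MBE); 25 is the canonical
   choice. Optionally the whole pipeline runs separately per sex.

The package ships a synthetic-data generator that emulates the statistical
structure this clock assumes — saturating (logarithmic), linear or
piecewise monotone trends, methylation-dependent noise, sex offsets and
missingness — so training, prediction and evaluation are fully testable
without downloading any cohort.

## Worked example

```python
from betaclock import (ClockConfig, SimConfig, simulate_dataset,
                       train_two_stage, predict_two_stage, compute_metrics)
from betaclock.simulate import simulate_like

cohort, truth = simulate_dataset(SimConfig(
    n_samples=1500, n_sites=100, n_informative=16,
    curve_family="piecewise", noise_scale=0.03, seed=7,
))
newcomers = simulate_like(truth, 200, seed=8)

model, _ = train_two_stage(cohort, ClockConfig(), cutoff=25)
pred = predict_two_stage(model, newcomers)
print(pred.head(4).round(2))
```

```
           stage1_age  final_age  cohort  n_sites_used  max_log_likelihood
sample_id
t00000           70.0       69.0  senior            16               27.70
t00001           35.0       28.0  senior            16               28.29
t00002           30.0       26.0  senior            16               26.62
t00003           98.0       98.0  senior            16               31.22
```

Each row is one sample: the initial whole-population estimate
(`stage1_age`), the cohort it was routed to, the refined prediction
(`final_age`), how many reference sites the sample actually carried, and
the peak log-likelihood. Scoring against the known simulated ages:

```
stage 1: MAE 3.77 y, MBE +1.26 y
stage 2: MAE 2.97 y, MBE +0.44 y
junior cohort (age <= 25): MAE 4.06 -> 1.60 y
```

The two-stage refinement cuts the overall error and bias, and the gain is
concentrated in the junior cohort — the regime where methylation changes
fastest and a single whole-life fit is most wrong.

The same workflow is available from the shell:

```bash
betaclock simulate --n-samples 1500 --curve-family piecewise --seed 7 --out-dir data/
betaclock train --betas data/betas.tsv --metadata data/metadata.tsv \
    --scan-cutoffs 10:30 --out model.json --scan-out scan.tsv
betaclock predict --model model.json --betas data/betas.tsv --out pred.tsv
betaclock evaluate --predictions pred.tsv --metadata data/metadata.tsv
betaclock cv --betas data/betas.tsv --metadata data/metadata.tsv \
    --k 10 --seed 0 --baselines lasso,elasticnet --out-dir cv/
```

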