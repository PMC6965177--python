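# corrnoise

Pearson correlation under measurement error: simulators for additive,
multiplicative, combined ("realistic") and generalized correlated error
models, closed-form expected correlation and attenuation coefficients,
bias-regime classification (attenuation / inflation / sign flip),
correction (disattenuation) estimators, and the associated simulation
experiments (kinetic network attenuation, technical-replicate averaging,
Monte-Carlo correlation envelopes, multivariate corrected recovery).

## Library overview

- `corrnoise.models` — `TrueSignal`, `MultiTrueSignal`, `ErrorSpec`,
  `NoisySample`; `simulate_bivariate`, `simulate_multivariate`,
  `sample_corr`, `theoretical_var`. The generalized correlated model is
  the internal core; the special models are its `pi = +/-1` reductions.
  Every error component draws from its own RNG sub-stream, so runs are
  bit-reproducible and components can be toggled independently.
- `corrnoise.analytic` — `expected_corr`, `attenuation_coeff`,
  `null_corr`, `classify_regime`, `limiting_surface`, plus a raw-moment
  cross-check (`expected_corr_raw`) and a vectorized evaluator.
- `corrnoise.correction` — `correct_corr` (exact algebraic inverse of
  `expected_corr`, with +/-1 clipping flagged and the raw value kept),
  `correct_matrix`, and a replicate-based variance plug-in for the
  purely additive uncorrelated case.
- `corrnoise.experiments` — `mm_profiles` / `network_attenuation_sweep`
  (enzyme-kinetics correlation network under growing error),
  `make_replicate_sets` / `replicate_avg_corr`, `mc_envelope`,
  `synth_covariance` / `recovery_experiment`.

```python
import corrnoise as cn

sig = cn.TrueSignal(mu_x=100, mu_y=100, var_x=1, var_y=1, rho0=0.8)
err = cn.ErrorSpec.additive(var_au_x=0.75)
sample = cn.simulate_bivariate(sig, err, n=1000, seed=7)
r = cn.sample_corr(sample.data)             # ~ 0.8 / 1.75
cn.correct_corr(r, sig, err).rho_corrected  # ~ 0.8
```

## CLI

```bash
corrnoise simulate --model additive --n 1000 --seed 7 --params params.yaml --out run/
corrnoise expected-corr --params params.yaml --regime
corrnoise correct --input matrix.csv --errors errors.yaml --out run/
corrnoise experiment {kinetics,replicates,envelope,recovery} --config cfg.yaml --out run/
```

Parameter files are YAML or JSON (auto-detected by extension); unknown
keys are rejected. Each run writes CSV outputs plus `manifest.json`
(config echo + hash, seed, version, wall time). Exit codes: 2 config
error, 3 numeric error, 4 I/O error.

Example `params.yaml`:

```yaml
signal: {mu_x: 100, mu_y: 100, var_x: 1, var_y: 1, rho0: 0.8}
error:  {model_kind: additive, var_au_x: 0.75, var_au_y: 0.75, var_ac: 0.25, sign: 1}
```

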