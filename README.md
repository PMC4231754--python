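# srnasilence

Quantitative framework for how ribosome binding at a target's 5'UTR
modulates small-RNA (sRNA) silencing. The mRNA interaction region is
naked, ribosome-bound or sRNA-bound; coarse-graining yields effective
rates for mRNA turnover, sRNA–mRNA interaction and translation as
functions of the ribosome–RBS affinity `x` and the dimensionless ratios
`w` (degradation with vs without a bound ribosome), `y` (sRNA binding
with vs without a bound ribosome) and `z` (complex dissociation vs
degradation). The package provides:

- **`model_core`** — effective rates, closed-form and numeric steady
  states of the mass-action system, silencing efficacy (fold
  repression), response curves over selectable axes, and transcription-
  ratio regime classification. Two reference parameter presets
  (`fig2`, `fig5`) ship with the package.
- **`stochastic`** — stationary covariance from the linear
  fluctuation–dissipation (Lyapunov) relation `JC + CJᵀ + N = 0`,
  protein noise `η = σ²/⟨p⟩²`, noise curves with/without sRNA, an exact
  Gillespie simulator over the seven elementary reactions (independent
  oracle), and local-maximum detection for anomalous noise profiles.
- **`synthetic_data`** — seeded generators for plate-reader time series,
  per-cell flow-cytometry samples (gamma-distributed, intrinsic +
  extrinsic CV²) and transcription-shutoff qPCR Cq series, each with a
  JSON truth sidecar for closed-loop estimator scoring.
- **`estimators`** — expression from GFP-vs-OD slopes in the linear
  window, repeat aggregation with the `n⁻¹·sqrt(Σ[(g_r−g)² + σ_gr²])`
  error rule, autofluorescence correction, efficacy ratios with
  delta-method errors, CV² noise estimation, efficiency-corrected ΔΔCq
  quantification and half-life fits of `f(t) = f₀·2^(−t/τ½)`.
- **`inference`** — per-variant affinity inversion from unregulated
  expression, weighted least-squares fitting of the interaction
  parameters, bootstrap classification of competition (`y/w < 1`) vs
  recruitment (`y/w > 1`), the noise-signature trend test, and the
  end-to-end seeded pipeline.

## CLI

```sh
# model curves for a preset (efficacy + noise CSVs)
srnasilence predict --preset fig2 --y 100 --alpha-s 1 --outdir curves/

# synthetic datasets with truth sidecars
srnasilence simulate --truth-mode recruitment --seed 1 --outdir sim/

# estimates (expression, efficacy, noise, half-life)
srnasilence estimate --indir sim/ --outdir results/

# interaction-mode fit from the expression table
srnasilence fit --results results/expression.csv --out results/mode_fit.json

# everything at once
srnasilence run --truth-mode recruitment --seed 1 --out report.json
```

Parameter files are flat YAML mappings with keys `alpha_m, alpha_s,
beta_m0, beta_s, beta_p, k0, gamma0, x, w, y, z` (rates in 1/min,
molecule counts); pass them with `--config`.

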