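# crte — kernel estimation of cumulative residual Tsallis entropy

`crte` estimates the cumulative residual Tsallis entropy (CRTE) and its
dynamic version (DCRTE) from a univariate sample of non-negative
lifetimes, for reliability and survival analysts who want a
survival-function-based uncertainty measure rather than a density-based
one. The observations may come from a strictly stationary, ρ-mixing
dependent sequence; independence is the special case ρ(k) ≡ 0.

## The estimators

For a lifetime X with survival function F̄, the CRTE of order α (α > 0,
α ≠ 1) and its dynamic version at age t are

    η_α(X)    = (1/(α−1)) · (1 − ∫₀^∞ F̄(x)^α dx)
    η_α(X; t) = (1/(α−1)) · (1 − ∫_t^∞ (F̄(x)/F̄(t))^α dx)

The package plugs a recursive kernel density estimate into these
integrals. With a kernel K and a decreasing bandwidth schedule
b_j = c·j^(−θ), 0 < θ < 1,

    f*_n(x) = (1/(n√b_n)) Σ_j b_j^(−1/2) K((x − X_j)/b_j),
    f̂_n(x) = f*_n(x)/β_{0.5},        β_s = 1/(1 − θs),
    F̄̂_n(t) = ∫_t^∞ f̂_n(x) dx,

and η̂_α is obtained by substituting F̄̂_n for F̄. For the Gaussian
kernel the survival estimate is evaluated in closed form as a weighted
sum of normal tail probabilities. Asymptotic standard errors use the
first-order variance constant

    σ_η² = α² C_K ∫₀^∞ F̄^(2α−1)(x) dx / ((α−1)² β_{0.5}²),

with C_K = ∫K², either with the exact model survival (oracle mode) or
with the kernel estimate plugged in. Exact reference values for the
exponential, uniform and Weibull laws live in `crte.theory`; a seeded
generator of i.i.d. and Gaussian-copula AR(1) (ρ-mixing) sequences lives
in `crte.datagen`.

## Worked example

Generate 500 i.i.d. unit-rate exponential lifetimes, estimate the CRTE
of order α = 2, and compare with the exact value:

```sh
crte generate --family iid --n 500 --seed 42 --out sample.csv
crte estimate --input sample.csv --alpha 2
```

```json
{
  "value": 0.5170707199466834,
  "se": 0.09587355613484615,
  "n": 500,
  "alpha": 2.0
}
```

The exact CRTE of an Exponential(λ) lifetime is (λα−1)/(λα(α−1)) = 0.5
here, so the estimate errs by about 0.017; `se` is the first-order
plug-in standard error √(σ̂_η²/(n·b_n)) (a conservative bound — see
`docs/methods.md`). The exact reference values:

```sh
crte theory --model exponential --lambda 1 --alpha 2 --t 1.0
# {"crte": 0.5, "sigma_eta_sq": 0.21157..., "dcrte": 0.5, "sigma_eta_x_sq": 0.63348...}
```

(`dcrte` equals `crte` at every age t because the exponential law is
memoryless.) A full Monte Carlo normality study of the standardized
statistic z = √(n·b_n)(η̂_α − η_α)/σ_η, with per-replicate records and
histogram CSVs:

```sh
crte simulate --preset headline --seed 7 --out results/
# alpha=1.5: mean_z=+0.0443 var_z=0.3902 KS=0.1316 (p=0.000)
# alpha=2:   mean_z=+0.0929 var_z=0.2103 KS=0.2154 (p=0.000)
# alpha=3:   mean_z=+0.1468 var_z=0.0858 KS=0.3156 (p=0.000)
```

The z-histograms are unimodal and centred near zero; their variance is
well below 1 because the first-order σ_η overstates the spread of the
integrated estimator (`docs/methods.md` discusses this at length).

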