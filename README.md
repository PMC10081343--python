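# tofsaa

Joint maximum-likelihood estimation of the **activity** and **attenuation**
maps of a 2D time-of-flight PET scan from the emission data alone —
the *simultaneous activity and attenuation* (SAA) problem — with a
linearized biconvex ADMM solver, optional total-variation constraints, and
the classical MLAA / Huber-penalized P-MLAA algorithms as references.

The package is aimed at image-reconstruction researchers studying the SAA
inverse problem: it ships a complete simulation pipeline (piecewise-constant
anthropomorphic phantom, parallel-beam TOF projectors with exact adjoints,
Poisson noise), the four solvers behind one interface, and the study
drivers (noiseless convergence, noisy ensembles, bias–variance analysis)
that quantify them.

## Model

The mean TOF coincidence data for LOR ℓ and TOF window *i* are

```
c_iℓ = exp(−P_ℓᵀ μ) · T_iℓᵀ λ,
```

where `P` is the X-ray (Radon) projector, `T` the TOF projector with
Gaussian window profile `w_i(t) = exp[−(t−t_i)²/(2σ²)]` along each LOR, λ
the activity and μ the attenuation (cm⁻¹). Counts are Poisson,
`C_iℓ ~ Poisson(c_iℓ)`, and estimation minimizes the negative
log-likelihood

```
ℓ(λ, μ) = Σ_iℓ [ c_iℓ − C_iℓ log c_iℓ ]
```

subject to `1ᵀλ = N_total`, `λ ≥ 0`, `μ ≥ 0`, and optionally
`‖λ‖_TV ≤ γ_λ`, `‖μ‖_TV ≤ γ_μ`. The likelihood is *biconvex* in
`(Tλ, Pμ)`; the ADMM splitting `y = Ax`, `A = diag(T, P)` isolates that
coupling into a separable inner problem solved exactly per iteration (a
closed-form quadratic root per data bin, a scalar Newton solve per LOR),
while the simplex/nonnegativity/TV constraints become projections. Step
sizes are parameterized by two free ratios ρ_λ, ρ_μ with
`σ τ = 1/‖op‖²` per block.

## Worked example

```python
import tofsaa as t

cfg = t.StudyConfig(n_iter=2000)          # 64×64 desk-scale study
report = t.run_noiseless_study(cfg)       # phantom → data → ADMM-TVSAA
print({k: round(v, 5) for k, v in report["final"].items() if k != "iter"})
```

prints (a ~3 minute run)

```
{'rmse_act': 0.00052, 'rmse_att': 0.00219, 'rmse_data': 0.00018,
 'tv_lam': 137.3031, 'tv_mu': 22.09395}
```

i.e. after 2000 iterations of the TV-constrained solver on noiseless data
the activity is recovered to 0.05 % normalized RMSE, the attenuation to
0.2 % (attenuation always converges more slowly — it only reaches the data
through the survival factors), the data misfit is at 0.02 % of the data
mean, and both image TV values sit at their constraint budgets (the truth
TV values, 137.31 and 21.88 here).

The same pipeline runs from the shell:

```sh
saa run --algo admm-tvsaa --iters 2000 --out results/noiseless
saa study ensemble --config cfg.yaml --out results/ensemble
```

writing per-iteration `metrics.csv`, checkpoint images (`images.npz`) and a
`summary.json`.

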