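# Methods

## The estimation problem

A 2D TOF-PET acquisition is modelled as independent Poisson counts per
(TOF window, LOR) bin with mean `c_iℓ = exp(−P_ℓᵀμ) · T_iℓᵀλ`. Scatter and
random coincidences are not modelled. Because activity and attenuation
enter the mean only through the product of the TOF projection and the
survival factor, the data determine the pair only up to a multiplicative
constant; the total-annihilation constraint `1ᵀλ = N_total` removes that
ambiguity. Maximum-likelihood estimation is a biconvex problem: convex in
λ for fixed μ and vice versa, but not jointly convex. None of the solvers
here carries a global-convergence guarantee; convergence is assessed
empirically, which is also how the underlying method is characterised.

## Geometry and TOF discretisation

* Parallel-beam layout: `n_views` angles at `k·π/n_views`, `n_rays` rays
  per view with pitch `fov/n_rays`, laid symmetrically about the FOV
  centre. The X-ray projector is built by exact ray–pixel
  intersection-length tracing and stored as a sparse matrix, so the
  adjoint is the exact transpose (verified by inner-product tests at
  1e-10 relative tolerance).
* TOF windows are Gaussian in the along-LOR coordinate `t`, whose origin
  is the closest approach of the LOR to the FOV centre. `σ` is the
  Gaussian standard deviation, `FWHM = 2√(2 ln 2)·σ`, window spacing
  `Δt = FWHM/2`, window centres symmetric about 0. The TOF matrix scales
  each X-ray entry by the window weight at the pixel centre. Window
  weights are deliberately not normalised over windows: their sum is
  nearly constant (≈2.13) for this spacing, and any global factor is
  absorbed by the count constraint.
* The reference configuration is a 30 cm FOV with 176 pixels/rays/views,
  17 windows and 4.5 cm TOF FWHM (≈300 ps timing). The package's
  desk-scale default keeps every ratio (rays = grid size, Δt = FWHM/2,
  same FOV and FWHM) at 64×64 with 9 windows so a full study runs in
  minutes; `StudyConfig.full_scale()` restores the full size.

## Solvers

**ADMM-SAA.** The splitting `y = Ax`, `A = diag(T, P)` moves the
likelihood onto splitting variables `y = (y_λ, y_μ)` where it is separable
per bin/LOR. One outer iteration is: a linearized proximal x-update (λ
projected onto the positive simplex by the sort-based algorithm, μ onto
the nonnegative orthant), recomputation of `Tλ`, `Pμ`, an inner block
minimisation of the biconvex y-subproblem (`N_y` alternations between an
exact quadratic-root update for y_λ and `N_newt` Newton steps per LOR for
y_μ, thresholded at zero after each Newton solve), and dual ascent with
one scalar σ per block. Exactly four system-operator products are
consumed per outer iteration (instrumented and asserted in the tests).
All variables are zero-initialised. Step sizes derive from two free
ratios: `σ_λ = ρ_λ/‖T‖`, `τ_λ = 1/(ρ_λ‖T‖)` and likewise for μ with ‖P‖.

Numerical details: the y_λ root formula `(b + √(b² + 4σC))/(2σ)` covers
the zero-count case automatically; the Newton iterate is clamped at −60
before exponentiation (the step is otherwise unguarded — the curvature
`exp(−y)·y_λ + σ` is strictly positive); a fixed Newton count with no
early exit keeps runs deterministic and comparable. The default inner
counts `N_y = 100`, `N_newt = 10` solve the inner problem to numerical
accuracy (doubling `N_y` changes results below 1e-6 relative).

**ADMM-TVSAA.** Isotropic TV constraints `‖λ‖_TV ≤ γ_λ`, `‖μ‖_TV ≤ γ_μ`
are added through extra splitting variables on the forward-difference
gradients (replicate boundary; divergence is the exact negative adjoint).
Per variable the stacked operator is `(T; D)` or `(P; D)` with a single σ
from the stacked operator norm and the same two free ratios — the
minimal-parameter extension consistent with the unconstrained
parametrization. The z-update is the Euclidean projection onto the TV
ball: per-pixel gradient magnitudes projected onto the ℓ₁ ball (block
soft-thresholding, reusing the simplex machinery), directions preserved.
The splitting variables therefore satisfy their budgets exactly at every
iteration, while the images approach theirs as the gradient-consensus
residual vanishes. With both γ infinite the iteration reduces exactly to
ADMM-SAA (asserted in the tests). Budgets in study configs are expressed
as fractions of the ground-truth TV and converted to absolute values at
setup.

**MLAA.** The classical alternation: an EM step for λ, renormalisation to
`N_total`, a transmission-type gradient step for μ with the standard
curvature surrogate, and nonnegativity projection. Pixels with zero
update denominators are left unchanged; an all-zero activity (possible
only with all-zero counts) restarts uniform at the renormalisation. The
strongest correctness oracle available is asserted in the tests: with
noiseless data at the truth, one full sweep reproduces the truth to
1e-8 relative.

**P-MLAA.** Huber penalties `β H_δ(λ) + γ H_δ(μ)` applied to the
isotropic gradient magnitude, so that for small δ they approximate the
same isotropic TV used elsewhere (δ defaults to 0.1 % of each image
maximum). The λ-step follows the one-step-late construction (penalty
gradient at the current iterate added to the EM denominator); the μ-step
adds the penalty gradient to the numerator and a diagonal curvature bound
(1/δ per pixel) to the denominator. One-step-late updates have no
positivity guarantee: pixels with non-positive denominators fall back to
the unpenalized update, counted and logged rather than silently clamped.
The penalty weights that hit prescribed image-TV values at a given
iteration number are found by coordinate-wise bisection on log β / log γ;
the TV response is monotone in each weight only below the regime where
fallbacks dominate, so the search brackets should stay below it.

## Data scaling and step-size tuning

Count data are normalised by `size(C)/‖C‖₂` before reconstruction, which
makes tuned step-size ratios independent of scan duration. The exact
equivariance behind this — `C → aC` with `N_total → aN_total`,
`γ_λ → aγ_λ`, `σ_λ → σ_λ/a`, `τ_λ → aτ_λ`, `σ_μ → aσ_μ`, `τ_μ → τ_μ/a`
maps iterates as `λ → aλ`, `y_λ → ay_λ`, `u_λ → u_λ`, `μ, y_μ → μ, y_μ`,
`u_μ → au_μ` — is asserted iterate-by-iterate at 1e-8 relative tolerance.
Reported images are mapped back to phantom units, so metrics compare
directly with ground truth.

The two ratios must be re-tuned whenever the operators change. For the
desk-scale operators on normalised data a log-grid scan of noiseless
TV-constrained convergence selected `ρ_λ = 0.003`, `ρ_μ = 30` (stable one
step further down in ρ_λ; roughly an order of magnitude slower one step
up). These are the `StudyConfig` defaults; nothing in the library layer
hides them.

## Phantom and synthetic data

The phantom is a parameterised stand-in for an anthropomorphic torso
slice: elliptical soft-tissue body (0.096 cm⁻¹), two low-attenuation
lung-like ellipses (0.035 cm⁻¹), a spine-like disk at the top of the
soft-tissue display window (0.115 cm⁻¹), three hot activity lesions, a
background body activity and a central cold spot; activity is normalised
to maximum 1.0. Pixels take a feature's value if their centre lies inside
it; later features overwrite earlier ones; generation is deterministic.
An optional interior circle truncates the activity for interior-problem
studies. The images are piecewise constant — gradient-sparse by
construction, the regime TV constraints exploit — and they do not emulate
anatomical texture, partial-volume effects, scatter or randoms, detector
blur, or out-of-plane activity. Passing tests therefore demonstrate
correctness of the estimation machinery under its own forward model
(inverse-crime conditions), not clinical performance.

Noise realisations rescale the mean data to a total count (4×10⁶ by
default) and draw each bin from an independent Poisson; realisation *r*
of an ensemble uses seed `seed + r`.

## Study conditions and problem sizes

* Noiseless study: 64×64 grid, 64 views/rays, 9 windows, ADMM-TVSAA with
  γ at the truth TV values, 2000 iterations (~3 min).
* Ensemble study: 32×32 grid, 32 views/rays, 7 windows, 10 realisations
  at 4×10⁶ counts, 500 iterations, MLAA vs ADMM-TVSAA, bias and pixel-std
  normalised by the truth mean. "Bias" is the RMSE of the ensemble-mean
  image (one of several possible conventions; documented here because the
  alternative — mean absolute bias — is equally defensible).
* The full 176-scale configuration ships (`StudyConfig.full_scale()`)
  but is not exercised by the test suite.

## Known limitations

* Convergence of the biconvex ADMM is empirical; badly chosen ratios
  (e.g. ρ_λ ≲ 1e-4 or ρ_λ ≳ 0.1 at desk scale) stall or diverge, and a
  divergence surfaces as a FloatingPointError from the simplex projection
  rather than being silently absorbed.
* The TOF projector evaluates the window weight at the pixel centre; for
  pixels comparable in size to σ this is a first-order approximation
  (visible only at very coarse grids).
* 2D only; no scatter/randoms, no detector effects, no list-mode data.
* The interior-truncation study reproduces the qualitative behaviour
  (activity recovered, attenuation only inside the activity support) but
  no quantitative claims are made outside the support.
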