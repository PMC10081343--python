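"""Linearized biconvex ADMM for simultaneous activity/attenuation estimation.

The constrained maximum-likelihood problem

    min_{lam, mu}  l(lam, mu)   s.t.  1'lam = Ntotal, lam >= 0, mu >= 0,

with the TOF-PET Poisson negative log-likelihood l, is split through the
block-diagonal system operator A = diag(T, P) as Ax = y, giving a biconvex
coupling term g(y_lam, y_mu) = sum_il [exp(-y_mu,l) y_lam,il
- C_il (-y_mu,l + log y_lam,il)].  One outer iteration performs:

1. x-update: a linearized proximal step; lam is projected onto the positive
   simplex {lam >= 0, 1'lam = Ntotal}, mu onto the nonnegative orthant.
2. y-update: ``n_y`` alternations of two exact convex minimisations —
   a per-bin closed-form quadratic root for y_lam and a per-LOR Newton
   solve (``n_newton`` steps, clipped at zero afterwards) for y_mu.
   No system-operator products occur inside this inner loop.
3. dual ascent u += sigma (Ax - y) with one scalar sigma per block.

Step sizes are parametrised by two free ratios rho_lam, rho_mu with
sigma tau = 1 / ||op||^2 per block, mirroring a Chambolle-Pock style
preconditioning.  Exactly four system-operator products (T, T', P, P') are
consumed per outer iteration.  All variables are zero-initialised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StepSizes",
    "AlgoParams",
    "LoopParams",
    "SAAState",
    "make_step_sizes",
    "simplex_project",
    "pos",
    "saa_init",
    "x_update",
    "y_lam_closed_form",
    "y_mu_newton",
    "y_update_biconvex",
    "admm_saa_iterate",
]


def pos(x: np.ndarray) -> np.ndarray:
    """Nonnegativity projection: negative entries are set to zero."""
    return np.maximum(x, 0.0)


@dataclass(frozen=True)
class StepSizes:
    """Primal/dual step sizes for the two variable blocks.

    Satisfies sigma_lam * tau_lam = 1 / norm_T**2 and likewise for mu when
    built through :func:`make_step_sizes`; data rescaling (see
    ``forward.apply_data_scaling``) transforms the fields directly and
    preserves these products.
    """

    sigma_lam: float
    tau_lam: float
    sigma_mu: float
    tau_mu: float
    norm_T: float | None = None
    norm_P: float | None = None
    rho_lam: float | None = None
    rho_mu: float | None = None


def make_step_sizes(
    rho_lam: float, rho_mu: float, norm_T: float, norm_P: float
) -> StepSizes:
    """Step sizes from the two free ratio parameters.

    sigma_lam = rho_lam / ||T||, tau_lam = 1 / (rho_lam ||T||), and the
    same pattern for the mu block with ||P||.
    """
    for name, v in (
        ("rho_lam", rho_lam),
        ("rho_mu", rho_mu),
        ("norm_T", norm_T),
        ("norm_P", norm_P),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return StepSizes(
        sigma_lam=rho_lam / norm_T,
        tau_lam=1.0 / (rho_lam * norm_T),
        sigma_mu=rho_mu / norm_P,
        tau_mu=1.0 / (rho_mu * norm_P),
        norm_T=norm_T,
        norm_P=norm_P,
        rho_lam=rho_lam,
        rho_mu=rho_mu,
    )


@dataclass(frozen=True)
class LoopParams:
    """Inner-loop counts: biconvex alternations and Newton steps."""

    n_y: int = 100
    n_newton: int = 10

    def __post_init__(self) -> None:
        if self.n_y < 1 or self.n_newton < 1:
            raise ValueError("n_y and n_newton must be at least 1")


@dataclass(frozen=True)
class AlgoParams:
    """Everything the iteration needs besides the data and operators.

    ``gamma_lam`` / ``gamma_mu`` are absolute TV budgets, used only by the
    TV-constrained variant (``numpy.inf`` disables a constraint).
    """

    steps: StepSizes
    Ntotal: float
    gamma_lam: float = np.inf
    gamma_mu: float = np.inf
    loops: LoopParams = LoopParams()

    def __post_init__(self) -> None:
        if self.Ntotal <= 0:
            raise ValueError("Ntotal must be positive")
        if self.gamma_lam <= 0 or self.gamma_mu <= 0:
            raise ValueError("TV budgets must be positive")


def simplex_project(v: np.ndarray, total: float) -> np.ndarray:
    """Euclidean projection onto {x >= 0, sum(x) = total}.

    Sort-based thresholding (Duchi et al. style): the projection is
    max(v - theta, 0) with theta chosen so the result sums to ``total``.
    Accepts any array shape; the projection is applied to the flattened
    values and the shape restored.
    """
    if total <= 0:
        raise ValueError("simplex total must be positive")
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("cannot project an empty vector")
    flat = v.ravel()
    if not np.all(np.isfinite(flat)):
        raise FloatingPointError("non-finite values in simplex projection input")
    u = np.sort(flat)[::-1]
    css = np.cumsum(u) - total
    j = np.arange(1, flat.size + 1)
    rho = np.nonzero(u - css / j > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(flat - theta, 0.0).reshape(v.shape)


@dataclass
class SAAState:
    """All iterates of the ADMM algorithm plus cached forward products.

    ``t_lam`` and ``p_mu`` cache T lam and P mu of the current primal
    iterate so the next x-update needs no extra operator products.
    """

    lam: np.ndarray
    mu: np.ndarray
    y_lam: np.ndarray
    y_mu: np.ndarray
    u_lam: np.ndarray
    u_mu: np.ndarray
    t_lam: np.ndarray
    p_mu: np.ndarray


def saa_init(ops) -> SAAState:
    """Zero initialization of every algorithm variable."""
    n_win, n_lor = ops.n_windows, ops.n_lor
    z_img = np.zeros(ops.img_shape)
    z_tof = np.zeros((n_win, n_lor))
    z_lor = np.zeros(n_lor)
    return SAAState(
        lam=z_img.copy(),
        mu=z_img.copy(),
        y_lam=z_tof.copy(),
        y_mu=z_lor.copy(),
        u_lam=z_tof.copy(),
        u_mu=z_lor.copy(),
        t_lam=z_tof.copy(),
        p_mu=z_lor.copy(),
    )


def x_update(state: SAAState, steps: StepSizes, Ntotal: float, ops) -> SAAState:
    """Linearized proximal update of (lam, mu).

    lam <- simplex_project(lam - tau_lam T' ubar_lam, Ntotal) with
    ubar_lam = u_lam + sigma_lam (T lam - y_lam); mu <- pos(mu - tau_mu P'
    ubar_mu) analogously.  Consumes exactly one T' and one P' product
    (the forward products are read from the state's cache).
    """
    ubar_lam = state.u_lam + steps.sigma_lam * (state.t_lam - state.y_lam)
    ubar_mu = state.u_mu + steps.sigma_mu * (state.p_mu - state.y_mu)
    lam = simplex_project(state.lam - steps.tau_lam * ops.back_tof(ubar_lam), Ntotal)
    mu = pos(state.mu - steps.tau_mu * ops.back_x(ubar_mu))
    return replace(state, lam=lam, mu=mu)


def y_lam_closed_form(b, C, sigma_lam: float):
    """Exact minimiser of the separable y_lam subproblem per bin.

    Solves sigma y^2 - b y - C = 0 taking the nonnegative root,
    y = (b + sqrt(b^2 + 4 sigma C)) / (2 sigma); for C = 0 this reduces to
    max(b / sigma, 0).  Vectorised over bins.
    """
    if sigma_lam <= 0:
        raise ValueError("sigma_lam must be positive")
    b = np.asarray(b, dtype=float)
    C = np.asarray(C, dtype=float)
    return (b + np.sqrt(b * b + 4.0 * sigma_lam * C)) / (2.0 * sigma_lam)


def y_mu_newton(
    y_mu: np.ndarray,
    y_lam_per_lor: np.ndarray,
    C_per_lor: np.ndarray,
    u_mu: np.ndarray,
    p_mu: np.ndarray,
    sigma_mu: float,
    n_newton: int = 10,
) -> np.ndarray:
    """Per-LOR Newton solve of the y_mu subproblem, clipped at zero.

    The objective derivative is psi'(y) = -exp(-y) yl + Cl - u + sigma (y -
    Pmu) with strictly positive curvature exp(-y) yl + sigma, so the Newton
    step is always well defined.  A fixed number of steps is taken and
    negative values are thresholded to zero only after the loop.
    """
    if sigma_mu <= 0:
        raise ValueError("sigma_mu must be positive")
    y = np.asarray(y_mu, dtype=float).copy()
    for _ in range(n_newton):
        # exp of large -y would overflow; the bound keeps the iterate in a
        # range where the Newton step is still a full descent step.
        np.clip(y, -60.0, None, out=y)
        e = np.exp(-y) * y_lam_per_lor
        g = -e + C_per_lor - u_mu + sigma_mu * (y - p_mu)
        y -= g / (e + sigma_mu)
    return pos(y)


def y_update_biconvex(
    y_lam: np.ndarray,
    y_mu: np.ndarray,
    t_lam: np.ndarray,
    p_mu: np.ndarray,
    u_lam: np.ndarray,
    u_mu: np.ndarray,
    C: np.ndarray,
    steps: StepSizes,
    loops: LoopParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating exact minimisation of the biconvex y subproblem.

    Runs ``loops.n_y`` alternations between the closed-form y_lam update
    and the Newton y_mu solve.  The forward products ``t_lam`` and ``p_mu``
    are precomputed inputs; no operator product happens here.
    """
    C_per_lor = C.sum(axis=0)
    b_base = u_lam + steps.sigma_lam * t_lam
    y_mu = np.asarray(y_mu, dtype=float).copy()
    for _ in range(loops.n_y):
        b = b_base - np.exp(-y_mu)[None, :]
        y_lam = y_lam_closed_form(b, C, steps.sigma_lam)
        y_mu = y_mu_newton(
            y_mu,
            y_lam.sum(axis=0),
            C_per_lor,
            u_mu,
            p_mu,
            steps.sigma_mu,
            loops.n_newton,
        )
    return y_lam, y_mu


def inner_objective(
    y_lam, y_mu, t_lam, p_mu, u_lam, u_mu, C, steps: StepSizes
) -> float:
    """Value of the y subproblem objective (used by convergence checks).

    g(y) - u'y + sigma/2 ||Ax - y||^2 with the convention C log y -> 0
    where C = 0, and +inf where C > 0 but y_lam = 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logy = np.where(C > 0, np.log(np.where(y_lam > 0, y_lam, 1.0)), 0.0)
        if np.any((C > 0) & (y_lam <= 0)):
            return np.inf
    g = np.sum(np.exp(-y_mu)[None, :] * y_lam) + np.sum(
        C * (y_mu[None, :] - logy)
    )
    g -= np.sum(u_lam * y_lam) + np.sum(u_mu * y_mu)
    g += 0.5 * steps.sigma_lam * np.sum((y_lam - t_lam) ** 2)
    g += 0.5 * steps.sigma_mu * np.sum((y_mu - p_mu) ** 2)
    return float(g)


def admm_saa_iterate(state: SAAState, C: np.ndarray, params: AlgoParams, ops) -> SAAState:
    """One outer ADMM iteration: x-update, forward products, biconvex
    y-update, dual ascent.  Exactly two forward and two adjoint
    system-operator products are consumed."""
    st = params.steps
    state = x_update(state, st, params.Ntotal, ops)
    t_lam = ops.forward_tof(state.lam)
    p_mu = ops.forward_x(state.mu)
    y_lam, y_mu = y_update_biconvex(
        state.y_lam,
        state.y_mu,
        t_lam,
        p_mu,
        state.u_lam,
        state.u_mu,
        C,
        st,
        params.loops,
    )
    u_lam = state.u_lam + st.sigma_lam * (t_lam - y_lam)
    u_mu = state.u_mu + st.sigma_mu * (p_mu - y_mu)
    return SAAState(
        lam=state.lam,
        mu=state.mu,
        y_lam=y_lam,
        y_mu=y_mu,
        u_lam=u_lam,
        u_mu=u_mu,
        t_lam=t_lam,
        p_mu=p_mu,
    )
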