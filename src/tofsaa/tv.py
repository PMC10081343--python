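"""Isotropic total-variation machinery and the TV-constrained ADMM variant.

The discrete gradient uses forward differences with replicate boundary
(zero difference at the far edge); the divergence is its exact negative
adjoint.  The isotropic TV seminorm is the sum over pixels of the
Euclidean norm of the gradient 2-vector.

The TV-constrained algorithm augments the splitting with gradient blocks:
per variable the stacked operator is (T; D) for the activity and (P; D)
for the attenuation, each with a single scalar sigma derived from the
stacked operator norm and the same two free ratio parameters as the
unconstrained algorithm.  The extra z-updates are Euclidean projections
onto the isotropic-TV ball, i.e. per-pixel gradient magnitudes projected
onto the l1 ball (block soft-thresholding reusing the simplex machinery),
so the splitting variables satisfy their TV budgets exactly at every
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .admm import (
    AlgoParams,
    StepSizes,
    pos,
    simplex_project,
    y_update_biconvex,
)
from .projectors import operator_norm

__all__ = [
    "grad",
    "div",
    "tv_seminorm",
    "project_tv_ball",
    "grad_matrix",
    "stacked_operator_norm",
    "TVConstraints",
    "TVSAAState",
    "tvsaa_init",
    "make_tvsaa_step_sizes",
    "admm_tvsaa_iterate",
]


def grad(img: np.ndarray) -> np.ndarray:
    """Forward-difference gradient field, shape (2, n, n): (d/dx, d/dy).

    x differences run along columns, y differences along rows; the far
    edge difference is zero (replicate boundary).
    """
    img = np.asarray(img, dtype=float)
    g = np.zeros((2,) + img.shape)
    g[0, :, :-1] = img[:, 1:] - img[:, :-1]
    g[1, :-1, :] = img[1:, :] - img[:-1, :]
    return g


def div(field: np.ndarray) -> np.ndarray:
    """Discrete divergence, the exact negative adjoint of :func:`grad`:
    <grad(x), f> = <x, -div(f)> for all x, f."""
    fx, fy = field[0], field[1]
    out = np.zeros_like(fx)
    out[:, :-1] += fx[:, :-1]
    out[:, 1:] -= fx[:, :-1]
    out[:-1, :] += fy[:-1, :]
    out[1:, :] -= fy[:-1, :]
    return out


def grad_magnitude(field: np.ndarray) -> np.ndarray:
    return np.sqrt(field[0] ** 2 + field[1] ** 2)


def tv_seminorm(img: np.ndarray) -> float:
    """Isotropic TV: sum over pixels of sqrt(dx^2 + dy^2)."""
    return float(grad_magnitude(grad(img)).sum())


@lru_cache(maxsize=8)
def grad_matrix(n: int) -> sp.csr_matrix:
    """Sparse matrix of :func:`grad` on an n-by-n grid, shape (2 n^2, n^2).

    Row block 0 holds the x differences, block 1 the y differences, in the
    same raveled order as the array form.
    """
    B = sp.diags([-np.ones(n), np.ones(n - 1)], [0, 1], format="lil")
    B[n - 1, n - 1] = 0.0
    B = B.tocsr()
    eye = sp.identity(n, format="csr")
    Dx = sp.kron(eye, B, format="csr")
    Dy = sp.kron(B, eye, format="csr")
    return sp.vstack([Dx, Dy], format="csr")


def stacked_operator_norm(
    A: sp.spmatrix, grid_n: int, n_iter: int = 200, seed: int = 0
) -> float:
    """Spectral norm of the stacked operator (A; D) with D = grad_matrix."""
    return operator_norm(
        sp.vstack([A.tocsr(), grad_matrix(grid_n)], format="csr"),
        n_iter=n_iter,
        seed=seed,
    )


def project_tv_ball(field: np.ndarray, gamma: float) -> np.ndarray:
    """Euclidean projection of a gradient field onto {z : sum_p |z_p|_2 <= gamma}.

    Per-pixel magnitudes are projected onto the l1 ball of radius gamma
    (simplex projection when the constraint is active); directions are
    preserved.  gamma = inf returns the field unchanged.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    m = grad_magnitude(field)
    total = m.sum()
    if total <= gamma:
        return field.copy()
    m_proj = simplex_project(m, gamma)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(m > 0, m_proj / np.where(m > 0, m, 1.0), 0.0)
    return field * scale[None, :, :]


@dataclass(frozen=True)
class TVConstraints:
    """Absolute TV budgets for the two images."""

    gamma_lam: float
    gamma_mu: float

    def __post_init__(self) -> None:
        if self.gamma_lam <= 0 or self.gamma_mu <= 0:
            raise ValueError("TV budgets must be positive")


@dataclass
class TVSAAState:
    """ADMM iterates extended with gradient splitting/dual pairs.

    ``z_lam``/``z_mu`` are the TV splitting variables for D lam and D mu
    with duals ``v_lam``/``v_mu``; ``d_lam``/``d_mu`` cache the gradients
    of the current primal iterate.
    """

    lam: np.ndarray
    mu: np.ndarray
    y_lam: np.ndarray
    y_mu: np.ndarray
    u_lam: np.ndarray
    u_mu: np.ndarray
    z_lam: np.ndarray
    z_mu: np.ndarray
    v_lam: np.ndarray
    v_mu: np.ndarray
    t_lam: np.ndarray
    p_mu: np.ndarray
    d_lam: np.ndarray
    d_mu: np.ndarray


def tvsaa_init(ops) -> TVSAAState:
    """Zero initialization of every variable of the TV-constrained solver."""
    n_win, n_lor = ops.n_windows, ops.n_lor
    z_img = np.zeros(ops.img_shape)
    z_field = np.zeros((2,) + ops.img_shape)
    return TVSAAState(
        lam=z_img.copy(),
        mu=z_img.copy(),
        y_lam=np.zeros((n_win, n_lor)),
        y_mu=np.zeros(n_lor),
        u_lam=np.zeros((n_win, n_lor)),
        u_mu=np.zeros(n_lor),
        z_lam=z_field.copy(),
        z_mu=z_field.copy(),
        v_lam=z_field.copy(),
        v_mu=z_field.copy(),
        t_lam=np.zeros((n_win, n_lor)),
        p_mu=np.zeros(n_lor),
        d_lam=z_field.copy(),
        d_mu=z_field.copy(),
    )


def make_tvsaa_step_sizes(
    rho_lam: float, rho_mu: float, ops, n_iter: int = 200, seed: int = 0
) -> StepSizes:
    """Step sizes from the stacked operator norms ||(T; D)|| and ||(P; D)||.

    Same two free ratios as the unconstrained algorithm; sigma tau =
    1/||stacked op||^2 per variable block.
    """
    n = ops.img_shape[0]
    norm_T_stack = stacked_operator_norm(ops.T, n, n_iter=n_iter, seed=seed)
    norm_P_stack = stacked_operator_norm(ops.P, n, n_iter=n_iter, seed=seed)
    from .admm import make_step_sizes

    return make_step_sizes(rho_lam, rho_mu, norm_T_stack, norm_P_stack)


def admm_tvsaa_iterate(
    state: TVSAAState, C: np.ndarray, params: AlgoParams, ops
) -> TVSAAState:
    """One outer iteration of the TV-constrained splitting.

    Identical to the unconstrained iteration except that the x-updates
    carry the gradient-block back-projections, the z-updates project onto
    the TV balls, and the gradient duals are updated with their block's
    sigma.  Still exactly four system-operator products; gradient products
    are O(n^2) and not counted.
    """
    st = params.steps
    ubar_lam = state.u_lam + st.sigma_lam * (state.t_lam - state.y_lam)
    ubar_mu = state.u_mu + st.sigma_mu * (state.p_mu - state.y_mu)
    vbar_lam = state.v_lam + st.sigma_lam * (state.d_lam - state.z_lam)
    vbar_mu = state.v_mu + st.sigma_mu * (state.d_mu - state.z_mu)
    lam = simplex_project(
        state.lam - st.tau_lam * (ops.back_tof(ubar_lam) - div(vbar_lam)),
        params.Ntotal,
    )
    mu = pos(state.mu - st.tau_mu * (ops.back_x(ubar_mu) - div(vbar_mu)))
    t_lam = ops.forward_tof(lam)
    p_mu = ops.forward_x(mu)
    d_lam = grad(lam)
    d_mu = grad(mu)
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
    z_lam = project_tv_ball(d_lam + state.v_lam / st.sigma_lam, params.gamma_lam)
    z_mu = project_tv_ball(d_mu + state.v_mu / st.sigma_mu, params.gamma_mu)
    return TVSAAState(
        lam=lam,
        mu=mu,
        y_lam=y_lam,
        y_mu=y_mu,
        u_lam=state.u_lam + st.sigma_lam * (t_lam - y_lam),
        u_mu=state.u_mu + st.sigma_mu * (p_mu - y_mu),
        z_lam=z_lam,
        z_mu=z_mu,
        v_lam=state.v_lam + st.sigma_lam * (d_lam - z_lam),
        v_mu=state.v_mu + st.sigma_mu * (d_mu - z_mu),
        t_lam=t_lam,
        p_mu=p_mu,
        d_lam=d_lam,
        d_mu=d_mu,
    )
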