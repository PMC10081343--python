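"""MLAA and Huber-penalized P-MLAA reference algorithms.

MLAA alternates a Poisson-likelihood EM step for the activity with a
transmission-type gradient step for the attenuation:

    a_l   = exp(-sum_k P_lk mu_k)
    lam_k <- lam_k * [sum_il T_ilk C_il/(T lam)_il] / [sum_il a_l T_ilk]
    lam   <- lam * Ntotal / sum(lam)
    mu_k  <- mu_k + [sum_l P_lk sum_i (a_l (T lam)_il - C_il)]
                    / [sum_l P_lk L_l a_l sum_i (T lam)_il],   L_l = sum_k P_lk
    mu    <- pos(mu)

The activity must be strictly positive at initialisation and stays
nonnegative; the total-count renormalisation makes 1'lam = Ntotal hold
exactly after every iteration.  Pixels with a zero update denominator are
left unchanged.

P-MLAA adds Huber penalties beta H_delta(lam) + gamma H_delta(mu), applied
to the isotropic gradient magnitude so that for small delta the penalty
approximates the isotropic TV seminorm.  The activity step uses the
one-step-late (OSL) construction — the penalty gradient, evaluated at the
current iterate, augments the EM denominator — and the attenuation step
augments the numerator with -gamma grad H and the denominator with the
diagonal curvature bound gamma/delta.  OSL offers no positivity guarantee:
pixels whose augmented denominator is nonpositive fall back to the
unpenalized update and are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .admm import pos
from .tv import div, grad, grad_magnitude

__all__ = [
    "MLAAState",
    "PMLAAParams",
    "mlaa_init",
    "mlaa_iterate",
    "pmlaa_iterate",
    "huber_value_and_grad",
    "tune_pmlaa_penalties",
]

logger = logging.getLogger(__name__)


@dataclass
class MLAAState:
    """Current activity (strictly positive at init) and attenuation maps."""

    lam: np.ndarray
    mu: np.ndarray


@dataclass(frozen=True)
class PMLAAParams:
    """Penalty weights and Huber smoothing parameters (absolute units)."""

    beta: float
    gamma: float
    delta_lam: float
    delta_mu: float

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.delta_lam <= 0 or self.delta_mu <= 0:
            raise ValueError("Huber smoothing parameters must be positive")

    @classmethod
    def from_fractions(
        cls,
        beta: float,
        gamma: float,
        lam_max: float,
        mu_max: float,
        delta_frac: float = 1e-3,
    ) -> "PMLAAParams":
        """Smoothing set to a fraction (default 0.1%) of each image maximum."""
        return cls(beta, gamma, delta_frac * lam_max, delta_frac * mu_max)


def mlaa_init(ops, Ntotal: float) -> MLAAState:
    """Uniform strictly-positive activity summing to Ntotal; zero attenuation."""
    lam = np.full(ops.img_shape, Ntotal / ops.n_pix)
    return MLAAState(lam=lam, mu=np.zeros(ops.img_shape))


def huber_value_and_grad(
    img: np.ndarray, delta: float
) -> tuple[float, np.ndarray]:
    """Huber penalty of the isotropic gradient magnitude, with gradient.

    H_delta(img) = sum_p h_delta(g_p), g_p = |grad(img)_p|_2, with
    h_delta(g) = g^2/(2 delta) for g <= delta and g - delta/2 beyond; for
    delta -> 0 this approaches the isotropic TV seminorm.  The gradient
    follows by the chain rule: D'(w . D img) with per-pixel weight
    w = min(1/delta, 1/g).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    g = grad(img)
    m = grad_magnitude(g)
    quad = m <= delta
    value = float(np.where(quad, m * m / (2.0 * delta), m - delta / 2.0).sum())
    w = np.where(quad, 1.0 / delta, 1.0 / np.where(quad, 1.0, m))
    grad_img = -div(w[None, :, :] * g)
    return value, grad_img


def _renormalize(lam: np.ndarray, Ntotal: float, ops) -> np.ndarray:
    """Enforce 1'lam = Ntotal exactly; an all-zero activity (which the EM
    step produces for all-zero counts) restarts uniform."""
    s = lam.sum()
    if s > 0:
        return lam * (Ntotal / s)
    return np.full_like(lam, Ntotal / ops.n_pix)


def _em_factors(state: MLAAState, C: np.ndarray, ops):
    """Shared pieces of the activity EM step; returns (a, numerator image,
    sensitivity image)."""
    a = np.exp(-ops.forward_x(state.mu))
    t_lam = ops.forward_tof(state.lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(t_lam > 0, C / np.where(t_lam > 0, t_lam, 1.0), 0.0)
    num = ops.back_tof(ratio)
    sens = ops.back_tof(np.broadcast_to(a, C.shape))
    return a, num, sens


def _mu_step_terms(lam: np.ndarray, a: np.ndarray, C: np.ndarray, ops):
    """Numerator/denominator images of the transmission-type mu update."""
    s = ops.forward_tof(lam).sum(axis=0)  # per-LOR activity TOF sum
    C_per_lor = C.sum(axis=0)
    chord = ops.P @ np.ones(ops.n_pix)  # per-LOR total intersection length
    num = ops.back_x(a * s - C_per_lor)
    den = ops.back_x(chord * a * s)
    return num, den


def em_activity_step(state: MLAAState, C: np.ndarray, ops) -> np.ndarray:
    """The multiplicative EM activity update alone (no renormalisation).

    Monotonically non-increases the Poisson negative log-likelihood at
    fixed attenuation — the classical EM descent property.
    """
    _, num, sens = _em_factors(state, C, ops)
    return state.lam * np.where(sens > 0, num / np.where(sens > 0, sens, 1.0), 1.0)


def mlaa_iterate(state: MLAAState, C: np.ndarray, Ntotal: float, ops) -> MLAAState:
    """One full MLAA sweep: EM activity update, count renormalisation,
    transmission attenuation step, nonnegativity projection."""
    a, num, sens = _em_factors(state, C, ops)
    lam = state.lam * np.where(sens > 0, num / np.where(sens > 0, sens, 1.0), 1.0)
    lam = _renormalize(lam, Ntotal, ops)
    mu_num, mu_den = _mu_step_terms(lam, a, C, ops)
    mu = state.mu + np.where(mu_den > 0, mu_num / np.where(mu_den > 0, mu_den, 1.0), 0.0)
    return MLAAState(lam=lam, mu=pos(mu))


def pmlaa_iterate(
    state: MLAAState,
    C: np.ndarray,
    Ntotal: float,
    params: PMLAAParams,
    ops,
) -> MLAAState:
    """One P-MLAA sweep (one-step-late activity step, penalized mu step).

    Reduces to :func:`mlaa_iterate` exactly when beta = gamma = 0.
    """
    a, num, sens = _em_factors(state, C, ops)
    _, hgrad_lam = huber_value_and_grad(state.lam, params.delta_lam)
    den = sens + params.beta * hgrad_lam
    bad = den <= 0
    if np.any(bad & (sens > 0)):
        n_bad = int(np.count_nonzero(bad & (sens > 0)))
        logger.warning("OSL fallback to unpenalized update at %d pixels", n_bad)
        den = np.where(bad, sens, den)
    lam = state.lam * np.where(sens > 0, num / np.where(den > 0, den, 1.0), 1.0)
    lam = _renormalize(lam, Ntotal, ops)
    mu_num, mu_den = _mu_step_terms(lam, a, C, ops)
    _, hgrad_mu = huber_value_and_grad(state.mu, params.delta_mu)
    mu_num = mu_num - params.gamma * hgrad_mu
    mu_den = mu_den + params.gamma / params.delta_mu
    mu = state.mu + np.where(mu_den > 0, mu_num / np.where(mu_den > 0, mu_den, 1.0), 0.0)
    return MLAAState(lam=lam, mu=pos(mu))


def tune_pmlaa_penalties(
    C: np.ndarray,
    Ntotal: float,
    ops,
    target_tv_lam: float,
    target_tv_mu: float,
    n_iter: int,
    delta_lam: float,
    delta_mu: float,
    n_bisect: int = 12,
    n_sweeps: int = 2,
    log_bracket_beta: tuple[float, float] = (-8.0, 2.0),
    log_bracket_gamma: tuple[float, float] = (-8.0, 6.0),
) -> PMLAAParams:
    """Search penalty weights so the images reach target TV values.

    Coordinate-wise bisection on log10(beta) and log10(gamma), exploiting
    that image TV after a fixed number of iterations decreases
    monotonically in its penalty weight; the targets are matched in the
    sense of the TV of the n_iter-th iterate.  The brackets should stay
    below the weights where OSL fallbacks dominate (there the TV response
    stops being monotone); the defaults suit data normalised by
    size(C)/||C||_2.
    """
    from .tv import tv_seminorm

    def run(beta: float, gamma: float):
        params = PMLAAParams(beta, gamma, delta_lam, delta_mu)
        st = mlaa_init(ops, Ntotal)
        for _ in range(n_iter):
            st = pmlaa_iterate(st, C, Ntotal, params, ops)
        return tv_seminorm(st.lam), tv_seminorm(st.mu)

    log_beta = sum(log_bracket_beta) / 2.0
    log_gamma = sum(log_bracket_gamma) / 2.0
    for _ in range(n_sweeps):
        lo, hi = log_bracket_beta
        for _ in range(n_bisect):
            log_beta = (lo + hi) / 2.0
            tv_l, _ = run(10.0**log_beta, 10.0**log_gamma)
            if tv_l > target_tv_lam:
                lo = log_beta  # too little smoothing -> raise beta
            else:
                hi = log_beta
        lo, hi = log_bracket_gamma
        for _ in range(n_bisect):
            log_gamma = (lo + hi) / 2.0
            _, tv_m = run(10.0**log_beta, 10.0**log_gamma)
            if tv_m > target_tv_mu:
                lo = log_gamma
            else:
                hi = log_gamma
    return PMLAAParams(10.0**log_beta, 10.0**log_gamma, delta_lam, delta_mu)
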