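"""TOF-PET forward model: mean data, Poisson sampling, likelihood, scaling.

The mean coincidence data follow

    c_il = exp(-P_l' mu) * (T_il' lam),

i.e. the TOF projection of the activity attenuated by the survival factor
of LOR l.  Scatter and random coincidences are not modelled.  Measured
counts are independent Poisson draws per (window, LOR) bin.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .admm import AlgoParams

__all__ = [
    "attenuation_factors",
    "mean_data",
    "sample_counts",
    "normalize_counts",
    "neg_log_likelihood",
    "apply_data_scaling",
]


def attenuation_factors(mu: np.ndarray, ops) -> np.ndarray:
    """Per-LOR survival factors a_l = exp(-P_l' mu), in (0, 1] for mu >= 0."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("attenuation must be nonnegative (project first)")
    return np.exp(-ops.forward_x(mu))


def mean_data(lam: np.ndarray, mu: np.ndarray, ops) -> np.ndarray:
    """Mean TOF coincidence data c_il, shape (n_windows, n_lor)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("activity must be nonnegative")
    a = attenuation_factors(mu, ops)
    return a[None, :] * ops.forward_tof(lam)


def sample_counts(c: np.ndarray, total_counts: float, seed: int) -> np.ndarray:
    """Poisson realisation with the mean data rescaled to a target total.

    The mean data are scaled so their sum equals ``total_counts``, then each
    (window, LOR) bin is drawn independently from a Poisson distribution.
    Reproducible given ``seed``.
    """
    c = np.asarray(c, dtype=float)
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    tot = c.sum()
    if not tot > 0:
        raise ValueError("mean data must have positive total")
    rng = np.random.default_rng(seed)
    return rng.poisson(c * (total_counts / tot)).astype(float)


def normalize_counts(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale count data by size(C)/||C||_2; returns (scaled data, factor).

    The factor makes the tuned step-size ratios independent of the raw
    count scale (e.g. scan duration); the companion parameter/variable
    transformation is :func:`apply_data_scaling`.
    """
    C = np.asarray(C, dtype=float)
    nrm = np.linalg.norm(C)
    if nrm == 0:
        raise ValueError("cannot normalize all-zero data")
    a = C.size / nrm
    return C * a, a


def neg_log_likelihood(lam: np.ndarray, mu: np.ndarray, C: np.ndarray, ops) -> float:
    """Poisson negative log-likelihood sum_il [c_il - C_il log c_il].

    Conventions: 0 * log 0 = 0; returns +inf if any bin has C > 0 where the
    model mean is 0.
    """
    c = mean_data(lam, mu, ops)
    return neg_log_likelihood_from_mean(c, C)


def neg_log_likelihood_from_mean(c: np.ndarray, C: np.ndarray) -> float:
    """Likelihood evaluated directly from precomputed mean data."""
    C = np.asarray(C, dtype=float)
    if c.shape != C.shape:
        raise ValueError(f"shape mismatch: mean {c.shape} vs counts {C.shape}")
    support = C > 0
    if np.any(support & (c <= 0)):
        return np.inf
    val = c.sum() - np.sum(C[support] * np.log(c[support]))
    return float(val)


def apply_data_scaling(params: AlgoParams, a: float) -> AlgoParams:
    """Parameter transformation matching a count rescaling C -> a C.

    Ntotal -> a Ntotal, gamma_lam -> a gamma_lam, sigma_lam -> sigma_lam/a,
    tau_lam -> a tau_lam, sigma_mu -> a sigma_mu, tau_mu -> tau_mu/a; the
    attenuation-side budget gamma_mu is unchanged (mu does not rescale).
    Under this transformation the iterates transform as lam -> a lam,
    y_lam -> a y_lam, u_lam -> u_lam, mu -> mu, y_mu -> y_mu, u_mu -> a u_mu.
    """
    if a <= 0:
        raise ValueError("scale factor must be positive")
    st = params.steps
    steps = replace(
        st,
        sigma_lam=st.sigma_lam / a,
        tau_lam=st.tau_lam * a,
        sigma_mu=st.sigma_mu * a,
        tau_mu=st.tau_mu / a,
    )
    gamma_lam = params.gamma_lam * a if np.isfinite(params.gamma_lam) else params.gamma_lam
    return replace(params, steps=steps, Ntotal=params.Ntotal * a, gamma_lam=gamma_lam)
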