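"""Parallel-beam X-ray and TOF projection operators for 2D TOF-PET.

The scanner is modelled as a 2D parallel-beam arrangement of lines of
response (LORs): ``n_views`` view angles covering a pi-radian arc, each with
``n_rays`` parallel rays.  The X-ray projector ``P`` maps an image to its
line integrals (entries are exact ray/pixel intersection lengths, traced
Siddon-style).  The TOF projector ``T`` additionally weights each pixel's
contribution by a Gaussian time-of-flight window profile

    w_i(t) = exp[-(t - t_i)^2 / (2 sigma_TOF^2)],

where ``t`` is the signed position of the pixel centre along the LOR,
measured from the LOR's closest approach to the field-of-view centre, and
the window centres ``t_i`` are spaced by half the spatial FWHM of the
profile.  Both operators are materialised as sparse matrices, so adjoints
are exact transposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator

__all__ = [
    "SPEED_OF_LIGHT_CM_PER_NS",
    "FWHM_PER_SIGMA",
    "ScanGeometry",
    "TOFModel",
    "SystemOperators",
    "build_xray_projector",
    "build_tof_projector",
    "build_system_operators",
    "tof_window_weight",
    "operator_norm",
]

SPEED_OF_LIGHT_CM_PER_NS = 29.9792458
#: FWHM of a Gaussian in units of its standard deviation, 2*sqrt(2 ln 2).
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ScanGeometry:
    """2D parallel-beam scan layout on a square image grid.

    Parameters
    ----------
    grid_n : int
        Pixels per image side.
    fov_cm : float
        Field-of-view width in cm; pixel size is ``fov_cm / grid_n``.
    n_views : int
        Number of view angles, laid out at ``k * pi / n_views``.
    n_rays : int
        Rays per view, symmetric about the FOV centre with pitch
        ``fov_cm / n_rays``.
    """

    grid_n: int
    fov_cm: float
    n_views: int
    n_rays: int

    def __post_init__(self) -> None:
        if self.grid_n < 1:
            raise ValueError("grid_n must be positive")
        if self.fov_cm <= 0:
            raise ValueError("fov_cm must be positive")
        if self.n_views < 1 or self.n_rays < 1:
            raise ValueError("n_views and n_rays must be positive")

    @property
    def pixel_size_cm(self) -> float:
        return self.fov_cm / self.grid_n

    @property
    def ray_spacing_cm(self) -> float:
        return self.fov_cm / self.n_rays

    @property
    def view_angles(self) -> np.ndarray:
        """Strictly increasing angles in [0, pi)."""
        return np.arange(self.n_views) * np.pi / self.n_views

    @property
    def ray_offsets_cm(self) -> np.ndarray:
        """Signed ray offsets from the FOV centre, symmetric about 0."""
        return (np.arange(self.n_rays) + 0.5 - 0.5 * self.n_rays) * self.ray_spacing_cm

    @property
    def n_lor(self) -> int:
        return self.n_views * self.n_rays

    @property
    def n_pix(self) -> int:
        return self.grid_n * self.grid_n


@dataclass(frozen=True)
class TOFModel:
    """Gaussian TOF window model along each LOR.

    ``sigma_cm`` is the standard deviation of the Gaussian window profile,
    related to the spatial resolution by ``fwhm_cm = 2 sqrt(2 ln 2) sigma``.
    Window centres are spaced by ``fwhm_cm / 2`` and are symmetric about the
    closest approach of the LOR to the FOV centre.
    """

    fwhm_cm: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.fwhm_cm <= 0:
            raise ValueError("fwhm_cm must be positive")
        if self.n_windows < 1 or self.n_windows % 2 == 0:
            raise ValueError("n_windows must be a positive odd count")

    @property
    def sigma_cm(self) -> float:
        return self.fwhm_cm / FWHM_PER_SIGMA

    @property
    def delta_t_cm(self) -> float:
        """Window-centre spacing, half the spatial FWHM."""
        return self.fwhm_cm / 2.0

    @property
    def centers_cm(self) -> np.ndarray:
        half_span = (self.n_windows - 1) / 2.0
        return (np.arange(self.n_windows) - half_span) * self.delta_t_cm

    def timing_resolution_ps(self) -> float:
        """Coincidence timing resolution equivalent to the spatial FWHM.

        A timing difference dt localises the annihilation within
        dx = c dt / 2, so dt = 2 dx / c.
        """
        return 1e3 * 2.0 * self.fwhm_cm / SPEED_OF_LIGHT_CM_PER_NS

    def window_weight(self, t, i: int) -> np.ndarray:
        """Gaussian sensitivity of window ``i`` at along-LOR position ``t``."""
        if not 0 <= i < self.n_windows:
            raise IndexError(f"window index {i} out of range")
        t = np.asarray(t, dtype=float)
        return np.exp(-((t - self.centers_cm[i]) ** 2) / (2.0 * self.sigma_cm**2))

    def window_weight_sum(self, t) -> np.ndarray:
        """Sum of all window weights at position ``t`` (approximately
        constant, ~2.13, for the FWHM/2 spacing)."""
        t = np.asarray(t, dtype=float)[..., None]
        return np.exp(
            -((t - self.centers_cm) ** 2) / (2.0 * self.sigma_cm**2)
        ).sum(axis=-1)


def tof_window_weight(t, i: int, tof: TOFModel) -> np.ndarray:
    """Gaussian TOF window weight w_i(t); 1.0 at the window centre."""
    return tof.window_weight(t, i)


def _trace_ray(px, py, ux, uy, lines, half, h, n):
    """Exact intersection lengths of one ray with the pixel grid.

    The ray is x(s) = (px, py) + s (ux, uy) with |u| = 1.  Returns flat
    pixel indices (row-major, y-major) and lengths in cm.
    """
    ts = []
    s_min, s_max = -np.inf, np.inf
    for p, u in ((px, ux), (py, uy)):
        if abs(u) > 1e-12:
            ts.append((lines - p) / u)
            lo, hi = (-half - p) / u, (half - p) / u
            if lo > hi:
                lo, hi = hi, lo
            s_min, s_max = max(s_min, lo), min(s_max, hi)
        elif not (-half <= p <= half):
            return np.empty(0, dtype=np.int64), np.empty(0)
    s = np.unique(np.concatenate(ts))
    s = s[(s >= s_min - 1e-12) & (s <= s_max + 1e-12)]
    if s.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    mids = 0.5 * (s[1:] + s[:-1])
    lens = np.diff(s)
    x = px + mids * ux
    y = py + mids * uy
    ix = np.floor((x + half) / h).astype(np.int64)
    iy = np.floor((y + half) / h).astype(np.int64)
    ok = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n) & (lens > 1e-12)
    return (iy[ok] * n + ix[ok]), lens[ok]


def build_xray_projector(geom: ScanGeometry) -> sp.csr_matrix:
    """Sparse X-ray projection matrix P of shape (n_lor, n_pix).

    Entry (l, k) is the intersection length in cm of LOR l with pixel k, so
    ``P @ mu.ravel()`` approximates the attenuation line integrals.
    LOR index l = view * n_rays + ray; pixel index k = iy * grid_n + ix.
    """
    n, fov = geom.grid_n, geom.fov_cm
    half, h = fov / 2.0, geom.pixel_size_cm
    lines = -half + h * np.arange(n + 1)
    rows, cols, vals = [], [], []
    offsets = geom.ray_offsets_cm
    for iv, theta in enumerate(geom.view_angles):
        ct, st = np.cos(theta), np.sin(theta)
        for ir, s_off in enumerate(offsets):
            k, lens = _trace_ray(s_off * ct, s_off * st, -st, ct, lines, half, h, n)
            if k.size:
                rows.append(np.full(k.size, iv * geom.n_rays + ir, dtype=np.int64))
                cols.append(k)
                vals.append(lens)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:  # pragma: no cover - degenerate geometry
        rows = cols = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    P = sp.csr_matrix((vals, (rows, cols)), shape=(geom.n_lor, geom.n_pix))
    P.sum_duplicates()
    return P


def lor_pixel_positions(geom: ScanGeometry, P: sp.coo_matrix) -> np.ndarray:
    """Signed along-LOR coordinate of each nonzero entry's pixel centre.

    The origin is the closest approach of the LOR to the FOV centre; for a
    pixel centre q and view direction u the coordinate is t = q . u.
    """
    n = geom.grid_n
    half, h = geom.fov_cm / 2.0, geom.pixel_size_cm
    ix = P.col % n
    iy = P.col // n
    xc = -half + (ix + 0.5) * h
    yc = -half + (iy + 0.5) * h
    theta = geom.view_angles[P.row // geom.n_rays]
    return -np.sin(theta) * xc + np.cos(theta) * yc


def build_tof_projector(
    geom: ScanGeometry,
    tof: TOFModel,
    P: sp.csr_matrix | None = None,
    weight_cutoff: float = 0.0,
) -> sp.csr_matrix:
    """Sparse TOF projection matrix T of shape (n_windows * n_lor, n_pix).

    Row i * n_lor + l holds the X-ray entries of LOR l scaled by the TOF
    window weight w_i(t) at each pixel's along-LOR coordinate, so that
    T_{ilk} = w_i(t_kl) P_lk.  ``weight_cutoff`` optionally drops entries
    whose weight falls below the cutoff (memory saving at large scale; the
    default keeps every entry so sum-over-windows identities are exact).
    """
    if P is None:
        P = build_xray_projector(geom)
    coo = P.tocoo()
    t = lor_pixel_positions(geom, coo)
    inv_two_sigma2 = 1.0 / (2.0 * tof.sigma_cm**2)
    rows, cols, vals = [], [], []
    for i, ti in enumerate(tof.centers_cm):
        w = np.exp(-((t - ti) ** 2) * inv_two_sigma2)
        if weight_cutoff > 0.0:
            keep = w > weight_cutoff
            rows.append(coo.row[keep] + i * geom.n_lor)
            cols.append(coo.col[keep])
            vals.append(coo.data[keep] * w[keep])
        else:
            rows.append(coo.row + i * geom.n_lor)
            cols.append(coo.col)
            vals.append(coo.data * w)
    T = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(tof.n_windows * geom.n_lor, geom.n_pix),
    )
    return T


def operator_norm(op, n_iter: int = 200, seed: int = 0) -> float:
    """Largest singular value of a linear map by seeded power iteration.

    ``op`` may be a scipy sparse matrix or a LinearOperator with a working
    adjoint.  Deterministic given ``seed``; returns 0.0 for the zero map.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    if isinstance(op, LinearOperator):
        matvec, rmatvec = op.matvec, op.rmatvec
    else:
        opT = op.T.tocsr() if sp.issparse(op) else op.T
        matvec = lambda x: op @ x  # noqa: E731
        rmatvec = lambda y: opT @ y  # noqa: E731
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(op.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        z = rmatvec(matvec(v))
        nz = np.linalg.norm(z)
        if nz == 0.0:
            return 0.0
        v = z / nz
    return float(np.linalg.norm(matvec(v)))


@dataclass
class SystemOperators:
    """The X-ray projector P, TOF projector T, and their spectral norms.

    Wraps the sparse matrices with image-shaped apply/adjoint helpers and an
    operator-product counter used to verify the per-iteration product budget
    of the reconstruction algorithms.
    """

    P: sp.csr_matrix
    T: sp.csr_matrix
    norm_P: float
    norm_T: float
    geom: ScanGeometry | None = None
    tof: TOFModel | None = None
    img_shape: tuple[int, int] | None = None
    counts: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.img_shape is None:
            if self.geom is not None:
                self.img_shape = (self.geom.grid_n, self.geom.grid_n)
            else:
                side = int(round(np.sqrt(self.P.shape[1])))
                self.img_shape = (side, self.P.shape[1] // side)
        # Pre-transposed CSR copies make adjoint products as fast as forward.
        self._PT = self.P.T.tocsr()
        self._TT = self.T.T.tocsr()
        self.reset_counts()

    @property
    def n_pix(self) -> int:
        return self.P.shape[1]

    @property
    def n_lor(self) -> int:
        return self.P.shape[0]

    @property
    def n_windows(self) -> int:
        return self.T.shape[0] // self.n_lor

    def reset_counts(self) -> None:
        self.counts = {"P": 0, "PT": 0, "T": 0, "TT": 0}

    @property
    def total_products(self) -> int:
        return sum(self.counts.values())

    def forward_x(self, img: np.ndarray) -> np.ndarray:
        """Line integrals P @ img, shape (n_lor,)."""
        self.counts["P"] += 1
        return self.P @ np.asarray(img).ravel()

    def back_x(self, sino: np.ndarray) -> np.ndarray:
        """Adjoint P^T @ sino as an image."""
        self.counts["PT"] += 1
        return (self._PT @ np.asarray(sino).ravel()).reshape(self.img_shape)

    def forward_tof(self, img: np.ndarray) -> np.ndarray:
        """TOF projection T @ img, shape (n_windows, n_lor)."""
        self.counts["T"] += 1
        return (self.T @ np.asarray(img).ravel()).reshape(self.n_windows, self.n_lor)

    def back_tof(self, tof_sino: np.ndarray) -> np.ndarray:
        """Adjoint T^T @ tof_sino as an image."""
        self.counts["TT"] += 1
        return (self._TT @ np.asarray(tof_sino).ravel()).reshape(self.img_shape)


def build_system_operators(
    geom: ScanGeometry,
    tof: TOFModel,
    n_norm_iter: int = 200,
    seed: int = 0,
    weight_cutoff: float = 0.0,
    cache_dir=None,
) -> SystemOperators:
    """Build P and T for a geometry/TOF pair and estimate their norms.

    With ``cache_dir`` set, operators are loaded from / saved to an npz
    cache keyed by a hash of the configuration.
    """
    if cache_dir is not None:
        from .io import load_operators, save_operators

        cached = load_operators(geom, tof, cache_dir)
        if cached is not None:
            return cached
    P = build_xray_projector(geom)
    T = build_tof_projector(geom, tof, P=P, weight_cutoff=weight_cutoff)
    ops = SystemOperators(
        P=P,
        T=T,
        norm_P=operator_norm(P, n_iter=n_norm_iter, seed=seed),
        norm_T=operator_norm(T, n_iter=n_norm_iter, seed=seed),
        geom=geom,
        tof=tof,
    )
    if cache_dir is not None:
        save_operators(ops, cache_dir)
    return ops
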