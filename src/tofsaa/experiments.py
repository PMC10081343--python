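"""Study orchestration: noiseless runs, noisy ensembles, metric tracking.

A study is fully specified by a :class:`StudyConfig` (geometry, TOF model,
phantom options, algorithm and its parameters, seeds).  Pipelines are
deterministic given the config: phantom -> operators -> mean data ->
(optional Poisson sampling) -> reconstruction -> metrics.

Count data are normalised by size(C)/||C||_2 before reconstruction, and
the constraint/step-size parameters are expressed in the normalised scale
via the exact scaling relations of ``forward.apply_data_scaling``;
reported images are mapped back to the phantom scale, so every metric is
directly comparable with the ground-truth images.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import admm as _admm
from . import forward as _fwd
from . import mlaa as _mlaa
from . import tv as _tv
from .metrics import EnsembleResult, data_rmse, normalized_rmse
from .phantom import PhantomSpec, make_phantom
from .projectors import ScanGeometry, TOFModel, build_system_operators

__all__ = [
    "StudyConfig",
    "Problem",
    "RunResult",
    "build_problem",
    "reconstruct",
    "run_noiseless_study",
    "run_noisy_ensemble",
]

ALGOS = ("mlaa", "pmlaa", "admm-saa", "admm-tvsaa")


@dataclass(frozen=True)
class StudyConfig:
    """One fully reproducible study specification.

    The default scale (64x64 grid, 64 views/rays, 9 TOF windows, 2000
    iterations) is the package's desk-scale configuration; it preserves
    the reference ratios rays = grid_n and window spacing = FWHM/2 on a
    30 cm FOV.  ``full_scale`` returns the full 176/176/17 configuration.

    The step-size ratio defaults are the result of the tuning step the
    method requires whenever the system operators change (here: for the
    desk-scale operators, on normalised data); see docs/methods.md.
    """

    grid_n: int = 64
    fov_cm: float = 30.0
    n_views: int = 64
    n_rays: int = 64
    tof_fwhm_cm: float = 4.5
    n_windows: int = 9
    algo: str = "admm-tvsaa"
    n_iter: int = 2000
    checkpoints: tuple[int, ...] = (50, 100, 200, 500, 2000)
    rho_lam: float = 0.003
    rho_mu: float = 30.0
    gamma_lam_frac: float = 1.0
    gamma_mu_frac: float = 1.0
    n_y: int = 100
    n_newton: int = 10
    beta: float = 0.0
    gamma_w: float = 0.0
    huber_delta_frac: float = 1e-3
    total_counts: float = 4e6
    n_realizations: int = 100
    seed: int = 0
    truncation_radius_cm: float | None = None
    metrics_every: int = 1

    def __post_init__(self) -> None:
        if self.algo not in ALGOS:
            raise ValueError(f"algo must be one of {ALGOS}")

    @classmethod
    def full_scale(cls, **overrides) -> "StudyConfig":
        base = dict(
            grid_n=176, n_views=176, n_rays=176, n_windows=17, n_iter=5000,
            checkpoints=(50, 100, 200, 500, 2000, 5000),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def ensemble_scale(cls, **overrides) -> "StudyConfig":
        """Reduced configuration for noisy-ensemble studies: 32x32 grid,
        500 iterations, 10 Poisson realizations at the reference 4e6 total
        counts."""
        base = dict(
            grid_n=32, n_views=32, n_rays=32, n_windows=7, n_iter=500,
            checkpoints=(100, 200, 500), n_realizations=10, metrics_every=0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "checkpoints" in d:
            d["checkpoints"] = tuple(d["checkpoints"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["checkpoints"] = list(self.checkpoints)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class Problem:
    """Phantom, operators and mean data realised from a config."""

    cfg: StudyConfig
    act: np.ndarray
    att: np.ndarray
    ops: object
    c: np.ndarray  # noiseless mean data, phantom activity scale
    Ntotal: float
    tv_act: float
    tv_att: float


def build_problem(cfg: StudyConfig, ops=None) -> Problem:
    """Realise the phantom, system operators and mean data for a config."""
    spec = PhantomSpec(
        grid_n=cfg.grid_n,
        fov_cm=cfg.fov_cm,
        truncation_radius_cm=cfg.truncation_radius_cm,
    )
    act, att = make_phantom(spec)
    if ops is None:
        geom = ScanGeometry(cfg.grid_n, cfg.fov_cm, cfg.n_views, cfg.n_rays)
        tof = TOFModel(cfg.tof_fwhm_cm, cfg.n_windows)
        ops = build_system_operators(geom, tof, seed=cfg.seed)
    c = _fwd.mean_data(act, att, ops)
    return Problem(
        cfg=cfg,
        act=act,
        att=att,
        ops=ops,
        c=c,
        Ntotal=float(act.sum()),
        tv_act=_tv.tv_seminorm(act),
        tv_att=_tv.tv_seminorm(att),
    )


@dataclass
class RunResult:
    """Reconstruction output: checkpoint images (phantom scale) and the
    per-iteration metrics table."""

    algo: str
    images: dict = field(default_factory=dict)  # iter -> (act, att)
    metrics: list = field(default_factory=list)  # list of row dicts
    final_act: np.ndarray | None = None
    final_att: np.ndarray | None = None

    def metric_series(self, key: str) -> np.ndarray:
        return np.array([row[key] for row in self.metrics])


def reconstruct(
    problem: Problem,
    C: np.ndarray,
    cfg: StudyConfig | None = None,
    algo: str | None = None,
    n_iter: int | None = None,
    lam_scale: float = 1.0,
    checkpoints: tuple[int, ...] = (),
    metrics_every: int | None = None,
) -> RunResult:
    """Run one reconstruction on count data C (phantom scale x lam_scale).

    ``cfg`` defaults to the problem's own config; a different config may be
    passed to reuse one problem (phantom/operators/mean data) across
    algorithm variants.  ``lam_scale`` is the factor relating the data to
    the phantom activity (1 for noiseless mean data; total_counts / sum(c)
    for Poisson data), used to report images and Ntotal consistently.
    Metric rows are appended every ``metrics_every`` iterations (0 disables
    tracking).
    """
    cfg = cfg or problem.cfg
    ops = problem.ops
    algo = algo or cfg.algo
    n_iter = n_iter or cfg.n_iter
    metrics_every = cfg.metrics_every if metrics_every is None else metrics_every
    Cn, a = _fwd.normalize_counts(C)
    img_scale = a * lam_scale  # phantom units -> reconstruction units
    Ntot = problem.Ntotal * img_scale
    result = RunResult(algo=algo)

    if algo in ("admm-saa", "admm-tvsaa"):
        if algo == "admm-tvsaa":
            steps = _tv.make_tvsaa_step_sizes(cfg.rho_lam, cfg.rho_mu, ops, seed=cfg.seed)
            gamma_lam = cfg.gamma_lam_frac * problem.tv_act * img_scale
            gamma_mu = cfg.gamma_mu_frac * problem.tv_att
        else:
            steps = _admm.make_step_sizes(cfg.rho_lam, cfg.rho_mu, ops.norm_T, ops.norm_P)
            gamma_lam = gamma_mu = np.inf
        params = _admm.AlgoParams(
            steps=steps,
            Ntotal=Ntot,
            gamma_lam=gamma_lam,
            gamma_mu=gamma_mu,
            loops=_admm.LoopParams(cfg.n_y, cfg.n_newton),
        )
        state = _tv.tvsaa_init(ops) if algo == "admm-tvsaa" else _admm.saa_init(ops)
        step_fn = _tv.admm_tvsaa_iterate if algo == "admm-tvsaa" else _admm.admm_saa_iterate
        for it in range(1, n_iter + 1):
            state = step_fn(state, Cn, params, ops)
            lam_p = state.lam / img_scale
            mu_p = state.mu
            if metrics_every and (it % metrics_every == 0 or it == n_iter):
                c_est = np.exp(-state.p_mu)[None, :] * state.t_lam
                row = _metric_row(it, lam_p, mu_p, c_est, Cn, problem)
                if algo == "admm-tvsaa":
                    row["tv_z_lam"] = float(
                        _tv.grad_magnitude(state.z_lam).sum() / img_scale
                    )
                    row["tv_z_mu"] = float(_tv.grad_magnitude(state.z_mu).sum())
                result.metrics.append(row)
            if it in checkpoints:
                result.images[it] = (lam_p.copy(), mu_p.copy())
    elif algo in ("mlaa", "pmlaa"):
        state = _mlaa.mlaa_init(ops, Ntot)
        if algo == "pmlaa":
            pparams = _mlaa.PMLAAParams.from_fractions(
                cfg.beta,
                cfg.gamma_w,
                lam_max=float(problem.act.max()) * img_scale,
                mu_max=float(problem.att.max()),
                delta_frac=cfg.huber_delta_frac,
            )
        for it in range(1, n_iter + 1):
            if algo == "pmlaa":
                state = _mlaa.pmlaa_iterate(state, Cn, Ntot, pparams, ops)
            else:
                state = _mlaa.mlaa_iterate(state, Cn, Ntot, ops)
            lam_p = state.lam / img_scale
            mu_p = state.mu
            if metrics_every and (it % metrics_every == 0 or it == n_iter):
                c_est = _fwd.mean_data(state.lam, state.mu, ops)
                result.metrics.append(
                    _metric_row(it, lam_p, mu_p, c_est, Cn, problem)
                )
            if it in checkpoints:
                result.images[it] = (lam_p.copy(), mu_p.copy())
    else:  # pragma: no cover
        raise ValueError(f"unknown algorithm {algo!r}")

    result.final_act = lam_p
    result.final_att = mu_p
    return result


def _metric_row(it, lam_p, mu_p, c_est, Cn, problem: Problem) -> dict:
    return {
        "iter": it,
        "nll": _fwd.neg_log_likelihood_from_mean(c_est, Cn),
        "rmse_act": normalized_rmse(lam_p, problem.act),
        "rmse_att": normalized_rmse(mu_p, problem.att),
        "rmse_data": data_rmse(c_est, Cn),
        "tv_lam": _tv.tv_seminorm(lam_p),
        "tv_mu": _tv.tv_seminorm(mu_p),
    }


def run_noiseless_study(
    cfg: StudyConfig, out_dir=None, problem: Problem | None = None
) -> dict:
    """Reconstruction from noiseless mean data, with full metric tracking.

    Returns a report dict with the problem, the run result and final
    metrics; optionally writes metrics.csv, summary.json and images.npz.
    """
    problem = problem or build_problem(cfg)
    run = reconstruct(
        problem, problem.c, cfg=cfg, checkpoints=tuple(cfg.checkpoints),
        lam_scale=1.0,
    )
    final = run.metrics[-1] if run.metrics else {}
    report = {
        "config": asdict(cfg),
        "problem": problem,
        "run": run,
        "final": {k: final.get(k) for k in
                  ("iter", "rmse_act", "rmse_att", "rmse_data", "tv_lam", "tv_mu")},
        "tv_truth": {"activity": problem.tv_act, "attenuation": problem.tv_att},
    }
    if out_dir is not None:
        _write_study_outputs(Path(out_dir), cfg, problem, run, report["final"])
    return report


def run_noisy_ensemble(
    cfg: StudyConfig, out_dir=None, problem: Problem | None = None
) -> EnsembleResult:
    """Reconstruct an ensemble of Poisson noise realizations.

    Realization r uses seed cfg.seed + r; images are stored at the
    configured checkpoints in phantom scale.
    """
    problem = problem or build_problem(cfg)
    checkpoints = tuple(it for it in cfg.checkpoints if it <= cfg.n_iter)
    res = EnsembleResult(
        checkpoints=checkpoints,
        n_realizations=cfg.n_realizations,
        algo=cfg.algo,
    )
    stacks_act = {it: [] for it in checkpoints}
    stacks_att = {it: [] for it in checkpoints}
    lam_scale = cfg.total_counts / problem.c.sum()
    for r in range(cfg.n_realizations):
        C = _fwd.sample_counts(problem.c, cfg.total_counts, seed=cfg.seed + r)
        run = reconstruct(
            problem,
            C,
            cfg=cfg,
            lam_scale=lam_scale,
            checkpoints=checkpoints,
            metrics_every=0,
        )
        for it in checkpoints:
            act_img, att_img = run.images[it]
            stacks_act[it].append(act_img)
            stacks_att[it].append(att_img)
    for it in checkpoints:
        res.activity[it] = np.stack(stacks_act[it])
        res.attenuation[it] = np.stack(stacks_att[it])
    if out_dir is not None:
        _write_ensemble_outputs(Path(out_dir), cfg, problem, res)
    return res


def _write_study_outputs(out: Path, cfg, problem, run: RunResult, final: dict):
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    if run.metrics:
        keys = list(run.metrics[0].keys())
        with open(out / "metrics.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            w.writerows(run.metrics)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {"algo": run.algo, "final": final,
             "tv_truth": {"activity": problem.tv_act, "attenuation": problem.tv_att}},
            fh, indent=2)
    arrays = {"activity_truth": problem.act, "attenuation_truth": problem.att,
              "activity_final": run.final_act, "attenuation_final": run.final_att}
    for it, (a_img, m_img) in run.images.items():
        arrays[f"activity_{it:06d}"] = a_img
        arrays[f"attenuation_{it:06d}"] = m_img
    np.savez(out / "images.npz", **arrays)


def _write_ensemble_outputs(out: Path, cfg, problem, res: EnsembleResult):
    from .metrics import bias_std_curve

    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    rows = []
    for quantity, truth in (("activity", problem.act), ("attenuation", problem.att)):
        for it, (bias, std) in zip(
            res.checkpoints, bias_std_curve(res, truth, quantity)
        ):
            rows.append({"quantity": quantity, "iter": it, "bias": bias, "std": std})
    with open(out / "bias_std.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["quantity", "iter", "bias", "std"])
        w.writeheader()
        w.writerows(rows)
    arrays = {}
    for it in res.checkpoints:
        arrays[f"activity_mean_{it:06d}"] = res.mean_image("activity", it)
        arrays[f"activity_std_{it:06d}"] = res.std_image("activity", it)
        arrays[f"attenuation_mean_{it:06d}"] = res.mean_image("attenuation", it)
        arrays[f"attenuation_std_{it:06d}"] = res.std_image("attenuation", it)
    np.savez(out / "ensemble_images.npz", **arrays)
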