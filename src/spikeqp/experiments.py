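"""Config-driven task suite: each task wires a feature basis, an input
vector and a tuned network, runs seeded trials, and summarizes the spiking
solution against the non-spiking MAP oracle.

Tasks
-----
discrimination      one strong cause among N=100 strongly overlapping ones
mixture             strong cause plus a random non-negative background
approximation       an input outside the conic hull of the features
regularization      overcomplete basis, variants none / L1 / L2 / leak
variability         overcomplete shifted-cosine basis; irregular spiking
mistuning           variability network with perturbed connectivity
noise_robustness    variability network with injected white noise
shuffles            trial- and bin-shuffled surrogates of the variability task
network_comparison  tuned non-leaky vs leaky signal-tracking variant

Default parameters (number of neurons N=100, threshold 1, reset 0,
tau_s = 5 ms, dt = 0.01 ms, alpha = beta = 0, non-leaky) apply when a
field is omitted.  Default durations are desk-scale (tens of seconds);
longer runs are a config change away.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, objective
from .generative import FeatureBasis, Observation, make_cosine_features, make_random_features
from .network import (
    KernelSpec,
    NetworkParams,
    SimConfig,
    SpikeRaster,
    perturb_connectivity,
    simulate,
    stability_check,
)

__all__ = ["TaskSpec", "ExperimentResult", "run_task", "regularization_suite",
           "build_task_inputs", "TASK_NAMES"]

TASK_NAMES = (
    "discrimination",
    "mixture",
    "approximation",
    "regularization",
    "variability",
    "mistuning",
    "noise_robustness",
    "shuffles",
    "network_comparison",
)


@dataclass
class TaskSpec:
    """One task configuration; unset fields take the defaults above."""

    name: str = "discrimination"
    M: int | None = None  # input dimension; task-specific default
    N: int = 100
    basis_kind: str | None = None  # uniform01 | uniform_sym | cosine
    alpha: float = 0.0
    beta: float = 0.0
    theta: float = 1.0
    tau_m: float = np.inf  # s; np.inf = non-leaky
    kernel_kind: str = "exponential"
    tau_s: float = 5e-3
    delay: float = 0.0
    dt: float = 1e-5
    duration: float = 20.0
    n_trials: int = 1
    input_scale: float = 50.0
    stim_index: int = 9  # 0-based index of the stimulated feature ("10th")
    noise_var: float = 0.0
    perturb_interval: tuple[float, float] | None = None  # mistuning range
    background_high: float = 10.0  # mixture background amplitude bound
    T_grid: list[float] | None = None  # integration windows for error curves
    window_length: float = 0.1  # moving-window size (s) for time courses
    bin_width: float = 0.1  # bin-shuffle width (s)
    regularization: str = "none"  # none | L1 | L2 | leak
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in TASK_NAMES:
            raise ValueError(f"unknown task {self.name!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tau_m"] = None if np.isinf(self.tau_m) else self.tau_m
        return d


@dataclass
class ExperimentResult:
    spec: TaskSpec
    seed: int
    basis: FeatureBasis
    obs: Observation
    net: NetworkParams
    rasters: list[SpikeRaster]
    rates: np.ndarray  # full-window rates of trial 0
    r_map: np.ndarray | None
    curve: analysis.ErrorCurve | None
    summary: dict
    raster_paths: list[str] = field(default_factory=list)


def _apply_regularization(spec: TaskSpec) -> TaskSpec:
    variant = spec.regularization
    if variant == "L1":
        return dataclasses.replace(spec, alpha=10.0)
    if variant == "L2":
        return dataclasses.replace(spec, beta=0.5)
    if variant == "leak":
        return dataclasses.replace(spec, tau_m=50e-3)
    return spec


def build_task_inputs(spec: TaskSpec, seed: int) -> tuple[FeatureBasis, Observation]:
    """Construct the feature basis and input vector for one task."""
    rng = np.random.default_rng(seed)
    basis_seed = int(rng.integers(0, 2**31 - 1))
    kind = spec.basis_kind
    if kind is None:
        kind = {
            "regularization": "uniform_sym",
            "variability": "cosine",
            "mistuning": "cosine",
            "noise_robustness": "cosine",
            "shuffles": "cosine",
        }.get(spec.name, "uniform01")
    M = spec.M
    if M is None:
        M = {"uniform01": 100, "uniform_sym": 10, "cosine": 2}[kind]
    if kind == "uniform01":
        basis = make_random_features(M, spec.N, 0.0, 1.0, seed=basis_seed)
    elif kind == "uniform_sym":
        basis = make_random_features(M, spec.N, -0.5, 0.5, seed=basis_seed)
    elif kind == "cosine":
        basis = make_cosine_features(spec.N)
    else:
        raise ValueError(f"unknown basis kind {kind!r}")

    U = basis.U
    k = spec.stim_index
    if spec.name == "mixture":
        bg = rng.uniform(0.0, spec.background_high, size=spec.N)
        bg[k] = 0.0
        mu = spec.input_scale * U[:, k] + U @ bg
    elif spec.name == "approximation":
        mu = np.zeros(basis.M)
        mu[0] = 1000.0
    elif spec.name == "network_comparison":
        idx = spec.extra.get("mixture_indices", (9, 19, 29, 39))
        coef = spec.extra.get("mixture_coefficients", (50.0, 50.0, 5.0, 1.0))
        r_true = np.zeros(spec.N)
        for i, c in zip(idx, coef):
            r_true[i] = c
        mu = U @ r_true
    else:
        mu = spec.input_scale * U[:, k]
    return basis, Observation(mu=mu)


def _map_solution(basis: FeatureBasis, obs: Observation, alpha: float, beta: float
                  ) -> np.ndarray:
    qp = objective.build_qp(basis, obs, alpha, beta)
    if basis.N <= 20:
        return objective.solve_map_active_set(qp)
    tol = 1e-8 * max(1.0, float(np.abs(qp.g).max()))  # drive sets the scale
    return objective.solve_map_projected_gradient(qp, tol=tol)


def run_task(spec: TaskSpec, seed: int = 0, out_dir: str | Path | None = None
             ) -> ExperimentResult:
    """Run one configured task: build inputs, tune, simulate trials,
    compare the spiking solution to the MAP oracle, optionally write
    rasters / curves / summary to ``out_dir``."""
    spec = _apply_regularization(spec)
    basis, obs = build_task_inputs(spec, seed)
    kernel = KernelSpec(kind=spec.kernel_kind, tau_s=spec.tau_s, delay=spec.delay)
    from .network import tune_network

    net = tune_network(basis, obs, spec.alpha, spec.beta, spec.theta,
                       spec.tau_m, kernel)
    if spec.name == "network_comparison" and spec.extra.get("variant") == "signal_tracking":
        net = tune_network(basis, obs, spec.alpha, spec.beta, theta=0.5,
                           tau_m=spec.extra.get("leak_tau_m", 20e-3), kernel=kernel)
    allow_unstable = spec.extra.get("allow_unstable", spec.name == "mistuning")
    if spec.name == "mistuning":
        low, high = spec.perturb_interval or (-0.2, 0.0)
        net = perturb_connectivity(net, low, high, seed=seed + 7919)
    stab = stability_check(net)
    if stab["unstable"] and not allow_unstable:
        raise RuntimeError(
            "network is unstable (max symmetrized-J eigenvalue "
            f"{stab['max_eigenvalue']:.3g}); aborting"
        )

    rasters = []
    for trial in range(spec.n_trials):
        cfg = SimConfig(dt=spec.dt, duration=spec.duration,
                        seed=seed * 100_003 + trial, noise_var=spec.noise_var)
        rasters.append(simulate(net, cfg))

    rates = analysis.estimate_rates(rasters[0]).rates
    qp = objective.build_qp(basis, obs, spec.alpha, spec.beta)
    r_map = _map_solution(basis, obs, spec.alpha, spec.beta)
    mu_hat = analysis.reconstruct_input(basis, rates)

    T_grid = spec.T_grid
    if T_grid is None:
        T_grid = list(np.geomspace(0.1, spec.duration, 8))
    curve = analysis.error_vs_window(rasters, basis, obs.mu, T_grid,
                                     metric="percentage")

    summary: dict = {
        "task": spec.name,
        "seed": seed,
        "rates_final": rates.tolist(),
        "r_map": r_map.tolist(),
        "kkt_residual_rates": objective.kkt_residual(qp, rates),
        "percentage_error_final": analysis.percentage_error(obs.mu, mu_hat)
        if rates.sum() else None,
        "angular_error_final": analysis.angular_error(obs.mu, mu_hat)
        if rates.sum() else None,
        "map_percentage_error": analysis.percentage_error(
            obs.mu, analysis.reconstruct_input(basis, r_map))
        if r_map.sum() else None,
        "stability": {"max_eigenvalue": stab["max_eigenvalue"],
                      "unstable": stab["unstable"]},
        "n_trials": spec.n_trials,
        "error_curve": {
            "T": list(map(float, curve.windows)),
            "percentage_error": list(map(float, curve.errors)),
            "slope": curve.slope,
        },
    }
    if spec.name in ("variability", "mistuning", "noise_robustness", "shuffles"):
        stats = analysis.isi_statistics(rasters[0])
        summary["population_cv_isi"] = stats["population_cv"]
        summary["n_neurons_in_cv"] = stats["n_neurons_used"]
    if spec.name == "regularization":
        thr = spec.extra.get("sparsity_rate_threshold", 0.5)
        summary["sparsity_fraction_active"] = float(np.mean(rates > thr))
        summary["regularization"] = spec.regularization
    if spec.name == "shuffles" and spec.n_trials >= 2:
        sh = analysis.trial_shuffle(rasters, seed=seed + 13)
        t_grid = np.arange(0.0, min(2.0, spec.duration - spec.window_length),
                           spec.window_length)
        orig = analysis.error_time_course(rasters, basis, obs.mu,
                                          spec.window_length, t_grid)
        surr = analysis.error_time_course(sh, basis, obs.mu,
                                          spec.window_length, t_grid)
        binned = [analysis.bin_shuffle(r, spec.bin_width, seed=seed + 17)
                  for r in rasters]
        bcur = analysis.error_time_course(binned, basis, obs.mu,
                                          spec.window_length, t_grid)
        summary["shuffle_curves"] = {
            "t": t_grid.tolist(),
            "original": orig.errors.tolist(),
            "trial_shuffled": surr.errors.tolist(),
            "bin_shuffled": bcur.errors.tolist(),
        }

    result = ExperimentResult(
        spec=spec, seed=seed, basis=basis, obs=obs, net=net, rasters=rasters,
        rates=rates, r_map=r_map, curve=curve, summary=summary,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": res.spec.to_dict(), "seed": res.seed}
    for k, ras in enumerate(res.rasters):
        p = out_dir / f"raster_trial{k:03d}.csv"
        ras.to_csv(p, meta=meta)
        res.raster_paths.append(str(p))
    res.summary["raster_paths"] = res.raster_paths
    res.summary["config"] = res.spec.to_dict()
    curve = res.curve
    with open(out_dir / "error_curve.csv", "w") as fh:
        fh.write("T_s,mean_error,sem\n")
        for w, e, s in zip(curve.windows, curve.errors, curve.sems):
            fh.write(f"{w},{e},{s}\n")
    (out_dir / "summary.json").write_text(json.dumps(res.summary, indent=1))


def regularization_suite(spec: TaskSpec | None = None, seed: int = 0,
                         out_dir: str | Path | None = None) -> dict:
    """Run the overcomplete identification task under the four
    regularization variants (none, L1 alpha=10, L2 beta=0.5, leak
    tau_m=50 ms) and report sparsity plus angular-error curves."""
    base = spec or TaskSpec(name="regularization", duration=10.0)
    if base.name != "regularization":
        raise ValueError("spec.name must be 'regularization'")
    out: dict = {}
    for variant in ("none", "L1", "L2", "leak"):
        s = dataclasses.replace(base, regularization=variant)
        sub = Path(out_dir) / variant if out_dir is not None else None
        res = run_task(s, seed=seed, out_dir=sub)
        out[variant] = res
    if out_dir is not None:
        summary = {v: out[v].summary for v in out}
        Path(out_dir, "suite_summary.json").write_text(
            json.dumps(summary, indent=1))
    return out
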