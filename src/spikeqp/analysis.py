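"""Raster analysis: rate estimates, decoding errors, ISI variability,
error-vs-window scaling, and shuffle surrogates.

Rates are spike counts over a window divided by the window length.  The
decoded input is the reconstruction U r_hat; its quality is measured as an
angular error (degrees between mu and U r_hat) or a percentage error
(100 ||mu - U r_hat|| / ||mu||).  Integration windows are anchored at time
zero; moving windows are used for time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .generative import FeatureBasis
from .network import SpikeRaster

__all__ = [
    "RateEstimate",
    "ErrorCurve",
    "estimate_rates",
    "reconstruct_input",
    "angular_error",
    "percentage_error",
    "isi_statistics",
    "error_vs_window",
    "error_time_course",
    "trial_shuffle",
    "bin_shuffle",
]


@dataclass(frozen=True)
class RateEstimate:
    window_start: float
    window_length: float
    rates: np.ndarray  # Hz, length N


@dataclass(frozen=True)
class ErrorCurve:
    """Trial-averaged decoding error per window, with a log-log slope fit."""

    windows: np.ndarray  # window sizes or window times (s)
    errors: np.ndarray  # mean over trials
    sems: np.ndarray
    n_trials: int
    slope: float | None = None
    slope_ci: tuple[float, float] | None = None


def estimate_rates(raster: SpikeRaster, t0: float = 0.0, T: float | None = None
                   ) -> RateEstimate:
    """Per-neuron firing rate (count / T) in the window [t0, t0 + T)."""
    if T is None:
        T = raster.duration - t0
    if T <= 0:
        raise ValueError("window length must be positive")
    if t0 < 0 or t0 + T > raster.duration + 1e-12:
        raise ValueError("window extends beyond the recorded raster")
    counts = raster.spike_counts(t0, T)
    return RateEstimate(window_start=t0, window_length=T,
                        rates=counts.astype(float) / T)


def reconstruct_input(basis: FeatureBasis, rates: RateEstimate | np.ndarray
                      ) -> np.ndarray:
    """Reconstructed input vector U r_hat."""
    r = rates.rates if isinstance(rates, RateEstimate) else np.asarray(rates)
    if r.shape[0] != basis.N:
        raise ValueError("rate vector length does not match basis")
    return basis.U @ r


def angular_error(mu: np.ndarray, mu_hat: np.ndarray) -> float:
    """Angle in degrees between the input and its reconstruction.

    Scale-invariant in both arguments; undefined (raises) for a zero
    vector — callers treat all-silent windows as missing data.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    mu_hat = np.asarray(mu_hat, dtype=float).ravel()
    na, nb = np.linalg.norm(mu), np.linalg.norm(mu_hat)
    if na == 0 or nb == 0:
        raise ValueError("angular error is undefined for a zero vector")
    c = np.clip(mu @ mu_hat / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def percentage_error(mu: np.ndarray, mu_hat: np.ndarray) -> float:
    """100 * ||mu - mu_hat|| / ||mu||."""
    mu = np.asarray(mu, dtype=float).ravel()
    mu_hat = np.asarray(mu_hat, dtype=float).ravel()
    n = np.linalg.norm(mu)
    if n == 0:
        raise ValueError("percentage error is undefined for zero input")
    return float(100.0 * np.linalg.norm(mu - mu_hat) / n)


def isi_statistics(raster: SpikeRaster, min_spikes: int = 3) -> dict:
    """Per-neuron inter-spike-interval CV and the population average.

    CV = std(ISI) / mean(ISI) over a neuron's ISIs; neurons with fewer than
    ``min_spikes`` spikes (fewer than 2 ISIs) are excluded and counted.
    """
    if min_spikes < 3:
        raise ValueError("min_spikes must be >= 3 (CV needs >= 2 ISIs)")
    isis: dict[int, np.ndarray] = {}
    cvs: dict[int, float] = {}
    excluded = 0
    for i in range(raster.n_neurons):
        t = raster.spike_times_of(i)
        if t.size < min_spikes:
            excluded += 1
            continue
        d = np.diff(np.sort(t))
        isis[i] = d
        cvs[i] = float(d.std() / d.mean())
    if not cvs:
        raise ValueError("no neuron has enough spikes for an ISI CV")
    pooled = np.concatenate(list(isis.values()))
    return {
        "isis": isis,
        "cv": cvs,
        "population_cv": float(np.mean(list(cvs.values()))),
        "pooled_cv": float(pooled.std() / pooled.mean()),
        "n_neurons_used": len(cvs),
        "n_excluded": excluded,
    }


def _mean_errors(
    rasters: list[SpikeRaster],
    basis: FeatureBasis,
    mu: np.ndarray,
    windows: np.ndarray,
    metric,
    anchored: bool,
    window_length: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    errs = np.full((len(rasters), len(windows)), np.nan)
    for k, ras in enumerate(rasters):
        for m, w in enumerate(windows):
            if anchored:
                est = estimate_rates(ras, 0.0, w)
            else:
                est = estimate_rates(ras, w, window_length)
            if est.rates.sum() == 0:
                continue  # all-silent window: excluded from the average
            errs[k, m] = metric(mu, reconstruct_input(basis, est))
    mean = np.full(errs.shape[1], np.nan)
    sem = np.zeros(errs.shape[1])
    for m in range(errs.shape[1]):
        col = errs[~np.isnan(errs[:, m]), m]
        if col.size:
            mean[m] = col.mean()
        if col.size > 1:
            sem[m] = col.std(ddof=1) / np.sqrt(col.size)
    return mean, sem, len(rasters)


def error_vs_window(
    rasters: list[SpikeRaster],
    basis: FeatureBasis,
    mu: np.ndarray,
    T_grid,
    metric: str = "angular",
) -> ErrorCurve:
    """Trial-averaged decoding error for growing integration windows
    anchored at time zero, with an OLS fit of log error vs log T.

    The slope distinguishes deterministic rate-estimation error (~1/T,
    slope -1) from what independent Poisson spiking would give (slope
    -1/2).  The 95% CI is the OLS slope standard error times 1.96.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    fn = angular_error if metric == "angular" else percentage_error
    mean, sem, n = _mean_errors(rasters, basis, mu, T_grid, fn, anchored=True)
    ok = np.isfinite(mean) & (mean > 0)
    slope = ci = None
    if ok.sum() >= 2:
        fit = stats.linregress(np.log(T_grid[ok]), np.log(mean[ok]))
        slope = float(fit.slope)
        ci = (slope - 1.96 * fit.stderr, slope + 1.96 * fit.stderr)
    return ErrorCurve(windows=T_grid, errors=mean, sems=sem, n_trials=n,
                      slope=slope, slope_ci=ci)


def error_time_course(
    rasters: list[SpikeRaster],
    basis: FeatureBasis,
    mu: np.ndarray,
    window_length: float,
    t_grid,
    metric: str = "angular",
) -> ErrorCurve:
    """Trial-averaged decoding error in moving windows [t, t + window_length)."""
    t_grid = np.asarray(t_grid, dtype=float)
    fn = angular_error if metric == "angular" else percentage_error
    mean, sem, n = _mean_errors(
        rasters, basis, mu, t_grid, fn, anchored=False,
        window_length=window_length,
    )
    return ErrorCurve(windows=t_grid, errors=mean, sems=sem, n_trials=n)


def trial_shuffle(rasters: list[SpikeRaster], seed: int = 0) -> list[SpikeRaster]:
    """Surrogate trials built by drawing, independently for each neuron, its
    whole-trial spike train from a random trial (a permutation across
    trials per neuron).  Per-neuron marginal statistics are preserved;
    cross-neuron coordination within a trial is destroyed."""
    if len(rasters) < 2:
        return list(rasters)
    durations = {round(r.duration, 9) for r in rasters}
    if len(durations) > 1:
        raise ValueError("trial durations differ")
    Ns = {r.n_neurons for r in rasters}
    if len(Ns) > 1:
        raise ValueError("trial neuron counts differ")
    n_trials = len(rasters)
    N = rasters[0].n_neurons
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_trials) for _ in range(N)])  # (N, trials)
    out = []
    per_neuron = [[r.spike_times_of(i) for r in rasters] for i in range(N)]
    for k in range(n_trials):
        neurons, times = [], []
        for i in range(N):
            t = per_neuron[i][perms[i, k]]
            neurons.append(np.full(t.size, i, dtype=np.int64))
            times.append(t)
        neurons = np.concatenate(neurons)
        times = np.concatenate(times)
        order = np.argsort(times, kind="stable")
        out.append(
            SpikeRaster(neurons=neurons[order], times=times[order],
                        n_neurons=N, duration=rasters[0].duration)
        )
    return out


def bin_shuffle(raster: SpikeRaster, bin_width: float, seed: int = 0
                ) -> SpikeRaster:
    """Surrogate raster with time bins permuted within the trial,
    independently per neuron (spikes shifted by whole-bin offsets; a final
    partial bin stays in place).  Per-neuron spike counts are preserved."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(raster.duration / bin_width + 1e-12))
    if n_bins <= 1:
        return raster
    rng = np.random.default_rng(seed)
    new_times = raster.times.copy()
    for i in range(raster.n_neurons):
        sel = raster.neurons == i
        t = raster.times[sel]
        b = np.floor(t / bin_width).astype(int)
        perm = rng.permutation(n_bins)
        in_range = b < n_bins
        shifted = t.copy()
        shifted[in_range] = t[in_range] + (perm[b[in_range]] - b[in_range]) * bin_width
        new_times[sel] = shifted
    order = np.argsort(new_times, kind="stable")
    return SpikeRaster(
        neurons=raster.neurons[order], times=new_times[order],
        n_neurons=raster.n_neurons, duration=raster.duration,
    )
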