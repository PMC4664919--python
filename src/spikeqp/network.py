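"""Integrate-and-fire network whose long-run spike counts solve the QP.

Each of N neurons integrates a constant drive ``g_i`` plus recurrent
synaptic input through a connectivity matrix ``J``::

    dV_i/dt = g_i + sum_{j != i} J_ij sum_l k(t - t_j^l)   [ - V_i / tau_m ]

A neuron spikes when its voltage reaches the threshold ``theta`` and is
then reset to ``H_i``; the reset is an instantaneous voltage assignment
(a delta-function self-kernel with weight ``J_ii = H_i - theta``), never
routed through the synaptic filter.  With the tuned wiring

    J = -U^T U - beta I,   g = U^T mu - alpha 1,   H_i = theta + J_ii,

the time-averaged firing rates of the (non-leaky) network converge to the
MAP cause intensities: active neurons balance their net input to zero and
silenced neurons integrate net inhibition, which is exactly the KKT system
of the non-negative quadratic program.  Explaining away is implemented
dynamically: each spike of neuron j inhibits neuron i in proportion to the
overlap u_i . u_j of their feature vectors.

Synaptic kernels are normalized to integrate to one.  Exponential kernels
(time constant ``tau_s``) are realized by one auxiliary current state per
neuron with exact per-step decay; delta kernels deliver the whole jump
J_ij at the arrival step (zero-delay deltas arrive one Euler step after
the spike, making same-step mutual causation well defined).

On reset the supra-threshold excess is discarded by default
(``SimConfig.carry_excess`` keeps it instead).  Carrying the excess is the
natural continuum limit for delta jumps, but it is lossless: for feature
pairs with u_i . u_j = -1 the excitatory jump J_ij = +1 exactly equals the
threshold-to-reset gap, and with carried excess two such neurons lock into
a self-sustaining loop firing every other Euler step — a 50 kHz artifact
living in the null space of J, invisible to the decoder and undamped.
Discarding the excess (at most one step's input for continuous kernels,
and the overshoot of a single jump for delta kernels) breaks the loop
while leaving the long-run rate balance unchanged.

Integration is one-step Euler, dt = 0.01 ms by default.  Injected white
noise is interpreted as per-unit-time variance (per-step increment
sd = sqrt(variance * dt)); a per-step interpretation is available via
``SimConfig.noise_per_step``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .generative import FeatureBasis, Observation

__all__ = [
    "KernelSpec",
    "NetworkParams",
    "SimConfig",
    "SpikeRaster",
    "tune_network",
    "perturb_connectivity",
    "stability_check",
    "mistuning_ratios",
    "simulate",
    "discrete_exp_kernel_weights",
]


@dataclass(frozen=True)
class KernelSpec:
    """Synaptic kernel: 'exponential' (time constant tau_s) or 'delta',
    either with a transmission delay in seconds."""

    kind: str = "exponential"
    tau_s: float = 5e-3
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "delta"):
            raise ValueError("kernel kind must be 'exponential' or 'delta'")
        if self.kind == "exponential" and self.tau_s <= 0:
            raise ValueError("exponential kernel needs tau_s > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass(frozen=True)
class NetworkParams:
    """Wiring of one spiking network (all voltages in threshold units)."""

    J: np.ndarray
    g: np.ndarray
    theta: float
    H: np.ndarray
    tau_m: float = np.inf  # membrane time constant (s); inf = non-leaky
    kernel: KernelSpec = field(default_factory=KernelSpec)

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=float)
        g = np.asarray(self.g, dtype=float).ravel()
        H = np.asarray(self.H, dtype=float).ravel()
        if J.shape != (g.size, g.size) or H.size != g.size:
            raise ValueError("inconsistent J/g/H dimensions")
        if np.any(H >= self.theta):
            raise ValueError("every reset voltage must lie below threshold")
        if not (self.tau_m > 0):
            raise ValueError("tau_m must be positive (np.inf for non-leaky)")
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "H", H)

    @property
    def N(self) -> int:
        return self.g.shape[0]

    @property
    def leaky(self) -> bool:
        return np.isfinite(self.tau_m)


@dataclass(frozen=True)
class SimConfig:
    dt: float = 1e-5  # Euler step (s); 0.01 ms
    duration: float = 1.0  # total simulated time (s)
    seed: int = 0
    v0: np.ndarray | None = None  # fixed initial voltages; None = uniform [H, theta)
    noise_var: float = 0.0  # injected white-noise variance (threshold^2 / s)
    noise_per_step: bool = False  # interpret noise_var as per-step variance
    record_voltages: bool = False
    record_stride: int = 100  # store every k-th step when recording
    carry_excess: bool = False  # add supra-threshold excess to the reset voltage

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")


@dataclass(frozen=True)
class SpikeRaster:
    """Time-sorted spike events from one trial."""

    neurons: np.ndarray  # int indices, 0-based
    times: np.ndarray  # spike times (s), sorted
    n_neurons: int
    duration: float
    voltages: np.ndarray | None = None  # optional (n_rec, N) traces
    voltage_times: np.ndarray | None = None

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def spike_counts(self, t0: float = 0.0, T: float | None = None) -> np.ndarray:
        """Per-neuron spike count in the window [t0, t0 + T)."""
        if T is None:
            T = self.duration - t0
        sel = (self.times >= t0) & (self.times < t0 + T)
        return np.bincount(self.neurons[sel], minlength=self.n_neurons)

    def spike_times_of(self, i: int) -> np.ndarray:
        return self.times[self.neurons == i]

    def to_csv(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("neuron_index,time_s\n")
            for i, t in zip(self.neurons, self.times):
                fh.write(f"{i},{t:.8f}\n")
        sidecar = {"n_neurons": self.n_neurons, "duration": self.duration}
        if meta:
            sidecar.update(meta)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeRaster":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta = json.loads(path.with_suffix(".json").read_text())
        if data.size == 0:
            neurons = np.empty(0, dtype=np.int64)
            times = np.empty(0)
        else:
            neurons = data[:, 0].astype(np.int64)
            times = data[:, 1]
        return cls(
            neurons=neurons,
            times=times,
            n_neurons=int(meta["n_neurons"]),
            duration=float(meta["duration"]),
        )


def tune_network(
    basis: FeatureBasis,
    obs: Observation,
    alpha: float = 0.0,
    beta: float = 0.0,
    theta: float = 1.0,
    tau_m: float = np.inf,
    kernel: KernelSpec | None = None,
) -> NetworkParams:
    """Wire a network so its long-run rates solve the QP for (U, mu, alpha, beta).

    J = -U^T U - beta I; g = U^T mu - alpha 1; H_i = theta + J_ii.  The L1
    coefficient alpha acts as global inhibition on the drive; the L2
    coefficient beta lowers every reset voltage by beta.
    """
    if obs.M != basis.M:
        raise ValueError("observation dimension does not match basis")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    U = basis.U
    J = -(U.T @ U) - beta * np.eye(basis.N)
    g = U.T @ obs.mu - alpha
    H = theta + np.diag(J)
    if np.any(H >= theta):
        raise ValueError("tuning failed: some J_ii >= 0 (zero feature vector?)")
    return NetworkParams(
        J=J, g=g, theta=theta, H=H, tau_m=tau_m,
        kernel=kernel if kernel is not None else KernelSpec(),
    )


def perturb_connectivity(
    net: NetworkParams,
    low: float,
    high: float,
    seed: int = 0,
    include_diagonal: bool = True,
) -> NetworkParams:
    """Mistune the wiring: add an i.i.d. uniform-[low, high] component to
    every entry of J (optionally sparing the diagonal).  Reset voltages are
    recomputed from the perturbed diagonal, H_i = theta + J_ii."""
    if low > high:
        raise ValueError("need low <= high")
    rng = np.random.default_rng(seed)
    delta = rng.uniform(low, high, size=net.J.shape)
    if not include_diagonal:
        np.fill_diagonal(delta, 0.0)
    J = net.J + delta
    H = net.theta + np.diag(J) if include_diagonal else net.H
    if np.any(H >= net.theta):
        raise ValueError("perturbation drove a reset voltage to threshold")
    return replace(net, J=J, H=H)


def stability_check(net: NetworkParams) -> dict:
    """Eigenvalues of the symmetrized connectivity; any positive eigenvalue
    signals likely runaway dynamics (the tuned -U^T U - beta I has none)."""
    sym = 0.5 * (net.J + net.J.T)
    eig = np.linalg.eigvalsh(sym)
    return {
        "eigenvalues": eig,
        "max_eigenvalue": float(eig[-1]),
        "unstable": bool(eig[-1] > 1e-10),
    }


def mistuning_ratios(J_opt: np.ndarray, J_pert: np.ndarray) -> dict:
    """Relative size of a connectivity perturbation, three conventions:
    mean of entrywise |delta|/|J|, mean|delta| / mean|J|, and the Frobenius
    ratio ||delta||_F / ||J||_F."""
    delta = np.abs(np.asarray(J_pert) - np.asarray(J_opt))
    absJ = np.abs(np.asarray(J_opt))
    ok = absJ > 1e-8  # entrywise ratio undefined for (near-)zero entries
    return {
        "mean_entrywise_ratio": float(np.mean(delta[ok] / absJ[ok])),
        "mean_abs_ratio": float(delta.mean() / absJ.mean()),
        "frobenius_ratio": float(np.linalg.norm(delta) / np.linalg.norm(absJ)),
    }


def discrete_exp_kernel_weights(dt: float, tau_s: float, horizon: float = 0.2):
    """Euler-grid weights of the normalized exponential kernel.

    The per-step jump is scaled so that dt * sum(weights) telescopes to 1
    (exactly, up to truncation at ``horizon`` seconds)."""
    rho = np.exp(-dt / tau_s)
    n = int(round(horizon / dt))
    k0 = (1.0 - rho) / dt
    return k0 * rho ** np.arange(n)


# ---------------------------------------------------------------------------
# numba Euler cores
# ---------------------------------------------------------------------------


@njit(cache=True)
def _euler_core(
    Jjump,  # (N, N) per-spike jump to the synaptic state (exp) or voltage (delta)
    g,
    theta,
    H,
    inv_tau_m,  # 0.0 for non-leaky
    dt,
    n_steps,
    decay,  # per-step synaptic decay (exp); ignored for delta
    is_delta,
    delay_steps,  # effective delivery delay in steps, >= 1
    V,
    s,
    noise_sd,  # per-step noise increment sd; 0 disables
    noise_seed,
    carry_excess,
    rec_stride,  # <= 0 disables voltage recording
    Vrec,
):
    N = g.shape[0]
    D = delay_steps
    buf = np.zeros((D, N))
    pending = np.zeros(D, dtype=np.int64)
    cap = 4096
    sp_n = np.empty(cap, dtype=np.int64)
    sp_t = np.empty(cap)
    n_sp = 0
    spk = np.empty(N, dtype=np.int64)
    np.random.seed(noise_seed)
    n_rec = 0
    for t in range(n_steps):
        slot = t % D
        if pending[slot] > 0:
            if is_delta:
                for i in range(N):
                    V[i] += buf[slot, i]
                    buf[slot, i] = 0.0
            else:
                for i in range(N):
                    s[i] += buf[slot, i]
                    buf[slot, i] = 0.0
            pending[slot] = 0
        nsp = 0
        if is_delta:
            for i in range(N):
                dv = dt * (g[i] - V[i] * inv_tau_m)
                if noise_sd > 0.0:
                    dv += noise_sd * np.random.normal()
                V[i] += dv
                if V[i] >= theta:
                    spk[nsp] = i
                    nsp += 1
                    if carry_excess:
                        V[i] = H[i] + (V[i] - theta)
                    else:
                        V[i] = H[i]
        else:
            for i in range(N):
                dv = dt * (g[i] + s[i] - V[i] * inv_tau_m)
                if noise_sd > 0.0:
                    dv += noise_sd * np.random.normal()
                V[i] += dv
                s[i] *= decay
                if V[i] >= theta:
                    spk[nsp] = i
                    nsp += 1
                    if carry_excess:
                        V[i] = H[i] + (V[i] - theta)
                    else:
                        V[i] = H[i]
        if nsp > 0:
            tgt = (t + D) % D if D == 1 else (t + delay_steps) % D
            for k in range(nsp):
                j = spk[k]
                if n_sp >= cap:
                    cap *= 2
                    new_n = np.empty(cap, dtype=np.int64)
                    new_t = np.empty(cap)
                    new_n[:n_sp] = sp_n[:n_sp]
                    new_t[:n_sp] = sp_t[:n_sp]
                    sp_n = new_n
                    sp_t = new_t
                sp_n[n_sp] = j
                sp_t[n_sp] = (t + 1) * dt
                n_sp += 1
                for i in range(N):
                    buf[tgt, i] += Jjump[i, j]
            pending[tgt] += nsp
        if rec_stride > 0 and t % rec_stride == 0:
            for i in range(N):
                Vrec[n_rec, i] = V[i]
            n_rec += 1
        if not np.isfinite(V[0]):
            raise ValueError("non-finite voltage (instability)")
    return sp_n[:n_sp], sp_t[:n_sp], n_rec


def simulate(net: NetworkParams, cfg: SimConfig) -> SpikeRaster:
    """Run one Euler-integrated trial and return the spike raster.

    Initial voltages are uniform on [H_i, theta) unless ``cfg.v0`` is given.
    Fully reproducible: ``cfg.seed`` drives both the initial condition and
    the injected noise.
    """
    N = net.N
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    rng = np.random.default_rng(cfg.seed)
    if cfg.v0 is not None:
        V = np.asarray(cfg.v0, dtype=float).copy()
        if V.shape != (N,):
            raise ValueError("v0 has wrong shape")
    else:
        V = rng.uniform(net.H, net.theta)
    s = np.zeros(N)

    kern = net.kernel
    is_delta = kern.kind == "delta"
    delay_steps = max(int(round(kern.delay / dt)), 1)
    J_off = net.J.copy()
    np.fill_diagonal(J_off, 0.0)  # self-coupling is the instantaneous reset
    if is_delta:
        Jjump = J_off
        decay = 1.0
    else:
        rho = np.exp(-dt / kern.tau_s)
        # scale so that dt * sum_n jump * rho^n = J_ij exactly
        Jjump = J_off * (1.0 - rho) / dt
        decay = rho
    if cfg.noise_var > 0:
        var_step = cfg.noise_var if cfg.noise_per_step else cfg.noise_var * dt
        noise_sd = float(np.sqrt(var_step))
    else:
        noise_sd = 0.0
    noise_seed = int(rng.integers(0, 2**31 - 1))

    if cfg.record_voltages:
        n_rec_max = n_steps // cfg.record_stride + 1
        Vrec = np.empty((n_rec_max, N))
        rec_stride = cfg.record_stride
    else:
        Vrec = np.empty((1, N))
        rec_stride = 0

    inv_tau_m = 0.0 if not net.leaky else 1.0 / net.tau_m
    sp_n, sp_t, n_rec = _euler_core(
        np.ascontiguousarray(Jjump),
        net.g,
        float(net.theta),
        net.H,
        inv_tau_m,
        dt,
        n_steps,
        decay,
        is_delta,
        delay_steps,
        V,
        s,
        noise_sd,
        noise_seed,
        cfg.carry_excess,
        rec_stride,
        Vrec,
    )
    voltages = Vrec[:n_rec].copy() if cfg.record_voltages else None
    vtimes = (
        np.arange(n_rec) * cfg.record_stride * dt if cfg.record_voltages else None
    )
    return SpikeRaster(
        neurons=sp_n,
        times=sp_t,
        n_neurons=N,
        duration=n_steps * dt,
        voltages=voltages,
        voltage_times=vtimes,
    )
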