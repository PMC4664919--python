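"""The non-negative quadratic program and its non-spiking solvers.

MAP inference of the cause intensities reduces to minimizing

    L(r) = 1/2 ||mu - U r||^2 + alpha * sum_j r_j + beta/2 * sum_j r_j^2

over the non-negative orthant r >= 0 (the Gaussian likelihood is taken at
unit noise scale; alpha and beta are interpreted on that scale).  With

    W = -U^T U - beta I        g = U^T mu - alpha 1

this is equivalent to maximizing g^T r + 1/2 r^T W r, i.e. minimizing the
energy E(r) = -g^T r - 1/2 r^T W r subject to r >= 0.

Two reference solvers live here:

* a projected-gradient solver (the workhorse for any N), and
* an exhaustive active-set oracle that enumerates supports (exact, N <= 20),

plus the rate-network dynamics dr_i/dt = [g_i + (W r)_i + r_i]^+ - r_i,
which performs gradient descent on E within the orthant and whose fixpoint
is the MAP estimate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .generative import FeatureBasis, Observation

__all__ = [
    "QPProblem",
    "RateTrajectory",
    "build_qp",
    "loss",
    "energy",
    "kkt_residual",
    "solve_map_projected_gradient",
    "solve_map_active_set",
    "solution_is_unique",
    "simulate_rate_dynamics",
]


@dataclass(frozen=True)
class QPProblem:
    """Derived optimization data W, g for one (U, mu, alpha, beta)."""

    W: np.ndarray
    g: np.ndarray
    U: FeatureBasis
    mu: Observation
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        g = np.asarray(self.g, dtype=float).ravel()
        if W.shape != (g.size, g.size):
            raise ValueError("W must be N x N with N = len(g)")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "g", g)

    @property
    def N(self) -> int:
        return self.g.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W": self.W.tolist(),
            "g": self.g.tolist(),
            "U": self.U.U.tolist(),
            "mu": self.mu.mu.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "QPProblem":
        d = json.loads(Path(path).read_text())
        U = np.asarray(d["U"], dtype=float)
        norms = np.linalg.norm(U, axis=0)
        basis = FeatureBasis(U=U, norm_flag=bool(np.allclose(norms, 1.0, atol=1e-12)))
        return cls(
            W=np.asarray(d["W"]),
            g=np.asarray(d["g"]),
            U=basis,
            mu=Observation(mu=np.asarray(d["mu"])),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
        )


@dataclass(frozen=True)
class RateTrajectory:
    """Euler trajectory of the rate network with the energy along it."""

    times: np.ndarray
    rates: np.ndarray  # (n_times, N)
    energies: np.ndarray


def build_qp(
    basis: FeatureBasis, obs: Observation, alpha: float = 0.0, beta: float = 0.0
) -> QPProblem:
    """W = -U^T U - beta I and g = U^T mu - alpha 1."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    if obs.M != basis.M:
        raise ValueError("observation dimension does not match basis")
    U = basis.U
    W = -(U.T @ U) - beta * np.eye(basis.N)
    g = U.T @ obs.mu - alpha
    return QPProblem(W=W, g=g, U=basis, mu=obs, alpha=alpha, beta=beta)


def loss(
    basis: FeatureBasis,
    obs: Observation,
    r: np.ndarray,
    alpha: float = 0.0,
    beta: float = 0.0,
) -> float:
    """1/2 ||mu - U r||^2 + alpha sum(r) + beta/2 sum(r^2), for r >= 0."""
    r = np.asarray(r, dtype=float).ravel()
    if np.any(r < 0):
        raise ValueError("r has negative entries (outside the feasible set)")
    resid = obs.mu - basis.U @ r
    return float(0.5 * resid @ resid + alpha * r.sum() + 0.5 * beta * r @ r)


def energy(qp: QPProblem, r: np.ndarray) -> float:
    """E(r) = -g^T r - 1/2 r^T W r; equals loss(r) - loss(0)."""
    r = np.asarray(r, dtype=float).ravel()
    return float(-qp.g @ r - 0.5 * r @ qp.W @ r)


def kkt_residual(qp: QPProblem, r: np.ndarray) -> float:
    """Maximum violation of the stationarity conditions at r >= 0.

    At the constrained optimum the net drive g + W r is zero on active
    coordinates (r_i > 0) and non-positive on inactive ones; the residual is
    the largest absolute deviation from those conditions.
    """
    r = np.asarray(r, dtype=float).ravel()
    if np.any(r < 0):
        raise ValueError("r has negative entries")
    drive = qp.g + qp.W @ r
    viol = np.where(r > 0, np.abs(drive), np.maximum(drive, 0.0))
    return float(viol.max()) if viol.size else 0.0


def solve_map_projected_gradient(
    qp: QPProblem,
    step: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 200_000,
    r0: np.ndarray | None = None,
) -> np.ndarray:
    """Projected gradient ascent on g^T r + 1/2 r^T W r over r >= 0.

    ``step`` defaults to 1/lambda_max(-W), which guarantees monotone
    convergence for the concave objective.  Raises on non-convergence,
    carrying the last KKT residual in the message.
    """
    W, g = qp.W, qp.g
    if step is None:
        lam = float(np.linalg.eigvalsh(-W).max())
        step = 1.0 / max(lam, 1e-12)
    r = np.zeros(qp.N) if r0 is None else np.asarray(r0, dtype=float).copy()
    if np.any(r < 0):
        raise ValueError("r0 must be non-negative")
    # Nesterov-accelerated projected gradient with energy restarts; the
    # plain method crawls when U^T U is badly conditioned (strong overlaps).
    y = r.copy()
    t_mom = 1.0
    e_prev = energy(qp, r)
    for it in range(max_iter):
        r_new = np.maximum(0.0, y + step * (g + W @ y))
        e_new = energy(qp, r_new)
        if e_new > e_prev:  # momentum overshoot: restart from last iterate
            y = r.copy()
            t_mom = 1.0
            r_new = np.maximum(0.0, y + step * (g + W @ y))
            e_new = energy(qp, r_new)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        y = r_new + ((t_mom - 1.0) / t_next) * (r_new - r)
        r, t_mom, e_prev = r_new, t_next, e_new
        if it % 10 == 0 and kkt_residual(qp, r) <= tol:
            return r
    if kkt_residual(qp, r) <= tol:
        return r
    raise RuntimeError(
        f"projected gradient did not converge in {max_iter} iterations "
        f"(last KKT residual {kkt_residual(qp, r):.3e})"
    )


def solve_map_active_set(qp: QPProblem) -> np.ndarray:
    """Exact MAP by exhaustive enumeration of active supports (N <= 20).

    For each candidate support S the equality-constrained solution solves
    (U_S^T U_S + beta I) r_S = g_S; it is a KKT point if r_S >= 0 and the
    net drive on the complement is <= 0.  The feasible KKT point with the
    lowest loss is returned.  With alpha = beta = 0 and linearly dependent
    columns the optimum may be non-unique; one minimizer of the set is
    reported (least-norm on the support).
    """
    N = qp.N
    if N > 20:
        raise ValueError("active-set enumeration is limited to N <= 20")
    A = -qp.W  # U^T U + beta I, positive semi-definite
    g = qp.g
    best_r = None
    best_loss = np.inf
    for k in range(N + 1):
        for S in itertools.combinations(range(N), k):
            S = list(S)
            r = np.zeros(N)
            if S:
                sub = A[np.ix_(S, S)]
                try:
                    r_S = np.linalg.solve(sub, g[S])
                except np.linalg.LinAlgError:
                    r_S = np.linalg.lstsq(sub, g[S], rcond=None)[0]
                if np.any(r_S < -1e-12):
                    continue
                r[S] = np.maximum(r_S, 0.0)
            drive = g + qp.W @ r
            inactive = np.setdiff1d(np.arange(N), S)
            if inactive.size and drive[inactive].max(initial=-np.inf) > 1e-10:
                continue
            lv = loss(qp.U, qp.mu, r, qp.alpha, qp.beta)
            if lv < best_loss - 1e-14:
                best_loss = lv
                best_r = r
    if best_r is None:
        raise RuntimeError("no feasible KKT point found (numerical failure)")
    return best_r


def solution_is_unique(qp: QPProblem, r: np.ndarray, tol: float = 1e-10) -> bool:
    """Whether the minimizer at ``r`` is the unique one.

    With beta > 0 the objective is strictly convex.  Otherwise uniqueness
    is flagged via the rank of the Gram matrix on the active support: a
    rank-deficient support admits feasible directions of constant loss.
    """
    if qp.beta > 0:
        return True
    S = np.flatnonzero(np.asarray(r) > tol)
    if S.size == 0:
        return True
    sub = (-qp.W)[np.ix_(S, S)]
    return bool(np.linalg.matrix_rank(sub, tol=1e-10) == S.size)


def simulate_rate_dynamics(
    qp: QPProblem,
    r0: np.ndarray,
    dt: float = 0.01,
    T: float = 50.0,
    record_every: int = 1,
) -> RateTrajectory:
    """Euler integration of dr_i/dt = [g_i + (W r)_i + r_i]^+ - r_i.

    The trajectory stays in the non-negative orthant and the energy is
    non-increasing along it; the step is halved (up to 30 times) whenever a
    step would increase the energy, and an error is raised if halving cannot
    restore monotonicity.
    """
    r = np.asarray(r0, dtype=float).copy()
    if np.any(r < 0):
        raise ValueError("r0 must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(T / dt))
    times = [0.0]
    rates = [r.copy()]
    energies = [energy(qp, r)]
    t = 0.0
    for _ in range(n_steps):
        e_old = energies[-1]
        h = dt
        for _halving in range(31):
            r_new = r + h * (np.maximum(0.0, qp.g + qp.W @ r + r) - r)
            e_new = energy(qp, r_new)
            if e_new <= e_old + 1e-9:
                break
            h *= 0.5
        else:
            raise RuntimeError(
                f"energy increased at t={t:.4f} despite step halving "
                f"(dE={e_new - e_old:.3e}); reduce dt"
            )
        r = r_new
        t += h
        times.append(t)
        rates.append(r.copy())
        energies.append(e_new)
    idx = np.arange(0, len(times), record_every)
    if idx[-1] != len(times) - 1:
        idx = np.append(idx, len(times) - 1)
    return RateTrajectory(
        times=np.asarray(times)[idx],
        rates=np.asarray(rates)[idx],
        energies=np.asarray(energies)[idx],
    )
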