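"""Generative model of causes and observations.

An observation ``mu`` (length M) is a linear combination of N feature
vectors (the columns of U) weighted by non-negative cause intensities
``r``, plus optional i.i.d. Gaussian noise::

    mu = U r + eps,   r_i >= 0,   eps_k ~ N(0, noise_sd^2)

A priori the intensities are independent with density proportional to
``H(r) * exp(-alpha*r - beta*r^2/2)`` — a Gaussian truncated to the
non-negative half-line.  ``beta = 0`` gives an exponential (Laplace-type)
prior, ``alpha = 0`` a half-normal.

This module builds feature bases (random uniform-entry and shifted-cosine
constructions), samples causes from the prior, and synthesizes
observations.  All randomness is seeded and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "FeatureBasis",
    "PriorParams",
    "Observation",
    "make_random_features",
    "make_cosine_features",
    "sample_prior_causes",
    "synthesize_observation",
    "pairwise_overlaps",
]


@dataclass(frozen=True)
class FeatureBasis:
    """An M x N matrix whose columns are the feature vectors of the causes."""

    U: np.ndarray
    norm_flag: bool = True
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if U.ndim != 2 or U.shape[0] < 1 or U.shape[1] < 1:
            raise ValueError("U must be a 2-D matrix with M, N >= 1")
        if not np.all(np.isfinite(U)):
            raise ValueError("feature matrix contains non-finite entries")
        object.__setattr__(self, "U", U)
        if self.norm_flag:
            norms = np.linalg.norm(U, axis=0)
            if not np.allclose(norms, 1.0, atol=1e-12):
                raise ValueError("norm_flag set but columns are not unit norm")

    @property
    def M(self) -> int:
        return self.U.shape[0]

    @property
    def N(self) -> int:
        return self.U.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write the basis as CSV (one column per feature vector) plus a
        JSON sidecar with construction metadata."""
        path = Path(path)
        header = ",".join(str(j) for j in range(self.N))
        np.savetxt(path, self.U, delimiter=",", header=header, comments="")
        sidecar = {"M": self.M, "N": self.N, "norm_flag": self.norm_flag}
        sidecar.update(self.meta)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureBasis":
        path = Path(path)
        U = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        norm_flag = bool(meta.pop("norm_flag", False))
        meta.pop("M", None)
        meta.pop("N", None)
        return cls(U=U, norm_flag=norm_flag, meta=meta)


@dataclass(frozen=True)
class PriorParams:
    """L1 (``alpha``) and L2 (``beta``) prior coefficients, both >= 0."""

    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass(frozen=True)
class Observation:
    """An input vector mu of length M and the noise level that produced it."""

    mu: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float).ravel()
        if not np.all(np.isfinite(mu)):
            raise ValueError("observation contains non-finite entries")
        object.__setattr__(self, "mu", mu)

    @property
    def M(self) -> int:
        return self.mu.shape[0]


def make_random_features(
    M: int, N: int, low: float = 0.0, high: float = 1.0, seed: int = 0
) -> FeatureBasis:
    """Feature vectors with i.i.d. uniform-[low, high) entries, each column
    normalized to unit Euclidean length.

    With entries on [0, 1] the columns are strongly overlapping: for large M
    the mean pairwise dot product approaches E[x]^2 / E[x^2] = 3/4.
    Symmetric entries ([-0.5, 0.5]) give near-orthogonal columns instead.
    """
    if M < 1 or N < 1:
        raise ValueError("M and N must be >= 1")
    if not low < high:
        raise ValueError("need low < high")
    rng = np.random.default_rng(seed)
    U = rng.uniform(low, high, size=(M, N))
    norms = np.linalg.norm(U, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate all-zero column before normalization")
    U = U / norms
    meta = {"construction": "uniform", "low": low, "high": high, "seed": seed}
    return FeatureBasis(U=U, norm_flag=True, meta=meta)


def make_cosine_features(N: int) -> FeatureBasis:
    """Shifted-cosine basis: M = 2, column j = (cos(2*pi*j/N), sin(2*pi*j/N))
    for j = 1..N.

    All columns have unit norm and the matrix has rank 2, so for N > 2 the
    basis is highly overcomplete: the same 2-D input admits many non-negative
    representations.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    j = np.arange(1, N + 1)
    theta = 2.0 * np.pi * j / N
    U = np.vstack([np.cos(theta), np.sin(theta)])
    meta = {"construction": "cosine", "N": N}
    return FeatureBasis(U=U, norm_flag=True, meta=meta)


def sample_prior_causes(
    prior: PriorParams, N: int, n_samples: int = 1, seed: int = 0
) -> np.ndarray:
    """Draw i.i.d. cause intensities from the truncated-Gaussian prior.

    Density proportional to ``exp(-alpha*r - beta*r^2/2)`` on r >= 0.
    Returns an (n_samples, N) array.
    """
    alpha, beta = prior.alpha, prior.beta
    if alpha == 0.0 and beta == 0.0:
        raise ValueError("alpha = beta = 0 gives a non-normalizable prior")
    rng = np.random.default_rng(seed)
    size = (n_samples, N)
    if beta == 0.0:
        return rng.exponential(scale=1.0 / alpha, size=size)
    # Gaussian with mean -alpha/beta, sd 1/sqrt(beta), truncated to r >= 0.
    sd = 1.0 / np.sqrt(beta)
    mean = -alpha / beta
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def synthesize_observation(
    basis: FeatureBasis, r: np.ndarray, noise_sd: float = 0.0, seed: int = 0
) -> Observation:
    """mu = U r + Gaussian noise with the given per-component sd."""
    r = np.asarray(r, dtype=float).ravel()
    if r.shape[0] != basis.N:
        raise ValueError(f"r has length {r.shape[0]}, basis has N={basis.N}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mu = basis.U @ r
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mu = mu + rng.normal(0.0, noise_sd, size=basis.M)
    return Observation(mu=mu, noise_sd=noise_sd)


def pairwise_overlaps(basis: FeatureBasis) -> dict:
    """Cosine overlaps between feature vectors.

    Returns the full Gram matrix together with the off-diagonal values and
    their mean.  Requires a unit-norm basis (otherwise the dot product is
    not a cosine).
    """
    if not basis.norm_flag:
        raise ValueError("overlaps are defined for unit-norm bases only")
    G = basis.U.T @ basis.U
    off = G[~np.eye(basis.N, dtype=bool)]
    return {"matrix": G, "offdiag": off, "mean": float(off.mean())}
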