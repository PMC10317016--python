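"""Fixed random reservoirs (echo state networks) and their state evolution.

The reservoir is a leaky-integrator echo state network: an ``n``-node
recurrent network with a fixed random sparse internal matrix ``A`` and a
fixed random input matrix ``W``.  Driven by a ``q``-dimensional input
series the state obeys

    r_{i+1} = (1 - l) r_i + l tanh(A r_i + W x_i + b)

with leakage ``l`` in [0, 1] and scalar bias ``b``.  Only the linear
readout (see :mod:`rctip.readout`) is ever trained; ``A`` and ``W`` are
generated once from a seed and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse as sp

__all__ = ["ReservoirParams", "Reservoir", "StateSequence", "build_reservoir", "evolve"]


@dataclass(frozen=True)
class ReservoirParams:
    """Hyperparameters of a random reservoir.

    Parameters
    ----------
    n:
        Number of reservoir nodes.
    leakage:
        Leak rate ``l`` in [0, 1]; convex mixing between the previous state
        and the new nonlinear drive.
    bias:
        Scalar bias ``b`` added inside the tanh.
    spectral_radius:
        Largest absolute eigenvalue the internal matrix ``A`` is rescaled to.
    density:
        Fraction of nonzero entries of ``A``.
    input_scaling:
        Input-matrix entries are drawn uniformly in
        ``[-input_scaling, +input_scaling]``.
    seed:
        Seed for the (otherwise irreproducible) random matrices.
    washout:
        Number of initial states discarded downstream so the state forgets
        its arbitrary initialisation.
    """

    n: int = 100
    leakage: float = 0.9
    bias: float = 0.0
    spectral_radius: float = 0.9
    density: float = 0.05
    input_scaling: float = 0.1
    seed: int = 0
    washout: int = 50

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"reservoir size n must be >= 1, got {self.n}")
        if not 0.0 <= self.leakage <= 1.0:
            raise ValueError(f"leakage must lie in [0, 1], got {self.leakage}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must lie in [0, 1], got {self.density}")
        if self.spectral_radius < 0:
            raise ValueError("spectral_radius must be nonnegative")
        if self.input_scaling <= 0:
            raise ValueError("input_scaling must be positive")
        if self.washout < 0:
            raise ValueError("washout must be nonnegative")


@dataclass(frozen=True)
class Reservoir:
    """A built reservoir: fixed matrices plus the evolution scalars."""

    A: np.ndarray
    W: np.ndarray
    leakage: float
    bias: float
    washout: int = 50

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            A=self.A,
            W=self.W,
            leakage=self.leakage,
            bias=self.bias,
            washout=self.washout,
        )

    @classmethod
    def load(cls, path) -> "Reservoir":
        with np.load(path) as f:
            return cls(
                A=f["A"],
                W=f["W"],
                leakage=float(f["leakage"]),
                bias=float(f["bias"]),
                washout=int(f["washout"]),
            )


@dataclass(frozen=True)
class StateSequence:
    """Reservoir states aligned with the driving series.

    ``states[i]`` is the state that has absorbed inputs up to ``x_{i-1}``
    (``states[0]`` is the initial state), so the pair
    ``(states[i], x_i)`` is a one-step-ahead predictor pairing.
    """

    states: np.ndarray  # (T, n)
    washout: int = 0

    def __len__(self) -> int:
        return self.states.shape[0]


def build_reservoir(params: ReservoirParams, q: int) -> Reservoir:
    """Construct the fixed random matrices of a reservoir.

    ``A`` has approximately ``density * n**2`` nonzero entries drawn
    uniformly in [-1, 1] and is rescaled so its spectral radius equals
    ``params.spectral_radius``; ``W`` is dense uniform in
    ``[-input_scaling, input_scaling]``.  The same seed always yields
    bitwise-identical matrices.
    """
    if q < 1:
        raise ValueError(f"input dimension q must be >= 1, got {q}")
    rng = np.random.default_rng(params.seed)
    n = params.n
    A = sp.random(
        n,
        n,
        density=params.density,
        random_state=rng,
        data_rvs=lambda size: rng.uniform(-1.0, 1.0, size),
        format="csr",
    ).toarray()
    if A.any() and params.spectral_radius > 0:
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        if rho > 0:
            A *= params.spectral_radius / rho
    elif params.spectral_radius == 0:
        A = np.zeros_like(A)
    W = rng.uniform(-params.input_scaling, params.input_scaling, size=(n, q))
    return Reservoir(A=A, W=W, leakage=params.leakage, bias=params.bias,
                     washout=params.washout)


def evolve(res: Reservoir, X: np.ndarray, r0: np.ndarray | None = None) -> StateSequence:
    """Drive the reservoir with a series and return the state sequence.

    Parameters
    ----------
    res:
        A built reservoir with input dimension ``q``.
    X:
        Input series of shape ``(T, q)``.
    r0:
        Initial state (length ``n``); zeros by default.

    Returns
    -------
    StateSequence
        ``T`` states; ``states[0] == r0`` and ``states[i]`` has absorbed
        inputs up to ``x_{i-1}``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != res.q:
        raise ValueError(
            f"input series must have shape (T, {res.q}), got {X.shape}")
    n = res.n
    if r0 is None:
        r = np.zeros(n)
    else:
        r = np.asarray(r0, dtype=float)
        if r.shape != (n,):
            raise ValueError(f"r0 must have length {n}, got shape {r.shape}")
    T = X.shape[0]
    states = np.empty((T, n))
    states[0] = r
    l = res.leakage
    A, W, b = res.A, res.W, res.bias
    # pre-project the whole input once; the recurrence itself is sequential
    WX = X @ W.T + b
    for i in range(T - 1):
        r = (1.0 - l) * r + l * np.tanh(A @ r + WX[i])
        states[i + 1] = r
    return StateSequence(states=states, washout=res.washout)
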