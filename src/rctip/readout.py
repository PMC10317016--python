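"""Window-local readout weights and the weight-difference feature.

The linear readout ``W_out`` (a ``q x n`` matrix) maps the reservoir state
back to the observed ``q``-dimensional data.  Fitted on a trailing window
of length ``T_w``, it encodes the dynamics governing that window; the
detection feature is the difference between the readouts of two adjacent
non-overlapping windows,

    dW_out(i) = W_out(i + T_w) - W_out(i),

flattened row-major to a vector of length ``q * n``.  Two fitting routes
are provided and are exactly equivalent: direct ridge regression on the
window, and recursive least squares (RLS) streamed through the window from
the gain initialisation ``P_0 = I / gamma`` (RLS with ``gamma`` equals
ridge with penalty ``beta = gamma``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import linalg

from .reservoir import StateSequence

__all__ = [
    "RidgeSpec",
    "ReadoutWeights",
    "RLSState",
    "WeightDelta",
    "fit_window_readout",
    "rls_init",
    "rls_step",
    "sliding_weights",
    "weight_deltas",
]

Method = Literal["ridge", "rls"]


@dataclass(frozen=True)
class RidgeSpec:
    """Ridge regression settings: squared-Frobenius penalty with weight beta."""

    beta: float = 1e-4

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"ridge penalty beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class ReadoutWeights:
    """A window-local readout matrix ``W_out`` of shape (q, n).

    ``window`` is the half-open index pair ``[start, end)`` of the samples
    the fit used; the ``anchor`` is the window end ``t``, so the fit used
    the ``T_w`` samples trailing time ``t``.
    """

    matrix: np.ndarray
    window: tuple[int, int]
    method: Method = "ridge"

    @property
    def anchor(self) -> int:
        return self.window[1]


@dataclass
class RLSState:
    """Running state of the recursive least-squares readout estimator."""

    W: np.ndarray  # (q, n)
    P: np.ndarray  # (n, n) gain matrix, symmetric positive definite
    gamma: float


@dataclass(frozen=True)
class WeightDelta:
    """Flattened readout difference anchored at time ``anchor``.

    The vector spans the data window ``[anchor - T_w, anchor + T_w)``: it
    contrasts the readout fitted just before ``anchor`` with the one fitted
    just after.
    """

    vector: np.ndarray  # (q * n,)
    anchor: int
    T_w: int


def fit_window_readout(
    states: np.ndarray, targets: np.ndarray, spec: RidgeSpec = RidgeSpec()
) -> np.ndarray:
    """Exact ridge minimiser of ``sum_i ||W r_i - x_i||^2 + beta ||W||_F^2``.

    Parameters
    ----------
    states:
        Window of reservoir states, shape ``(T_w, n)``.
    targets:
        Matching window of observations, shape ``(T_w, q)``.

    Returns
    -------
    ndarray of shape ``(q, n)``
        Solved via the regularised normal equations
        ``(R^T R + beta I) W^T = R^T X``.
    """
    R = np.asarray(states, dtype=float)
    X = np.asarray(targets, dtype=float)
    if R.ndim != 2 or X.ndim != 2 or R.shape[0] != X.shape[0]:
        raise ValueError(f"incompatible window shapes {R.shape} and {X.shape}")
    if R.shape[0] < 2:
        raise ValueError("window must contain at least 2 samples")
    if not (np.isfinite(R).all() and np.isfinite(X).all()):
        raise ValueError("non-finite values in regression window")
    n = R.shape[1]
    G = R.T @ R + spec.beta * np.eye(n)
    if spec.beta > 0:
        Wt = linalg.solve(G, R.T @ X, assume_a="pos")
    else:  # unregularised: fall back to least squares for rank safety
        Wt = np.linalg.lstsq(R, X, rcond=None)[0]
    return Wt.T


def rls_init(n: int, q: int, gamma: float = 0.01) -> RLSState:
    """Fresh RLS state: zero weights, gain ``P_0 = I / gamma``."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return RLSState(W=np.zeros((q, n)), P=np.eye(n) / gamma, gamma=gamma)


def rls_step(state: RLSState, r: np.ndarray, x: np.ndarray) -> RLSState:
    """One rank-one recursive least-squares update.

        e   = x - W r
        W' = W + e (r^T P) / (1 + r^T P r)
        P' = P - (P r)(r^T P) / (1 + r^T P r)

    ``P`` stays symmetric positive definite.  The input state is not
    modified; a new state is returned.
    """
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.isfinite(r).all() and np.isfinite(x).all()):
        raise ValueError("non-finite RLS inputs")
    Pr = state.P @ r
    denom = 1.0 + r @ Pr
    e = x - state.W @ r
    W = state.W + np.outer(e, Pr) / denom
    P = state.P - np.outer(Pr, Pr) / denom
    P = 0.5 * (P + P.T)  # guard symmetry against roundoff
    return RLSState(W=W, P=P, gamma=state.gamma)


def _rls_window(states: np.ndarray, targets: np.ndarray, gamma: float) -> np.ndarray:
    st = rls_init(states.shape[1], targets.shape[1], gamma)
    for r, x in zip(states, targets):
        st = rls_step(st, r, x)
    return st.W


def sliding_weights(
    states: StateSequence | np.ndarray,
    X: np.ndarray,
    T_w: int,
    stride: int,
    spec: RidgeSpec = RidgeSpec(),
    method: Method = "ridge",
    washout: int | None = None,
) -> list[ReadoutWeights]:
    """Fit one readout per sliding window along the series.

    Anchors sit at ``t = washout + T_w, washout + T_w + stride, ...`` and
    each readout is fitted on the trailing half-open window
    ``[t - T_w, t)`` of (state, observation) pairs.  With ``method="rls"``
    the estimator restarts from ``P_0 = I/gamma`` (``gamma = beta``) at
    each window start, which reproduces the ridge solution exactly.
    """
    if isinstance(states, StateSequence):
        if washout is None:
            washout = states.washout
        S = states.states
    else:
        S = np.asarray(states, dtype=float)
        if washout is None:
            washout = 0
    X = np.asarray(X, dtype=float)
    T = S.shape[0]
    if X.shape[0] != T:
        raise ValueError("states and series must have equal length")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if T_w + washout > T:
        raise ValueError(
            f"series of length {T} too short for window {T_w} + washout {washout}")
    out: list[ReadoutWeights] = []
    for t in range(washout + T_w, T + 1, stride):
        Rw = S[t - T_w : t]
        Xw = X[t - T_w : t]
        if method == "ridge":
            W = fit_window_readout(Rw, Xw, spec)
        elif method == "rls":
            W = _rls_window(Rw, Xw, gamma=spec.beta if spec.beta > 0 else 0.01)
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append(ReadoutWeights(matrix=W, window=(t - T_w, t), method=method))
    return out


def weight_deltas(weights: Sequence[ReadoutWeights], T_w: int) -> list[WeightDelta]:
    """Form ``dW_out(i) = W_out(i + T_w) - W_out(i)`` along the anchor grid.

    The weight sequence's stride must divide ``T_w`` so every anchor has
    its partner window ``T_w`` later on the same grid.
    """
    by_anchor = {w.anchor: w for w in weights}
    out: list[WeightDelta] = []
    for w in weights:
        partner = by_anchor.get(w.anchor + T_w)
        if partner is None:
            continue
        delta = (partner.matrix - w.matrix).ravel(order="C")
        out.append(WeightDelta(vector=delta, anchor=w.anchor, T_w=T_w))
    if not out and len(weights) > 1:
        anchors = sorted(by_anchor)
        stride = anchors[1] - anchors[0]
        raise ValueError(
            f"no anchor has a partner {T_w} steps later; stride {stride} "
            f"must divide T_w={T_w}")
    return out
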