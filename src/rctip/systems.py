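"""Synthetic testbed generators with mid-run parameter or structure switches.

Three chaotic systems of increasing dimension serve as benchmarks:

* **Lorenz63** (3-D): the classical atmospheric-convection model with the
  Prandtl number ``sigma`` switching between two values at ``t_p``.
* **Coupled Lorenz network** (3m-D): ``m`` Lorenz oscillators coupled
  through a binary adjacency matrix via their ``y`` variables; at ``t_p``
  the adjacency matrix is rewired or densified.
* **Kuramoto-Sivashinsky** (spatially extended): the spatiotemporally
  chaotic fourth-order PDE with a spatial forcing ``mu * cos(2 pi x /
  lambda)`` whose amplitude ``mu`` switches at ``t_p``.

All ODE systems use fixed-step RK4; the PDE uses a periodic pseudospectral
discretisation with fourth-order exponential time differencing (ETDRK4).
Every generated run records its ground truth (switch index, parameter
values before/after, signed intensity change) so the detection pipeline is
fully testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "MultivariateSeries",
    "LabeledRun",
    "simulate_lorenz63_switch",
    "simulate_coupled_lorenz",
    "simulate_ks_switch",
    "random_adjacency",
    "rewire_random",
    "densify",
    "subsample_channels",
    "add_observation_noise",
    "make_benchmark",
]


@dataclass(frozen=True)
class Truth:
    """Ground-truth change metadata of a generated run.

    ``params`` carries auxiliary generator constants that do not change at
    the switch (e.g. the per-oscillator scale factors of the coupled
    network) so a run can be re-integrated exactly from its record.
    """

    t_p: int | None
    before: object = None
    after: object = None
    delta_h: float = 0.0
    params: object = None


@dataclass(frozen=True)
class MultivariateSeries:
    """A regularly sampled multivariate series with optional ground truth."""

    values: np.ndarray  # (T, q)
    dt: float
    truth: Truth | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError(f"series values must be 2-D (T, q), got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("series contains non-finite values")
        if self.truth is not None and self.truth.t_p is not None:
            if not 0 <= self.truth.t_p < v.shape[0]:
                raise ValueError("truth.t_p outside series length")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabeledRun:
    """A training/test run with its true change time and intensity."""

    series: MultivariateSeries
    t_p: int | None
    delta_h: float = 0.0


# ---------------------------------------------------------------------------
# Lorenz63


def _rk4(f: Callable, y: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _lorenz_rhs(sigma: float, rho: float = 28.0, zeta: float = 8.0 / 3.0):
    def f(y: np.ndarray) -> np.ndarray:
        x, yy, z = y
        return np.array([sigma * (yy - x), rho * x - yy - x * z, x * yy - zeta * z])

    return f


def simulate_lorenz63_switch(
    sigma_1: float,
    sigma_2: float,
    t_p: int | None,
    length: int,
    dt: float = 0.02,
    rho: float = 28.0,
    zeta: float = 8.0 / 3.0,
    init: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MultivariateSeries:
    """Integrate Lorenz63 with ``sigma`` switching ``sigma_1 -> sigma_2`` at ``t_p``.

    One RK4 step per output sample (sampling interval = ``dt``).  Initial
    values default to uniform draws in [0, 1].  Gaussian observation noise
    of standard deviation ``noise_sd`` is added after integration.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.0, 1.0, size=3) if init is None else np.asarray(init, float)
    f1, f2 = _lorenz_rhs(sigma_1, rho, zeta), _lorenz_rhs(sigma_2, rho, zeta)
    out = np.empty((length, 3))
    out[0] = y
    switch = length if t_p is None else t_p
    for i in range(1, length):
        y = _rk4(f1 if i <= switch else f2, y, dt)
        out[i] = y
    truth = Truth(t_p=t_p, before=sigma_1, after=sigma_2,
                  delta_h=(sigma_2 - sigma_1) if t_p is not None else 0.0)
    series = MultivariateSeries(values=out, dt=dt, truth=truth)
    if noise_sd > 0:
        series = add_observation_noise(series, noise_sd, rng)
    return series


# ---------------------------------------------------------------------------
# Coupled Lorenz network


def random_adjacency(m: int, n_edges: int, rng: np.random.Generator) -> np.ndarray:
    """Random directed 0-1 adjacency matrix with ``n_edges`` off-diagonal ones."""
    slots = [(i, j) for i in range(m) for j in range(m) if i != j]
    if n_edges > len(slots):
        raise ValueError(f"at most {len(slots)} edges fit in a {m}-node graph")
    A = np.zeros((m, m), dtype=int)
    for k in rng.choice(len(slots), size=n_edges, replace=False):
        A[slots[k]] = 1
    return A


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency matrix must be 0-1 valued")
    if np.diag(A).any():
        raise ValueError("adjacency matrix must have zero diagonal")
    return A.astype(float)


def rewire_random(A: np.ndarray, seed) -> np.ndarray:
    """Random reconnection: same edge count, different endpoint set."""
    A = np.asarray(A)
    _check_adjacency(A)
    m = A.shape[0]
    n_edges = int(A.sum())
    if n_edges == 0 or m < 3:
        raise ValueError("rewiring needs >= 1 edge and >= 3 nodes")
    rng = np.random.default_rng(seed)
    while True:
        B = random_adjacency(m, n_edges, rng)
        if not np.array_equal(B, A):
            return B


def densify(A: np.ndarray, added_edges: int, seed) -> np.ndarray:
    """Add ``added_edges`` new off-diagonal edges to a 0-1 adjacency matrix."""
    A = np.asarray(A)
    _check_adjacency(A)
    m = A.shape[0]
    free = [(i, j) for i in range(m) for j in range(m) if i != j and A[i, j] == 0]
    if added_edges > len(free):
        raise ValueError(f"cannot add {added_edges} edges; only {len(free)} slots free")
    rng = np.random.default_rng(seed)
    B = A.copy()
    for k in rng.choice(len(free), size=added_edges, replace=False):
        B[free[k]] = 1
    return B


def _coupled_rhs(A: np.ndarray, c: float, h: np.ndarray):
    rho = 28.0 * (1.0 + h)

    def f(y: np.ndarray) -> np.ndarray:
        x, yy, z = y[0], y[1], y[2]
        coupling = c * (A @ yy - A.sum(axis=1) * yy)
        dx = -10.0 * (x - yy) + coupling
        dy = rho * x - yy - x * z
        dz = -(8.0 / 3.0) * z + x * yy
        return np.stack([dx, dy, dz])

    return f


def simulate_coupled_lorenz(
    A_before: np.ndarray,
    A_after: np.ndarray,
    t_p: int | None,
    length: int,
    c: float = 1.0,
    h: np.ndarray | None = None,
    m: int | None = None,
    dt: float = 0.002,
    sample_every: int = 6,
    init: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MultivariateSeries:
    """Integrate ``m`` diffusively y-coupled Lorenz oscillators.

    Oscillator ``k`` obeys

        dx_k = -10 (x_k - y_k) + c sum_l a_kl (y_l - y_k)
        dy_k = 28 (1 + h_k) x_k - y_k - x_k z_k
        dz_k = -8/3 z_k + x_k y_k

    with the adjacency matrix switching ``A_before -> A_after`` at output
    sample ``t_p``.  The trajectory is integrated at step ``dt`` and
    subsampled every ``sample_every`` steps; channels are ordered
    ``(x_1, y_1, z_1, ..., x_m, y_m, z_m)``.  ``h_k`` rescales each
    oscillator (default uniform in [-0.2, 0.2]); inits uniform [-10, 10].
    """
    Ab = _check_adjacency(A_before)
    Aa = _check_adjacency(A_after)
    if Ab.shape != Aa.shape:
        raise ValueError("before/after adjacency shapes differ")
    m = Ab.shape[0] if m is None else m
    if Ab.shape != (m, m):
        raise ValueError(f"adjacency must be {m} x {m}")
    rng = np.random.default_rng(seed)
    if h is None:
        h = rng.uniform(-0.2, 0.2, size=m)
    h = np.asarray(h, float)
    if h.shape != (m,):
        raise ValueError(f"h must have length {m}")
    if init is None:
        y = rng.uniform(-10.0, 10.0, size=(3, m))
    else:
        y = np.asarray(init, float).reshape(3, m)
    f1, f2 = _coupled_rhs(Ab, c, h), _coupled_rhs(Aa, c, h)
    out = np.empty((length, 3 * m))
    out[0] = y.T.ravel()
    switch = length if t_p is None else t_p
    for i in range(1, length):
        f = f1 if i <= switch else f2
        for _ in range(sample_every):
            y = _rk4(f, y, dt)
        out[i] = y.T.ravel()
    truth = Truth(t_p=t_p, before=np.asarray(A_before), after=np.asarray(A_after),
                  delta_h=0.0)
    series = MultivariateSeries(values=out, dt=dt * sample_every, truth=truth)
    if noise_sd > 0:
        series = add_observation_noise(series, noise_sd, rng)
    return series


# ---------------------------------------------------------------------------
# Kuramoto-Sivashinsky with spatial forcing


class BlowUpError(RuntimeError):
    """The PDE field became non-finite during integration."""


def _etdrk4_coeffs(Lop: np.ndarray, dt: float, M: int = 32):
    """Kassam-Trefethen contour-integral ETDRK4 coefficients for diagonal L."""
    E = np.exp(dt * Lop)
    E2 = np.exp(dt * Lop / 2.0)
    r = np.exp(1j * np.pi * (np.arange(1, M + 1) - 0.5) / M)
    LR = dt * Lop[:, None] + r[None, :]
    Q = dt * np.real(np.mean((np.exp(LR / 2.0) - 1.0) / LR, axis=1))
    f1 = dt * np.real(np.mean(
        (-4.0 - LR + np.exp(LR) * (4.0 - 3.0 * LR + LR ** 2)) / LR ** 3, axis=1))
    f2 = dt * np.real(np.mean(
        (2.0 + LR + np.exp(LR) * (-2.0 + LR)) / LR ** 3, axis=1))
    f3 = dt * np.real(np.mean(
        (-4.0 - 3.0 * LR - LR ** 2 + np.exp(LR) * (4.0 - LR)) / LR ** 3, axis=1))
    return E, E2, Q, f1, f2, f3


def _ks_integrate(
    v: np.ndarray,
    n_steps: int,
    coeffs,
    g: np.ndarray,
    f_hat: np.ndarray,
    store_every: int = 0,
    out: np.ndarray | None = None,
    out_offset: int = 0,
    Q: int = 0,
) -> np.ndarray:
    """Advance the rfft field ``v`` by ``n_steps`` ETDRK4 steps.

    ``g = -0.5 i k`` (dealiased) carries the ``-u u_x`` term; ``f_hat`` is
    the rfft of the static spatial forcing, treated as part of the
    nonlinear term.  If ``store_every`` > 0, writes the physical field into
    ``out`` every that many steps starting at ``out_offset``.
    """
    E, E2, Qc, f1, f2, f3 = coeffs

    def N(vh):
        u = np.fft.irfft(vh, n=Q)
        return g * np.fft.rfft(u * u) + f_hat

    j = out_offset
    for s in range(n_steps):
        Nv = N(v)
        a = E2 * v + Qc * Nv
        Na = N(a)
        b = E2 * v + Qc * Na
        Nb = N(b)
        cc = E2 * a + Qc * (2.0 * Nb - Nv)
        Nc = N(cc)
        v = E * v + Nv * f1 + 2.0 * (Na + Nb) * f2 + Nc * f3
        if store_every and (s + 1) % store_every == 0:
            u = np.fft.irfft(v, n=Q)
            if not np.isfinite(u).all():
                raise BlowUpError(f"KS field blew up at inner step {s + 1}")
            out[j] = u
            j += 1
    return v


def simulate_ks_switch(
    mu_1: float,
    mu_2: float,
    t_p: int | None,
    length: int,
    lam: float = 12.0,
    L: float = 60.0,
    Q: int = 128,
    dt: float = 0.01,
    sample_every: int = 20,
    transient: float = 50.0,
    init: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MultivariateSeries:
    """Integrate the forced Kuramoto-Sivashinsky equation

        u_t = -u u_x - u_xx - u_xxxx + mu cos(2 pi x / lambda)

    on a periodic domain of length ``L`` (which must be a multiple of the
    forcing wavelength ``lambda``) discretised on ``Q`` grid points, with
    ``mu`` switching ``mu_1 -> mu_2`` at output sample ``t_p``.  ETDRK4
    pseudospectral stepping at ``dt``, sampled every ``sample_every``
    steps.  A transient of ``transient`` time units under ``mu_1`` is
    discarded so sampling starts from developed spatiotemporal chaos;
    ``init`` defaults to a small-amplitude smooth random field.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ratio = L / lam
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"domain length L={L} must be a multiple of lambda={lam}")
    rng = np.random.default_rng(seed)
    x = L * np.arange(Q) / Q
    if init is None:
        u = np.zeros(Q)
        for mode in range(1, 4):
            u += (rng.normal(0.0, 0.1) * np.cos(2 * np.pi * mode * x / L)
                  + rng.normal(0.0, 0.1) * np.sin(2 * np.pi * mode * x / L))
    else:
        u = np.asarray(init, float)
        if u.shape != (Q,):
            raise ValueError(f"init must have shape ({Q},)")
    k = 2.0 * np.pi * np.fft.rfftfreq(Q, d=L / Q)
    Lop = k ** 2 - k ** 4
    # 2/3-rule dealiasing folded into the nonlinear multiplier
    g = -0.5j * k
    g[k > (2.0 / 3.0) * k.max()] = 0.0
    coeffs = _etdrk4_coeffs(Lop, dt)
    fhat_1 = np.fft.rfft(mu_1 * np.cos(2 * np.pi * x / lam))
    fhat_2 = np.fft.rfft(mu_2 * np.cos(2 * np.pi * x / lam))
    v = np.fft.rfft(u)
    n_trans = int(round(transient / dt))
    v = _ks_integrate(v, n_trans, coeffs, g, fhat_1, Q=Q)
    out = np.empty((length, Q))
    u0 = np.fft.irfft(v, n=Q)
    if not np.isfinite(u0).all():
        raise BlowUpError("KS field blew up during the transient")
    out[0] = u0
    switch = length if t_p is None else t_p
    n1 = min(switch, length - 1)
    v = _ks_integrate(v, n1 * sample_every, coeffs, g, fhat_1,
                      store_every=sample_every, out=out, out_offset=1, Q=Q)
    if n1 < length - 1:
        v = _ks_integrate(v, (length - 1 - n1) * sample_every, coeffs, g, fhat_2,
                          store_every=sample_every, out=out, out_offset=1 + n1, Q=Q)
    truth = Truth(t_p=t_p, before=mu_1, after=mu_2,
                  delta_h=(mu_2 - mu_1) if t_p is not None else 0.0)
    series = MultivariateSeries(values=out, dt=dt * sample_every, truth=truth)
    if noise_sd > 0:
        series = add_observation_noise(series, noise_sd, rng)
    return series


# ---------------------------------------------------------------------------
# Post-processing and benchmark batching


def subsample_channels(series: MultivariateSeries, q_sub: int) -> MultivariateSeries:
    """Keep every ``(q / q_sub)``-th spatial channel (``q_sub`` must divide ``q``)."""
    q = series.q
    if q_sub < 1 or q % q_sub != 0:
        raise ValueError(f"q'={q_sub} must divide the channel count {q}")
    step = q // q_sub
    return replace(series, values=series.values[:, ::step])


def add_observation_noise(
    series: MultivariateSeries, noise_sd: float, seed
) -> MultivariateSeries:
    """Add i.i.d. Gaussian observation noise N(0, noise_sd^2) per entry."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd == 0:
        return series
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = series.values + rng.normal(0.0, noise_sd, size=series.values.shape)
    return replace(series, values=noisy)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Generation settings of one benchmark batch (training or test role)."""

    system: str  # lorenz63 | coupled_lorenz | ks
    n_runs: int
    role: str  # train | test
    length: int
    T_w: int = 300
    noise_sd: float = 0.0
    seed: int = 0
    washout: int = 50
    options: dict = field(default_factory=dict)


def _t_p_band(spec: BenchmarkSpec) -> tuple[int, int]:
    """Admissible switch-placement band for the role.

    Training switches must leave a full window on both sides
    (``[T_w, N - T_w]``, tightened by the reservoir washout on the left);
    test switches must leave a full scan span (``[2 T_w, N - 2 T_w]``).
    """
    if spec.role == "train":
        lo, hi = spec.T_w + spec.washout, spec.length - spec.T_w
    elif spec.role == "test":
        lo, hi = 2 * spec.T_w, spec.length - 2 * spec.T_w
    else:
        raise ValueError(f"role must be 'train' or 'test', got {spec.role!r}")
    if lo > hi:
        raise ValueError(
            f"run length {spec.length} cannot host a switch for role {spec.role}")
    return lo, hi


# --- batched integrators -----------------------------------------------------
# make_benchmark integrates all runs of a batch simultaneously (state arrays
# carry a leading run axis; each run switches its own parameters at its own
# t_p).  This matches the per-run simulators' dynamics exactly and amortises
# the Python stepping overhead across the batch.


def _lorenz63_batch(s1, s2, t_ps, length, dt, inits,
                    rho=28.0, zeta=8.0 / 3.0) -> np.ndarray:
    R = len(t_ps)
    y = np.array(inits, dtype=float)  # (R, 3)
    out = np.empty((R, length, 3))
    out[:, 0] = y

    def f(y, sigma):
        x, yy, z = y[:, 0], y[:, 1], y[:, 2]
        return np.stack([sigma * (yy - x), rho * x - yy - x * z,
                         x * yy - zeta * z], axis=1)

    for i in range(1, length):
        sigma = np.where(i <= t_ps, s1, s2)
        k1 = f(y, sigma)
        k2 = f(y + 0.5 * dt * k1, sigma)
        k3 = f(y + 0.5 * dt * k2, sigma)
        k4 = f(y + dt * k3, sigma)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[:, i] = y
    return out


def _coupled_batch(A0, A1, t_ps, length, c, h, dt, sample_every,
                   inits) -> np.ndarray:
    R, m = h.shape
    y = np.array(inits, dtype=float)  # (R, 3, m)
    rho = 28.0 * (1.0 + h)
    out = np.empty((R, length, 3 * m))
    out[:, 0] = y.transpose(0, 2, 1).reshape(R, 3 * m)
    deg0, deg1 = A0.sum(axis=2), A1.sum(axis=2)

    def f(y, A, deg):
        x, yy, z = y[:, 0], y[:, 1], y[:, 2]
        coupling = c * (np.einsum("rkl,rl->rk", A, yy) - deg * yy)
        dx = -10.0 * (x - yy) + coupling
        dy = rho * x - yy - x * z
        dz = -(8.0 / 3.0) * z + x * yy
        return np.stack([dx, dy, dz], axis=1)

    for i in range(1, length):
        pre = (i <= t_ps)
        A = np.where(pre[:, None, None], A0, A1)
        deg = np.where(pre[:, None], deg0, deg1)
        for _ in range(sample_every):
            k1 = f(y, A, deg)
            k2 = f(y + 0.5 * dt * k1, A, deg)
            k3 = f(y + 0.5 * dt * k2, A, deg)
            k4 = f(y + dt * k3, A, deg)
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[:, i] = y.transpose(0, 2, 1).reshape(R, 3 * m)
    return out


def _ks_batch(mu1, mu2, t_ps, length, lam, L, Q, dt, sample_every,
              transient, inits) -> np.ndarray:
    R = len(t_ps)
    x = L * np.arange(Q) / Q
    k = 2.0 * np.pi * np.fft.rfftfreq(Q, d=L / Q)
    Lop = k ** 2 - k ** 4
    g = -0.5j * k
    g[k > (2.0 / 3.0) * k.max()] = 0.0
    coeffs = _etdrk4_coeffs(Lop, dt)
    E, E2, Qc, f1, f2, f3 = coeffs
    base = np.fft.rfft(np.cos(2 * np.pi * x / lam))
    fh1 = mu1[:, None] * base[None, :]
    fh2 = mu2[:, None] * base[None, :]
    v = np.fft.rfft(np.array(inits, dtype=float), axis=1)  # (R, K)

    def step(v, fh, n_steps):
        def N(vh):
            u = np.fft.irfft(vh, n=Q, axis=1)
            return g * np.fft.rfft(u * u, axis=1) + fh

        for _ in range(n_steps):
            Nv = N(v)
            a = E2 * v + Qc * Nv
            Na = N(a)
            b = E2 * v + Qc * Na
            Nb = N(b)
            cc = E2 * a + Qc * (2.0 * Nb - Nv)
            Nc = N(cc)
            v = E * v + Nv * f1 + 2.0 * (Na + Nb) * f2 + Nc * f3
        return v

    v = step(v, fh1, int(round(transient / dt)))
    out = np.empty((R, length, Q))
    u = np.fft.irfft(v, n=Q, axis=1)
    if not np.isfinite(u).all():
        raise BlowUpError("KS field blew up during the transient")
    out[:, 0] = u
    for i in range(1, length):
        fh = np.where((i <= t_ps)[:, None], fh1, fh2)
        v = step(v, fh, sample_every)
        u = np.fft.irfft(v, n=Q, axis=1)
        if not np.isfinite(u).all():
            raise BlowUpError(f"KS field blew up at sample {i}")
        out[:, i] = u
    return out


def make_benchmark(spec: BenchmarkSpec) -> list[LabeledRun]:
    """Generate ``n_runs`` seeded labeled runs for one testbed.

    Every stochastic draw (switch time, parameter values, initial
    conditions, observation noise) descends from ``spec.seed`` through a
    spawned per-run seed sequence, so batches regenerate exactly.  All
    runs of the batch are integrated simultaneously (vectorised over the
    run axis) with the same dynamics as the single-run simulators.
    """
    lo, hi = _t_p_band(spec)
    root = np.random.SeedSequence(spec.seed)
    run_seeds = root.spawn(spec.n_runs)
    opts = spec.options
    R = spec.n_runs
    t_ps = np.empty(R, dtype=int)
    sim_rngs = []
    if spec.system == "lorenz63":
        dt = opts.get("dt", 0.02)
        s1 = np.empty(R)
        s2 = np.empty(R)
        inits = np.empty((R, 3))
        sigma_delta = opts.get("sigma_delta")  # fixed |sigma_2 - sigma_1|
        for j, ss in enumerate(run_seeds):
            rng = np.random.default_rng(ss)
            t_ps[j] = rng.integers(lo, hi + 1)
            s_lo, s_hi = opts.get("sigma_range", (5.0, 15.0))
            if sigma_delta is None:
                s1[j], s2[j] = rng.uniform(s_lo, s_hi, size=2)
            else:
                a = rng.uniform(s_lo, s_hi - sigma_delta)
                b = a + sigma_delta
                s1[j], s2[j] = (a, b) if rng.random() < 0.5 else (b, a)
            srng = np.random.default_rng(ss.spawn(1)[0])
            inits[j] = srng.uniform(0.0, 1.0, size=3)
            sim_rngs.append(srng)
        values = _lorenz63_batch(s1, s2, t_ps, spec.length, dt, inits)
        truths = [Truth(t_p=int(t_ps[j]), before=s1[j], after=s2[j],
                        delta_h=s2[j] - s1[j]) for j in range(R)]
        dt_eff = dt
    elif spec.system == "coupled_lorenz":
        m = opts.get("m", 5)
        n_edges = opts.get("n_edges", 6)
        change = opts.get("change", "rewire")
        dt = opts.get("dt", 0.002)
        sample_every = opts.get("sample_every", 6)
        A0 = np.empty((R, m, m))
        A1 = np.empty((R, m, m))
        h = np.empty((R, m))
        inits = np.empty((R, 3, m))
        for j, ss in enumerate(run_seeds):
            rng = np.random.default_rng(ss)
            t_ps[j] = rng.integers(lo, hi + 1)
            a0 = random_adjacency(m, n_edges, rng)
            if change == "rewire":
                a1 = rewire_random(a0, rng)
            elif change == "densify":
                a1 = densify(a0, opts.get("added_edges", 8), rng)
            else:
                raise ValueError(f"unknown structural change {change!r}")
            A0[j], A1[j] = a0, a1
            srng = np.random.default_rng(ss.spawn(1)[0])
            h[j] = srng.uniform(-0.2, 0.2, size=m)
            inits[j] = srng.uniform(-10.0, 10.0, size=(3, m))
            sim_rngs.append(srng)
        values = _coupled_batch(A0, A1, t_ps, spec.length,
                                opts.get("c", 1.0), h, dt, sample_every, inits)
        truths = [Truth(t_p=int(t_ps[j]), before=A0[j].astype(int),
                        after=A1[j].astype(int), delta_h=0.0,
                        params={"h": h[j], "c": opts.get("c", 1.0)})
                  for j in range(R)]
        dt_eff = dt * sample_every
    elif spec.system == "ks":
        lam, L = opts.get("lam", 12.0), opts.get("L", 60.0)
        Q, dt = opts.get("Q", 128), opts.get("dt", 0.01)
        sample_every = opts.get("sample_every", 20)
        transient = opts.get("transient", 50.0)
        mu1 = np.empty(R)
        mu2 = np.empty(R)
        inits = np.zeros((R, Q))
        x = L * np.arange(Q) / Q
        for j, ss in enumerate(run_seeds):
            rng = np.random.default_rng(ss)
            t_ps[j] = rng.integers(lo, hi + 1)
            mu1[j], mu2[j] = rng.uniform(*opts.get("mu_range", (-1.0, 1.0)),
                                         size=2)
            srng = np.random.default_rng(ss.spawn(1)[0])
            for mode in range(1, 4):
                inits[j] += (srng.normal(0.0, 0.1) * np.cos(2 * np.pi * mode * x / L)
                             + srng.normal(0.0, 0.1) * np.sin(2 * np.pi * mode * x / L))
            sim_rngs.append(srng)
        values = _ks_batch(mu1, mu2, t_ps, spec.length, lam, L, Q,
                           dt, sample_every, transient, inits)
        truths = [Truth(t_p=int(t_ps[j]), before=mu1[j], after=mu2[j],
                        delta_h=mu2[j] - mu1[j]) for j in range(R)]
        dt_eff = dt * sample_every
    else:
        raise ValueError(f"unknown system {spec.system!r}")

    runs: list[LabeledRun] = []
    q_sub = opts.get("q_sub", 32) if spec.system == "ks" else None
    for j in range(R):
        series = MultivariateSeries(values=values[j], dt=dt_eff, truth=truths[j])
        if spec.noise_sd > 0:
            series = add_observation_noise(series, spec.noise_sd, sim_rngs[j])
        if q_sub:
            series = subsample_channels(series, q_sub)
        runs.append(LabeledRun(series=series, t_p=int(t_ps[j]),
                               delta_h=series.truth.delta_h))
    return runs
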