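"""Benchmark harness, error metrics, and detection-assisted forecasting.

The harness wires the full pipeline — generate labeled runs, extract
readout-difference features, fit the detector, scan every test run, and
locate the peaks — and reports the mean absolute position error (in
sample indices) and, for the regression task, the mean absolute intensity
error.  Because the sampling step differs per testbed, position errors
are always quoted in samples, not time units.

The forecasting utilities close the reservoir loop (the readout output is
fed back as the next input) to demonstrate that a detected tipping point
improves prediction: training only on the post-change segment beats
training on the whole contaminated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .detector import (
    Detection,
    DetectorModel,
    build_data_features,
    build_training_set,
    ensemble_mean_scan,
    fit_scaler,
    locate_tipping,
    scan,
    train_detector,
)
from .readout import RidgeSpec, fit_window_readout
from .reservoir import Reservoir, ReservoirParams, build_reservoir, evolve
from .systems import BenchmarkSpec, LabeledRun, make_benchmark

__all__ = [
    "position_error",
    "intensity_error",
    "benchmark_preset",
    "BenchmarkConfig",
    "ExperimentReport",
    "run_benchmark",
    "ForecastResult",
    "forecast",
    "segmented_forecast_compare",
    "tune_correlation_study",
]


def position_error(
    detections: Sequence[Detection | int], truths: Sequence[int]
) -> tuple[float, np.ndarray]:
    """Mean and per-run absolute position errors |t_hat_p - t_p| in samples."""
    if len(detections) != len(truths):
        raise ValueError("one detection per truth required")
    t_hat = np.array([d.t_hat_p if isinstance(d, Detection) else d
                      for d in detections], dtype=float)
    errs = np.abs(t_hat - np.asarray(truths, dtype=float))
    return float(errs.mean()), errs


def intensity_error(
    detections: Sequence[Detection | float], truths: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Mean and per-run absolute intensity errors |dh_hat - dh| (signed compare)."""
    if len(detections) != len(truths):
        raise ValueError("one detection per truth required")
    dh_hat = np.array([d.delta_h_hat if isinstance(d, Detection) else d
                       for d in detections], dtype=float)
    errs = np.abs(dh_hat - np.asarray(truths, dtype=float))
    return float(errs.mean()), errs


# ---------------------------------------------------------------------------
# Full-pipeline benchmark


@dataclass
class BenchmarkConfig:
    """Everything one benchmark needs, fully seeded.

    ``feature_kind='raw_window'`` switches the detector to the DATA
    baselines (same labeling and scan, raw data-window features).
    ``ensemble`` trains one classifier per subsystem of ``ensemble_q``
    channels and averages their scan curves (the networked-system rule).
    """

    system: str = "lorenz63"
    task: str = "regression"
    n_train: int = 100
    n_test: int = 30
    train_length: int = 1000
    test_length: int = 5000
    T_w: int = 300
    stride: int = 10
    noise_sd: float = 0.0
    feature_kind: str = "weight_delta"
    ensemble: bool = False
    ensemble_q: int = 3
    negatives_per_run: int = 50
    reservoir: ReservoirParams = field(default_factory=lambda: ReservoirParams(n=20))
    ridge_beta: float = 0.1
    detector_family: str | None = None
    detector_hyper: dict = field(default_factory=dict)
    seed: int = 0
    threshold: float | None = None
    matched_locator: bool = True
    subsystem_label_filter: bool = True
    system_options: dict = field(default_factory=dict)


@dataclass
class ExperimentReport:
    """Per-run and mean errors of one benchmark, plus its full config echo."""

    position_errors: np.ndarray
    mean_position_error: float
    intensity_errors: np.ndarray | None
    mean_intensity_error: float | None
    detections: list[Detection]
    truths_t_p: list[int]
    truths_delta_h: list[float]
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_position_error": self.mean_position_error,
            "mean_intensity_error": self.mean_intensity_error,
            "position_errors": [float(e) for e in self.position_errors],
            "intensity_errors": None if self.intensity_errors is None
            else [float(e) for e in self.intensity_errors],
            "t_hat_p": [d.t_hat_p for d in self.detections],
            "t_p": self.truths_t_p,
            "config": self.config,
            "seed": self.seed,
        }


def _train_models(
    cfg: BenchmarkConfig, train_runs: Sequence[LabeledRun], res: Reservoir,
    spec: RidgeSpec, seeds: np.random.SeedSequence,
) -> list[DetectorModel]:
    """One detector, or one per subsystem when ``cfg.ensemble`` is set."""
    s_feat, s_model = (int(s.generate_state(1)[0] % 2**31) for s in seeds.spawn(2))
    scaler = fit_scaler(train_runs)
    models: list[DetectorModel] = []
    if cfg.ensemble:
        q_tot = train_runs[0].series.q
        n_sub = q_tot // cfg.ensemble_q
        for k in range(n_sub):
            sl = slice(k * cfg.ensemble_q, (k + 1) * cfg.ensemble_q)
            runs_k = list(train_runs)
            if cfg.subsystem_label_filter:
                # positives only from runs where subsystem k's own incoming
                # edges changed; unchanged rows would be labeled as changes
                kept = []
                for r in train_runs:
                    tr = r.series.truth
                    if (tr is not None and isinstance(tr.before, np.ndarray)
                            and np.asarray(tr.before).ndim == 2
                            and np.array_equal(np.asarray(tr.before)[k],
                                               np.asarray(tr.after)[k])):
                        continue
                    kept.append(r)
                if kept:
                    runs_k = kept
            fs = build_training_set(
                runs_k, res, cfg.T_w, spec, cfg.task,
                negatives_per_run=cfg.negatives_per_run,
                seed=s_feat + k, channel_slice=sl, scaler=scaler)
            models.append(train_detector(fs, cfg.detector_family, seed=s_model + k,
                                         T_w=cfg.T_w, scaler=scaler.narrow(sl),
                                         **dict(cfg.detector_hyper)))
    elif cfg.feature_kind == "raw_window":
        fs = build_data_features(
            train_runs, cfg.T_w, cfg.task,
            negatives_per_run=cfg.negatives_per_run, seed=s_feat,
            washout=res.washout, scaler=scaler)
        models.append(train_detector(fs, cfg.detector_family, seed=s_model,
                                     feature_kind="raw_window", T_w=cfg.T_w,
                                     scaler=scaler, **dict(cfg.detector_hyper)))
    else:
        fs = build_training_set(
            train_runs, res, cfg.T_w, spec, cfg.task,
            negatives_per_run=cfg.negatives_per_run, seed=s_feat, scaler=scaler)
        models.append(train_detector(fs, cfg.detector_family, seed=s_model,
                                     T_w=cfg.T_w, scaler=scaler,
                                     **dict(cfg.detector_hyper)))
    return models


def _detect_run(
    cfg: BenchmarkConfig, run: LabeledRun, res: Reservoir,
    models: Sequence[DetectorModel], spec: RidgeSpec,
) -> Detection:
    from dataclasses import replace as _replace

    if cfg.ensemble:
        curves = []
        for k, model in enumerate(models):
            sl = slice(k * cfg.ensemble_q, (k + 1) * cfg.ensemble_q)
            sub = _replace(run.series, values=run.series.values[:, sl])
            curves.append(scan(sub, res, model, cfg.T_w, cfg.stride, spec))
        curve = ensemble_mean_scan(curves)
    else:
        curve = scan(run.series, res, models[0], cfg.T_w, cfg.stride, spec)
    bump = (2 * cfg.T_w // cfg.stride + 1) if cfg.matched_locator else None
    return locate_tipping(curve, threshold=cfg.threshold, bump_span=bump,
                          refine_width=cfg.T_w // 2)


def run_benchmark(cfg: BenchmarkConfig) -> ExperimentReport:
    """Generate -> train -> scan -> locate -> metrics, fully seeded."""
    root = np.random.SeedSequence(cfg.seed)
    s_train, s_test, s_models = root.spawn(3)
    train_spec = BenchmarkSpec(
        system=cfg.system, n_runs=cfg.n_train, role="train",
        length=cfg.train_length, T_w=cfg.T_w, noise_sd=cfg.noise_sd,
        seed=int(s_train.generate_state(1)[0] % 2**31),
        washout=cfg.reservoir.washout, options=dict(cfg.system_options))
    test_spec = BenchmarkSpec(
        system=cfg.system, n_runs=cfg.n_test, role="test",
        length=cfg.test_length, T_w=cfg.T_w, noise_sd=cfg.noise_sd,
        seed=int(s_test.generate_state(1)[0] % 2**31),
        washout=cfg.reservoir.washout, options=dict(cfg.system_options))
    train_runs = make_benchmark(train_spec)
    test_runs = make_benchmark(test_spec)

    q = cfg.ensemble_q if cfg.ensemble else train_runs[0].series.q
    res = build_reservoir(cfg.reservoir, q)
    spec = RidgeSpec(beta=cfg.ridge_beta)
    models = _train_models(cfg, train_runs, res, spec, s_models)

    detections = [_detect_run(cfg, run, res, models, spec) for run in test_runs]
    truths_tp = [run.t_p for run in test_runs]
    mean_pos, pos_errs = position_error(detections, truths_tp)
    truths_dh = [run.delta_h for run in test_runs]
    if cfg.task == "regression":
        mean_int, int_errs = intensity_error(detections, truths_dh)
    else:
        mean_int, int_errs = None, None
    cfg_echo = asdict(cfg)
    cfg_echo["reservoir"] = asdict(cfg.reservoir)
    return ExperimentReport(
        position_errors=pos_errs, mean_position_error=mean_pos,
        intensity_errors=int_errs, mean_intensity_error=mean_int,
        detections=detections, truths_t_p=truths_tp, truths_delta_h=truths_dh,
        config=cfg_echo, seed=cfg.seed)


def benchmark_preset(system: str, task: str = "regression", scale: float = 1.0,
                     seed: int = 0, **overrides) -> BenchmarkConfig:
    """Study conditions for each testbed, shrinkable with ``scale``.

    Run counts follow each system's experimental design (500/100 runs for
    Lorenz63, 1000/100 for the coupled network, 2000/100 for the forced
    KS equation); series lengths, sampling steps and noise levels are the
    conditions of the corresponding benchmark.  ``scale`` shrinks only the
    run counts (desk-scale reproduction); every field can be overridden.
    """
    presets = {
        "lorenz63": dict(
            n_train=500, n_test=100, train_length=1000, test_length=5000,
            reservoir=ReservoirParams(n=20, input_scaling=0.1),
        ),
        "coupled_lorenz": dict(
            n_train=1000, n_test=100, train_length=1000, test_length=3000,
            task="classification", ensemble=True, ensemble_q=3,
            negatives_per_run=20,
            reservoir=ReservoirParams(n=20, input_scaling=0.1, leakage=0.5),
            system_options={"change": "rewire"},
        ),
        "ks": dict(
            n_train=2000, n_test=100, train_length=1000, test_length=2000,
            noise_sd=float(np.sqrt(0.2)), negatives_per_run=20,
            reservoir=ReservoirParams(n=20, input_scaling=0.1),
        ),
    }
    if system not in presets:
        raise ValueError(f"unknown system {system!r}")
    kw = dict(presets[system])
    kw.setdefault("task", task)
    if task != "regression":
        kw["task"] = task
    kw.update(overrides)
    kw["n_train"] = max(2, int(round(kw["n_train"] * scale)))
    kw["n_test"] = max(1, int(round(kw["n_test"] * scale)))
    return BenchmarkConfig(system=system, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Detection-assisted forecasting


@dataclass(frozen=True)
class ForecastResult:
    """A closed-loop forecast with its per-step error against the truth."""

    predicted: np.ndarray  # (steps, q)
    reference: np.ndarray | None
    per_step_rms: np.ndarray | None
    rms: float | None
    segment: tuple[int, int]


def forecast(
    segment: np.ndarray,
    res: Reservoir,
    spec: RidgeSpec,
    steps: int,
    reference: np.ndarray | None = None,
    segment_span: tuple[int, int] = (0, 0),
) -> ForecastResult:
    """Fit a readout on a training segment and run the reservoir closed-loop.

    The readout ``x_hat(i+1) = W_out r(i+1)`` is fitted one-step-ahead on
    the (washed-out) segment; prediction then feeds each output back as
    the next input for ``steps`` iterations.  If a reference continuation
    is given the RMS error per step (across channels) is reported.
    """
    X = np.asarray(segment, float)
    w = res.washout
    if X.shape[0] < w + max(res.q, 2) + 1:
        raise ValueError("training segment too short for washout and fitting")
    seq = evolve(res, X)
    S = seq.states
    W_out = fit_window_readout(S[w:], X[w:], spec)
    # closed loop from the end of the segment
    r = S[-1]
    # states[-1] has absorbed inputs up to X[-2]; absorb the final sample first
    l, A, W, b = res.leakage, res.A, res.W, res.bias
    r = (1 - l) * r + l * np.tanh(A @ r + W @ X[-1] + b)
    preds = np.empty((steps, X.shape[1]))
    for i in range(steps):
        x_hat = W_out @ r
        preds[i] = x_hat
        r = (1 - l) * r + l * np.tanh(A @ r + W @ x_hat + b)
    per_step = rms = None
    if reference is not None:
        ref = np.asarray(reference, float)[:steps]
        per_step = np.sqrt(np.mean((preds[: len(ref)] - ref) ** 2, axis=1))
        rms = float(np.sqrt(np.mean((preds[: len(ref)] - ref) ** 2)))
    return ForecastResult(predicted=preds, reference=reference,
                          per_step_rms=per_step, rms=rms, segment=segment_span)


def segmented_forecast_compare(
    series: np.ndarray,
    t_hat_p: int,
    res: Reservoir,
    spec: RidgeSpec,
    steps: int,
    reference: np.ndarray,
) -> tuple[float, float]:
    """Whole-series vs post-detection training, compared on one forecast.

    Returns ``(err_pred1, err_pred2)``: RMS of the ``steps``-step
    closed-loop forecast against the true continuation when the readout is
    trained on the full series [0, N_t) (regions I and II, straddling the
    change) versus only on [t_hat_p, N_t) (region II, post-change).
    """
    X = np.asarray(series, float)
    if not 0 < t_hat_p < X.shape[0]:
        raise ValueError("t_hat_p must split the series with both parts nonempty")
    full = forecast(X, res, spec, steps, reference, segment_span=(0, X.shape[0]))
    post = forecast(X[t_hat_p:], res, spec, steps, reference,
                    segment_span=(t_hat_p, X.shape[0]))
    return full.rms, post.rms


def tune_correlation_study(
    n_reservoirs: int,
    ranges: dict,
    cfg: BenchmarkConfig,
    forecast_steps: int = 100,
    seed: int = 0,
) -> dict:
    """Sample random reservoir hyperparameters; pair forecast and detection error.

    For each draw, the same reservoir settings are used (a) to forecast a
    held-out stationary run closed-loop and (b) to run the detection
    benchmark; the Spearman correlation between the two error columns
    quantifies whether better predictors are better detectors.
    """
    if n_reservoirs < 2:
        raise ValueError("need at least 2 reservoirs")
    for key, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"degenerate range for {key!r}")
    from dataclasses import replace as _replace

    from .systems import simulate_lorenz63_switch

    rng = np.random.default_rng(seed)
    probe = simulate_lorenz63_switch(10.0, 10.0, None, 1200 + forecast_steps,
                                     seed=int(rng.integers(2**31)))
    pairs = []
    for k in range(n_reservoirs):
        draw = {key: float(rng.uniform(lo, hi)) for key, (lo, hi) in ranges.items()}
        params = _replace(cfg.reservoir, seed=int(rng.integers(2**31)), **draw)
        res = build_reservoir(params, probe.q)
        fc = forecast(probe.values[:1200], res, RidgeSpec(cfg.ridge_beta),
                      forecast_steps, reference=probe.values[1200:])
        sub_cfg = _replace(cfg, reservoir=params)
        report = run_benchmark(sub_cfg)
        pairs.append((fc.rms, report.mean_position_error))
    pred_err, det_err = map(np.array, zip(*pairs))
    rho = float(stats.spearmanr(pred_err, det_err).statistic)
    return {"prediction_errors": pred_err, "detection_errors": det_err,
            "spearman_rho": rho}
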