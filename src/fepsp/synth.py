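"""Synthetic evoked-sweep generator calibrated to the study's printed tables.

No raw recordings are available for this experiment, so the package ships a
generative stand-in whose sweeps have the statistical structure the analysis
assumes.  The waveform model is phenomenological:

    V(t) = -[A_f * K_fast(dt) * G_0(dt) + A_n * K_nmda(dt) * G_floor(dt)] + noise

with ``dt = t - t_stim``, where ``K`` are peak-normalised biexponential
synaptic kernels (fast non-NMDA and slow NMDA components) and ``G`` is a
multiplicative gating envelope representing intact GABAergic inhibition
truncating the late phase (fully for the fast component, down to
``gate_floor`` for the slow NMDA component).  Gating is active only in the
drug-free baseline condition; blocking the GABA receptors (picrotoxin +
CGP55845) removes the gate and *reveals* the late phase, and adding D-AP5
removes the NMDA component (``A_n = 0``).  Gating is multiplicative because
disinhibition reveals, rather than adds, the late phase.

Variability has three tiers: per-sample Gaussian noise, per-sweep
multiplicative amplitude jitter (``trial_cv``), and per-slice lognormal
component scalings (``slice_cv_*``) that reproduce the between-slice SEMs of
the study's group tables.  ``calibrate_preset`` solves for waveform
parameters such that the *pipeline's own measurements* of a noiseless sweep
hit a target feature set (peak, latency, durations, receptor-contribution
percentages), so every preset is consistent with this package's measurement
rules by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from .io import (DatasetManifest, SliceEntry, SweepRef, Trace, TraceMeta,
                 write_manifest, write_sweep_table)
from .protocol import CONDITIONS, ProtocolSpec

DEFAULT_STIM_MS = 10.0
DEFAULT_RECORD_MS = 130.0


class CalibrationError(RuntimeError):
    """Preset calibration could not reach its targets within bounds."""


@dataclass(frozen=True)
class SynthParams:
    """Generative parameters for one slice's evoked responses.

    Amplitudes are in mV (the waveform is negative-going; amplitudes are
    stored positive), time constants in ms.  ``gate_time_ms`` is the
    half-transition time of the inhibitory gate, ``gate_width_ms`` its
    10-90% transition width and ``gate_floor`` the fraction of the late
    phase that escapes intact inhibition.  ``nmda_log_shift``, if set,
    replaces the mean-one log-offset of the per-slice NMDA scaling (used by
    calibrated cohort presets to centre the expected measured NMDA
    contribution on the table value).
    """

    a_fast_mV: float = 0.7
    tau_rise_fast_ms: float = 0.5
    tau_decay_fast_ms: float = 2.0
    a_nmda_mV: float = 0.15
    tau_rise_nmda_ms: float = 2.0
    tau_decay_nmda_ms: float = 40.0
    gate_time_ms: float = 3.0
    gate_width_ms: float = 2.0
    gate_floor: float = 0.08
    noise_sd_mV: float = 0.01
    trial_cv: float = 0.05
    slice_cv_fast: float = 0.15
    slice_cv_nmda: float = 0.25
    slice_cv_common: float = 0.15
    nmda_log_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_fast_mV < 0 or self.a_nmda_mV < 0:
            raise ValueError("component amplitudes must be non-negative")
        for rise, decay, label in (
                (self.tau_rise_fast_ms, self.tau_decay_fast_ms, "fast"),
                (self.tau_rise_nmda_ms, self.tau_decay_nmda_ms, "nmda")):
            if rise <= 0 or decay <= 0:
                raise ValueError(f"{label} time constants must be positive")
            if rise >= decay:
                raise ValueError(f"{label} tau_rise must be < tau_decay")
        if self.gate_time_ms <= 0 or self.gate_width_ms <= 0:
            raise ValueError("gate_time_ms and gate_width_ms must be positive")
        if not 0.0 <= self.gate_floor <= 1.0:
            raise ValueError("gate_floor must lie in [0, 1]")
        if self.noise_sd_mV < 0:
            raise ValueError("noise_sd_mV must be non-negative")
        for cv in (self.trial_cv, self.slice_cv_fast, self.slice_cv_nmda,
                   self.slice_cv_common):
            if not 0.0 <= cv < 1.0:
                raise ValueError("coefficients of variation must lie in [0, 1)")


# ---------------------------------------------------------------------------
# waveform primitives

def biexp_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Stationary point of the biexponential difference kernel."""
    if not 0 < tau_rise_ms < tau_decay_ms:
        raise ValueError("need 0 < tau_rise < tau_decay")
    return (math.log(tau_decay_ms / tau_rise_ms)
            * tau_rise_ms * tau_decay_ms / (tau_decay_ms - tau_rise_ms))


def biexp_kernel(t_ms, tau_rise_ms: float, tau_decay_ms: float):
    """Peak-normalised biexponential kernel.

    ``K(t) = [exp(-t/tau_decay) - exp(-t/tau_rise)] / K_raw(t*)`` with the
    peak value 1 at ``t* = ln(tau_decay/tau_rise) * tau_rise * tau_decay /
    (tau_decay - tau_rise)``; K(0) = 0 and K -> 0 as t -> inf.  Negative
    times map to 0.
    """
    t_star = biexp_peak_time(tau_rise_ms, tau_decay_ms)
    norm = math.exp(-t_star / tau_decay_ms) - math.exp(-t_star / tau_rise_ms)
    t = np.asarray(t_ms, dtype=float)
    tt = np.maximum(t, 0.0)
    k = (np.exp(-tt / tau_decay_ms) - np.exp(-tt / tau_rise_ms)) / norm
    k = np.where(t < 0, 0.0, k)
    return k if k.ndim else float(k)


#: 10-90% width of the logistic in units of its scale parameter
_LOGISTIC_1090 = 2.0 * math.log(9.0)


def gating_envelope(t_ms, gate_time_ms: float, gate_width_ms: float,
                    gate_floor: float, active: bool = True):
    """Monotone non-increasing inhibition envelope in [gate_floor, 1].

    A logistic transition from 1 (t << gate_time) to ``gate_floor``
    (t >> gate_time) with half-transition at ``gate_time_ms`` and 10-90%
    width ``gate_width_ms``.  With ``active=False`` (GABA receptors blocked)
    the envelope is identically 1.
    """
    t = np.asarray(t_ms, dtype=float)
    if not active:
        g = np.ones_like(t)
        return g if g.ndim else float(g)
    s = gate_width_ms / _LOGISTIC_1090
    g = gate_floor + (1.0 - gate_floor) * expit(-(t - gate_time_ms) / s)
    return g if g.ndim else float(g)


def mean_waveform(params: SynthParams, condition: str, t_rel_ms) -> np.ndarray:
    """Noise-free evoked waveform (mV) at times relative to the stimulus.

    Intact inhibition (baseline condition) gates the two components with
    different completeness: the fast non-NMDA component is truncated fully
    (floor 0) while the slow NMDA component escapes at ``gate_floor``.  A
    single shared floor cannot reproduce the observed combination of a
    ~4 ms baseline response and an inhibition share of ~85% of the
    disinhibited AUC — the fast tail leaking through the floor would hold
    the response above the duration threshold — whereas a partial escape of
    the slow phase (sub-threshold, so it adds area but not duration) can.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t = np.asarray(t_rel_ms, dtype=float)
    gated = condition == "baseline"
    resp = params.a_fast_mV * biexp_kernel(t, params.tau_rise_fast_ms,
                                           params.tau_decay_fast_ms)
    if gated:
        resp = resp * gating_envelope(t, params.gate_time_ms,
                                      params.gate_width_ms, 0.0)
    if condition != "gaba_nmda_block":
        nmda = params.a_nmda_mV * biexp_kernel(
            t, params.tau_rise_nmda_ms, params.tau_decay_nmda_ms)
        if gated:
            nmda = nmda * gating_envelope(t, params.gate_time_ms,
                                          params.gate_width_ms,
                                          params.gate_floor)
        resp = resp + nmda
    return -resp


def _lognormal_factor(rng: np.random.Generator, cv: float,
                      log_shift: float | None = None) -> float:
    """One multiplicative factor; mean 1 unless ``log_shift`` overrides."""
    if cv == 0 and log_shift is None:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = -0.5 * sigma * sigma if log_shift is None else log_shift
    return float(np.exp(mu + sigma * rng.standard_normal()))


def simulate_sweep(params: SynthParams, condition: str,
                   rng: np.random.Generator | None = None,
                   meta: TraceMeta | None = None,
                   stim_ms: float = DEFAULT_STIM_MS,
                   record_ms: float = DEFAULT_RECORD_MS,
                   sampling_interval_ms: float = 0.1,
                   slice_scale: tuple[float, float] = (1.0, 1.0),
                   ) -> Trace:
    """Simulate one evoked sweep.

    ``slice_scale = (fast, nmda)`` carries the per-slice component scalings
    drawn once per recording; per-sweep trial jitter and Gaussian sample
    noise are drawn from ``rng`` (pass ``None`` for a fully deterministic,
    noise-free sweep).
    """
    if record_ms < stim_ms + 120.0:
        raise ValueError("record must extend >= 120 ms past the stimulus")
    n = int(round(record_ms / sampling_interval_ms))
    t_rel = np.arange(n) * sampling_interval_ms - stim_ms
    sf, sn = slice_scale
    if rng is None:
        jf = jn = 1.0
        noise = 0.0
    else:
        jf = _lognormal_factor(rng, params.trial_cv)
        jn = _lognormal_factor(rng, params.trial_cv)
        noise = (rng.standard_normal(n) * params.noise_sd_mV
                 if params.noise_sd_mV > 0 else 0.0)
    scaled = replace(params, a_fast_mV=params.a_fast_mV * sf * jf,
                     a_nmda_mV=params.a_nmda_mV * sn * jn)
    v = mean_waveform(scaled, condition, t_rel) + noise
    meta = meta or TraceMeta("synthetic", condition=condition)
    if meta.condition != condition:
        meta = replace(meta, condition=condition)
    return Trace(voltage_mV=v, sampling_interval_ms=sampling_interval_ms,
                 stimulus_time_ms=stim_ms, meta=meta)


def noiseless_response(params: SynthParams, condition: str,
                       meta: TraceMeta | None = None) -> Trace:
    """Deterministic mean response for one condition (no jitter, no noise)."""
    return simulate_sweep(params, condition, rng=None, meta=meta)


def draw_slice_scales(params: SynthParams, rng: np.random.Generator
                      ) -> tuple[float, float]:
    """Per-slice (fast, nmda) component scalings.

    A common slice-quality factor multiplies both components (it cancels in
    contribution ratios); component-specific factors move the NMDA/non-NMDA
    balance.  The NMDA-specific factor uses ``nmda_log_shift`` when the
    preset supplies one, so that the expected measured NMDA contribution
    matches the calibration target.
    """
    common = _lognormal_factor(rng, params.slice_cv_common)
    gf = _lognormal_factor(rng, params.slice_cv_fast)
    gn = _lognormal_factor(rng, params.slice_cv_nmda, params.nmda_log_shift)
    return common * gf, common * gn


def simulate_slice_recording(params: SynthParams,
                             protocol: ProtocolSpec | None = None,
                             rng=None,
                             meta_base: TraceMeta | None = None,
                             ) -> list[Trace]:
    """Simulate a full three-epoch recording session for one slice.

    One sweep per stimulus at the protocol's 20 s spacing over the baseline,
    GABA-blockade and GABA+NMDA-blockade epochs, each tagged with its
    condition and session time.  Per-slice component scalings are drawn once
    and applied to every sweep.
    """
    protocol = protocol or ProtocolSpec()
    rng = np.random.default_rng(rng)
    meta_base = meta_base or TraceMeta("synthetic")
    scales = draw_slice_scales(params, rng)
    sweeps: list[Trace] = []
    t_s = 0.0
    for condition in CONDITIONS:
        for _ in range(protocol.sweeps_per_epoch(condition)):
            meta = replace(meta_base, condition=condition, sweep_time_s=t_s)
            sweeps.append(simulate_sweep(params, condition, rng=rng,
                                         meta=meta, slice_scale=scales))
            t_s += protocol.stim_interval_s
    return sweeps


@dataclass(frozen=True)
class CohortSpec:
    """One experimental group to simulate: preset parameters plus size."""

    group: str
    timepoint_weeks: int
    eye_input: str
    n_slices: int
    params: SynthParams
    seed: int | np.random.SeedSequence = 0
    hemisphere: str = "left"
    name: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")


def simulate_cohort(spec: CohortSpec,
                    protocol: ProtocolSpec | None = None,
                    out_dir: str | Path | None = None,
                    ) -> tuple[DatasetManifest, dict[str, list[Trace]]]:
    """Simulate ``n_slices`` independent recordings for one group.

    Per-slice seeds are spawned deterministically from the master seed.
    With ``out_dir`` set, sweep files and a manifest are written via the
    package's plain-text formats; the manifest is returned either way.
    """
    protocol = protocol or ProtocolSpec()
    seed = spec.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(spec.n_slices)
    entries: list[SliceEntry] = []
    traces: dict[str, list[Trace]] = {}
    out_root = Path(out_dir) if out_dir is not None else None
    for i, child in enumerate(children):
        slice_id = f"{spec.name}-s{i + 1:02d}"
        meta = TraceMeta(slice_id=slice_id, hemisphere=spec.hemisphere,
                         eye_input=spec.eye_input, group=spec.group,
                         timepoint_weeks=spec.timepoint_weeks)
        sweeps = simulate_slice_recording(spec.params, protocol, child, meta)
        traces[slice_id] = sweeps
        refs = []
        for j, sw in enumerate(sweeps):
            rel = f"{slice_id}/sweep_{j:04d}.tsv"
            if out_root is not None:
                dest = out_root / rel
                dest.parent.mkdir(parents=True, exist_ok=True)
                write_sweep_table(sw, dest)
            refs.append(SweepRef(file=rel, condition=sw.meta.condition,
                                 sweep_time_s=sw.meta.sweep_time_s))
        entries.append(SliceEntry(slice_id=slice_id, hemisphere=spec.hemisphere,
                                  eye_input=spec.eye_input, group=spec.group,
                                  timepoint_weeks=spec.timepoint_weeks,
                                  sweeps=refs))
    manifest = DatasetManifest(protocol=protocol, slices=entries,
                               root=out_root or Path())
    manifest.validate(check_files=out_root is not None)
    if out_root is not None:
        write_manifest(manifest, out_root / "manifest.yaml")
    return manifest, traces


# ---------------------------------------------------------------------------
# stimulus-intensity calibration

def io_curve_calibrate(params: SynthParams,
                       intensities: Iterable[float],
                       i_half: float = 1.0,
                       i_slope: float = 0.15,
                       saturation_rtol: float = 0.01) -> float:
    """Stimulus intensity giving 75% of the maximal response.

    Response amplitude is modelled as a saturating logistic drive of
    intensity scaling the evoked components; the routine measures the
    response over the supplied grid, checks the top of the grid has
    saturated, and returns the intensity whose response is 75% of the
    plateau (the session-start calibration rule).
    """
    grid = np.sort(np.asarray(list(intensities), dtype=float))
    if grid.size < 3:
        raise CalibrationError("need an intensity grid of >= 3 points")
    base_amp = abs(float(np.min(noiseless_response(params, "baseline").voltage_mV)))

    def response(i):
        return base_amp / (1.0 + np.exp(-(i - i_half) / i_slope))

    amps = response(grid)
    plateau = float(amps[-1])
    if plateau <= 0 or (plateau - amps[-2]) > saturation_rtol * plateau:
        raise CalibrationError("intensity grid does not reach saturation")
    target = 0.75 * plateau
    if amps[0] >= target:
        raise CalibrationError("intensity grid starts above the 75% point")
    return float(brentq(lambda i: response(i) - target, grid[0], grid[-1],
                        xtol=1e-10))


# ---------------------------------------------------------------------------
# calibration of presets against target feature sets

@dataclass(frozen=True)
class CalibrationTargets:
    """Noiseless pipeline outputs a preset must reproduce."""

    peak_mV: float
    latency_ms: float
    duration_baseline_ms: float
    duration_gaba_block_ms: float
    gaba_pct: float
    nmda_pct: float

    def __post_init__(self) -> None:
        if self.peak_mV >= 0:
            raise ValueError("peak_mV must be negative (negative-going fEPSP)")
        if not 0 < self.gaba_pct < 100:
            raise ValueError("gaba_pct must lie in (0, 100)")
        if not 0 <= self.nmda_pct < 100:
            raise ValueError("nmda_pct must lie in [0, 100)")
        if self.nmda_pct > 0 and not (self.duration_baseline_ms
                                      < self.duration_gaba_block_ms):
            raise ValueError("baseline duration must be shorter than the "
                             "GABA-blocked duration")


def pipeline_measurements(params: SynthParams) -> dict[str, float]:
    """Measure a noiseless parameter set with the package's own pipeline."""
    from .contributions import gaba_contribution, nmda_contribution
    from .features import extract_features

    fs = {c: extract_features(noiseless_response(params, c))
          for c in CONDITIONS}
    return {
        "peak_mV": fs["baseline"].peak_amplitude_mV,
        "latency_ms": fs["baseline"].latency_to_peak_ms,
        "duration_baseline_ms": fs["baseline"].duration_ms,
        "duration_gaba_block_ms": fs["gaba_block"].duration_ms,
        "gaba_pct": gaba_contribution(fs["baseline"].auc_mV_ms,
                                      fs["gaba_block"].auc_mV_ms),
        "nmda_pct": nmda_contribution(fs["gaba_block"].auc_mV_ms,
                                      fs["gaba_nmda_block"].auc_mV_ms),
    }


def continuous_peak_time(params: SynthParams, condition: str = "baseline",
                         window_ms: tuple[float, float] = (0.05, 10.0)) -> float:
    """Off-grid argmin time of the mean waveform (ms from stimulus)."""
    res = minimize_scalar(lambda t: mean_waveform(params, condition, t),
                          bounds=window_ms, method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x)


def _signed_solve(fun: Callable[[float], float], lo: float, hi: float,
                  what: str, xtol: float = 1e-9, soft: bool = False) -> float:
    """Brentq with an explicit bracket check.

    With ``soft=True`` an unbracketed residual returns the better endpoint
    instead of raising — used inside calibration iterations whose final
    closure check decides success.
    """
    flo, fhi = fun(lo), fun(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        if soft:
            return lo if abs(flo) <= abs(fhi) else hi
        raise CalibrationError(
            f"cannot bracket {what}: residuals {flo:.4g} and {fhi:.4g}")
    return float(brentq(fun, lo, hi, xtol=xtol))


def _solve_quantized(fun: Callable[[float], float], lo: float, hi: float,
                     what: str, f_tol: float, n_scan: int = 48,
                     soft: bool = False, x0: float | None = None) -> float:
    """Root of a locally monotone step function.

    Scans a log-spaced grid for sign changes of the residual (the measured
    durations are quantized to the sampling grid and need not be globally
    monotone in the parameter), then bisects inside the bracketing pair
    nearest the current value ``x0``, accepting any point with
    ``|f| <= f_tol``.
    """
    if x0 is not None and abs(fun(x0)) <= f_tol:
        return float(x0)
    xs = np.geomspace(lo, hi, n_scan)
    fs = [fun(x) for x in xs]
    hits = [float(x) for x, f in zip(xs, fs) if abs(f) <= f_tol]
    brackets = [(xs[i], fs[i], xs[i + 1], fs[i + 1])
                for i in range(len(xs) - 1) if fs[i] * fs[i + 1] < 0]
    ref = math.log(x0) if x0 is not None else math.log(math.sqrt(lo * hi))
    if hits:
        return min(hits, key=lambda x: abs(math.log(x) - ref))
    if not brackets:
        j = int(np.argmin(np.abs(fs)))
        if soft:
            return float(xs[j])
        raise CalibrationError(
            f"cannot bracket {what}: closest residual {fs[j]:.4g} at {xs[j]:.4g}")
    a, fa, b, fb = min(brackets,
                       key=lambda br: abs(math.log(0.5 * (br[0] + br[2])) - ref))
    for _ in range(80):
        mid = 0.5 * (a + b)
        fm = fun(mid)
        if abs(fm) <= f_tol:
            return mid
        if fm * fb > 0:
            b, fb = mid, fm
        else:
            a, fa = mid, fm
    return 0.5 * (a + b)


def calibrate_preset(targets: CalibrationTargets | Mapping[str, float],
                     base: SynthParams | None = None,
                     max_outer: int = 15) -> SynthParams:
    """Solve generator parameters so the noiseless pipeline hits ``targets``.

    The fast-component decay and NMDA rise time constants stay fixed; the
    fast rise time is solved for latency, the NMDA decay for the
    GABA-blocked duration, the component amplitudes for peak amplitude and
    NMDA contribution, and the gate half-time / floor for baseline duration
    and GABA contribution — each by a 1-D root find on the pipeline's own
    noiseless measurements, iterated to joint closure.
    """
    if not isinstance(targets, CalibrationTargets):
        targets = CalibrationTargets(**dict(targets))
    p = base or SynthParams(
        a_fast_mV=abs(targets.peak_mV),
        tau_rise_fast_ms=1.4, tau_decay_fast_ms=3.0,
        a_nmda_mV=0.25 * abs(targets.peak_mV),
        tau_rise_nmda_ms=2.0, tau_decay_nmda_ms=40.0,
        gate_time_ms=3.0, gate_width_ms=0.5, gate_floor=0.05,
        noise_sd_mV=0.0, trial_cv=0.0,
        slice_cv_fast=0.0, slice_cv_nmda=0.0, slice_cv_common=0.0)
    if targets.nmda_pct == 0:
        p = replace(p, a_nmda_mV=0.0)
    dt = 0.1  # sampling grid of the simulated sweeps

    def with_(**kw):
        return replace(p, **kw)

    dur_tol = 0.5 * dt + 1e-9

    worst = ""
    for outer in range(max_outer):
        soft = True  # best-effort inside iterations; final closure decides

        # --- fast rise time <- latency of the gated composite; solved first
        # because the fast shape feeds every later quantity.  The continuous
        # solve (argmax of the analytic waveform, searched near the fast
        # peak to avoid the sub-threshold late hump) only initialises; later
        # iterations re-trim on the sampled measurement, which is constant
        # over a plateau of rise times and therefore settles.
        if outer == 0:
            p = with_(tau_rise_fast_ms=_signed_solve(
                lambda x: continuous_peak_time(with_(tau_rise_fast_ms=x),
                                               window_ms=(0.05, 5.0))
                - targets.latency_ms,
                0.05, p.tau_decay_fast_ms * 0.98, "tau_rise_fast (latency)",
                soft=soft))
        if abs(pipeline_measurements(p)["latency_ms"]
               - targets.latency_ms) > 0.5 * dt:
            p = with_(tau_rise_fast_ms=_solve_quantized(
                lambda x: pipeline_measurements(
                    with_(tau_rise_fast_ms=x))["latency_ms"]
                - targets.latency_ms,
                0.05, p.tau_decay_fast_ms * 0.98,
                "tau_rise_fast (grid latency)", f_tol=0.5 * dt + 1e-9,
                n_scan=32, soft=soft, x0=p.tau_rise_fast_ms))

        # --- overall scale <- peak amplitude (1-homogeneous, exact step)
        m = pipeline_measurements(p)
        c = targets.peak_mV / m["peak_mV"]
        p = with_(a_fast_mV=p.a_fast_mV * c, a_nmda_mV=p.a_nmda_mV * c)

        # --- gate stage.  The gate transition width sets how much of the
        # early response escapes before the cut (GABA contribution), with
        # the half-time re-solved inside so the cut always lands at the
        # baseline-duration target; the floor then trims the remaining GABA
        # residual via the sub-threshold late leak, capped so the leak
        # stays below the duration threshold.
        def _gate_time_for_duration(q: SynthParams) -> SynthParams:
            return replace(q, gate_time_ms=_solve_quantized(
                lambda x: pipeline_measurements(
                    replace(q, gate_time_ms=x))["duration_baseline_ms"]
                - targets.duration_baseline_ms,
                0.8, 15.0, "gate_time (baseline duration)", f_tol=dur_tol,
                n_scan=32, soft=True, x0=q.gate_time_ms))

        def _gaba_at_width(w: float) -> float:
            q = _gate_time_for_duration(replace(p, gate_width_ms=w))
            return pipeline_measurements(q)["gaba_pct"]

        floor_hi = 0.9
        if p.a_nmda_mV > 0:
            from .features import DURATION_PEAK_FRACTION
            theta = DURATION_PEAK_FRACTION * abs(targets.peak_mV)
            floor_hi = min(0.9, 0.95 * theta / p.a_nmda_mV)

        if outer == 0:
            p = with_(gate_width_ms=1.0, gate_floor=0.0)
        p = _gate_time_for_duration(p)
        for _ in range(3):
            # floor trim first: lifts the sub-threshold late leak until the
            # GABA contribution comes down to target (or the cap binds)
            p = with_(gate_floor=_signed_solve(
                lambda x: pipeline_measurements(
                    with_(gate_floor=x))["gaba_pct"] - targets.gaba_pct,
                0.0, floor_hi, "gate_floor (GABA contribution)", soft=True))
            p = _gate_time_for_duration(p)
            m = pipeline_measurements(p)
            if m["gaba_pct"] - targets.gaba_pct > 0.1:
                # floor capped and GABA still high: sharpen the gate so its
                # cut lands later for the same duration, passing more of
                # the early response
                p = _gate_time_for_duration(with_(gate_width_ms=_signed_solve(
                    lambda w: _gaba_at_width(w) - targets.gaba_pct,
                    0.15, p.gate_width_ms, "gate_width (GABA contribution)",
                    xtol=1e-4, soft=True)))
                m = pipeline_measurements(p)
            elif targets.gaba_pct - m["gaba_pct"] > 0.1 and p.gate_floor == 0:
                # GABA too low even with no leak: widen the gate so the cut
                # starts earlier for the same duration, passing less
                p = _gate_time_for_duration(with_(gate_width_ms=_signed_solve(
                    lambda w: _gaba_at_width(w) - targets.gaba_pct,
                    p.gate_width_ms, 4.0, "gate_width (GABA contribution)",
                    xtol=1e-4, soft=True)))
                m = pipeline_measurements(p)
            if (abs(m["gaba_pct"] - targets.gaba_pct) <= 0.1
                    and abs(m["duration_baseline_ms"]
                            - targets.duration_baseline_ms) <= dur_tol):
                break

        # the gate stage can move the sampled peak by one grid step; re-trim
        # the rise time against the grid latency (no-op when already on
        # target), then re-anchor the peak amplitude — a pure rescale
        # leaves every scale-invariant quantity untouched
        if abs(pipeline_measurements(p)["latency_ms"]
               - targets.latency_ms) > 0.5 * dt:
            p = with_(tau_rise_fast_ms=_solve_quantized(
                lambda x: pipeline_measurements(
                    with_(tau_rise_fast_ms=x))["latency_ms"]
                - targets.latency_ms,
                0.05, p.tau_decay_fast_ms * 0.98,
                "tau_rise_fast (grid latency)", f_tol=0.5 * dt + 1e-9,
                n_scan=32, soft=soft, x0=p.tau_rise_fast_ms))
        m = pipeline_measurements(p)
        c = targets.peak_mV / m["peak_mV"]
        p = with_(a_fast_mV=p.a_fast_mV * c, a_nmda_mV=p.a_nmda_mV * c)

        # --- NMDA pair: amplitude ratio and decay jointly set the NMDA
        # contribution and the disinhibited duration (gate-independent).
        if targets.nmda_pct > 0:
            for _ in range(6):
                p = with_(a_nmda_mV=p.a_fast_mV * _signed_solve(
                    lambda r: pipeline_measurements(
                        with_(a_nmda_mV=p.a_fast_mV * r))["nmda_pct"]
                    - targets.nmda_pct,
                    1e-4, 20.0, "a_nmda (NMDA contribution)", soft=soft))
                p = with_(tau_decay_nmda_ms=_solve_quantized(
                    lambda x: pipeline_measurements(
                        with_(tau_decay_nmda_ms=x))["duration_gaba_block_ms"]
                    - targets.duration_gaba_block_ms,
                    p.tau_rise_nmda_ms + 0.5, 600.0,
                    "tau_decay_nmda (blocked duration)", f_tol=dur_tol,
                    soft=soft, x0=p.tau_decay_nmda_ms))
                m = pipeline_measurements(p)
                if (abs(m["nmda_pct"] - targets.nmda_pct) <= 0.1
                        and abs(m["duration_gaba_block_ms"]
                                - targets.duration_gaba_block_ms) <= dur_tol):
                    break

        m = pipeline_measurements(p)
        c = targets.peak_mV / m["peak_mV"]
        p = with_(a_fast_mV=p.a_fast_mV * c, a_nmda_mV=p.a_nmda_mV * c)

        m = pipeline_measurements(p)
        checks = {
            "peak_mV": abs(m["peak_mV"] - targets.peak_mV)
            <= 0.005 * abs(targets.peak_mV),
            "latency_ms": abs(m["latency_ms"] - targets.latency_ms)
            <= 0.5 * dt + 1e-9,
            "duration_baseline_ms":
                abs(m["duration_baseline_ms"] - targets.duration_baseline_ms)
                <= dur_tol,
            "gaba_pct": abs(m["gaba_pct"] - targets.gaba_pct) <= 0.35,
            "nmda_pct": abs(m["nmda_pct"] - targets.nmda_pct) <= 0.35,
        }
        if targets.nmda_pct > 0:
            checks["duration_gaba_block_ms"] = abs(
                m["duration_gaba_block_ms"] - targets.duration_gaba_block_ms
            ) <= max(dur_tol, 0.005 * targets.duration_gaba_block_ms)
        if all(checks.values()):
            return p
        worst = ", ".join(
            f"{k}={m[k]:.4g} (target {getattr(targets, k):.4g})"
            for k, ok in checks.items() if not ok)
    raise CalibrationError(f"calibration did not converge: {worst}")


# ---------------------------------------------------------------------------
# group presets from the study's tables

@dataclass(frozen=True)
class PresetSpec:
    """Targets and cohort structure for one experimental group."""

    name: str
    group: str
    timepoint_weeks: int
    eye_input: str
    hemisphere: str
    n_slices: int
    targets: CalibrationTargets
    nmda_sem: float   # between-slice SEM of NMDA%, percentage points
    amp_sem: float    # between-slice SEM of baseline peak amplitude, mV


def _preset(name, group, tp, eye, hemi, n, peak, lat, dur_b, dur_g,
            gaba, nmda, nmda_sem, amp_sem):
    return PresetSpec(name, group, tp, eye, hemi, n,
                      CalibrationTargets(peak, lat, dur_b, dur_g, gaba, nmda),
                      nmda_sem, amp_sem)


#: Group presets.  Feature targets and SEMs come from the study's group
#: tables (baseline peak amplitude and latency; baseline and GABA-blocked
#: durations; GABA% and NMDA% contributions, with the NMDA% SEM setting the
#: between-slice spread).  ``control`` is the generic worked-example preset;
#: ``example-unoperated``/``example-operated`` are single-slice fixtures matching the published
#: example traces.
PRESETS: dict[str, PresetSpec] = {s.name: s for s in [
    _preset("control", "AMC", 32, "control", "left", 10,
            -0.70, 2.0, 4.1, 96.0, 85.0, 63.0, 2.0, 0.05),
    _preset("AMC-3wk-left", "AMC", 3, "control", "left", 9,
            -0.71, 2.0, 4.1, 96.0, 85.4, 62.7, 2.5, 0.08),
    _preset("AMC-3wk-right", "AMC", 3, "control", "right", 8,
            -0.67, 1.8, 3.7, 90.0, 82.0, 65.5, 1.6, 0.08),
    _preset("OHT-3wk-unoperated", "OHT", 3, "unoperated", "left", 10,
            -0.54, 2.0, 4.3, 77.0, 86.0, 62.0, 2.7, 0.02),
    _preset("OHT-3wk-operated", "OHT", 3, "operated", "right", 10,
            -0.57, 1.8, 4.1, 81.0, 84.0, 64.0, 3.2, 0.04),
    _preset("AMC-16wk-left", "AMC", 16, "control", "left", 17,
            -0.70, 2.1, 4.3, 85.0, 82.6, 53.4, 2.1, 0.05),
    _preset("AMC-16wk-right", "AMC", 16, "control", "right", 14,
            -0.56, 1.9, 4.1, 84.0, 81.5, 55.5, 2.1, 0.03),
    _preset("OHT-16wk-unoperated", "OHT", 16, "unoperated", "left", 10,
            -0.46, 2.0, 4.2, 73.0, 85.0, 60.0, 2.4, 0.04),
    _preset("OHT-16wk-operated", "OHT", 16, "operated", "right", 10,
            -0.52, 1.8, 3.9, 79.0, 85.0, 62.0, 2.2, 0.05),
    _preset("AMC-32wk-left", "AMC", 32, "control", "left", 15,
            -0.54, 2.0, 4.2, 75.0, 84.4, 57.0, 1.7, 0.03),
    _preset("AMC-32wk-right", "AMC", 32, "control", "right", 13,
            -0.62, 1.8, 3.7, 72.0, 85.8, 62.9, 2.6, 0.03),
    _preset("OHT-32wk-unoperated", "OHT", 32, "unoperated", "left", 12,
            -0.62, 1.9, 4.2, 66.0, 83.0, 53.0, 2.9, 0.03),
    _preset("OHT-32wk-operated", "OHT", 32, "operated", "right", 14,
            -0.54, 1.8, 3.9, 60.0, 80.0, 67.0, 3.0, 0.03),
    _preset("example-unoperated", "OHT", 32, "unoperated", "left", 2,
            -0.70, 2.0, 4.1, 96.0, 85.0, 54.0, 2.0, 0.03),
    _preset("example-operated", "OHT", 32, "operated", "right", 2,
            -0.54, 1.8, 3.9, 60.0, 80.0, 68.0, 2.0, 0.03),
]}


def list_presets() -> list[str]:
    return sorted(PRESETS)


#: Gauss-Hermite order for centring the per-slice NMDA scaling
_GH_NODES = 21


def _centre_nmda_shift(params: SynthParams, sigma_r: float,
                       target_pct: float) -> float:
    """Mean of ``ln(nmda/fast scaling ratio)`` giving E[measured NMDA%] = target.

    The measured contribution depends on the slice scalings only through the
    NMDA/fast ratio r (it is scale-invariant), so the expectation over the
    lognormal slice effects reduces to a 1-D Gauss-Hermite quadrature.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    weights = weights / weights.sum()
    base_ratio = params.a_nmda_mV / params.a_fast_mV

    def expected(mean_ln_r: float) -> float:
        vals = []
        for z in nodes:
            r = math.exp(mean_ln_r + sigma_r * z)
            m = pipeline_measurements(replace(
                params, a_nmda_mV=params.a_fast_mV * base_ratio * r))
            vals.append(m["nmda_pct"])
        return float(np.dot(weights, vals))

    return _signed_solve(lambda mu: expected(mu) - target_pct, -1.5, 1.5,
                         "nmda slice-scaling centre", xtol=1e-6)


@lru_cache(maxsize=None)
def get_preset(name: str) -> SynthParams:
    """Calibrated generator parameters for a named group preset.

    Waveform parameters are solved by :func:`calibrate_preset` against the
    preset's table targets; between-slice CVs are derived from the table
    SEMs (NMDA% SEM sets the component-ratio spread via the delta method,
    the amplitude SEM sets the common slice-quality spread), and the NMDA
    scaling is centred so the expected measured contribution equals the
    table mean.
    """
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; see list_presets()") from None
    p = calibrate_preset(spec.targets)

    pp = spec.targets.nmda_pct / 100.0
    sd_pts = spec.nmda_sem * math.sqrt(spec.n_slices)
    sigma_r = sd_pts / (100.0 * pp * (1.0 - pp)) if 0 < pp < 1 else 0.0
    sigma_spec = sigma_r / math.sqrt(2.0)
    cv_spec = math.sqrt(math.expm1(sigma_spec ** 2))
    cv_amp = spec.amp_sem * math.sqrt(spec.n_slices) / abs(spec.targets.peak_mV)
    sigma_amp_sq = math.log(1.0 + cv_amp ** 2)
    sigma_common_sq = max(sigma_amp_sq - sigma_spec ** 2, 0.0)
    cv_common = math.sqrt(math.expm1(sigma_common_sq))

    shift = None
    if sigma_r > 0 and pp > 0:
        mean_ln_r = _centre_nmda_shift(p, sigma_r, spec.targets.nmda_pct)
        # ln r = ln g_nmda - ln g_fast with mean-one fast scaling
        shift = mean_ln_r - 0.5 * sigma_spec ** 2
    return replace(p, noise_sd_mV=0.01, trial_cv=0.05,
                   slice_cv_fast=cv_spec, slice_cv_nmda=cv_spec,
                   slice_cv_common=cv_common, nmda_log_shift=shift)


def cohort_spec(name: str, n_slices: int | None = None,
                seed: int | np.random.SeedSequence = 0) -> CohortSpec:
    """CohortSpec for a named preset (size defaults to the table's n)."""
    spec = PRESETS[name]
    return CohortSpec(group=spec.group, timepoint_weeks=spec.timepoint_weeks,
                      eye_input=spec.eye_input,
                      n_slices=n_slices or spec.n_slices,
                      params=get_preset(name), seed=seed,
                      hemisphere=spec.hemisphere, name=name)
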