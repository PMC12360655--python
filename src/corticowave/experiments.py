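"""Experiment drivers.

Each driver runs the full chain -- network simulation, EEG projection,
wave classification -- for one of the model's characterisation protocols,
and returns machine-readable summaries.  All drivers are seed-deterministic
end to end: a single integer seed spawns independent substreams for the
simulation, the projection noise and the permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg import traces_to_eeg
from .network import (
    NetworkConfig,
    SimulationTraces,
    StimulusProtocol,
    build_network,
    make_dc_stimulus,
    make_random_step_stimulus,
    simulate,
)
from .wavefit import (
    FW_AXIS_ANGLE,
    NullDistribution,
    PlaneFitGrid,
    build_null,
    classify,
    compute_phase,
    get_roi,
    plane_fit,
    _rho_per_window,
)

DEFAULT_BAND = (7.0, 13.0)


# --------------------------------------------------------------------------
# shared classification pipeline


@dataclass
class ClassifiedRuns:
    """Stacked wave-fit output for a batch of trials (one ROI)."""

    times: np.ndarray           # (n_windows,) seconds
    alpha: np.ndarray           # (n_trials, n_windows)
    xi: np.ndarray
    rho: np.ndarray
    state: np.ndarray           # (n_trials, n_windows) of 'FW'|'BW'|'Null'
    null: NullDistribution

    def p_state(self, which: str, window_mask: np.ndarray | None = None) -> float:
        sel = self.state if window_mask is None else self.state[:, window_mask]
        return float(np.mean(sel == which))

    def p_timecourse(self, which: str) -> np.ndarray:
        return np.mean(self.state == which, axis=0)


def classify_traces(
    traces: SimulationTraces,
    rng: np.random.Generator,
    roi: str = "midline",
    null: NullDistribution | None = None,
    noise_sources: int = 5,
    band: tuple[float, float] = DEFAULT_BAND,
    grid: PlaneFitGrid = PlaneFitGrid(),
    reference_axis: float = FW_AXIS_ANGLE,
    null_trials: int = 4,
) -> ClassifiedRuns:
    """Project every trial to EEG and classify each 100 ms window.

    If no null distribution is given, one is built from the first
    ``null_trials`` trials of this dataset (electrode-position
    permutations at reduced temporal resolution).
    """
    roi_obj = get_roi(roi)
    pms = [
        compute_phase(traces_to_eeg(traces, k, rng, noise_sources), roi_obj, band)
        for k in range(traces.batch)
    ]
    if null is None:
        null = build_null(pms[:null_trials], rng, grid)
    alphas, xis, rhos, states = [], [], [], []
    for pm in pms:
        a, x, _ = plane_fit(pm.phases, roi_obj.positions, grid)
        r = _rho_per_window(pm.phases, roi_obj.positions, a, x)
        alphas.append(a)
        xis.append(x)
        rhos.append(r)
        states.append(classify(a, r, null, reference_axis))
    return ClassifiedRuns(
        pms[0].times, np.array(alphas), np.array(xis), np.array(rhos),
        np.array(states), null,
    )


# --------------------------------------------------------------------------
# response curve


def sigmoid4(x, floor, ceiling, slope, midpoint):
    return floor + (ceiling - floor) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_sigmoid(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """4-parameter logistic fit; returns (params, converged)."""
    from scipy.optimize import curve_fit

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo, hi = float(y.min()), float(y.max())
    x0 = float(x[np.argmin(np.abs(y - (lo + hi) / 2.0))])
    sign = 1.0 if y[-1] >= y[0] else -1.0
    try:
        p, _ = curve_fit(
            sigmoid4, x, y,
            p0=[lo, hi, sign * 8.0, x0],
            bounds=([-0.1, -0.1, -200.0, x.min()], [1.1, 1.1, 200.0, x.max()]),
            maxfev=20000,
        )
        return p, True
    except RuntimeError:
        return np.array([lo, hi, sign * 8.0, x0]), False


@dataclass
class ResponseCurve:
    currents: np.ndarray
    p_fw: np.ndarray
    p_bw: np.ndarray
    params_fw: np.ndarray  # (floor, ceiling, slope, midpoint)
    params_bw: np.ndarray
    converged: bool

    @property
    def threshold(self) -> float:
        """Threshold current: the 50% point between the sigmoid asymptotes."""
        return float(self.params_fw[3])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"current": self.currents, "p_fw": self.p_fw, "p_bw": self.p_bw}
        )


def run_response_curve(
    currents: np.ndarray | None = None,
    n_runs: int = 20,
    duration: float = 3.0,
    burn_in: float = 1.0,
    seed: int = 0,
    config: NetworkConfig | None = None,
    roi: str = "midline",
    noise_sources: int = 5,
) -> ResponseCurve:
    """FW/BW state probability during DC stimulation vs input current.

    Each current level is stimulated for ``duration`` seconds in ``n_runs``
    independent trials; the probabilities are the fractions of classified
    windows during stimulation.  A shared permutation null is built from a
    sample of trials across current levels.
    """
    if currents is None:
        currents = np.linspace(0.0, 2.0, 15)
    currents = np.asarray(currents, dtype=float)
    cfg = config or NetworkConfig()
    net = build_network(cfg)
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.generate_state(len(currents)) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])

    total = burn_in + duration
    roi_obj = get_roi(roi)
    grid = PlaneFitGrid()
    traces_all, pms_null = [], []
    for i, cur in enumerate(currents):
        stim = make_dc_stimulus(cur, burn_in, total)
        tr = simulate(net, stim, total, seed=int(sim_seeds[i]), batch=n_runs)
        traces_all.append(tr)
        pm = compute_phase(
            traces_to_eeg(tr, 0, rng, noise_sources), roi_obj, DEFAULT_BAND
        )
        pms_null.append(pm)
    null = build_null(pms_null[:: max(len(pms_null) // 4, 1)], rng, grid)

    p_fw, p_bw = [], []
    for tr in traces_all:
        runs = classify_traces(tr, rng, roi, null=null, noise_sources=noise_sources)
        sel = (runs.times >= burn_in + 0.2) & (runs.times < total)
        p_fw.append(runs.p_state("FW", sel))
        p_bw.append(runs.p_state("BW", sel))
    p_fw, p_bw = np.array(p_fw), np.array(p_bw)
    pars_fw, ok_fw = fit_sigmoid(currents, p_fw)
    pars_bw, ok_bw = fit_sigmoid(currents, p_bw)
    return ResponseCurve(currents, p_fw, p_bw, pars_fw, pars_bw, ok_fw and ok_bw)


# --------------------------------------------------------------------------
# impulse response


@dataclass
class ImpulseResponse:
    lags: np.ndarray            # seconds, 0 .. max_lag
    correlogram_fw: np.ndarray
    correlogram_bw: np.ndarray
    chance_lo: np.ndarray
    chance_hi: np.ndarray
    decay_lag_fw: float         # first post-peak lag inside the chance band

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "corr_fw": self.correlogram_fw,
                "corr_bw": self.correlogram_bw,
                "chance_lo": self.chance_lo,
                "chance_hi": self.chance_hi,
            }
        )


def _xcorr_at_lags(stim: np.ndarray, resp: np.ndarray, n_lags: int) -> np.ndarray:
    """Mean Pearson correlation of stim(t) with resp(t + lag) across trials."""
    out = np.zeros(n_lags)
    for lag in range(n_lags):
        s = stim[:, : stim.shape[1] - lag]
        r = resp[:, lag:]
        sc = s - s.mean(axis=1, keepdims=True)
        rc = r - r.mean(axis=1, keepdims=True)
        denom = np.sqrt((sc**2).sum(axis=1) * (rc**2).sum(axis=1))
        denom[denom == 0] = np.inf
        out[lag] = np.mean((sc * rc).sum(axis=1) / denom)
    return out


def run_impulse_response(
    amplitude: float = 1.2,
    duration: float = 8.0,
    burn_in: float = 1.0,
    n_trials: int = 20,
    n_shuffles: int = 100,
    max_lag: float = 1.5,
    seed: int = 0,
    config: NetworkConfig | None = None,
    noise_sources: int = 5,
) -> ImpulseResponse:
    """Temporal response function to suprathreshold random-step stimulation.

    The binary FW (and BW) state sequences are cross-correlated with the
    stimulus sequence; the chance band is the 95% interval of correlograms
    from shuffled trial pairings (stimulus of one trial against the
    response of another).
    """
    cfg = config or NetworkConfig()
    net = build_network(cfg)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_trials + 1) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])

    total = burn_in + duration
    runs_list, stims = [], []
    null = None
    dt_win = 0.01
    for i in range(n_trials):
        stim = make_random_step_stimulus(amplitude, total, seed=int(seeds[i]), onset=burn_in)
        tr = simulate(net, stim, total, seed=int(seeds[i]), batch=1)
        runs = classify_traces(tr, rng, null=null, noise_sources=noise_sources, null_trials=1)
        null = runs.null  # build once, reuse across trials
        sel = runs.times >= burn_in
        dt_win = float(np.median(np.diff(runs.times)))
        runs_list.append((runs.state[0, sel] == "FW", runs.state[0, sel] == "BW"))
        wf = tr.stimulus[np.round(runs.times[sel] / tr.dt).astype(int)]
        stims.append(wf > 0)
    fw = np.array([r[0] for r in runs_list], dtype=float)
    bw = np.array([r[1] for r in runs_list], dtype=float)
    st = np.array(stims, dtype=float)

    n_lags = int(round(max_lag / dt_win)) + 1
    corr_fw = _xcorr_at_lags(st, fw, n_lags)
    corr_bw = _xcorr_at_lags(st, bw, n_lags)

    sh_rng = np.random.default_rng(ss.spawn(1)[0])
    shuffled = np.empty((n_shuffles, n_lags))
    for k in range(n_shuffles):
        perm = sh_rng.permutation(n_trials)
        while np.any(perm == np.arange(n_trials)) and n_trials > 3:
            perm = sh_rng.permutation(n_trials)
        shuffled[k] = _xcorr_at_lags(st, fw[perm], n_lags)
    lo = np.quantile(shuffled, 0.025, axis=0)
    hi = np.quantile(shuffled, 0.975, axis=0)

    lags = np.arange(n_lags) * dt_win
    peak = int(np.argmax(corr_fw))
    decay = float("nan")
    inside = (corr_fw <= hi) & (corr_fw >= lo)
    for i in range(peak + 1, n_lags):
        if inside[i]:
            decay = lags[i]
            break
    return ImpulseResponse(lags, corr_fw, corr_bw, lo, hi, decay)


# --------------------------------------------------------------------------
# state timecourse


@dataclass
class StateTimecourse:
    times: np.ndarray          # relative to stimulus onset (s)
    p_fw: np.ndarray
    p_bw: np.ndarray
    onset: float
    offset: float
    time_to_first_peak: float       # s after onset
    return_to_baseline: float       # s after offset (slope-corrected)

    @property
    def log_ratio(self) -> np.ndarray:
        eps = 1e-3
        return np.log((self.p_fw + eps) / (self.p_bw + eps))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "p_fw": self.p_fw, "p_bw": self.p_bw})


def _first_peak_latency(times: np.ndarray, p: np.ndarray, onset: float,
                        smooth_n: int = 5, search: float = 0.5) -> float:
    """Latency of the first peak of the onset response.

    The zero-phase band-pass plus the 100 ms phase window smear the sharp
    onset transient into a plateau, inside which the sample argmax is
    noise; the latency is therefore taken as the centre of the post-onset
    region holding >= 95% of the onset maximum of the smoothed curve.
    """
    from scipy.ndimage import uniform_filter1d

    sm = uniform_filter1d(p, smooth_n)
    sel = (times >= onset) & (times <= onset + search)
    t_sel, p_sel = times[sel], sm[sel]
    top = p_sel >= 0.95 * p_sel.max()
    # contiguous plateau containing the first top sample
    first = int(np.flatnonzero(top)[0])
    last = first
    while last + 1 < len(top) and top[last + 1]:
        last += 1
    return float(t_sel[first : last + 1].mean() - onset)


def _return_to_baseline(
    times: np.ndarray, p: np.ndarray, onset: float, offset: float, rest_end: float,
    guard: float = 0.4,
) -> float:
    """First post-offset time at which the slope-corrected P(FW) re-enters
    the pre-stimulus baseline band (mean +- 2 SD).

    The last ``guard`` seconds before onset are excluded from the baseline:
    the zero-phase band-pass smears the onset response backwards by up to
    half the filter length, which would otherwise contaminate the band.
    """
    from scipy.ndimage import uniform_filter1d

    p = uniform_filter1d(p, 5)  # 50 ms; suppresses binomial sampling noise
    pre = times < onset - guard
    base_mean, base_sd = p[pre].mean(), p[pre].std()
    post = (times >= offset) & (times <= rest_end)
    t_post, p_post = times[post], p[post]
    # linear fit over the final 2 s of rest; remove the trend but keep the
    # level at the end of the rest period
    tail = t_post >= rest_end - 2.0
    coef = np.polyfit(t_post[tail], p_post[tail], 1)
    corrected = p_post - coef[0] * (t_post - t_post[-1])
    inband = np.abs(corrected - base_mean) <= 2.0 * base_sd
    idx = np.flatnonzero(inband)
    if len(idx) == 0:
        return float("nan")
    return float(t_post[idx[0]] - offset)


def run_state_timecourse(
    amplitude: float = 0.88,
    stim_duration: float = 5.0,
    rest_duration: float = 5.0,
    pre_duration: float = 1.5,
    burn_in: float = 1.0,
    n_runs: int = 100,
    seed: int = 0,
    config: NetworkConfig | None = None,
    noise_sources: int = 5,
    batch_size: int = 25,
) -> StateTimecourse:
    """Across-trial P(FW)/P(BW) timecourses for threshold DC stimulation.

    Latency metrics: ``time_to_first_peak`` is the first post-onset local
    maximum of P(FW); ``return_to_baseline`` is the first post-offset time
    at which the linearly detrended P(FW) re-enters the pre-stimulus
    mean +- 2 SD band.
    """
    cfg = config or NetworkConfig()
    net = build_network(cfg)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    onset = burn_in + pre_duration
    offset = onset + stim_duration
    total = offset + rest_duration
    stim = make_dc_stimulus(amplitude, onset, offset)

    n_batches = int(np.ceil(n_runs / batch_size))
    seeds = ss.generate_state(n_batches) % (2**31)
    states, null, times = [], None, None
    for i in range(n_batches):
        bs = min(batch_size, n_runs - i * batch_size)
        tr = simulate(net, stim, total, seed=int(seeds[i]), batch=bs)
        runs = classify_traces(tr, rng, null=null, noise_sources=noise_sources)
        null = runs.null
        states.append(runs.state)
        times = runs.times
    state = np.concatenate(states, axis=0)
    keep = times >= burn_in
    times = times[keep]
    p_fw = np.mean(state[:, keep] == "FW", axis=0)
    p_bw = np.mean(state[:, keep] == "BW", axis=0)

    ttfp = _first_peak_latency(times, p_fw, onset)
    rtb = _return_to_baseline(times, p_fw, onset, offset, total)
    return StateTimecourse(times - onset, p_fw, p_bw, onset, offset, ttfp, rtb)


def run_parameter_variation(
    param: str,
    values: np.ndarray,
    amplitude: float = 0.88,
    n_runs: int = 25,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Log-ratio timecourses for a swept connection weight.

    ``param`` is a NetworkConfig field (e.g. ``w_l4in_l4x`` for Layer-4
    input adaptation or ``w_fb_igib_igib`` for infragranular feedback); the
    weight is changed in every area simultaneously.
    """
    frames = []
    for val in values:
        cfg = NetworkConfig().replace(**{param: float(val)})
        tc = run_state_timecourse(
            amplitude=amplitude, n_runs=n_runs, seed=seed, config=cfg, **kwargs
        )
        frames.append(
            pd.DataFrame(
                {
                    "time": tc.times,
                    "p_fw": tc.p_fw,
                    "p_bw": tc.p_bw,
                    "log_ratio": tc.log_ratio,
                    "param": param,
                    "value": float(val),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# spectra


@dataclass
class SpectralSummary:
    table: pd.DataFrame  # columns: condition keys + node_type, peak_freq, peak_power

    def peak(self, node_type: str, **filters) -> float:
        t = self.table[self.table.node_type == node_type]
        for k, v in filters.items():
            t = t[np.isclose(t[k], v) if np.issubdtype(type(v), np.number) else (t[k] == v)]
        return float(t.peak_freq.mean())


def _node_spectra(
    traces: SimulationTraces,
    node_suffix: str,
    burn_in: float,
    fmin: float = 5.0,
    fmax: float = 15.0,
    prefix: str = "",
) -> tuple[float, float]:
    """Mean Welch spectrum over all areas/trials of one node type; returns
    (peak frequency, peak power) in the alpha search band."""
    from scipy.signal import welch

    fs = 1.0 / traces.dt
    i0 = int(round(burn_in / traces.dt))
    cfg = traces.config
    specs = []
    for a in range(1, cfg.n_areas + 1):
        x = traces.node(f"{prefix}Cx{a}.{node_suffix}")[:, i0:]
        x = x - x.mean(axis=1, keepdims=True)
        f, p = welch(x, fs=fs, nperseg=min(2048, x.shape[1]), nfft=2**15, axis=1)
        specs.append(p.mean(axis=0))
    p_mean = np.mean(specs, axis=0)
    sel = (f >= fmin) & (f <= fmax)
    k = np.argmax(p_mean[sel])
    return float(f[sel][k]), float(p_mean[sel][k])


def run_spectral_analysis(
    currents: np.ndarray | None = None,
    n_runs: int = 6,
    duration: float = 5.0,
    burn_in: float = 1.0,
    seed: int = 0,
    config: NetworkConfig | None = None,
) -> SpectralSummary:
    """Source-level spectra of IG_IB and SG_X vs stimulus current.

    Current 0 is the stimulus-OFF condition.  Peak frequencies are argmax
    of the zero-padded Welch spectrum in 5-15 Hz.
    """
    if currents is None:
        currents = np.linspace(0.0, 2.0, 11)
    cfg = config or NetworkConfig()
    net = build_network(cfg)
    seeds = np.random.SeedSequence(seed).generate_state(len(currents)) % (2**31)
    rows = []
    total = burn_in + duration
    for i, cur in enumerate(np.asarray(currents, float)):
        stim = make_dc_stimulus(cur, burn_in, total) if cur > 0 else None
        tr = simulate(net, stim, total, seed=int(seeds[i]), batch=n_runs)
        for node_type in ("IGIB", "SGX"):
            pk, pw = _node_spectra(tr, node_type, burn_in)
            rows.append(
                {"current": cur, "node_type": node_type, "peak_freq": pk, "peak_power": pw}
            )
    return SpectralSummary(pd.DataFrame(rows))


def suprathreshold_frequency_increase(
    summary: SpectralSummary, threshold: float = 0.88
) -> dict[str, float]:
    """Peak-frequency increase from the response threshold to the top of the
    swept current range, per node type."""
    out = {}
    for node_type in ("IGIB", "SGX"):
        t = summary.table[summary.table.node_type == node_type]
        supra = t[t.current >= threshold - 1e-9].sort_values("current")
        out[node_type] = float(supra.peak_freq.iloc[-1] - supra.peak_freq.iloc[0])
    return out


def run_delay_sweep(
    delays_ms: np.ndarray | None = None,
    amplitude: float = 1.2,
    n_runs: int = 4,
    duration: float = 5.0,
    burn_in: float = 1.0,
    seed: int = 0,
) -> SpectralSummary:
    """SG_X / IG_IB spectra vs inter-areal delay, full model vs the isolated
    forward pathway (pacemakers reduced to passive relays and the
    infragranular inter-areal feedback removed), during stimulation."""
    if delays_ms is None:
        delays_ms = np.arange(4, 41, 4)
    seeds = np.random.SeedSequence(seed).generate_state(len(delays_ms) * 2) % (2**31)
    rows = []
    total = burn_in + duration
    k = 0
    for delay in np.asarray(delays_ms, float):
        for config_name in ("full", "fw_isolated"):
            cfg = NetworkConfig().replace(delay_cx_cx=delay * 1e-3)
            if config_name == "fw_isolated":
                cfg = cfg.replace(ig_passive_relay=True, ig_feedback_enabled=False)
            net = build_network(cfg)
            stim = make_dc_stimulus(amplitude, burn_in, total)
            tr = simulate(net, stim, total, seed=int(seeds[k]), batch=n_runs)
            k += 1
            for node_type in ("IGIB", "SGX"):
                pk, pw = _node_spectra(tr, node_type, burn_in)
                rows.append(
                    {
                        "delay_ms": delay,
                        "configuration": config_name,
                        "node_type": node_type,
                        "peak_freq": pk,
                        "peak_power": pw,
                    }
                )
    return SpectralSummary(pd.DataFrame(rows))


def bw_scalp_phase_span(
    n_trials: int = 50,
    duration: float = 8.0,
    burn_in: float = 1.0,
    seed: int = 0,
    config: NetworkConfig | None = None,
    noise_sources: int = 5,
    electrodes: tuple[str, str] = ("Oz", "Fz"),
) -> float:
    """Predicted scalp phase difference between two electrodes in the
    resting backward-wave state.

    Simulates rest, classifies windows, and converts each BW window's
    fitted plane (gradient direction alpha, spatial frequency xi) into the
    predicted phase difference between the two electrode positions of the
    2D layout; returns the mean magnitude (rad) over BW windows and trials.
    """
    from .eeg import standard_montage

    cfg = config or NetworkConfig()
    net = build_network(cfg)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    mont = standard_montage()
    p1, p2 = (mont.pos2d[mont.picks([e])[0]] for e in electrodes)

    spans = []
    batch_size = 25
    seeds = ss.generate_state(int(np.ceil(n_trials / batch_size))) % (2**31)
    done = 0
    for bseed in seeds:
        bs = min(batch_size, n_trials - done)
        done += bs
        tr = simulate(net, None, duration, seed=int(bseed), batch=bs)
        runs = classify_traces(tr, rng, noise_sources=noise_sources)
        sel = runs.times >= burn_in
        bw = (runs.state[:, sel] == "BW")
        a = runs.xi[:, sel] * np.cos(runs.alpha[:, sel])
        b = runs.xi[:, sel] * np.sin(runs.alpha[:, sel])
        d = np.abs(a * (p1[0] - p2[0]) + b * (p1[1] - p2[1]))
        if bw.any():
            spans.append(d[bw])
    return float(np.concatenate(spans).mean())


# --------------------------------------------------------------------------
# pulvinar


@dataclass
class PulvinarSweep:
    response: pd.DataFrame       # columns: w_pul, current, p_fw, p_bw
    baseline_log_ratio: pd.DataFrame  # columns: w_pul, log_ratio
    epoch_maps: dict             # state label -> (node_type -> (n_areas, n_lags) map)
    power_profiles: pd.DataFrame  # columns: state, node_type, area, power


def epoch_triggered_map(
    traces: SimulationTraces,
    node_suffix: str,
    burn_in: float = 1.0,
    half_width: float = 0.15,
    band: tuple[float, float] = DEFAULT_BAND,
    ref_area: int = 2,
) -> np.ndarray:
    """Average spatial activity map around peaks of the reference area's
    band-limited IG_IB rate: (n_areas, n_lags)."""
    from scipy.signal import filtfilt, firwin, find_peaks

    fs = 1.0 / traces.dt
    i0 = int(round(burn_in / traces.dt))
    hw = int(round(half_width * fs))
    cfg = traces.config
    numtaps = int(round(3 * fs / band[0])) | 1
    b = firwin(numtaps, band, pass_zero=False, fs=fs)
    maps = []
    for trial in range(traces.batch):
        ref = traces.node(f"Cx{ref_area}.IGIB")[trial, i0:]
        ref_f = filtfilt(b, 1, ref - ref.mean())
        peaks, _ = find_peaks(ref_f, distance=int(0.05 * fs), height=0.0)
        peaks = peaks[(peaks > hw) & (peaks < len(ref_f) - hw)]
        if len(peaks) == 0:
            continue
        X = np.stack(
            [traces.node(f"Cx{a}.{node_suffix}")[trial, i0:] for a in range(1, cfg.n_areas + 1)]
        )
        ep = np.stack([X[:, p - hw : p + hw + 1] for p in peaks]).mean(axis=0)
        maps.append(ep)
    return np.mean(maps, axis=0) if maps else np.zeros((cfg.n_areas, 2 * hw + 1))


def oscillatory_power_profile(
    traces: SimulationTraces, burn_in: float = 1.0, band: tuple[float, float] = DEFAULT_BAND
) -> pd.DataFrame:
    """Band power per node type and area (mean over trials)."""
    from scipy.signal import welch

    fs = 1.0 / traces.dt
    i0 = int(round(burn_in / traces.dt))
    rows = []
    for node_type in ("SGX", "IGIB"):
        for a in range(1, traces.config.n_areas + 1):
            x = traces.node(f"Cx{a}.{node_type}")[:, i0:]
            x = x - x.mean(axis=1, keepdims=True)
            f, p = welch(x, fs=fs, nperseg=min(2048, x.shape[1]), axis=1)
            sel = (f >= band[0]) & (f <= band[1])
            rows.append(
                {"node_type": node_type, "area": a, "power": float(p[:, sel].mean())}
            )
    return pd.DataFrame(rows)


def run_pulvinar_sweep(
    w_grid: np.ndarray | None = None,
    currents: np.ndarray | None = None,
    n_runs: int = 8,
    duration: float = 3.0,
    burn_in: float = 1.0,
    seed: int = 0,
    noise_sources: int = 5,
) -> PulvinarSweep:
    """FW/BW probability over (pulvino-cortical weight, stimulus current),
    plus the epoch-triggered activity maps and power profiles of the three
    canonical states (resting BW, evoked FW, spontaneous pulvinar FW)."""
    if w_grid is None:
        w_grid = np.array([0.0, 1.1, 2.0])
    if currents is None:
        currents = np.linspace(0.0, 2.0, 9)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    seeds = ss.generate_state(len(w_grid) * len(currents) + 3) % (2**31)

    rows, base_rows = [], []
    k = 0
    null = None
    total = burn_in + duration
    for w in np.asarray(w_grid, float):
        cfg = NetworkConfig().replace(pulvinar_enabled=w > 0, w_pul_l4x=float(w))
        net = build_network(cfg)
        for cur in np.asarray(currents, float):
            stim = make_dc_stimulus(cur, burn_in, total) if cur > 0 else None
            tr = simulate(net, stim, total, seed=int(seeds[k]), batch=n_runs)
            k += 1
            runs = classify_traces(tr, rng, null=null, noise_sources=noise_sources)
            null = runs.null
            sel = runs.times >= burn_in + 0.2
            p_fw, p_bw = runs.p_state("FW", sel), runs.p_state("BW", sel)
            rows.append({"w_pul": w, "current": cur, "p_fw": p_fw, "p_bw": p_bw})
            if cur == 0.0:
                eps = 1e-3
                base_rows.append(
                    {"w_pul": w, "log_ratio": float(np.log((p_fw + eps) / (p_bw + eps)))}
                )

    # canonical states for the spatial maps
    epoch_maps, profiles = {}, []
    states = {
        "resting_bw": (NetworkConfig(), None),
        "evoked_fw": (NetworkConfig(), make_dc_stimulus(1.6, burn_in, total)),
        "spontaneous_fw": (
            NetworkConfig().replace(pulvinar_enabled=True, w_pul_l4x=2.0),
            None,
        ),
    }
    for i, (label, (cfg, stim)) in enumerate(states.items()):
        net = build_network(cfg)
        tr = simulate(net, stim, total, seed=int(seeds[len(w_grid) * len(currents) + i]), batch=n_runs)
        epoch_maps[label] = {
            nt: epoch_triggered_map(tr, nt, burn_in) for nt in ("SGX", "IGIB")
        }
        prof = oscillatory_power_profile(tr, burn_in)
        prof["state"] = label
        profiles.append(prof)

    return PulvinarSweep(
        pd.DataFrame(rows), pd.DataFrame(base_rows), epoch_maps,
        pd.concat(profiles, ignore_index=True),
    )


# --------------------------------------------------------------------------
# lateralization


@dataclass
class LateralizationResult:
    timecourse: pd.DataFrame       # columns: time, roi, p_fw, p_bw
    response: pd.DataFrame | None  # columns: current, roi, p_fw (if swept)
    rms_topography: np.ndarray     # (n_channels,) RMS in first 100 ms post-onset
    ch_names: tuple


def run_lateralization(
    stimulus_side: str = "L.",
    amplitude: float = 1.2,
    stim_duration: float = 1.0,
    pre_duration: float = 1.0,
    post_duration: float = 2.0,
    burn_in: float = 1.0,
    n_runs: int = 20,
    currents: np.ndarray | None = None,
    w_pul_left: float = 0.0,
    w_pul_right: float = 0.0,
    seed: int = 0,
    noise_sources: int = 5,
) -> LateralizationResult:
    """Dual-stream (two-hemisphere) simulation with per-hemisphere ROIs.

    With ``currents`` given, additionally sweeps a shared DC amplitude over
    both hemispheres and reports per-ROI response curves (used to probe
    hemisphere-specific pulvinar modulation via ``w_pul_left/right``).
    """
    pul = (w_pul_left > 0) or (w_pul_right > 0)
    cfg = NetworkConfig().replace(
        hemispheres=2,
        pulvinar_enabled=pul,
        w_pul_l4x=float(w_pul_left),
        w_pul_l4x_right=float(w_pul_right),
    )
    net = build_network(cfg)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    onset = burn_in + pre_duration
    offset = onset + stim_duration
    total = offset + post_duration
    stim_map = {stimulus_side: make_dc_stimulus(amplitude, onset, offset)}
    tr = simulate(net, stim_map, total, seed=int(ss.generate_state(1)[0] % 2**31), batch=n_runs)

    frames = []
    nulls = {}
    for roi in ("left", "right"):
        runs = classify_traces(tr, rng, roi=roi, noise_sources=noise_sources)
        nulls[roi] = runs.null
        keep = runs.times >= burn_in
        frames.append(
            pd.DataFrame(
                {
                    "time": runs.times[keep] - onset,
                    "roi": roi,
                    "p_fw": runs.p_timecourse("FW")[keep],
                    "p_bw": runs.p_timecourse("BW")[keep],
                }
            )
        )
    timecourse = pd.concat(frames, ignore_index=True)

    # RMS topography over the first 100 ms after onset (broadband EEG)
    i0 = int(round(onset * 100.0))
    rms = []
    for k in range(min(n_runs, 10)):
        eeg = traces_to_eeg(tr, k, rng, noise_sources=0)
        rms.append(np.sqrt(np.mean(eeg.data[:, i0 : i0 + 10] ** 2, axis=1)))
    rms_topo = np.mean(rms, axis=0)

    response = None
    if currents is not None:
        rows = []
        seeds = ss.generate_state(len(currents)) % (2**31)
        for i, cur in enumerate(np.asarray(currents, float)):
            stim = make_dc_stimulus(cur, burn_in, burn_in + 3.0)
            trc = simulate(net, stim, burn_in + 3.0, seed=int(seeds[i]), batch=n_runs)
            for roi in ("left", "right"):
                runs = classify_traces(
                    trc, rng, roi=roi, null=nulls[roi], noise_sources=noise_sources
                )
                sel = runs.times >= burn_in + 0.2
                rows.append(
                    {"current": cur, "roi": roi, "p_fw": runs.p_state("FW", sel),
                     "p_bw": runs.p_state("BW", sel)}
                )
        response = pd.DataFrame(rows)

    from .eeg import standard_montage

    return LateralizationResult(timecourse, response, rms_topo, standard_montage().ch_names)
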