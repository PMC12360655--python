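"""Infragranular bursting pacemaker populations.

Each infragranular node (IG_IB) is a homogeneous population of N = 350
Izhikevich neurons whose parameters place them in an intrinsically bursting
regime: short spike bursts recurring at roughly 100 ms intervals, i.e. an
alpha-band pacemaker.  The population is coupled to the rest of the rate
network through fixed conversions at its input and output:

* input: every neuron receives four times the node's summed input current
  plus a Gaussian noise term (mean ``mu_eps``, SD ``sigma_eps``), drawn
  independently per neuron and per 1 ms step -- the population's only
  source of variability.  A static mode (offsets drawn once per neuron,
  i.e. fixed heterogeneity) is available via ``PopulationNoise.mode``.
* output: the node's mean-field rate is the fraction of neurons spiking in
  the current 1 ms step divided by the step length (``output_gain`` = 1000
  by default), i.e. the population's instantaneous rate in Hz, which feeds
  the ordinary synaptic gating equations including the node's own
  self-excitatory synapse.

Membrane equations integrate at 0.5 ms (two sub-steps per 1 ms network
step); neurons are not coupled directly, only through the node-level
self-connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DT, I_BASE, SYNAPSE_CLASSES

#: membrane sub-step (ms units inside the Izhikevich equations)
SUBSTEP_MS = 0.5
#: input current scale from node (nA) to per-neuron drive
INPUT_SCALE = 4.0
#: default population size
N_NEURONS = 350
#: default output gain for the fraction-spiking -> mean-field-rate bridge.
#: The natural unit conversion is 1/dt (fraction per 1 ms bin -> Hz); the
#: extra 0.7 coupling efficiency is calibrated once so that the full network
#: holds its alpha-band backward rhythm at rest and reverses to a forward
#: wave at the published stimulation threshold.
OUTPUT_GAIN = 0.7 / DT

V_PEAK = 30.0


@dataclass(frozen=True)
class IzhikevichParams:
    a: float = 0.0067
    b: float = 0.2
    c: float = -50.0
    d: float = 2.0


@dataclass(frozen=True)
class PopulationNoise:
    """Per-neuron Gaussian drive offsets (Izhikevich current units)."""

    mu_eps: float = 6.0
    sigma_eps: float = 4.0
    mode: str = "white"  # "white": fresh draw per step; "static": once per neuron

    def __post_init__(self) -> None:
        if self.mode not in ("static", "white"):
            raise ValueError("noise mode must be 'static' or 'white'")


@dataclass
class PopulationState:
    v: np.ndarray
    u: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.v.shape[-1]

    @classmethod
    def init(
        cls,
        n_neurons: int = N_NEURONS,
        rng: np.random.Generator | None = None,
        params: IzhikevichParams = IzhikevichParams(),
    ) -> "PopulationState":
        """Random sub-threshold membrane potentials, u on the b*v nullcline."""
        if rng is None:
            v = np.full(n_neurons, -70.0)
        else:
            v = rng.uniform(-70.0, -50.0, n_neurons)
        return cls(v=v, u=params.b * v)


def izhikevich_step(
    state: PopulationState,
    per_neuron_current: np.ndarray,
    dt: float = SUBSTEP_MS * 1e-3,
    params: IzhikevichParams = IzhikevichParams(),
) -> tuple[PopulationState, np.ndarray]:
    """One explicit-Euler membrane sub-step with spike detection and reset.

    Canonical ordering: neurons whose potential reached 30 mV are flagged
    spiked and reset (v <- c, u <- u + d) *before* the Euler increment, so
    the reset is exact.  ``dt`` is in seconds; the canonical right-hand
    side is per millisecond, so the increment uses dt*1000.
    """
    if not (np.all(np.isfinite(state.v)) and np.all(np.isfinite(state.u))):
        raise FloatingPointError("non-finite membrane state (divergence)")
    h = dt * 1e3
    spiked = state.v >= V_PEAK
    v = np.where(spiked, params.c, state.v)
    u = np.where(spiked, state.u + params.d, state.u)
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + per_neuron_current
    v = np.clip(v + h * dv, -200.0, 1e3)
    u = u + h * params.a * (params.b * v - u)
    return PopulationState(v=v, u=u), spiked


def population_rate(spike_mask: np.ndarray) -> float:
    """Fraction of the population spiking this step, in [0, 1]."""
    return float(np.mean(spike_mask, axis=-1))


def spiking_input(
    node_current: float,
    noise: PopulationNoise,
    rng: np.random.Generator,
    static_offsets: np.ndarray | None = None,
    n_neurons: int = N_NEURONS,
) -> np.ndarray:
    """Per-neuron drive: 4*I_node + mu_eps + sigma_eps * N(0, 1).

    In static mode the caller passes the per-neuron offsets drawn once at
    simulation start; in white mode a fresh draw is made here.
    """
    if noise.mode == "static":
        if static_offsets is None:
            static_offsets = noise.sigma_eps * rng.standard_normal(n_neurons)
        return INPUT_SCALE * node_current + noise.mu_eps + static_offsets
    return (
        INPUT_SCALE * node_current
        + noise.mu_eps
        + noise.sigma_eps * rng.standard_normal(n_neurons)
    )


def simulate_population(
    duration: float,
    drive: np.ndarray | float = 0.0,
    seed: int | None = 0,
    n_neurons: int = N_NEURONS,
    noise: PopulationNoise = PopulationNoise(),
    params: IzhikevichParams = IzhikevichParams(),
    output_gain: float = OUTPUT_GAIN,
    self_weight: float = 0.7,
    i_base: float = I_BASE,
) -> np.ndarray:
    """Rate trace (Hz, 1 kHz sampling) of one isolated pacemaker node.

    The node receives ``i_base`` plus the optional ``drive`` time series
    (nA, one value per 1 ms step) and its own self-excitatory synapse
    (class ``ig_self_exc``, weight 0.7 by default).
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s for spectral estimates")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / DT))
    drive = np.broadcast_to(np.asarray(drive, dtype=float), (n_steps,))
    tau_self, gam_self = SYNAPSE_CLASSES["ig_self_exc"]

    state = PopulationState.init(n_neurons, rng, params)
    offsets = noise.sigma_eps * rng.standard_normal(n_neurons)
    s = 0.0
    rate = np.zeros(n_steps)
    for t in range(n_steps):
        node_current = i_base + drive[t] + self_weight * s
        In = spiking_input(node_current, noise, rng, offsets, n_neurons)
        spiked = np.zeros(n_neurons, bool)
        for _ in range(2):
            state, sp = izhikevich_step(state, In, params=params)
            spiked |= sp
        r = output_gain * population_rate(spiked)
        s = s + DT * (-s / tau_self + gam_self * (1.0 - s) * r)
        rate[t] = r
    return rate


def burst_intervals(
    rate: np.ndarray,
    fs: float = 1.0 / DT,
    smooth_ms: float = 20.0,
    threshold_frac: float = 0.5,
    refractory_ms: float = 20.0,
) -> np.ndarray:
    """Inter-burst intervals (s) from a population rate trace.

    Bursts are local maxima of the smoothed rate exceeding
    ``threshold_frac`` of its robust maximum (98th percentile).  Peaks
    closer than the refractory window plus ~60% of the population's
    dominant period (from the rate spectrum) are merged, so that ragged
    multi-peaked bursts count once.
    """
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import find_peaks, welch

    rate = np.asarray(rate, dtype=float)
    n_smooth = max(int(round(smooth_ms * fs / 1000.0)), 1)
    sm = uniform_filter1d(rate, n_smooth)
    height = threshold_frac * np.percentile(sm, 98)
    f, p = welch(rate - rate.mean(), fs=fs, nperseg=min(4096, len(rate)))
    band = (f >= 4.0) & (f <= 16.0)
    period = 1.0 / f[band][np.argmax(p[band])]
    min_dist = int(round(refractory_ms * fs / 1000.0 + 0.6 * period * fs))
    peaks, _ = find_peaks(sm, height=height, distance=max(min_dist, 1))
    return np.diff(peaks) / fs
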