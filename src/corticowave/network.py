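"""Hierarchical laminar network construction and simulation.

The model is a single-stream hierarchy of ``n_areas`` cortical areas, each
containing five nodes in three laminar compartments:

* ``L4X`` / ``L4IN``: excitatory/inhibitory pair in Layer 4 (input layer,
  with slow recurrent inhibition acting as response adaptation),
* ``SGX`` / ``SGIN``: excitatory/inhibitory pair in supragranular Layers 2/3
  (origin of feedforward projections),
* ``IGIB``: infragranular Layers 5/6 pacemaker, a population of bursting
  Izhikevich neurons (see :mod:`corticowave.pacemaker`).

Feedforward connections run SG_X -> L4_X of the next area; feedback runs
from IG_IB to the lower area's SG_IN (disynaptic inhibition of the
feedforward stream) and to the lower IG_IB (the backward-coupled pacemaker
chain that generates the resting backward wave).  A stimulus input layer
(IL_St, an L4-like pair, LGN analogue) feeds the first area, and a top
input pair (IL_Pr) drives the last area's pacemaker with bounded white
noise, keeping the backward pathway active.  Optionally a pulvinar node sits
between each pair of consecutive areas, relaying IG_IB output forward into
the next area's Layer 4 with half the cortical delay on each leg.

``simulate`` integrates the coupled system with forward Euler at 1 ms,
vectorised over a batch of independent trials.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .dynamics import DT, FICurveParams, SYNAPSE_CLASSES, fi_rate
from .pacemaker import (
    INPUT_SCALE,
    IzhikevichParams,
    N_NEURONS,
    OUTPUT_GAIN,
    PopulationNoise,
    V_PEAK,
)

LAMINAR_NODES = ("L4X", "L4IN", "SGX", "SGIN", "IGIB")

RATE_DIVERGENCE_LIMIT = 1e4


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameter tree of the model.  Defaults reproduce the published
    operating point; any field can be overridden (or loaded from YAML)."""

    n_areas: int = 3
    hemispheres: int = 1

    # intra-areal weights
    w_l4x_sgx: float = 1.0
    w_l4x_l4in: float = 1.0
    w_sgx_igib: float = 1.0
    w_igib_self: float = 0.7
    w_l4in_l4x: float = -1.2
    w_sgin_sgx: float = -2.0

    # inter-areal weights
    w_ff_sgx_l4x: float = 2.0
    w_fb_igib_sgin: float = 1.5
    w_fb_igib_igib: float = 1.0

    # input layers
    w_ilst_l4x: float = 2.0
    w_ilpr_igib: float = 1.0
    ilpr_noise_max: float = 0.3

    # pulvinar pathway
    pulvinar_enabled: bool = False
    w_igib_pul: float = 1.0
    w_pul_l4x: float = 2.0
    w_pul_l4x_right: float | None = None  # dual-stream override, right side

    # delays (s)
    delay_cx_cx: float = 0.012
    delay_cx_pul: float = 0.006

    # node dynamics
    i_base: float = 0.33
    fi: FICurveParams = field(default_factory=FICurveParams)
    tau_ou: float = 0.002
    sigma_ou: float = 0.025

    # pacemaker
    izhikevich: IzhikevichParams = field(default_factory=IzhikevichParams)
    population_noise: PopulationNoise = field(default_factory=PopulationNoise)
    n_neurons: int = N_NEURONS
    ig_output_gain: float = OUTPUT_GAIN

    # pathway-isolation switches
    ig_passive_relay: bool = False
    ig_feedback_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2 for any wave to exist")
        if self.hemispheres not in (1, 2):
            raise ValueError("hemispheres must be 1 or 2")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        raw = yaml.safe_load(io.StringIO(text)) or {}
        for key, sub in (
            ("fi", FICurveParams),
            ("izhikevich", IzhikevichParams),
            ("population_noise", PopulationNoise),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def replace(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class StimulusProtocol:
    """External current waveform injected at the stimulus input layer."""

    kind: str = "none"  # dc_step | random_step | none
    amplitude: float = 0.0
    onset: float = 0.0
    offset: float = 0.0
    update_rate: float = 10.0
    on_probability: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.kind not in ("dc_step", "random_step", "none"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    def waveform(self, n_steps: int, dt: float = DT) -> np.ndarray:
        trace = np.zeros(n_steps)
        if self.kind == "none" or self.amplitude == 0.0:
            return trace
        if self.kind == "dc_step":
            i0 = int(round(self.onset / dt))
            i1 = int(round(self.offset / dt))
            trace[i0:i1] = self.amplitude
            return trace
        # random_step: piecewise-constant over 1/update_rate blocks, each
        # independently ON with on_probability -- no periodicity introduced
        rng = np.random.default_rng(self.seed)
        block = int(round(1.0 / (self.update_rate * dt)))
        n_blocks = int(np.ceil(n_steps / block))
        on = rng.random(n_blocks) < self.on_probability
        trace[:] = np.repeat(on.astype(float) * self.amplitude, block)[:n_steps]
        i0 = int(round(self.onset / dt))
        trace[:i0] = 0.0
        return trace


def make_dc_stimulus(amplitude: float, onset: float, offset: float) -> StimulusProtocol:
    return StimulusProtocol(kind="dc_step", amplitude=amplitude, onset=onset, offset=offset)


def make_random_step_stimulus(
    amplitude: float, duration: float, seed: int | None = None, onset: float = 0.0
) -> StimulusProtocol:
    return StimulusProtocol(
        kind="random_step", amplitude=amplitude, onset=onset, offset=duration, seed=seed
    )


# --------------------------------------------------------------------------
# network construction


@dataclass
class Network:
    config: NetworkConfig
    node_names: list[str]
    node_kinds: list[str]  # "mf" | "ig" | "pul"
    index: dict[str, int]
    # connection arrays (parallel)
    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray
    tau: np.ndarray
    gamma: np.ndarray
    delay_steps: np.ndarray
    class_label: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_connections(self) -> int:
        return len(self.src)

    def connection_table(self):
        """Connection list as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "source": [self.node_names[i] for i in self.src],
                "target": [self.node_names[i] for i in self.dst],
                "weight": self.weight,
                "class": self.class_label,
                "delay": self.delay_steps * DT,
            }
        )


def _stream_prefix(cfg: NetworkConfig, hemi: int) -> str:
    if cfg.hemispheres == 1:
        return ""
    return ("L." if hemi == 0 else "R.")


def build_network(config: NetworkConfig) -> Network:
    """Instantiate nodes and the connection table for one or two streams."""
    names: list[str] = []
    kinds: list[str] = []
    index: dict[str, int] = {}
    rows: list[tuple[int, int, float, str, float]] = []

    def add_node(name: str, kind: str = "mf") -> None:
        if name in index:
            raise ValueError(f"duplicate node id {name!r}")
        index[name] = len(names)
        names.append(name)
        kinds.append(kind)

    def connect(s: str, t: str, w: float, cls: str, delay: float = 0.0) -> None:
        if cls not in SYNAPSE_CLASSES:
            raise ValueError(f"unknown synapse class {cls!r}")
        if s not in index or t not in index:
            raise ValueError(f"dangling node id in {s} -> {t}")
        if w == 0.0 and cls != "ig_self_exc":
            return  # zero-weight rows are no-ops; omit for exact pruning
        rows.append((index[s], index[t], w, cls, delay))

    cfg = config
    ig_kind = "mf" if cfg.ig_passive_relay else "ig"
    for h in range(cfg.hemispheres):
        p = _stream_prefix(cfg, h)
        for a in range(1, cfg.n_areas + 1):
            for nm in LAMINAR_NODES:
                add_node(f"{p}Cx{a}.{nm}", ig_kind if nm == "IGIB" else "mf")
        add_node(f"{p}ILSt.X")
        add_node(f"{p}ILSt.IN")
        add_node(f"{p}ILPr.X")
        add_node(f"{p}ILPr.IN")
        if cfg.pulvinar_enabled:
            for a in range(1, cfg.n_areas):
                add_node(f"{p}Pul{a}", "pul")

    dl = cfg.delay_cx_cx
    dp = cfg.delay_cx_pul
    for h in range(cfg.hemispheres):
        p = _stream_prefix(cfg, h)
        for a in range(1, cfg.n_areas + 1):
            connect(f"{p}Cx{a}.L4X", f"{p}Cx{a}.SGX", cfg.w_l4x_sgx, "fast_exc")
            connect(f"{p}Cx{a}.L4X", f"{p}Cx{a}.L4IN", cfg.w_l4x_l4in, "fast_exc")
            connect(f"{p}Cx{a}.SGX", f"{p}Cx{a}.IGIB", cfg.w_sgx_igib, "fast_exc")
            connect(f"{p}Cx{a}.IGIB", f"{p}Cx{a}.IGIB", cfg.w_igib_self, "ig_self_exc")
            connect(f"{p}Cx{a}.L4IN", f"{p}Cx{a}.L4X", cfg.w_l4in_l4x, "slow_inh")
            connect(f"{p}Cx{a}.SGIN", f"{p}Cx{a}.SGX", cfg.w_sgin_sgx, "fast_inh")
        for a in range(1, cfg.n_areas):
            connect(f"{p}Cx{a}.SGX", f"{p}Cx{a+1}.L4X", cfg.w_ff_sgx_l4x, "fast_exc", dl)
            connect(f"{p}Cx{a+1}.IGIB", f"{p}Cx{a}.SGIN", cfg.w_fb_igib_sgin, "fast_exc", dl)
            if cfg.ig_feedback_enabled:
                connect(f"{p}Cx{a+1}.IGIB", f"{p}Cx{a}.IGIB", cfg.w_fb_igib_igib, "slow_exc", dl)
        # stimulus input layer: an L4-like pair relaying into Cx1
        connect(f"{p}ILSt.X", f"{p}ILSt.IN", cfg.w_l4x_l4in, "fast_exc")
        connect(f"{p}ILSt.IN", f"{p}ILSt.X", cfg.w_l4in_l4x, "slow_inh")
        connect(f"{p}ILSt.X", f"{p}Cx1.L4X", cfg.w_ilst_l4x, "fast_exc", dl)
        # top input pair driving the last area's pacemaker
        connect(f"{p}ILPr.X", f"{p}ILPr.IN", cfg.w_l4x_l4in, "fast_exc")
        connect(f"{p}ILPr.IN", f"{p}ILPr.X", cfg.w_l4in_l4x, "slow_inh")
        connect(f"{p}ILPr.X", f"{p}Cx{cfg.n_areas}.IGIB", cfg.w_ilpr_igib, "fast_exc", dl)
        if cfg.pulvinar_enabled:
            w_out = cfg.w_pul_l4x
            if h == 1 and cfg.w_pul_l4x_right is not None:
                w_out = cfg.w_pul_l4x_right
            for a in range(1, cfg.n_areas):
                connect(f"{p}Cx{a}.IGIB", f"{p}Pul{a}", cfg.w_igib_pul, "fast_exc", dp)
                connect(f"{p}Pul{a}", f"{p}Cx{a+1}.L4X", w_out, "fast_exc", dp)

    src = np.array([r[0] for r in rows], dtype=np.intp)
    dst = np.array([r[1] for r in rows], dtype=np.intp)
    weight = np.array([r[2] for r in rows], dtype=float)
    tau = np.array([SYNAPSE_CLASSES[r[3]][0] for r in rows], dtype=float)
    gamma = np.array([SYNAPSE_CLASSES[r[3]][1] for r in rows], dtype=float)
    delay_steps = np.array([int(round(r[4] / DT)) for r in rows], dtype=np.intp)
    labels = [r[3] for r in rows]
    return Network(cfg, names, kinds, index, src, dst, weight, tau, gamma, delay_steps, labels)


# --------------------------------------------------------------------------
# simulation


@dataclass
class SimulationTraces:
    """Per-node rate time series at 1 kHz for a batch of trials."""

    rates: np.ndarray  # (batch, n_steps, n_nodes), Hz
    node_names: list[str]
    stimulus: np.ndarray  # (n_steps,) or (hemispheres, n_steps), nA
    dt: float
    config: NetworkConfig
    seed: int | None

    @property
    def n_steps(self) -> int:
        return self.rates.shape[1]

    @property
    def batch(self) -> int:
        return self.rates.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def node(self, name: str) -> np.ndarray:
        return self.rates[:, :, self.node_names.index(name)]

    def area_nodes(self, area: int, prefix: str = "") -> np.ndarray:
        cols = [self.node_names.index(f"{prefix}Cx{area}.{nm}") for nm in LAMINAR_NODES]
        return self.rates[:, :, cols]

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("rates", data=self.rates.astype(np.float32), compression="gzip")
            f.create_dataset("stimulus", data=self.stimulus)
            f.attrs["node_names"] = ",".join(self.node_names)
            f.attrs["dt"] = self.dt
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["config_yaml"] = self.config.to_yaml()

    @classmethod
    def load(cls, path: str) -> "SimulationTraces":
        import h5py

        with h5py.File(path, "r") as f:
            rates = np.asarray(f["rates"], dtype=float)
            stim = np.asarray(f["stimulus"])
            names = f.attrs["node_names"].split(",")
            dt = float(f.attrs["dt"])
            seed = int(f.attrs["seed"])
            cfg = NetworkConfig.from_yaml(f.attrs["config_yaml"])
        return cls(rates, names, stim, dt, cfg, None if seed < 0 else seed)


def simulate(
    network: Network,
    stimulus: StimulusProtocol | dict[str, StimulusProtocol] | None,
    duration: float,
    seed: int | None = 0,
    batch: int = 1,
    external_currents: dict[str, np.ndarray] | None = None,
) -> SimulationTraces:
    """Integrate the network for ``duration`` seconds (forward Euler, 1 ms).

    Independent random streams are used for cortical OU noise, pulvinar OU
    noise, the IL_Pr drive and the pacemaker populations, so that structural
    toggles (e.g. removing the pulvinar) leave the remaining streams
    untouched.  Output is bit-reproducible for a given (config, seed).

    ``stimulus`` may be one protocol (applied to every stream) or a mapping
    from stream prefix (``""`` or ``"L."``/``"R."``) to protocols.
    ``external_currents`` maps node names to per-step current traces (nA),
    used for impulse/perturbation experiments.
    """
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    cfg = network.config
    n_steps = int(round(duration / DT))
    n_nodes = network.n_nodes

    ss = np.random.SeedSequence(0 if seed is None else seed)
    rng_ou, rng_pul, rng_ilpr, rng_pace = (np.random.default_rng(s) for s in ss.spawn(4))

    kinds = np.array(network.node_kinds)
    mf_cols = np.flatnonzero(kinds == "mf")
    pul_cols = np.flatnonzero(kinds == "pul")
    ig_cols = np.flatnonzero(kinds == "ig")
    n_ig = len(ig_cols)

    # stimulus per stream -> per-node external drive at IL_St
    prefixes = [_stream_prefix(cfg, h) for h in range(cfg.hemispheres)]
    stim_traces = np.zeros((cfg.hemispheres, n_steps))
    if stimulus is not None:
        if isinstance(stimulus, dict):
            for h, p in enumerate(prefixes):
                if p in stimulus and stimulus[p] is not None:
                    stim_traces[h] = stimulus[p].waveform(n_steps)
        else:
            for h in range(cfg.hemispheres):
                stim_traces[h] = stimulus.waveform(n_steps)
    ilst_cols = [network.index[f"{p}ILSt.X"] for p in prefixes]
    ilpr_cols = [network.index[f"{p}ILPr.X"] for p in prefixes]

    ext = np.zeros((n_steps, n_nodes))
    if external_currents:
        for name, trace in external_currents.items():
            ext[: len(trace), network.index[name]] = trace

    src, dst = network.src, network.dst
    w, tau, gam = network.weight, network.tau, network.gamma
    # the explicit-Euler update itself contributes one step of latency, so a
    # connection delay of k steps reads back k-1 additional steps: the
    # target's rate then lags the source's by exactly k steps
    dly = np.maximum(network.delay_steps - 1, 0)
    M = np.zeros((n_nodes, network.n_connections))
    M[dst, np.arange(network.n_connections)] = 1.0
    Mw = M * w

    fi_p = cfg.fi
    iz = cfg.izhikevich
    pn = cfg.population_noise
    gain = cfg.ig_output_gain

    hist = np.zeros((n_steps + 1, batch, n_nodes))
    hist[0, :, :] = fi_rate(cfg.i_base, fi_p)  # mean-field resting rate everywhere

    s = np.zeros((batch, network.n_connections))
    eps = np.zeros((batch, n_nodes))
    v = rng_pace.uniform(-70.0, -50.0, (batch, n_ig, cfg.n_neurons))
    u = iz.b * v
    offsets = pn.sigma_eps * rng_pace.standard_normal((batch, n_ig, cfg.n_neurons))

    ou_fac = 1.0 - DT / cfg.tau_ou
    ou_amp = cfg.sigma_ou * np.sqrt(2.0 * DT / cfg.tau_ou)
    mf_noise_mask = np.zeros(n_nodes)
    mf_noise_mask[mf_cols] = 1.0
    mf_noise_mask[pul_cols] = 1.0

    for t in range(n_steps):
        t_del = np.maximum(t - dly, 0)
        r_del = hist[t_del, :, src].T  # (batch, n_conn)
        s += DT * (-s / tau + gam * (1.0 - s) * r_del)

        current = s @ Mw.T + cfg.i_base + eps * mf_noise_mask + ext[t]
        for h, col in enumerate(ilst_cols):
            current[:, col] += stim_traces[h, t]
        for col in ilpr_cols:
            current[:, col] += rng_ilpr.uniform(0.0, cfg.ilpr_noise_max, batch)

        r_new = fi_rate(current, fi_p)
        if n_ig:
            node_I = current[:, ig_cols][:, :, None]
            if pn.mode == "static":
                In = INPUT_SCALE * node_I + pn.mu_eps + offsets
            else:
                In = (
                    INPUT_SCALE * node_I
                    + pn.mu_eps
                    + pn.sigma_eps * rng_pace.standard_normal(v.shape)
                )
            spiked = np.zeros(v.shape, bool)
            for _ in range(2):
                sp = v >= V_PEAK
                spiked |= sp
                v = np.where(sp, iz.c, v)
                u = np.where(sp, u + iz.d, u)
                dv = 0.04 * v * v + 5.0 * v + 140.0 - u + In
                v = np.clip(v + 0.5 * dv, -200.0, 1e3)
                u = u + 0.5 * iz.a * (iz.b * v - u)
            r_new[:, ig_cols] = gain * spiked.mean(axis=2)
        hist[t + 1] = r_new
        if np.max(r_new) > RATE_DIVERGENCE_LIMIT:
            raise FloatingPointError(
                f"rate divergence (> {RATE_DIVERGENCE_LIMIT} Hz) at t={t * DT:.3f} s"
            )

        # OU noise for the next step; pulvinar nodes use a separate stream so
        # that the cortex-only model is bit-identical when the pathway is absent
        eps_new = eps * ou_fac
        eps_new[:, mf_cols] += ou_amp * rng_ou.standard_normal((batch, len(mf_cols)))
        if len(pul_cols):
            eps_new[:, pul_cols] += ou_amp * rng_pul.standard_normal((batch, len(pul_cols)))
        eps = eps_new

    stim_out = stim_traces[0] if cfg.hemispheres == 1 else stim_traces
    return SimulationTraces(hist[1:].transpose(1, 0, 2), list(network.node_names), stim_out, DT, cfg, seed)


# --------------------------------------------------------------------------
# source-level phase analysis


def _analytic_phase(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    from scipy.signal import filtfilt, firwin, hilbert

    numtaps = int(round(3 * fs / band[0])) | 1
    b = firwin(numtaps, band, pass_zero=False, fs=fs)
    return np.angle(hilbert(filtfilt(b, 1, x, axis=-1), axis=-1))


def phase_lag(x_low: np.ndarray, x_high: np.ndarray, fs: float = 1.0 / DT,
              band: tuple[float, float] = (7.0, 13.0)) -> float:
    """Mean circular phase difference phase(x_low) - phase(x_high).

    Negative values mean the higher area leads (a backward gradient),
    positive values mean the lower area leads (forward).
    """
    p1 = _analytic_phase(np.asarray(x_low, float), fs, band)
    p2 = _analytic_phase(np.asarray(x_high, float), fs, band)
    return float(np.angle(np.mean(np.exp(1j * (p1 - p2)))))


def source_phase_lags(
    traces: SimulationTraces,
    band: tuple[float, float] = (7.0, 13.0),
    burn_in: float = 1.0,
    prefix: str = "",
) -> dict[str, float]:
    """Per-compartment phase differences between the first and last area.

    Returns the summed consecutive-area circular lags for SG_X and IG_IB
    (summing consecutive pairs avoids the 2*pi wrap ambiguity of a direct
    end-to-end comparison when the total span approaches pi).
    """
    if traces.n_steps * traces.dt - burn_in < 3.0:
        raise ValueError("need at least 3 s of data after burn-in")
    i0 = int(round(burn_in / traces.dt))
    n_areas = traces.config.n_areas
    out = {}
    for comp in ("SGX", "IGIB"):
        total = 0.0
        for a in range(1, n_areas):
            lo = traces.node(f"{prefix}Cx{a}.{comp}")[:, i0:]
            hi = traces.node(f"{prefix}Cx{a + 1}.{comp}")[:, i0:]
            total += phase_lag(lo.ravel(), hi.ravel(), 1.0 / traces.dt, band)
        out[comp] = total
    return out
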