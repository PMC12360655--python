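"""Mean-field node dynamics.

Every non-spiking unit in the network is a rate node: its firing rate is an
instantaneous function of the summed input current (an FI curve), and all
temporal dynamics live in the saturating synaptic gating variables and in a
per-node Ornstein-Uhlenbeck noise current.  The FI curve is

    r(I) = (lam*I - beta) / (1 - exp(-theta*(lam*I - beta)))

with ``r`` in Hz and ``I`` in nA, continuously extended by ``1/theta`` at
``lam*I == beta``.  Synapses transmit the delayed presynaptic rate through a
gating variable ``s`` in [0, 1],

    ds/dt = -s/tau + gamma * (1 - s) * r(t - delay),

and each node's current is the weighted sum of its incoming gates plus a
constant base current, its noise current, and any external stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: integration step of the mean-field equations (s)
DT = 1e-3

#: baseline input current common to all nodes (nA)
I_BASE = 0.33


@dataclass(frozen=True)
class FICurveParams:
    """Parameters of the rate transfer function.

    lambda_slope
        excitability (Hz per nA).
    beta_offset
        threshold offset (Hz).
    theta_curvature
        curvature of the soft rectification (s).
    """

    lambda_slope: float = 270.0
    beta_offset: float = 108.0
    theta_curvature: float = 0.154

    def __post_init__(self) -> None:
        if self.lambda_slope <= 0 or self.theta_curvature <= 0:
            raise ValueError("lambda_slope and theta_curvature must be positive")


#: synapse classes: class label -> (tau_syn [s], gamma_sat)
SYNAPSE_CLASSES: dict[str, tuple[float, float]] = {
    "fast_exc": (0.020, 0.8),
    "slow_exc": (0.120, 0.5),
    "fast_inh": (0.003, 0.8),
    "slow_inh": (0.120, 0.1),
    "ig_self_exc": (0.001, 0.8),
}

_INHIBITORY = {"fast_inh", "slow_inh"}


@dataclass(frozen=True)
class SynapseSpec:
    """A weighted, delayed, saturating connection of one of the five classes."""

    weight: float
    class_label: str
    delay: float = 0.0
    tau_syn: float = field(default=None)  # type: ignore[assignment]
    gamma_sat: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.class_label not in SYNAPSE_CLASSES:
            raise ValueError(f"unknown synapse class {self.class_label!r}")
        tau, gam = SYNAPSE_CLASSES[self.class_label]
        if self.tau_syn is None:
            object.__setattr__(self, "tau_syn", tau)
        if self.gamma_sat is None:
            object.__setattr__(self, "gamma_sat", gam)
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if not 0.0 <= self.gamma_sat <= 1.0:
            raise ValueError("gamma_sat must lie in [0, 1]")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")
        if self.class_label in _INHIBITORY and self.weight > 0:
            raise ValueError("inhibitory synapse classes carry negative weights")
        if self.class_label not in _INHIBITORY and self.weight < 0:
            raise ValueError("excitatory synapse classes carry nonnegative weights")

    @property
    def steady_state_gate(self):
        """Equilibrium gate value for a constant presynaptic rate r:
        s* = gamma*r*tau / (1 + gamma*r*tau)."""

        def s_star(rate: float) -> float:
            grt = self.gamma_sat * rate * self.tau_syn
            return grt / (1.0 + grt)

        return s_star


def fi_rate(current, p: FICurveParams = FICurveParams()):
    """Firing rate (Hz) for input current (nA) through the FI curve.

    Continuous at the singular point (value 1/theta) and clipped at zero:
    the closed form can produce tiny negative values through floating error
    far below threshold, but rates are physical quantities.
    """
    current = np.asarray(current, dtype=float)
    if not np.all(np.isfinite(current)):
        raise ValueError("non-finite input current")
    x = p.lambda_slope * current - p.beta_offset
    with np.errstate(over="ignore", invalid="ignore"):
        denom = 1.0 - np.exp(-p.theta_curvature * x)
        r = np.where(np.abs(x) < 1e-12, 1.0 / p.theta_curvature, x / denom)
    return np.maximum(r, 0.0)[()] if r.ndim == 0 else np.maximum(r, 0.0)


@dataclass
class NoiseState:
    """Ornstein-Uhlenbeck noise current of one node (nA)."""

    epsilon: float = 0.0
    tau_eps: float = 0.002
    sigma_eps: float = 0.025

    def __post_init__(self) -> None:
        if self.tau_eps <= 0:
            raise ValueError("tau_eps must be positive")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be nonnegative")


def ou_amplitude(dt: float, tau: float) -> float:
    """Per-step noise amplitude factor pinning the stationary SD of the
    discrete OU (AR(1)) update to sigma exactly: sqrt(1 - (1 - dt/tau)^2).
    Equals the Euler-Maruyama sqrt(2*dt/tau) in the small-step limit."""
    decay = 1.0 - dt / tau
    return float(np.sqrt(max(1.0 - decay * decay, 0.0)))


def ou_step(state: NoiseState, dt: float, rng: np.random.Generator) -> NoiseState:
    """One step of the discretized OU noise.

    The update is eps <- eps*(1 - dt/tau) + sigma*A(dt, tau)*N(0,1) with the
    amplitude chosen so that the stationary standard deviation equals
    ``sigma_eps`` exactly at any step size (sigma is the only printed noise
    magnitude, so it is pinned to that observable).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eps = state.epsilon * (1.0 - dt / state.tau_eps)
    if state.sigma_eps > 0:
        eps += state.sigma_eps * ou_amplitude(dt, state.tau_eps) * rng.standard_normal()
    return NoiseState(eps, state.tau_eps, state.sigma_eps)


@dataclass
class SynapseState:
    """Gating variable of one synapse, in [0, 1]."""

    s_gate: float = 0.0


def synapse_step(
    state: SynapseState, presyn_rate_delayed: float, spec: SynapseSpec, dt: float
) -> SynapseState:
    """Forward-Euler update of the gating variable for one time step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if presyn_rate_delayed < 0:
        raise ValueError("presynaptic rate must be nonnegative")
    s = state.s_gate
    s_new = s + dt * (-s / spec.tau_syn + spec.gamma_sat * (1.0 - s) * presyn_rate_delayed)
    if s_new < 0.0 or s_new > 1.0:
        # numerical overshoot only; the continuous system stays in [0, 1]
        s_new = float(np.clip(s_new, 0.0, 1.0))
    return SynapseState(s_new)


@dataclass
class NodeInputTerms:
    """Additive current terms entering one node (all nA)."""

    i_base: float = I_BASE
    epsilon: float = 0.0
    i_external: float = 0.0


def node_input(
    terms: NodeInputTerms, incoming: list[tuple[SynapseSpec, SynapseState]]
) -> float:
    """Summed input current: sum_j w_j*s_j + I_base + eps + I_ext."""
    syn = sum(spec.weight * st.s_gate for spec, st in incoming)
    return syn + terms.i_base + terms.epsilon + terms.i_external
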