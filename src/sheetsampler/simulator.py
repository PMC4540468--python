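"""Discrete-time stochastic simulation of the sampling network.

Neurons carry a binary state ``z_k(t)`` that is 1 for exactly ``τ̃ = τ/δt``
steps after each spike (rectangular PSP / absolute refractoriness).  Within a
time step, inputs are updated first, then network neurons are visited in a
fresh uniformly random order; a neuron that is inactive or in the last step
of its active phase may spike with probability ``σ(u_k − log τ̃)``, where the
membrane potential ``u_k`` integrates the *current* (partially updated)
states.  Under the neural computability condition the long-run occupancy of
network states equals the posterior of the associated generative model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .model import NetworkParameters
from .plasticity import PlasticityConfig
from .topology import Topology

__all__ = [
    "SimConfig",
    "InputSchedule",
    "SimState",
    "SimResult",
    "membrane_potential",
    "input_spike_probability",
    "step",
    "sample_input_trace",
    "run",
    "simulate_reference",
    "empirical_marginals",
    "empirical_state_distribution",
]


@dataclass
class SimConfig:
    """Simulation control parameters.

    ``duration`` is in seconds; the PSP/refractory time ``tau`` must be an
    integer multiple of the step ``dt`` (defaults: 10 ms and 1 ms).
    """

    duration: float
    dt: float = 0.001
    tau: float = 0.010
    seed: int = 0
    record_z: bool = False
    record_y: bool = False
    record_events: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ratio = self.tau / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("tau must be a positive integer multiple of dt")

    @property
    def tau_steps(self) -> int:
        return int(round(self.tau / self.dt))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


class InputSchedule:
    """Piecewise-constant target activations x_i(t) ∈ [0, 1).

    Segments tile the simulated interval exactly: ``seg_ends`` holds the
    exclusive end step of each segment and the last entry equals the total
    number of steps.
    """

    def __init__(self, x: np.ndarray, seg_ends: np.ndarray, dt: float = 0.001):
        self.x = np.atleast_2d(np.asarray(x, dtype=float))
        self.seg_ends = np.asarray(seg_ends, dtype=np.int64)
        self.dt = dt
        if self.x.shape[0] != self.seg_ends.shape[0]:
            raise ValueError("one activation row per segment required")
        if np.any(np.diff(self.seg_ends) <= 0) or (self.seg_ends.size and
                                                   self.seg_ends[0] <= 0):
            raise ValueError("segment ends must be strictly increasing")
        if np.any(self.x < 0) or np.any(self.x >= 1):
            raise ValueError("target activations must lie in [0, 1)")

    @property
    def N(self) -> int:
        return self.x.shape[1]

    @property
    def n_steps(self) -> int:
        return int(self.seg_ends[-1])

    @classmethod
    def constant(cls, x: np.ndarray, n_steps: int, dt: float = 0.001) -> "InputSchedule":
        return cls(np.atleast_2d(x), np.array([n_steps]), dt)

    @classmethod
    def from_segments(cls, segments, dt: float = 0.001) -> "InputSchedule":
        """Build from a list of (duration_seconds, activation_vector)."""
        xs, ends, acc = [], [], 0
        for dur, x in segments:
            steps = int(round(dur / dt))
            if steps <= 0:
                continue
            acc += steps
            xs.append(np.asarray(x, dtype=float))
            ends.append(acc)
        return cls(np.stack(xs), np.array(ends), dt)

    def x_at_step(self, t: int) -> np.ndarray:
        seg = int(np.searchsorted(self.seg_ends, t, side="right"))
        return self.x[seg]

    def spike_probs(self, tau_steps: int) -> np.ndarray:
        return input_spike_probability(self.x, tau_steps)

    def mean_activation(self) -> np.ndarray:
        """Time-weighted mean of the target activations."""
        lengths = np.diff(np.concatenate([[0], self.seg_ends]))
        return (self.x * lengths[:, None]).sum(axis=0) / self.seg_ends[-1]


def input_spike_probability(x: np.ndarray, tau_steps: int) -> np.ndarray:
    """Per-step spike probability p = 1 − (1 − x)^(1/τ̃).

    Chosen so that the long-run mean of the input state variable matches the
    target activation: an input is inactive iff no spike occurred in the last
    τ̃ steps, hence ⟨y⟩ = 1 − (1 − p)^τ̃ = x.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("target activation must lie in [0, 1)")
    return 1.0 - np.power(1.0 - x, 1.0 / tau_steps)


@dataclass
class SimState:
    """Explicit network/input state for step-by-step simulation.

    Countdowns hold the number of remaining active steps; a unit's state is 1
    exactly while its countdown is positive.
    """

    z: np.ndarray
    cnt_z: np.ndarray
    y: np.ndarray
    cnt_y: np.ndarray
    t_step: int = 0

    @classmethod
    def zeros(cls, K: int, N: int) -> "SimState":
        return cls(np.zeros(K, dtype=int), np.zeros(K, dtype=int),
                   np.zeros(N, dtype=int), np.zeros(N, dtype=int))


def step(params: NetworkParameters, state: SimState,
         rs: np.random.RandomState, tau_steps: int,
         input_probs: Optional[np.ndarray] = None,
         aff_idx: Optional[np.ndarray] = None) -> SimState:
    """Advance the network by one time step (in place; returns the state).

    Inputs update first (each spikes with its per-step probability, resetting
    its countdown; omitted when ``input_probs`` is None, leaving y clamped);
    then network neurons are visited in a fresh random order, and a neuron
    that is inactive or in the last step of its active phase spikes with
    probability σ(u − log τ̃) evaluated on the current, partially updated
    state.  The RNG stream is consumed in the same documented order as the
    compiled kernel.
    """
    p = params
    K, N = p.K, p.N
    if aff_idx is None:
        aff_idx = _prepare(p, None)
    log_tau = math.log(tau_steps)
    if input_probs is not None:
        for i in range(N):
            if state.cnt_y[i] > 0:
                state.cnt_y[i] -= 1
            if rs.random_sample() < input_probs[i]:
                state.cnt_y[i] = tau_steps
            state.y[i] = 1 if state.cnt_y[i] > 0 else 0
    order = list(range(K))
    for k in range(K - 1, 0, -1):
        j = rs.randint(0, k + 1)
        order[k], order[j] = order[j], order[k]
    for k in order:
        if state.cnt_z[k] <= 1:
            u = p.b[k] + (p.Wexc[k] + p.Winh[k]) @ state.z
            u += sum(p.V[k, i] for i in aff_idx[k] if state.y[i])
            prob = 1.0 / (1.0 + math.exp(-(u - log_tau)))
            if rs.random_sample() < prob:
                state.cnt_z[k] = tau_steps
                state.z[k] = 1
            else:
                state.cnt_z[k] = 0
                state.z[k] = 0
        else:
            state.cnt_z[k] -= 1
    state.t_step += 1
    return state


def sample_input_trace(schedule: InputSchedule, tau_steps: int,
                       rng: np.random.Generator,
                       n_steps: int | None = None) -> np.ndarray:
    """Sample a dense (n_steps, N) binary input-state trace from a schedule.

    Uses the same spike/countdown process as the kernel (a spike sets the
    state for τ̃ steps, non-additively) but an independent RNG, so the same
    trace can be replayed to many network simulations (spike-level identity).
    """
    if n_steps is None:
        n_steps = schedule.n_steps
    N = schedule.N
    seg_p = schedule.spike_probs(tau_steps)
    # per-step probability rows
    lengths = np.diff(np.concatenate([[0], schedule.seg_ends]))
    p_step = np.repeat(seg_p, lengths, axis=0)[:n_steps]
    spikes = rng.random((n_steps, N)) < p_step
    Y = np.zeros((n_steps, N), dtype=np.uint8)
    cnt = np.zeros(N, dtype=np.int64)
    for t in range(n_steps):
        cnt = np.maximum(cnt - 1, 0)
        cnt[spikes[t]] = tau_steps
        Y[t] = cnt > 0
    return Y


def membrane_potential(params: NetworkParameters, z: np.ndarray,
                       y: np.ndarray) -> np.ndarray:
    """u_k = b_k + Σ_j (W^exc + W^inh)_kj z_j + Σ_i V_ki y_i."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    return params.b + params.W @ z + params.V @ y


@dataclass
class SimResult:
    """Outputs of a simulation run."""

    config: SimConfig
    params: NetworkParameters          # final parameters (mutated by plasticity)
    z: Optional[np.ndarray] = None     # (n_steps, K) uint8
    y: Optional[np.ndarray] = None
    events: Optional[np.ndarray] = None  # (n_ev, 2): step, unit (unit >= K: input)
    spike_count: np.ndarray = None
    input_spike_count: np.ndarray = None
    zsum: np.ndarray = None
    zzsum: Optional[np.ndarray] = None
    measure_steps: int = 0
    wmean: Optional[np.ndarray] = None  # time-mean Wexc over the wsum window
    b_sleep: Optional[np.ndarray] = None
    checkpoints: Optional[dict] = None

    @property
    def mean_activity(self) -> np.ndarray:
        """⟨z_k⟩ over the measurement window."""
        return self.zsum / max(self.measure_steps, 1)

    @property
    def firing_rate(self) -> np.ndarray:
        """Spikes per second per neuron over the full run."""
        return self.spike_count / self.config.duration

    def coactivation(self) -> np.ndarray:
        """⟨z_k z_j⟩ over the measurement window (requires accumulate_zz)."""
        if self.zzsum is None:
            raise ValueError("run was not configured to accumulate coactivations")
        return self.zzsum / max(self.measure_steps, 1)


def _prepare(params: NetworkParameters, topology: Optional[Topology]):
    K, N = params.K, params.N
    if topology is not None:
        aff_idx = topology.aff_idx
    else:
        aff_idx = np.tile(np.arange(N, dtype=np.int64), (K, 1))
    return aff_idx


def run(params: NetworkParameters, sim: SimConfig,
        schedule: Optional[InputSchedule] = None, *,
        topology: Optional[Topology] = None,
        fixed_y: Optional[np.ndarray] = None,
        y_trace: Optional[np.ndarray] = None,
        plasticity: Optional[PlasticityConfig] = None,
        exc_mask: Optional[np.ndarray] = None,
        measure_start: int = 0,
        accumulate_zz: bool = False,
        wsum_start: Optional[int] = None,
        checkpoint_every_s: Optional[float] = None,
        copy_params: bool = True) -> SimResult:
    """Execute a simulation run; bit-for-bit reproducible given the seed.

    Exactly one of ``schedule`` (stochastic spiking input) or ``fixed_y``
    (clamped input state) must be provided, except for input-free networks
    (N == 0 afferent drive, pass ``fixed_y`` of zeros).  When ``plasticity``
    is given, its rules are applied once per time step (Euler discretization)
    and the returned parameters are the learned ones.
    """
    p = params.copy() if copy_params else params
    K, N = p.K, p.N
    n_steps = sim.n_steps
    tau_steps = sim.tau_steps
    aff_idx = _prepare(p, topology)

    use_trace = y_trace is not None
    clamp = schedule is None and not use_trace
    if use_trace:
        y_trace = np.ascontiguousarray(y_trace, dtype=np.uint8)
        if y_trace.shape != (n_steps, N):
            raise ValueError("y_trace must have shape (n_steps, N)")
        y0 = np.zeros(N, dtype=np.int8)
        cnt_y0 = np.zeros(N, dtype=np.int64)
        seg_ends = np.array([n_steps], dtype=np.int64)
        seg_p = np.zeros((1, N))
    elif clamp:
        if fixed_y is None:
            fixed_y = np.zeros(N)
        y0 = np.asarray(fixed_y, dtype=np.int8).copy()
        cnt_y0 = (y0.astype(np.int64)) * tau_steps
        seg_ends = np.array([n_steps], dtype=np.int64)
        seg_p = np.zeros((1, N))
    else:
        if schedule.N != N:
            raise ValueError("schedule width does not match the input count")
        if schedule.n_steps < n_steps:
            raise ValueError("schedule does not cover the simulated interval")
        y0 = np.zeros(N, dtype=np.int8)
        cnt_y0 = np.zeros(N, dtype=np.int64)
        seg_ends = schedule.seg_ends
        seg_p = schedule.spike_probs(tau_steps)

    z0 = np.zeros(K, dtype=np.int8)
    cnt_z0 = np.zeros(K, dtype=np.int64)

    if plasticity is None:
        rule = _kernels.RULE_NONE
        aff_on, eta_V, eta_b, eta_W = False, 0.0, 0.0, 0.0
        m = np.zeros(K)
        Wmax, gamma, clip = 1.0, 1.0, True
        pairs = np.zeros((0, 2), dtype=np.int64)
    else:
        plasticity.validate(K)
        if plasticity.eta_V > 0 and p.family != "bernoulli":
            raise NotImplementedError(
                "the compiled run path applies the Bernoulli-family afferent "
                "rule; use plasticity.afferent_update for other families")
        rule = {"none": _kernels.RULE_NONE,
                "heuristic": _kernels.RULE_HEURISTIC,
                "wakesleep": _kernels.RULE_WAKESLEEP}[plasticity.rule]
        aff_on = plasticity.eta_V > 0
        eta_V, eta_b, eta_W = plasticity.eta_V, plasticity.eta_b, plasticity.eta_W
        m = np.asarray(plasticity.m, dtype=float)
        Wmax, gamma = plasticity.W_max, plasticity.gamma
        clip = plasticity.nonneg_clip
        if exc_mask is None and topology is not None:
            exc_mask = topology.exc_mask
        if exc_mask is None or rule == _kernels.RULE_NONE:
            pairs = np.zeros((0, 2), dtype=np.int64)
        else:
            iu = np.argwhere(np.triu(exc_mask, k=1)).astype(np.int64)
            pairs = np.ascontiguousarray(iu)

    b_sleep = p.b.copy() if rule == _kernels.RULE_WAKESLEEP else np.zeros(K)
    z_sleep = np.zeros(K, dtype=np.int8)
    cnt_sleep = np.zeros(K, dtype=np.int64)

    rec_z = np.zeros((n_steps if sim.record_z else 0, K), dtype=np.uint8)
    rec_y = np.zeros((n_steps if sim.record_y else 0, N), dtype=np.uint8)
    zsum = np.zeros(K)
    zzsum = np.zeros((K, K) if accumulate_zz else (0, 0))
    spike_count = np.zeros(K, dtype=np.int64)
    input_spike_count = np.zeros(N, dtype=np.int64)
    if wsum_start is None:
        wsum_start = n_steps  # off
    wsum = np.zeros((K, K))

    if checkpoint_every_s:
        ckpt_every = int(round(checkpoint_every_s / sim.dt))
        n_ckpt = n_steps // ckpt_every
    else:
        ckpt_every, n_ckpt = 0, 0
    ckpt_V = np.zeros((n_ckpt, K, N))
    ckpt_b = np.zeros((n_ckpt, K))
    ckpt_W = np.zeros((n_ckpt, K, K))

    if sim.record_events:
        max_ev = int(n_steps * (K / tau_steps + np.sum(seg_p.mean(axis=0)))) + 1024
    else:
        max_ev = 0
    events = np.zeros((max_ev, 2), dtype=np.int64)
    ev_count = np.zeros(1, dtype=np.int64)

    if not use_trace:
        y_trace = np.zeros((0, 0), dtype=np.uint8)
    _kernels.run_core(
        sim.seed, n_steps, tau_steps,
        seg_ends, seg_p, clamp,
        use_trace, y_trace,
        p.V, p.V0, p.b, p.Wexc, p.Winh, aff_idx,
        z0, cnt_z0, y0, cnt_y0,
        rule, aff_on, eta_V, eta_b, eta_W, sim.dt,
        m, Wmax, gamma, clip,
        b_sleep, z_sleep, cnt_sleep, pairs,
        rec_z, rec_y,
        measure_start, zsum, zzsum, accumulate_zz,
        spike_count, input_spike_count,
        wsum_start, wsum,
        ckpt_every, ckpt_V, ckpt_b, ckpt_W,
        sim.record_events, events, ev_count)

    checkpoints = None
    if n_ckpt:
        checkpoints = {
            "t": (np.arange(1, n_ckpt + 1) * ckpt_every) * sim.dt,
            "V": ckpt_V, "b": ckpt_b, "Wexc": ckpt_W,
        }
    wmean = None
    if wsum_start < n_steps:
        wmean = wsum / (n_steps - wsum_start)
    return SimResult(
        config=sim, params=p,
        z=rec_z if sim.record_z else None,
        y=rec_y if sim.record_y else None,
        events=events[:ev_count[0]] if sim.record_events else None,
        spike_count=spike_count, input_spike_count=input_spike_count,
        zsum=zsum, zzsum=zzsum if accumulate_zz else None,
        measure_steps=n_steps - measure_start,
        wmean=wmean,
        b_sleep=b_sleep if rule == _kernels.RULE_WAKESLEEP else None,
        checkpoints=checkpoints)


def simulate_reference(params: NetworkParameters, sim: SimConfig,
                       schedule: Optional[InputSchedule] = None, *,
                       topology: Optional[Topology] = None,
                       fixed_y: Optional[np.ndarray] = None) -> np.ndarray:
    """Pure-Python simulator consuming the RNG stream in the kernel's order.

    Returns the dense (n_steps, K) state trace.  Used as a bit-exact oracle
    for the JIT kernel on small problems; no plasticity support.
    """
    p = params
    K, N = p.K, p.N
    n_steps, tau_steps = sim.n_steps, sim.tau_steps
    aff_idx = _prepare(p, topology)
    rs = np.random.RandomState(sim.seed)

    clamp = schedule is None
    state = SimState.zeros(K, N)
    if clamp:
        if fixed_y is not None:
            state.y = np.asarray(fixed_y, dtype=int).copy()
            state.cnt_y = state.y * tau_steps
    else:
        seg_p = schedule.spike_probs(tau_steps)
    out = np.zeros((n_steps, K), dtype=np.uint8)
    seg = 0
    for t in range(n_steps):
        if clamp:
            probs = None
        else:
            while t >= schedule.seg_ends[seg]:
                seg += 1
            probs = seg_p[seg]
        step(p, state, rs, tau_steps, input_probs=probs, aff_idx=aff_idx)
        out[t] = state.z
    return out


def empirical_marginals(z_traces: np.ndarray, kernel_width: float,
                        dt: float = 0.001) -> np.ndarray:
    """Boxcar-smoothed per-neuron activation time series.

    ``z_traces`` is (n_steps, K) or (runs, n_steps, K); multiple runs are
    averaged before smoothing.  ``kernel_width`` is in seconds.
    """
    Z = np.asarray(z_traces, dtype=float)
    if Z.ndim == 3:
        Z = Z.mean(axis=0)
    w = int(round(kernel_width / dt))
    if w < 1:
        raise ValueError("kernel width must be at least one step")
    kern = np.ones(w) / w
    return np.stack([np.convolve(Z[:, k], kern, mode="same")
                     for k in range(Z.shape[1])], axis=1)


def empirical_state_distribution(z_trace: np.ndarray, burn_in: int = 0):
    """Occupancy frequency of network states after a burn-in.

    Returns ``(states, freqs)`` with states as a (M, K) array sorted
    lexicographically and frequencies summing to one.
    """
    Z = np.asarray(z_trace)
    if burn_in >= Z.shape[0]:
        raise ValueError("burn-in exceeds the trace length")
    Z = Z[burn_in:]
    K = Z.shape[1]
    shifts = np.arange(K - 1, -1, -1)
    codes = (Z.astype(np.int64) << shifts[None, :]).sum(axis=1)
    uniq, counts = np.unique(codes, return_counts=True)
    states = ((uniq[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    return states, counts / counts.sum()
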