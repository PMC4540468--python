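"""Experiment protocols: input generators, training loops and metrics.

Five study protocols exercise the model end to end; each has a short
descriptive id:

* ``tracking`` — a 6-neuron chain with fixed, analytically tractable
  parameters samples the time-varying posterior under transient structured
  input; repeated runs with spike-identical input are compared against the
  enumerated posterior marginals.
* ``experts``  — a 7×3 sheet with overlapping afferent fields learns local
  activity patterns (Dirichlet-drawn, Gamma-process timing) through afferent
  Hebbian and homeostatic plasticity, turning neurons into probabilistic
  local experts.
* ``cues``     — seven winner-take-all populations connected all-to-all learn
  the correlation structure of a cue/consistency stripe task through
  recurrent plasticity (wake-sleep or the local heuristic rule).
* ``sheet``    — a 12×12 sheet with sparse recurrent excitation learns
  spatial motifs presented at random locations; similarly tuned neurons form
  excitatory subnetworks.
* ``nested``   — a 2-neuron WTA exposed to nested weak/strong patterns
  illustrates why homeostatic intrinsic plasticity is needed; with fixed
  biases one neuron runs away and the other falls silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (GenerativeModel, NetworkParameters,
                    calibrate_prior_biases, enumerate_states, log_likelihood,
                    network_from_model, valid_states, STRONG_INHIBITION)
from .plasticity import PlasticityConfig
from .simulator import (InputSchedule, SimConfig, empirical_marginals, run,
                        sample_input_trace)
from .topology import (Topology, build_grid_sheet, build_population_topology,
                       sample_excitatory_mask)

__all__ = [
    "EXPERIMENTS",
    "TABLE_DEFAULTS",
    "ExperimentConfig",
    "MetricReport",
    "gen_tracking_input",
    "gen_experts_input",
    "gen_cues_input",
    "gen_cue_probe_input",
    "gen_sheet_input",
    "gen_nested_input",
    "stripe_patterns",
    "motif_value",
    "label_tuning",
    "label_tuning_motifs",
    "run_experiment",
    "marginal_comparison",
]

EXPERIMENTS = ("tracking", "experts", "cues", "sheet", "nested")

#: Default simulation parameters per experiment (time step 1 ms and
#: PSP/refractory time 10 ms throughout; inhibitory weight −100).
TABLE_DEFAULTS: dict[str, dict] = {
    "tracking": dict(duration=2.5, K=6, input_shape=(6, 18), field=(6, 6),
                     spacing=(0, 3), pi0=0.2, activity=(0.2, 0.55),
                     bhat=-1.0, exc_pairs=((0, 2), (2, 4), (3, 5)),
                     exc_weight=1.0,
                     eta_b=0.0, eta_V=0.0, eta_W=0.0),
    "experts": dict(duration=10000.0, neuron_shape=(3, 7),
                    input_shape=(6, 21), field=(6, 6), spacing=(0, 3),
                    pi0=0.1, activity=(0.1, 0.6), m=0.065, b_init=-2.0,
                    eta_b=1.0, eta_V=0.2, eta_W=0.0,
                    pattern_duration=0.2),
    "cues": dict(duration=25000.0, n_pops=7, pop_size=3, field=(6, 6),
                 pi0=0.1, activity=(0.1, 0.4), m=0.95 / 3, b_init=-1.0,
                 eta_b=0.1, eta_V=0.1, eta_W=0.005, eta_W_wakesleep=0.05,
                 W_max=1.41, gamma=31.6, pattern_duration=0.25),
    "sheet": dict(duration=10000.0, neuron_shape=(12, 12),
                  input_shape=(24, 24), field=(6, 6), spacing=(2, 2),
                  inhibition_range=2, p_conn=0.25,
                  pi0=0.1, activity=(0.1, 0.5), m=0.025, b_init=-3.0,
                  eta_b=10.0, eta_V=2.0, eta_W=1.0,
                  W_max=2.7049, gamma=733.69, pattern_duration=0.1),
    "nested": dict(duration=5000.0, K=2, field=(6, 6), pi0=0.2,
                   activity=(0.2, 0.8), m=0.32, b_init=-2.0,
                   eta_b=1.5, eta_V=0.3, eta_W=0.0, pattern_duration=1.0),
}

W_INH = STRONG_INHIBITION


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run.

    ``duration`` overrides the default simulated time (seconds);
    ``recurrent_rule`` selects none/heuristic/wakesleep for experiments with
    plastic recurrent synapses; ``overrides`` patches any default parameter.
    """

    experiment: str
    seed: int = 0
    duration: Optional[float] = None
    recurrent_rule: str = "heuristic"
    n_runs: int = 200                 # tracking: number of repetitions
    compute_loglik: bool = False
    loglik_samples: int = 10000
    checkpoint_every_s: Optional[float] = None
    fixed_bias: Optional[float] = None  # nested: disable homeostasis at this b
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENTS}")

    def defaults(self) -> dict:
        d = dict(TABLE_DEFAULTS[self.experiment])
        d.update(self.overrides)
        if self.duration is not None:
            d["duration"] = self.duration
        return d


@dataclass
class MetricReport:
    """Machine-readable summary of an experiment run."""

    experiment: str
    seed: int
    duration: float
    metrics: dict
    tables: dict = field(default_factory=dict)
    loglik_trace: Optional[pd.DataFrame] = None

    def validate_finite(self) -> None:
        for k, v in self.metrics.items():
            arr = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"metric {k!r} contains non-finite entries")


# ---------------------------------------------------------------------------
# input generators
# ---------------------------------------------------------------------------


def gen_tracking_input(rng: np.random.Generator, cfg: dict,
                       topology: Topology):
    """Pattern/background alternation for the 6-neuron tracking chain.

    Each neuron owns a preferred local activity pattern drawn uniformly from
    the configured range; time is tiled with random-length segments in which
    a random subset of mutually non-overlapping locations shows its pattern
    and all remaining inputs fire at the background activity.
    """
    lo, hi = cfg["activity"]
    pi0 = cfg["pi0"]
    K, N = topology.K, topology.N
    F = topology.field_size
    patterns = rng.uniform(lo, hi, size=(K, F))
    duration = cfg["duration"]
    segs = []
    t = 0.0
    while t < duration:
        dur = rng.uniform(0.05, 0.25)
        x = np.full(N, pi0)
        order = rng.permutation(K)
        active: list[int] = []
        for k in order:
            if rng.random() < 0.4 and not any(
                    topology.inh_mask[k, j] for j in active):
                active.append(k)
                x[topology.aff_idx[k]] = patterns[k]
        segs.append((min(dur, duration - t), x))
        t += dur
    return InputSchedule.from_segments(segs), patterns


def gen_experts_input(rng: np.random.Generator, cfg: dict,
                      topology: Topology, n_patterns: int = 3,
                      n_chains: int = 3, patterns: np.ndarray | None = None):
    """Dirichlet-drawn local patterns with Gamma-process on/off chains.

    Per location l and input j, the three pattern activities are
    0.5·Dirichlet(0.3, 0.3, 0.3) + 0.1 (range [0.1, 0.6]).  Independent
    chains alternate inactive phases (Gamma(k=10, θ=10) ms) and active phases
    (Gamma(k=10, θ=20) ms, i.e. 200 ms on average); an activating chain picks
    a uniform pattern and a location whose afferent field does not overlap
    any other active chain's location.
    """
    duration = cfg["duration"]
    pi0 = cfg["pi0"]
    N = topology.N
    F = topology.field_size
    # one population per distinct afferent field
    fields, loc_of_neuron = [], []
    seen: dict[tuple, int] = {}
    for k in range(topology.K):
        key = tuple(topology.aff_idx[k])
        if key not in seen:
            seen[key] = len(fields)
            fields.append(topology.aff_idx[k])
        loc_of_neuron.append(seen[key])
    L = len(fields)
    overlap = np.zeros((L, L), dtype=bool)
    for a in range(L):
        for c in range(a + 1, L):
            if set(fields[a].tolist()) & set(fields[c].tolist()):
                overlap[a, c] = overlap[c, a] = True

    if patterns is None:
        raw = rng.dirichlet([0.3] * n_patterns, size=(L, F))  # (L, F, P)
        patterns = 0.5 * np.transpose(raw, (0, 2, 1)) + 0.1   # (L, P, F)

    events = []  # (t_on, t_off, l, p)
    # event-driven: chains activate in chronological order, each avoiding the
    # locations of chains active at that moment (at most n_chains-1, so a free
    # location always exists when the architecture has enough sites)
    next_on = [rng.gamma(10.0, 10.0) / 1000.0 for _ in range(n_chains)]
    current: list[tuple[float, int] | None] = [None] * n_chains
    while True:
        c = int(np.argmin(next_on))
        t = next_on[c]
        if t >= duration:
            break
        dur = rng.gamma(10.0, 20.0) / 1000.0
        blocked: set[int] = set()
        for cc in range(n_chains):
            if cc != c and current[cc] is not None:
                t_off, l_cc = current[cc]
                if t_off > t:
                    blocked.add(l_cc)
                    blocked.update(np.flatnonzero(overlap[l_cc]).tolist())
        free = [l for l in range(L) if l not in blocked]
        assert free, "no non-overlapping location available"
        l = free[rng.integers(len(free))]
        p = int(rng.integers(n_patterns))
        events.append((t, t + dur, l, p))
        current[c] = (t + dur, l)
        next_on[c] = t + dur + rng.gamma(10.0, 10.0) / 1000.0

    dt = 0.001
    n_steps = int(round(duration / dt))
    bounds = {0, n_steps}
    ev_steps = []
    for (a, bnd, l, p) in events:
        sa, sb = int(round(a / dt)), min(int(round(bnd / dt)), n_steps)
        if sa < sb:
            bounds.update((sa, sb))
            ev_steps.append((sa, sb, l, p))
    cut = np.array(sorted(bounds))
    X = np.full((len(cut) - 1, N), pi0)
    starts = cut[:-1]
    for (sa, sb, l, p) in ev_steps:
        rows = np.flatnonzero((starts >= sa) & (starts < sb))
        X[np.ix_(rows, fields[l])] = patterns[l, p]
    schedule = InputSchedule(X, cut[1:], dt)
    return schedule, patterns, np.array(loc_of_neuron)


def stripe_patterns(field: tuple[int, int] = (6, 6), high: float = 0.4,
                    low: float = 0.1) -> np.ndarray:
    """Three width-2 vertical stripe patterns over a field, as (3, F) rows."""
    fr, fc = field
    cols = np.arange(fc)
    out = np.full((3, fr, fc), low)
    for p in range(3):
        out[p, :, (cols // 2) % 3 == p] = high
    return out.reshape(3, fr * fc)


def gen_cues_input(rng: np.random.Generator, cfg: dict, topology: Topology):
    """Cue/consistency stripe protocol for the seven-population network.

    The two outer locations show independently chosen cue patterns; the five
    inner locations all show the same pattern, which must differ from both
    cues.  Distinct cues determine the inner pattern uniquely (500 ms per
    combination); equal cues are ambiguous and the two valid inner patterns
    are shown for 250 ms each.  The nine cue combinations are cycled in fixed
    order, so all appear equally often.
    """
    high, low = cfg["activity"][1], cfg["activity"][0]
    duration = cfg["duration"]
    stripes = stripe_patterns(cfg["field"], high=high, low=low)
    n_pops = cfg["n_pops"]
    F = stripes.shape[1]
    inner = list(range(1, n_pops - 1))
    segs, labels = [], []
    t = 0.0
    while t < duration:
        for pl in range(3):
            for pr in range(3):
                others = [q for q in range(3) if q != pl and q != pr]
                if pl != pr:
                    choices = [(others[0], 0.5)]
                else:
                    choices = [(others[0], 0.25), (others[1], 0.25)]
                for p_in, dur in choices:
                    x = np.empty(n_pops * F)
                    blocks = np.full((n_pops, F), 0.0)
                    blocks[0] = stripes[pl]
                    blocks[-1] = stripes[pr]
                    for l in inner:
                        blocks[l] = stripes[p_in]
                    x = _blocks_to_input(blocks, topology)
                    segs.append((dur, x))
                    labels.append((pl, pr, p_in))
                    t += dur
                    if t >= duration:
                        break
                if t >= duration:
                    break
            if t >= duration:
                break
    return InputSchedule.from_segments(segs), labels, stripes


def _blocks_to_input(blocks: np.ndarray, topology: Topology) -> np.ndarray:
    """Scatter per-location field blocks into the flat input vector."""
    n_pops, F = blocks.shape
    x = np.empty(topology.N)
    pop_size = topology.K // n_pops
    for l in range(n_pops):
        k = l * pop_size
        x[topology.aff_idx[k]] = blocks[l]
    return x


def gen_cue_probe_input(pl: int, pr: int, duration: float, cfg: dict,
                        topology: Topology) -> InputSchedule:
    """Incomplete-observation probe: high-contrast cues, uninformative inner.

    Cue locations show their stripe pattern at raised contrast (0.6/0.1);
    all inner locations show a uniform "gray" activity of intermediate
    intensity, carrying no information about the pattern identity.
    """
    stripes = stripe_patterns(cfg["field"], high=0.6, low=0.1)
    n_pops = cfg["n_pops"]
    F = stripes.shape[1]
    blocks = np.full((n_pops, F), (0.6 + 0.1) / 2)
    blocks[0] = stripes[pl]
    blocks[-1] = stripes[pr]
    x = _blocks_to_input(blocks, topology)
    return InputSchedule.from_segments([(duration, x)])


def motif_value(motif: int, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Binary template of the three spatial motifs at absolute coordinates.

    0: grid lines (every other row or column), 1: width-2 diagonal stripes,
    2: 2×2 checkerboard.
    """
    if motif == 0:
        return (r % 2 == 0) | (c % 2 == 0)
    if motif == 1:
        return ((r + c) % 4) < 2
    return ((r // 2 + c // 2) % 2) == 0


def gen_sheet_input(rng: np.random.Generator, cfg: dict,
                    input_shape: tuple[int, int]):
    """Motifs at random torus locations, redrawn every pattern period.

    Two (possibly equal) motifs appear simultaneously at non-overlapping
    locations with a square footprint whose diameter exceeds the afferent
    field; motif pixels fire at the high rate and everything else at the
    background rate.
    """
    R, C = input_shape
    low, high = cfg["activity"]
    duration = cfg["duration"]
    period = cfg["pattern_duration"]
    n_segs = int(round(duration / period))
    segs = []
    rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    for _ in range(n_segs):
        x = np.full((R, C), low)
        placed: list[tuple[int, int, int]] = []
        for _ in range(2):
            for _attempt in range(200):
                d = int(rng.integers(8, 13))
                r0 = int(rng.integers(R))
                c0 = int(rng.integers(C))
                if all(_boxes_overlap(r0, c0, d, *prev, R, C) is False
                       for prev in placed):
                    break
            else:
                raise RuntimeError("motif placement retry budget exhausted")
            motif = int(rng.integers(3))
            rows = (np.arange(d) + r0) % R
            cols = (np.arange(d) + c0) % C
            tmpl = motif_value(motif, *np.meshgrid(np.arange(d), np.arange(d),
                                                   indexing="ij"))
            vals = np.where(tmpl, high, low)
            x[np.ix_(rows, cols)] = np.maximum(x[np.ix_(rows, cols)], vals)
            placed.append((r0, c0, d))
        segs.append((period, x.ravel()))
    return InputSchedule.from_segments(segs)


def _boxes_overlap(r0, c0, d0, r1, c1, d1, R, C) -> bool:
    def axis_overlap(a0, da, a1, db, size) -> bool:
        diff = (a1 - a0) % size
        return diff < da or (size - diff) % size < db or diff == 0

    return (axis_overlap(r0, d0, r1, d1, R) and
            axis_overlap(c0, d0, c1, d1, C))


def gen_nested_input(cfg: dict):
    """Strong / nested-weak / background patterns in equal time shares.

    The weak pattern's active set is a strict subset of the strong one —
    the hardest case for learning, since the strong expert always receives
    more afferent drive whenever the weak pattern is shown.
    """
    fr, fc = cfg["field"]
    lo, hi = cfg["activity"]
    strong_mask = np.zeros((fr, fc), dtype=bool)
    strong_mask[: fr - 2] = True           # 4 of 6 rows
    weak_mask = np.zeros_like(strong_mask)
    weak_mask[: fr - 4] = True             # 2 of 6 rows, strict subset
    strong = np.where(strong_mask, hi, lo).ravel()
    weak = np.where(weak_mask, hi, lo).ravel()
    background = np.full(fr * fc, lo)
    duration = cfg["duration"]
    seg = cfg["pattern_duration"]
    segs = []
    t, i = 0.0, 0
    cycle = [strong, weak, background]
    while t < duration:
        d = min(seg, duration - t)
        segs.append((d, cycle[i % 3]))
        t += d
        i += 1
    return InputSchedule.from_segments(segs), {"strong": strong, "weak": weak}


# ---------------------------------------------------------------------------
# analysis helpers
# ---------------------------------------------------------------------------


def label_tuning(V: np.ndarray, topology: Topology,
                 templates: np.ndarray) -> np.ndarray:
    """Assign each neuron the template best correlated with its weights.

    ``templates`` is (P, F) over the afferent-field pixels; correlation is
    computed between V restricted to the neuron's field and each template.
    """
    K = topology.K
    labels = np.empty(K, dtype=np.int64)
    for k in range(K):
        v = V[k, topology.aff_idx[k]]
        cors = []
        for tmpl in templates:
            sv, st = np.std(v), np.std(tmpl)
            cors.append(0.0 if sv == 0 or st == 0 else
                        float(np.corrcoef(v, tmpl)[0, 1]))
        labels[k] = int(np.argmax(cors))
    return labels


def label_tuning_motifs(V: np.ndarray, topology: Topology,
                        high: float = 0.5, low: float = 0.1) -> np.ndarray:
    """Motif tuning labels: best correlation over motifs and torus phases."""
    fr = fc = int(round(np.sqrt(topology.field_size)))
    K = topology.K
    labels = np.empty(K, dtype=np.int64)
    phases = [(pr, pc) for pr in range(4) for pc in range(4)]
    for k in range(K):
        v = V[k, topology.aff_idx[k]]
        best = np.full(3, -np.inf)
        rr, cc = np.meshgrid(np.arange(fr), np.arange(fc), indexing="ij")
        for motif in range(3):
            for pr, pc in phases:
                tmpl = np.where(motif_value(motif, rr + pr, cc + pc),
                                high, low).ravel()
                if np.std(v) == 0:
                    continue
                cor = float(np.corrcoef(v, tmpl)[0, 1])
                best[motif] = max(best[motif], cor)
        labels[k] = int(np.argmax(best))
    return labels


def cue_weight_groups(wmean: np.ndarray, labels: np.ndarray,
                      topology: Topology, n_pops: int, pop_size: int
                      ) -> pd.DataFrame:
    """Group the converged recurrent weights of the cue task.

    Groups: inner pairs with equal tuning; cue/inner pairs with compatible
    (differing) tuning; the two cue neurons with equal tuning; and all
    remaining pairs.  Returns per-group mean, max and count.
    """
    pop = np.repeat(np.arange(n_pops), pop_size)
    is_cue = (pop == 0) | (pop == n_pops - 1)
    rows = {g: [] for g in ("inner_same", "cue_inner_compatible",
                            "cue_cue_same", "other")}
    K = topology.K
    for k in range(K):
        for j in range(k + 1, K):
            if not topology.exc_mask[k, j]:
                continue
            w = wmean[k, j]
            same = labels[k] == labels[j]
            if not is_cue[k] and not is_cue[j]:
                g = "inner_same" if same else "other"
            elif is_cue[k] and is_cue[j]:
                g = "cue_cue_same" if same else "other"
            else:
                g = "other" if same else "cue_inner_compatible"
            rows[g].append(w)
    rec = [(g, float(np.mean(v)) if v else np.nan,
            float(np.max(v)) if v else np.nan, len(v))
           for g, v in rows.items()]
    return pd.DataFrame(rec, columns=["group", "mean_weight", "max_weight",
                                      "n_pairs"]).set_index("group")


def marginal_comparison(z_traces: np.ndarray, exact_marginals: np.ndarray,
                        kernel_width: float = 0.020, dt: float = 0.001,
                        discard: int = 0) -> dict:
    """Compare averaged network response with exact posterior marginals.

    ``z_traces`` is (runs, n_steps, K) from repetitions with spike-identical
    input, ``exact_marginals`` is (n_steps, K).  Returns the raw and
    box-smoothed mismatch arrays plus summary statistics; a leading/trailing
    ``discard`` window is dropped to avoid burn-in and smoothing-boundary
    artifacts.
    """
    Z = np.asarray(z_traces, dtype=float)
    if Z.ndim != 3:
        raise ValueError("z_traces must be (runs, n_steps, K)")
    if Z.shape[1] != exact_marginals.shape[0]:
        raise ValueError("trace and oracle lengths differ")
    p_net_raw = Z.mean(axis=0)
    p_net = empirical_marginals(Z, kernel_width, dt)
    p_theo = empirical_marginals(exact_marginals, kernel_width, dt)
    sl = slice(discard, Z.shape[1] - discard if discard else None)
    raw = (p_net_raw - exact_marginals)[sl]
    smooth = (p_net - p_theo)[sl]
    return {
        "mismatch_raw": raw,
        "mismatch_smoothed": smooth,
        "median_abs_smoothed": float(np.median(np.abs(smooth))),
        "median_abs_raw": float(np.median(np.abs(raw))),
        "mean_abs_smoothed": float(np.mean(np.abs(smooth))),
    }


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------


def build_tracking_network(rng: np.random.Generator, cfg: dict):
    """Fixed-parameter chain network with known generative model."""
    topo = build_grid_sheet(cfg["input_shape"], (1, cfg["K"]), cfg["field"],
                            cfg["spacing"])
    exc = np.zeros((cfg["K"], cfg["K"]), dtype=bool)
    for (a, c) in cfg["exc_pairs"]:
        exc[a, c] = exc[c, a] = True
    topo.exc_mask = exc & ~topo.inh_mask
    schedule, patterns = gen_tracking_input(rng, cfg, topo)
    pi = np.full((topo.K, topo.N), cfg["pi0"])
    for k in range(topo.K):
        pi[k, topo.aff_idx[k]] = patterns[k]
    model = GenerativeModel(
        family="bernoulli", params=pi, defaults=np.full(topo.N, cfg["pi0"]),
        Wexc_hat=np.where(topo.exc_mask, cfg["exc_weight"], 0.0),
        Winh_hat=np.where(topo.inh_mask, W_INH, 0.0),
        bhat=np.full(topo.K, cfg["bhat"]))
    params = network_from_model(model)
    return topo, model, params, schedule, patterns


def _fresh_params(topology: Topology, cfg: dict) -> NetworkParameters:
    """Zero-weight parameters with uniform initial excitability."""
    K, N = topology.K, topology.N
    from scipy.special import logit
    V0 = np.full(N, logit(cfg["pi0"]))
    A0 = np.log1p(np.exp(V0))
    return NetworkParameters(
        V=np.zeros((K, N)), V0=V0, A=np.zeros(K), A0=A0,
        b=np.full(K, cfg["b_init"]),
        Wexc=np.zeros((K, K)),
        Winh=np.where(topology.inh_mask, W_INH, 0.0))


def _model_from_learned(params: NetworkParameters, pi0: float,
                        bhat: np.ndarray) -> GenerativeModel:
    pi = expit(params.V + params.V0[None, :])
    return GenerativeModel(
        family="bernoulli", params=pi,
        defaults=np.full(params.N, pi0),
        Wexc_hat=params.Wexc.copy(), Winh_hat=params.Winh.copy(),
        bhat=bhat)


def _loglik_samples(schedule: InputSchedule, S: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw S held-out binary input samples from the training statistics."""
    lengths = np.diff(np.concatenate([[0], schedule.seg_ends]))
    seg = rng.choice(len(lengths), size=S, p=lengths / lengths.sum())
    return (rng.random((S, schedule.N)) < schedule.x[seg]).astype(float)


def _loglik_trace(checkpoints: dict, topology: Topology, pi0: float,
                  m: np.ndarray, Y: np.ndarray, states: np.ndarray
                  ) -> pd.DataFrame:
    recs = []
    Winh = np.where(topology.inh_mask, W_INH, 0.0)
    for c, t in enumerate(checkpoints["t"]):
        V = checkpoints["V"][c]
        Wexc = checkpoints["Wexc"][c]
        pi = expit(V + np.full(V.shape[1], _logit(pi0))[None, :])
        model = GenerativeModel(
            family="bernoulli", params=pi,
            defaults=np.full(V.shape[1], pi0),
            Wexc_hat=Wexc, Winh_hat=Winh,
            bhat=np.zeros(V.shape[0]))
        bhat = calibrate_prior_biases(Wexc, Winh, m, states=states)
        ll = log_likelihood(Y, model, bhat=bhat, states=states)
        recs.append((float(t), ll))
    return pd.DataFrame(recs, columns=["t", "loglik"])


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def run_experiment(config: ExperimentConfig) -> MetricReport:
    """Wire topology, simulator and plasticity for one protocol and run it."""
    cfg = config.defaults()
    rng = np.random.default_rng(config.seed)
    sim_seed = int(rng.integers(2 ** 31 - 1))
    name = config.experiment
    if name == "tracking":
        return _run_tracking(config, cfg, rng, sim_seed)
    if name == "experts":
        return _run_experts(config, cfg, rng, sim_seed)
    if name == "cues":
        return _run_cues(config, cfg, rng, sim_seed)
    if name == "sheet":
        return _run_sheet(config, cfg, rng, sim_seed)
    return _run_nested(config, cfg, rng, sim_seed)


def _run_tracking(config, cfg, rng, sim_seed) -> MetricReport:
    topo, model, params, schedule, patterns = build_tracking_network(rng, cfg)
    n_steps = int(round(cfg["duration"] / 0.001))
    tau_steps = 10
    Y = sample_input_trace(schedule, tau_steps, rng, n_steps)
    # exact transient posterior marginals for the realized input
    states = enumerate_states(topo.K).astype(float)
    quad = 0.5 * np.einsum("mk,kj,mj->m", states, params.W, states)
    logits = (quad + states @ params.b)[:, None] + (states @ params.V) @ Y.T
    logits -= logits.max(axis=0, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=0, keepdims=True)
    p_theo = (P.T @ states)
    traces = np.empty((config.n_runs, n_steps, topo.K), dtype=np.uint8)
    for r in range(config.n_runs):
        sim = SimConfig(cfg["duration"], seed=sim_seed + r, record_z=True)
        res = run(params, sim, y_trace=Y, topology=topo)
        traces[r] = res.z
    comp = marginal_comparison(traces, p_theo, discard=100)
    report = MetricReport(
        experiment="tracking", seed=config.seed, duration=cfg["duration"],
        metrics={
            "median_abs_mismatch_smoothed": comp["median_abs_smoothed"],
            "median_abs_mismatch_raw": comp["median_abs_raw"],
            "mean_abs_mismatch_smoothed": comp["mean_abs_smoothed"],
            "n_runs": config.n_runs,
        },
        tables={"mismatch_smoothed": pd.DataFrame(comp["mismatch_smoothed"])})
    report.validate_finite()
    return report


def _run_experts(config, cfg, rng, sim_seed) -> MetricReport:
    topo = build_grid_sheet(cfg["input_shape"], cfg["neuron_shape"],
                            cfg["field"], cfg["spacing"])
    schedule, patterns, loc_of_neuron = gen_experts_input(rng, cfg, topo)
    params = _fresh_params(topo, cfg)
    plast = PlasticityConfig(eta_V=cfg["eta_V"], eta_b=cfg["eta_b"],
                             m=np.full(topo.K, cfg["m"]), rule="none")
    sim = SimConfig(cfg["duration"], seed=sim_seed)
    res = run(params, sim, schedule, topology=topo, plasticity=plast,
              checkpoint_every_s=config.checkpoint_every_s,
              measure_start=int(0.5 * sim.n_steps))
    # frozen-parameter test run: column-silence statistics
    test_rng = np.random.default_rng(sim_seed + 1)
    test_sched, _, _ = gen_experts_input(test_rng, {**cfg, "duration": 100.0},
                                         topo, patterns=patterns)
    test_sim = SimConfig(100.0, seed=sim_seed + 2, record_z=True)
    test = run(res.params, test_sim, test_sched, topology=topo)
    pop_size = cfg["neuron_shape"][0]
    col0 = np.arange(pop_size)  # the three neurons of the first column
    silent = np.all(test.z[:, col0] == 0, axis=1).mean()
    metrics = {
        "mean_activity": res.mean_activity,
        "column_silence_fraction": float(silent),
        "test_mean_activity": test.z.mean(axis=0),
    }
    tables = {}
    loglik = None
    if config.compute_loglik and res.checkpoints is not None:
        states = valid_states(topo.inh_mask)
        Y = _loglik_samples(schedule, config.loglik_samples, rng)
        loglik = _loglik_trace(res.checkpoints, topo, cfg["pi0"],
                               np.full(topo.K, cfg["m"]), Y, states)
    report = MetricReport("experts", config.seed, cfg["duration"],
                          metrics, tables, loglik)
    report.validate_finite()
    report.params = res.params
    report.topology = topo
    report.patterns = patterns
    return report


def _run_cues(config, cfg, rng, sim_seed) -> MetricReport:
    topo = build_population_topology(cfg["n_pops"], cfg["pop_size"],
                                     cfg["field"], all_to_all_excitation=True)
    schedule, labels_in, stripes = gen_cues_input(rng, cfg, topo)
    params = _fresh_params(topo, cfg)
    rule = config.recurrent_rule
    eta_W = (cfg["eta_W_wakesleep"] if rule == "wakesleep" else
             cfg["eta_W"] if rule == "heuristic" else 0.0)
    plast = PlasticityConfig(
        eta_V=cfg["eta_V"], eta_b=cfg["eta_b"], eta_W=eta_W,
        m=np.full(topo.K, cfg["m"]), rule=rule,
        W_max=cfg["W_max"], gamma=cfg["gamma"])
    sim = SimConfig(cfg["duration"], seed=sim_seed)
    n_steps = sim.n_steps
    res = run(params, sim, schedule, topology=topo, plasticity=plast,
              wsum_start=int(0.9 * n_steps),
              measure_start=int(0.9 * n_steps),
              accumulate_zz=True,
              checkpoint_every_s=config.checkpoint_every_s)
    labels = label_tuning(res.params.V, topo, stripes)
    wmean = res.wmean if res.wmean is not None else res.params.Wexc
    groups = cue_weight_groups(wmean, labels, topo, cfg["n_pops"],
                               cfg["pop_size"])
    g = groups.fillna(0.0)  # a group can be empty in short/degenerate runs
    metrics = {
        "mean_activity": res.mean_activity,
        "w_inner_same": g.loc["inner_same", "mean_weight"],
        "w_cue_inner_compatible": g.loc["cue_inner_compatible", "mean_weight"],
        "w_cue_cue_same": g.loc["cue_cue_same", "mean_weight"],
        "w_other_max": g.loc["other", "max_weight"],
    }
    loglik = None
    if config.compute_loglik and res.checkpoints is not None:
        states = valid_states(topo.inh_mask)
        Y = _loglik_samples(schedule, config.loglik_samples, rng)
        loglik = _loglik_trace(res.checkpoints, topo, cfg["pi0"],
                               np.full(topo.K, cfg["m"]), Y, states)
    report = MetricReport("cues", config.seed, cfg["duration"], metrics,
                          {"weight_groups": groups}, loglik)
    report.validate_finite()
    report.params = res.params
    report.topology = topo
    report.labels = labels
    report.coactivation = res.coactivation()
    return report


def _run_sheet(config, cfg, rng, sim_seed) -> MetricReport:
    topo = build_grid_sheet(cfg["input_shape"], cfg["neuron_shape"],
                            cfg["field"], cfg["spacing"],
                            inhibition_range=cfg["inhibition_range"])
    topo.exc_mask = sample_excitatory_mask(topo, cfg["p_conn"], rng)
    period = cfg["pattern_duration"]
    warm = cfg.get("warmup", cfg["duration"] * 2 / 3)
    warm = max(1, int(round(warm / period))) * period
    measure = cfg["duration"] - warm
    measure = max(1, int(round(measure / period))) * period
    params = _fresh_params(topo, cfg)
    plast = PlasticityConfig(
        eta_V=cfg["eta_V"], eta_b=cfg["eta_b"], eta_W=cfg["eta_W"],
        m=np.full(topo.K, cfg["m"]), rule=config.recurrent_rule
        if config.recurrent_rule != "wakesleep" else "heuristic",
        W_max=cfg["W_max"], gamma=cfg["gamma"])
    schedule = gen_sheet_input(rng, cfg, cfg["input_shape"])
    sim = SimConfig(warm, seed=sim_seed)
    run(params, sim, schedule, topology=topo, plasticity=plast,
        copy_params=False)
    sched2 = gen_sheet_input(rng, {**cfg, "duration": measure},
                             cfg["input_shape"])
    sim2 = SimConfig(measure, seed=sim_seed + 1)
    res = run(params, sim2, sched2, topology=topo, plasticity=plast,
              copy_params=False)
    rate = float(res.spike_count.sum() / (topo.K * measure))
    labels = label_tuning_motifs(params.V, topo, high=cfg["activity"][1],
                                 low=cfg["activity"][0])
    same, diff, dist_rows = [], [], []
    coords = topo.neuron_coords.astype(float)
    nr, nc = cfg["neuron_shape"]
    for k in range(topo.K):
        for j in range(k + 1, topo.K):
            if not topo.exc_mask[k, j]:
                continue
            w = params.Wexc[k, j]
            (same if labels[k] == labels[j] else diff).append(w)
            dr = min(abs(coords[k, 0] - coords[j, 0]),
                     nr - abs(coords[k, 0] - coords[j, 0]))
            dc = min(abs(coords[k, 1] - coords[j, 1]),
                     nc - abs(coords[k, 1] - coords[j, 1]))
            dist_rows.append((np.hypot(dr, dc), w))
    dist_df = pd.DataFrame(dist_rows, columns=["distance", "weight"])
    dist_df["bin"] = pd.cut(dist_df["distance"], bins=[0, 3, 4.5, 6, 100])
    metrics = {
        "firing_rate_hz": rate,
        "mean_activity": res.mean_activity,
        "w_same_tuning": float(np.mean(same)) if same else 0.0,
        "w_diff_tuning": float(np.mean(diff)) if diff else 0.0,
        "expected_explained_inputs":
            float(topo.K * cfg["m"] * topo.field_size),
    }
    report = MetricReport(
        "sheet", config.seed, cfg["duration"], metrics,
        {"distance_weights":
            dist_df.groupby("bin", observed=True)["weight"].mean().to_frame()})
    report.validate_finite()
    report.params = params
    report.topology = topo
    report.labels = labels
    return report


def _run_nested(config, cfg, rng, sim_seed) -> MetricReport:
    topo = build_population_topology(1, cfg["K"], cfg["field"])
    schedule, patterns = gen_nested_input(cfg)
    params = _fresh_params(topo, cfg)
    eta_b = cfg["eta_b"]
    if config.fixed_bias is not None:
        params.b[:] = config.fixed_bias
        eta_b = 0.0
    plast = PlasticityConfig(eta_V=cfg["eta_V"], eta_b=eta_b,
                             m=np.full(topo.K, cfg["m"]), rule="none")
    sim = SimConfig(cfg["duration"], seed=sim_seed)
    n_steps = sim.n_steps
    final_window = min(1000.0, cfg["duration"] / 5)
    res = run(params, sim, schedule, topology=topo, plasticity=plast,
              measure_start=n_steps - int(final_window / sim.dt))
    act = np.sort(res.mean_activity)[::-1]
    metrics = {
        "dominant_activity": float(act[0]),
        "suppressed_activity": float(act[-1]),
        "mean_activity": res.mean_activity,
        "final_b": res.params.b,
    }
    report = MetricReport("nested", config.seed, cfg["duration"], metrics)
    report.validate_finite()
    report.params = res.params
    report.topology = topo
    report.patterns = patterns
    return report
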