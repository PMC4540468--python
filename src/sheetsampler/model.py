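"""Generative model, exact inference and model-level utilities.

The network is linked to an explicit probabilistic model over binary latent
variables ``z`` (one per network neuron) and observed variables ``y`` (one per
input channel):

* a Boltzmann-machine prior ``p(z) ∝ exp(½ zᵀŴz + zᵀb̂)`` whose strong negative
  couplings implement lateral inhibition (at most one of a group of competing
  hidden causes active at a time), and
* a local mixture likelihood in which each input ``y_i`` is governed by the
  single active hidden cause among its parents, or by a default hypothesis when
  none is active.  Bernoulli, Poisson and Gaussian channel families are
  supported in natural exponential-family form.

Everything in this module is exact (enumeration based) and serves both as the
construction route from abstract parameters to network parameters and as the
oracle against which the stochastic simulator is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp, logit

__all__ = [
    "GenerativeModel",
    "NetworkParameters",
    "PosteriorTable",
    "translate_likelihood",
    "network_from_model",
    "valid_states",
    "enumerate_states",
    "prior_log_prob",
    "prior_table",
    "likelihood_log_prob",
    "exact_posterior",
    "conditional_log_odds",
    "calibrate_prior_biases",
    "log_likelihood",
    "reconstruct_input",
    "STRONG_INHIBITION",
    "ENUMERATION_CAP",
    "FULL_ENUMERATION_CAP",
]

#: Finite surrogate for the theoretically infinite inhibitory coupling.  All
#: exact computations use the same finite value so that the conditional
#: log-odds of the enumerated model and the neuronal membrane potential agree
#: exactly over all states, including "forbidden" ones.
STRONG_INHIBITION = -100.0

#: Hard cap on K for constrained (valid-state) enumeration.
ENUMERATION_CAP = 24

#: Cap on K for full 2^K enumeration.
FULL_ENUMERATION_CAP = 20


class EnumerationCapError(ValueError):
    """Raised when a state enumeration would be combinatorially infeasible."""


class CalibrationError(RuntimeError):
    """Raised when prior-bias calibration fails to converge."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class GenerativeModel:
    """Abstract parameters of the joint distribution p(y, z | θ).

    Parameters
    ----------
    family
        Likelihood family, one of ``{"bernoulli", "poisson", "gaussian"}``.
    params
        (K, N) per-edge likelihood parameter (success probability, rate or
        mean).  Entries outside a neuron's afferent field must equal the
        default for that input, which encodes the convention V_ki = 0 for
        i ∉ I_k.
    defaults
        (N,) default-hypothesis parameter per input.
    Wexc_hat, Winh_hat
        (K, K) symmetric zero-diagonal prior couplings; excitatory entries are
        nonnegative, inhibitory entries nonpositive, with disjoint supports.
    bhat
        (K,) prior biases.
    sigma2
        Shared variance (Gaussian family only).
    """

    family: str
    params: np.ndarray
    defaults: np.ndarray
    Wexc_hat: np.ndarray
    Winh_hat: np.ndarray
    bhat: np.ndarray
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.defaults = np.asarray(self.defaults, dtype=float)
        self.Wexc_hat = np.asarray(self.Wexc_hat, dtype=float)
        self.Winh_hat = np.asarray(self.Winh_hat, dtype=float)
        self.bhat = np.asarray(self.bhat, dtype=float)
        self.validate()

    @property
    def K(self) -> int:
        return self.params.shape[0]

    @property
    def N(self) -> int:
        return self.params.shape[1]

    @property
    def W_hat(self) -> np.ndarray:
        """Combined prior coupling Ŵ = Ŵ^exc + Ŵ^inh."""
        return self.Wexc_hat + self.Winh_hat

    @property
    def inhibition_mask(self) -> np.ndarray:
        return self.Winh_hat < 0

    def validate(self) -> None:
        if self.family not in ("bernoulli", "poisson", "gaussian"):
            raise ValueError(f"unknown likelihood family {self.family!r}")
        K = self.params.shape[0]
        for name, M in (("Wexc_hat", self.Wexc_hat), ("Winh_hat", self.Winh_hat)):
            if M.shape != (K, K):
                raise ValueError(f"{name} must be K x K")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(M) != 0):
                raise ValueError(f"{name} must have zero diagonal")
        if np.any(self.Wexc_hat < 0):
            raise ValueError("Wexc_hat must be entrywise nonnegative")
        if np.any(self.Winh_hat > 0):
            raise ValueError("Winh_hat must be entrywise nonpositive")
        if np.any((self.Wexc_hat != 0) & (self.Winh_hat != 0)):
            raise ValueError("excitatory and inhibitory supports must be disjoint")
        _check_family_domain(self.family, self.params, self.defaults, self.sigma2)


@dataclass
class NetworkParameters:
    """Neuronal parameters (V, V0, A, A0, b, W^exc, W^inh).

    ``b`` holds the intrinsic excitabilities.  When built from a
    :class:`GenerativeModel` in inference mode, ``b = b̂ − A`` so that the
    network samples from the exact posterior; during learning ``b`` is free and
    homeostatic plasticity absorbs the (non-local) normalizers A_k.
    """

    V: np.ndarray
    V0: np.ndarray
    A: np.ndarray
    A0: np.ndarray
    b: np.ndarray
    Wexc: np.ndarray
    Winh: np.ndarray
    family: str = "bernoulli"

    def __post_init__(self) -> None:
        for name in ("V", "V0", "A", "A0", "b", "Wexc", "Winh"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def K(self) -> int:
        return self.V.shape[0]

    @property
    def N(self) -> int:
        return self.V.shape[1]

    @property
    def W(self) -> np.ndarray:
        return self.Wexc + self.Winh

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            self.V.copy(), self.V0.copy(), self.A.copy(), self.A0.copy(),
            self.b.copy(), self.Wexc.copy(), self.Winh.copy(), self.family,
        )


@dataclass
class PosteriorTable:
    """Enumerated distribution over binary network states."""

    states: np.ndarray      # (M, K) uint8
    log_weights: np.ndarray  # (M,) unnormalized
    probs: np.ndarray = field(init=False)
    marginals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lw = np.asarray(self.log_weights, dtype=float)
        self.probs = np.exp(lw - logsumexp(lw))
        self.marginals = self.probs @ self.states

    def prob_of(self, z: Sequence[int]) -> float:
        z = np.asarray(z, dtype=np.uint8)
        hit = np.all(self.states == z[None, :], axis=1)
        idx = np.flatnonzero(hit)
        return float(self.probs[idx[0]]) if idx.size else 0.0


# ---------------------------------------------------------------------------
# likelihood translation (abstract-to-neuronal parameter mapping)
# ---------------------------------------------------------------------------


def _check_family_domain(family: str, params: np.ndarray, defaults: np.ndarray,
                         sigma2: float) -> None:
    if family == "bernoulli":
        bad = ~((params > 0) & (params < 1))
        bad0 = ~((defaults > 0) & (defaults < 1))
        what = "success probability in (0,1)"
    elif family == "poisson":
        bad = ~(params > 0)
        bad0 = ~(defaults > 0)
        what = "rate > 0"
    else:  # gaussian
        if not sigma2 > 0:
            raise ValueError("gaussian family requires sigma2 > 0")
        bad = ~np.isfinite(params)
        bad0 = ~np.isfinite(defaults)
        what = "finite mean"
    if np.any(bad):
        k, i = np.argwhere(bad)[0]
        raise ValueError(f"likelihood parameter out of domain (need {what}) "
                         f"at (k={k}, i={i}): {params[k, i]}")
    if np.any(bad0):
        i = np.flatnonzero(bad0)[0]
        raise ValueError(f"default parameter out of domain (need {what}) "
                         f"at i={i}: {defaults[i]}")


def translate_likelihood(family: str, params: np.ndarray, defaults: np.ndarray,
                         sigma2: float = 1.0):
    """Map per-edge likelihood parameters to (V, V0, A, A0).

    The channels are written in natural exponential-family form relative to
    the default hypothesis, ``p(y_i | z_k=1) = h(y_i) exp((V_ki+V_0i) y_i −
    (A_ki+A_0i))``, so that

    * Bernoulli: ``V_ki = logit(π_ki) − V_0i``, ``A_ki = log(1+e^{V_ki+V_0i}) − A_0i``
    * Poisson:   ``V_ki = log(λ_ki) − V_0i``, ``A_ki = e^{V_ki+V_0i} − A_0i``
    * Gaussian:  ``V_ki = μ_ki/σ² − V_0i``,  ``A_ki = (σ²/2)(V_ki+V_0i)² − A_0i``

    For Bernoulli channels the round trip ``π_ki = σ(V_ki + V_0i)`` holds.
    """
    params = np.asarray(params, dtype=float)
    defaults = np.asarray(defaults, dtype=float)
    _check_family_domain(family, params, defaults, sigma2)
    if family == "bernoulli":
        V0 = logit(defaults)
        V = logit(params) - V0[None, :]
        A0 = np.log1p(np.exp(V0))
        A = np.log1p(np.exp(V + V0[None, :])) - A0[None, :]
    elif family == "poisson":
        V0 = np.log(defaults)
        V = np.log(params) - V0[None, :]
        A0 = np.exp(V0)
        A = np.exp(V + V0[None, :]) - A0[None, :]
    else:
        V0 = defaults / sigma2
        V = params / sigma2 - V0[None, :]
        A0 = 0.5 * sigma2 * V0 ** 2
        A = 0.5 * sigma2 * (V + V0[None, :]) ** 2 - A0[None, :]
    return V, V0, A, A0


def network_from_model(model: GenerativeModel) -> NetworkParameters:
    """Build network parameters from abstract model parameters.

    Recurrent weights are copied verbatim and excitabilities are set to
    ``b_k = b̂_k − A_k`` with ``A_k = Σ_i A_ki`` (inference mode).
    """
    V, V0, A_ki, A0 = translate_likelihood(
        model.family, model.params, model.defaults, model.sigma2)
    A = A_ki.sum(axis=1)
    b = model.bhat - A
    return NetworkParameters(
        V=V, V0=V0, A=A, A0=A0, b=b,
        Wexc=model.Wexc_hat.copy(), Winh=model.Winh_hat.copy(),
        family=model.family,
    )


# ---------------------------------------------------------------------------
# state enumeration
# ---------------------------------------------------------------------------


def enumerate_states(K: int) -> np.ndarray:
    """All 2^K binary states in lexicographic order (z_1 most significant)."""
    if K > FULL_ENUMERATION_CAP:
        raise EnumerationCapError(
            f"full enumeration of 2^{K} states exceeds the cap "
            f"(K <= {FULL_ENUMERATION_CAP})")
    idx = np.arange(2 ** K, dtype=np.int64)
    shifts = np.arange(K - 1, -1, -1)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


def valid_states(inhibition_mask: np.ndarray, cap: int = ENUMERATION_CAP) -> np.ndarray:
    """Enumerate binary states with no mutually inhibiting pair co-active.

    Returns the (M, K) array of states in lexicographic order.  The mask must
    be symmetric with a zero diagonal.  Backtracking over the lexicographic
    tree prunes invalid branches, so the cost is proportional to the number of
    valid prefixes rather than 2^K.
    """
    mask = np.asarray(inhibition_mask, dtype=bool)
    K = mask.shape[0]
    if mask.shape != (K, K) or not np.array_equal(mask, mask.T) or mask.diagonal().any():
        raise ValueError("inhibition mask must be symmetric with zero diagonal")
    if K > cap:
        raise EnumerationCapError(
            f"valid-state enumeration refused for K={K} > cap={cap} "
            f"(combinatorial size)")
    neighbors = [np.flatnonzero(mask[k]) for k in range(K)]
    out: list[np.ndarray] = []
    z = np.zeros(K, dtype=np.uint8)

    def rec(k: int) -> None:
        if k == K:
            out.append(z.copy())
            return
        z[k] = 0
        rec(k + 1)
        if not any(z[j] for j in neighbors[k] if j < k):
            z[k] = 1
            rec(k + 1)
            z[k] = 0

    rec(0)
    return np.array(out, dtype=np.uint8)


# ---------------------------------------------------------------------------
# prior / likelihood / posterior
# ---------------------------------------------------------------------------


def _quadratic_form(states: np.ndarray, W: np.ndarray) -> np.ndarray:
    S = states.astype(float)
    return 0.5 * np.einsum("mk,kj,mj->m", S, W, S)


def prior_log_prob(z: Sequence[int], model: GenerativeModel) -> float:
    """Unnormalized log prior weight ½ zᵀŴz + zᵀb̂ (finite inhibition)."""
    z = np.asarray(z, dtype=float)
    return float(0.5 * z @ model.W_hat @ z + z @ model.bhat)


def prior_table(model: GenerativeModel) -> PosteriorTable:
    """Normalized prior over all 2^K states (finite-inhibition surrogate)."""
    states = enumerate_states(model.K)
    lw = _quadratic_form(states, model.W_hat) + states.astype(float) @ model.bhat
    return PosteriorTable(states, lw)


def _log_pmf_default(family: str, y: np.ndarray, V0: np.ndarray, A0: np.ndarray,
                     sigma2: float) -> np.ndarray:
    """log h_i(y_i) + V_0i y_i − A_0i, per input (the z-independent part)."""
    if family == "bernoulli":
        return V0 * y - A0
    if family == "poisson":
        from scipy.special import gammaln
        return V0 * y - A0 - gammaln(y + 1.0)
    return V0 * y - A0 - 0.5 * y ** 2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)


def _check_support(family: str, y: np.ndarray) -> None:
    y = np.asarray(y)
    if family == "bernoulli" and not np.all((y == 0) | (y == 1)):
        raise ValueError("bernoulli observations must be binary")
    if family == "poisson" and (np.any(y < 0) or np.any(y != np.floor(y))):
        raise ValueError("poisson observations must be nonnegative integers")


def likelihood_log_prob(y: Sequence[float], z: Sequence[int],
                        model: GenerativeModel, *, strict: bool = False) -> float:
    """log p(y | z, θ) up to the z-independent constant: zᵀVy − zᵀA.

    The base measure h(y) is dropped; it cancels in any posterior computation.
    In ``strict`` mode, states violating the at-most-one-parent constraint are
    rejected; the default finite-inhibition mode evaluates the exponential-
    family form as written for any z.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_support(model.family, y)
    if strict:
        # co-active inhibiting pairs are exactly the states in which some
        # input would have more than one active parent
        active = np.flatnonzero(z)
        for a in range(len(active)):
            for bdx in range(a + 1, len(active)):
                if model.inhibition_mask[active[a], active[bdx]]:
                    raise ValueError(
                        f"state violates the at-most-one-parent constraint: "
                        f"neurons {active[a]} and {active[bdx]} are co-active")
    V, V0, A_ki, A0 = translate_likelihood(
        model.family, model.params, model.defaults, model.sigma2)
    A = A_ki.sum(axis=1)
    return float(z @ V @ y - z @ A)


def exact_posterior(y: Sequence[float], model: GenerativeModel) -> PosteriorTable:
    """Closed-form posterior p(z | y, θ) by full 2^K enumeration.

    Per-state log weight: ½ zᵀŴz + zᵀVy + zᵀ(b̂ − A), normalized over all
    states with the finite inhibition surrogate.
    """
    y = np.asarray(y, dtype=float)
    _check_support(model.family, y)
    params = network_from_model(model)
    states = enumerate_states(model.K)
    S = states.astype(float)
    lw = _quadratic_form(states, params.W) + S @ (params.V @ y + params.b)
    return PosteriorTable(states, lw)


def conditional_log_odds(k: int, z_rest: Sequence[int], y: Sequence[float],
                         params: NetworkParameters) -> float:
    """log p(z_k=1 | z_\\k, y) − log p(z_k=0 | z_\\k, y) from the joint.

    Evaluated as the difference of the two full joint log-weights; for
    parameters built via :func:`network_from_model` this equals the membrane
    potential exactly (neural computability condition).
    """
    y = np.asarray(y, dtype=float)
    z_rest = np.asarray(z_rest, dtype=float)
    K = params.K
    z1 = np.empty(K)
    z1[:k] = z_rest[:k]
    z1[k + 1:] = z_rest[k:]
    z0 = z1.copy()
    z1[k] = 1.0
    z0[k] = 0.0
    W = params.W
    drive = params.V @ y + params.b

    def logw(z: np.ndarray) -> float:
        return float(0.5 * z @ W @ z + z @ drive)

    return logw(z1) - logw(z0)


# ---------------------------------------------------------------------------
# prior-bias calibration & log-likelihood
# ---------------------------------------------------------------------------


def _prior_states(Wexc: np.ndarray, Winh: np.ndarray) -> np.ndarray:
    K = Wexc.shape[0]
    if K <= 16:
        return enumerate_states(K)
    return valid_states(np.asarray(Winh) < 0)


def calibrate_prior_biases(Wexc: np.ndarray, Winh: np.ndarray,
                           m: Sequence[float], *, tol: float = 1e-6,
                           damping: float = 0.5, max_iter: int = 20000,
                           states: np.ndarray | None = None) -> np.ndarray:
    """Find prior biases b̂ with ⟨z_k⟩ under p(z | θ) equal to targets m.

    Damped fixed-point iteration ``b̂ ← b̂ + damping · (log m − log ⟨z⟩)``
    against the enumerated prior.  For K above the full-enumeration range the
    prior is enumerated over inhibition-respecting valid states.
    """
    Wexc = np.asarray(Wexc, dtype=float)
    Winh = np.asarray(Winh, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0) or np.any(m >= 1):
        raise ValueError("targets m must lie in (0, 1)")
    if states is None:
        states = _prior_states(Wexc, Winh)
    S = states.astype(float)
    quad = _quadratic_form(states, Wexc + Winh)
    bhat = logit(m).copy()
    for _ in range(max_iter):
        lw = quad + S @ bhat
        p = np.exp(lw - logsumexp(lw))
        marg = p @ S
        resid = marg - m
        if np.max(np.abs(resid)) < tol:
            return bhat
        bhat = bhat + damping * (np.log(m) - np.log(np.maximum(marg, 1e-300)))
    raise CalibrationError(
        f"prior-bias calibration did not converge; residuals: {resid}")


def log_likelihood(y_samples: np.ndarray, model: GenerativeModel, *,
                   bhat: np.ndarray | None = None,
                   m: Sequence[float] | None = None,
                   states: np.ndarray | None = None) -> float:
    """Average log-likelihood (1/S) Σ_s log Σ_z p(z|θ) Π_i p(y_i^s|z,θ).

    The z-sum runs over inhibition-respecting valid states and the full
    channel pmf (base measure restored) is used, so values are absolute and
    comparable across parameter settings.  If ``bhat`` is not given it is
    calibrated so the prior matches the activation targets ``m``.
    """
    Y = np.atleast_2d(np.asarray(y_samples, dtype=float))  # (S, N)
    if Y.shape[0] == 0:
        raise ValueError("empty sample list")
    _check_support(model.family, Y)
    if model.K == 0:
        V0 = (logit(model.defaults) if model.family == "bernoulli"
              else np.log(model.defaults) if model.family == "poisson"
              else model.defaults / model.sigma2)
        A0 = (np.log1p(np.exp(V0)) if model.family == "bernoulli"
              else np.exp(V0) if model.family == "poisson"
              else 0.5 * model.sigma2 * V0 ** 2)
        base = _log_pmf_default(model.family, Y, V0[None, :], A0[None, :],
                                model.sigma2)
        return float(np.mean(base.sum(axis=1)))
    if states is None:
        states = _prior_states(model.Wexc_hat, model.Winh_hat)
    if bhat is None:
        if m is None:
            bhat = model.bhat
        else:
            bhat = calibrate_prior_biases(model.Wexc_hat, model.Winh_hat, m,
                                          states=states)
    S = states.astype(float)
    quad = _quadratic_form(states, model.Wexc_hat + model.Winh_hat)
    prior_lw = quad + S @ np.asarray(bhat, dtype=float)
    prior_lw = prior_lw - logsumexp(prior_lw)
    V, V0, A_ki, A0 = translate_likelihood(
        model.family, model.params, model.defaults, model.sigma2)
    A = A_ki.sum(axis=1)
    base = _log_pmf_default(model.family, Y, V0[None, :], A0[None, :],
                            model.sigma2).sum(axis=1)           # (S,)
    lw = prior_lw[:, None] - (S @ A)[:, None] + (S @ V) @ Y.T   # (M, S)
    per_sample = logsumexp(lw, axis=0) + base
    return float(np.mean(per_sample))


def reconstruct_input(z_trace: np.ndarray, params: NetworkParameters) -> np.ndarray:
    """Mean generative reconstruction of the input over a state window.

    Returns ⟨y_i^gen⟩ = (1/T) Σ_t σ(V_0i + Σ_k z_k(t) V_ki); with Bernoulli
    channels this is the model's expected input activity given the response.
    """
    Z = np.atleast_2d(np.asarray(z_trace, dtype=float))
    if Z.shape[0] == 0:
        raise ValueError("reconstruction window is empty")
    return expit(Z @ params.V + params.V0[None, :]).mean(axis=0)
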