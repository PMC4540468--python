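"""Learning rules: afferent Hebbian, homeostatic intrinsic, recurrent.

Four rules act on the network parameters, all derived from (or heuristically
matched to) stochastic online expectation-maximization on the generative
model:

* afferent Hebbian:     ΔV_ki = δt·η_V·z_k·(y_i − ⟨y_i⟩_model),
  where ⟨y_i⟩_model = ∂A_ki/∂V_ki is σ(V_ki+V_0i) for Bernoulli channels;
* homeostatic intrinsic: Δb_k = δt·η_b·(m_k − z_k), driving each neuron's
  long-term activity to the target m_k (the variational E-step);
* wake-sleep recurrent:  ΔW_kj = δt·η_W·(z_k z_j |wake − z_k z_j |sleep),
  the sleep coactivations supplied by a companion prior sampler;
* heuristic recurrent:   ΔW_kj = δt·η_W·[z_k z_j − (m_k m_j +
  tan(½π W_kj / W_max)/γ)], a fully local rule whose fixed points invert the
  arctan weight–covariance map W(c) = (W_max/(π/2))·arctan(γ c).

The functions here are the single-step reference implementations operating on
numpy arrays; the simulation kernel applies the identical updates in compiled
code once per time step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "PlasticityConfig",
    "CoactivationStats",
    "afferent_update",
    "homeostatic_update",
    "wakesleep_update",
    "heuristic_update",
    "estimate_covariance",
    "fit_ltd_parameters",
    "ltd_curve",
]


@dataclass
class PlasticityConfig:
    """Learning rates, homeostatic targets and LTD parameters.

    Rates are in 1/s; ``m`` holds the per-neuron long-term activation targets.
    ``rule`` selects the recurrent-weight rule ("none", "wakesleep" or
    "heuristic"); ``(W_max, gamma)`` parameterize the heuristic LTD function.
    ``nonneg_clip`` keeps V and W^exc nonnegative (the default, as for
    biological excitatory synapses); the underlying theory also supports
    sign-free weights.
    """

    eta_V: float = 0.0
    eta_b: float = 0.0
    eta_W: float = 0.0
    m: np.ndarray = None
    rule: str = "none"
    W_max: float = 1.0
    gamma: float = 1.0
    nonneg_clip: bool = True

    def validate(self, K: int | None = None) -> None:
        if min(self.eta_V, self.eta_b, self.eta_W) < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.rule not in ("none", "wakesleep", "heuristic"):
            raise ValueError(f"unknown recurrent rule {self.rule!r}")
        if self.m is None:
            self.m = np.zeros(K if K else 0)
        self.m = np.asarray(self.m, dtype=float)
        if K is not None and self.m.shape != (K,):
            if self.m.size == 1:
                self.m = np.full(K, float(self.m))
            else:
                raise ValueError("m must have one target per neuron")
        if self.m.size and (self.eta_b > 0 or self.rule == "heuristic"):
            if np.any(self.m <= 0) or np.any(self.m >= 1):
                raise ValueError("targets m must lie in (0, 1)")
        if self.rule == "heuristic" and (self.W_max <= 0 or self.gamma <= 0):
            raise ValueError("heuristic rule requires W_max > 0 and gamma > 0")

    def timescale_warnings(self, tau: float, pattern_duration: float) -> list[str]:
        """Check the timescale ordering τ ≪ pattern ≪ 1/η_b ≪ 1/η_V.

        A factor of ~5 per relation is typically sufficient; violations are
        reported as warnings, not errors.
        """
        out = []
        chain = [("tau", tau), ("pattern duration", pattern_duration)]
        if self.eta_b > 0:
            chain.append(("1/eta_b", 1.0 / self.eta_b))
        if self.eta_V > 0:
            chain.append(("1/eta_V", 1.0 / self.eta_V))
        for (n1, t1), (n2, t2) in zip(chain, chain[1:]):
            if t2 < 5 * t1:
                out.append(f"timescale separation weak: {n2}={t2:.3g}s is not "
                           f">= 5x {n1}={t1:.3g}s")
        return out


@dataclass
class CoactivationStats:
    """Running means and coactivations of the network response."""

    mean_z: np.ndarray      # ⟨z_k⟩
    coact: np.ndarray       # ⟨z_k z_j⟩
    n_steps: int

    @property
    def covariance(self) -> np.ndarray:
        """c_kj = ⟨z_k z_j⟩ − ⟨z_k⟩⟨z_j⟩."""
        return self.coact - np.outer(self.mean_z, self.mean_z)


def _family_expectation(V: np.ndarray, V0: np.ndarray, family: str,
                        sigma2: float) -> np.ndarray:
    """⟨y_i⟩ under the channel model, i.e. ∂A_ki/∂V_ki."""
    if family == "bernoulli":
        return expit(V + V0[None, :])
    if family == "poisson":
        return np.exp(V + V0[None, :])
    return sigma2 * (V + V0[None, :])


def afferent_update(V: np.ndarray, z: np.ndarray, y: np.ndarray,
                    V0: np.ndarray, eta_V: float, dt: float, *,
                    aff_mask: np.ndarray | None = None,
                    family: str = "bernoulli", sigma2: float = 1.0,
                    nonneg_clip: bool = True) -> np.ndarray:
    """One Euler step of the afferent Hebbian rule (in place).

    Only synapses of currently active neurons change; each moves the channel
    expectation toward the observed input.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    dV = dt * eta_V * z[:, None] * (y[None, :] - _family_expectation(
        V, V0, family, sigma2))
    if aff_mask is not None:
        dV = np.where(aff_mask, dV, 0.0)
    V += dV
    if nonneg_clip:
        np.maximum(V, 0.0, out=V)
    return V


def homeostatic_update(b: np.ndarray, z: np.ndarray, m: np.ndarray,
                       eta_b: float, dt: float) -> np.ndarray:
    """One Euler step of homeostatic intrinsic plasticity (in place)."""
    b += dt * eta_b * (np.asarray(m, dtype=float) - np.asarray(z, dtype=float))
    return b


def wakesleep_update(Wexc: np.ndarray, z_wake: np.ndarray, z_sleep: np.ndarray,
                     eta_W: float, dt: float, *, exc_mask: np.ndarray,
                     nonneg_clip: bool = True) -> np.ndarray:
    """One Euler step of the wake-sleep recurrent rule (in place).

    The update contrasts input-driven coactivations with coactivations of the
    companion prior sampler; it is computed once per unordered pair and
    mirrored, which preserves symmetry exactly.
    """
    zw = np.asarray(z_wake, dtype=float)
    zs = np.asarray(z_sleep, dtype=float)
    dW = dt * eta_W * (np.outer(zw, zw) - np.outer(zs, zs))
    dW[~np.asarray(exc_mask, dtype=bool)] = 0.0
    Wexc += dW
    if nonneg_clip:
        np.maximum(Wexc, 0.0, out=Wexc)
    return Wexc


def ltd_curve(c: np.ndarray, W_max: float, gamma: float) -> np.ndarray:
    """Equilibrium weight as a function of covariance: W(c) = (2W_max/π)·arctan(γc)."""
    return W_max / (np.pi / 2.0) * np.arctan(gamma * np.asarray(c, dtype=float))


def heuristic_update(Wexc: np.ndarray, z: np.ndarray, m: np.ndarray,
                     eta_W: float, dt: float, *, exc_mask: np.ndarray,
                     W_max: float, gamma: float,
                     nonneg_clip: bool = True) -> np.ndarray:
    """One Euler step of the local heuristic recurrent rule (in place).

    The LTD term m_k m_j + tan(½π W/W_max)/γ diverges as W → W_max, bounding
    the weights; W is clamped to [0, W_max(1−1e−6)] to keep the tangent
    finite.
    """
    z = np.asarray(z, dtype=float)
    m = np.asarray(m, dtype=float)
    mask = np.asarray(exc_mask, dtype=bool)
    cap = W_max * (1.0 - 1e-6)
    ltd = np.outer(m, m) + np.tan(0.5 * np.pi * np.clip(Wexc, -cap, cap)
                                  / W_max) / gamma
    dW = dt * eta_W * (np.outer(z, z) - ltd)
    dW[~mask] = 0.0
    Wexc += dW
    lo = 0.0 if nonneg_clip else -cap
    np.clip(Wexc, lo, cap, out=Wexc)
    Wexc[~mask] = 0.0
    return Wexc


def estimate_covariance(z_trace: np.ndarray, window: slice | None = None
                        ) -> CoactivationStats:
    """Plug-in means and coactivations of a state trace over a window."""
    Z = np.asarray(z_trace, dtype=float)
    if window is not None:
        Z = Z[window]
    if Z.shape[0] == 0:
        raise ValueError("covariance window is empty")
    mean_z = Z.mean(axis=0)
    coact = (Z.T @ Z) / Z.shape[0]
    return CoactivationStats(mean_z, coact, Z.shape[0])


def fit_ltd_parameters(weights: Sequence[float], covariances: Sequence[float],
                       weight_floor: float = 0.01):
    """Fit (W_max, γ) of the arctan weight–covariance map by least squares.

    Only synapses with converged weight above ``weight_floor`` enter the fit
    (weights pinned at zero by the nonnegativity clip would otherwise distort
    it).  Returns ``(W_max, gamma), residuals``.
    """
    W = np.asarray(weights, dtype=float)
    c = np.asarray(covariances, dtype=float)
    keep = W > weight_floor
    W, c = W[keep], c[keep]
    if W.size < 2:
        raise ValueError(
            f"need at least 2 synapses with weight > {weight_floor} to fit "
            f"the LTD curve (got {W.size})")
    if np.all(c <= 0):
        raise ValueError("degenerate data: no positive covariances to fit")
    p0 = (max(W.max() * 1.2, 1e-3), 1.0 / max(np.median(c[c > 0]), 1e-6))
    popt, _ = curve_fit(ltd_curve, c, W, p0=p0, maxfev=20000)
    W_max, gamma = float(popt[0]), float(popt[1])
    resid = W - ltd_curve(c, W_max, gamma)
    return (W_max, gamma), resid
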