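"""Distilling wake-sleep learning into a local rule: the LTD curve.

Wake-sleep learning needs a companion prior sampler; its converged weights
W_kj and the coactivation covariances c_kj that produced them lie on a
curve W(c) = (W_max/(pi/2)) * arctan(gamma * c).  Fitting (W_max, gamma)
yields the fully local heuristic rule whose LTD term inverts this map.
"""

import numpy as np

import sheetsampler as ss

# synthetic converged pairs exactly on the curve, plus clipped-at-zero
# synapses that the weight floor must exclude
true = (1.41, 31.6)
c = np.linspace(0.005, 0.2, 25)
W = ss.ltd_curve(c, *true)
W_all = np.concatenate([W, [0.0, 0.004]])
c_all = np.concatenate([c, [-0.08, -0.01]])

(W_max, gamma), resid = ss.fit_ltd_parameters(W_all, c_all, weight_floor=0.01)
print(f"generating parameters: W_max={true[0]}, gamma={true[1]}")
print(f"recovered parameters:  W_max={W_max:.4f}, gamma={gamma:.4f}")
print(f"max |residual| = {np.max(np.abs(resid)):.2e}")
print("\nequilibrium weight for covariance c=0.04:",
      round(float(ss.ltd_curve(0.04, W_max, gamma)), 4))
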