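"""Exact inference in a small generative model and its network translation.

Builds a 3-neuron model (one competing pair plus an associated third unit),
translates the abstract parameters to neuronal parameters, and shows that the
membrane potential equals the conditional log-odds of the enumerated
posterior — the condition that makes the spiking dynamics a sampler.
"""

import numpy as np

import sheetsampler as ss

rng = np.random.default_rng(0)
K, N = 3, 4
pi = rng.uniform(0.3, 0.7, (K, N))          # per-edge Bernoulli parameters
pi0 = np.full(N, 0.2)                        # default-hypothesis activity
Winh = np.zeros((K, K))
Winh[0, 1] = Winh[1, 0] = ss.STRONG_INHIBITION   # units 0,1 compete
Wexc = np.zeros((K, K))
Wexc[1, 2] = Wexc[2, 1] = 1.0                    # units 1,2 associate
model = ss.GenerativeModel("bernoulli", pi, pi0, Wexc, Winh,
                           bhat=np.array([-1.0, -1.0, -0.5]))

params = ss.network_from_model(model)
print("afferent weights V (logit ratios):")
print(np.round(params.V, 3))
print("excitabilities b = bhat - A:", np.round(params.b, 3))

y = np.array([1, 1, 0, 0])
post = ss.exact_posterior(y, model)
print("\nposterior marginals given y =", y, "->", np.round(post.marginals, 4))
print("most likely state:", post.states[np.argmax(post.probs)],
      "with probability", round(float(post.probs.max()), 4))

z = np.array([0, 1, 0])
u = ss.membrane_potential(params, z, y)
lo = [ss.conditional_log_odds(k, np.delete(z, k), y, params) for k in range(K)]
print("\nmembrane potentials      :", np.round(u, 6))
print("conditional log-odds     :", np.round(lo, 6))
print("(equal -> the network's firing condition implements Bayes rule)")
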