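"""Motor-regressor encoding model with permutation significance.

Simulates a tail-free session with calcium imaging at 10 Hz, plants one
neuron coupled to instantaneous tail-beat frequency (iTBF) and three null
neurons, and fits the four-regressor linear model (iTBA, iTBA-rise, iTBF,
iTBF-rise, each convolved with a 1.5-s indicator kernel).
"""

import numpy as np

from swimencode import synthgen
from swimencode.pipeline import RunConfig, run_encoding_pipeline

rng = np.random.default_rng(2)
schedule = synthgen.make_schedule(40, rng)
trace, truth = synthgen.synth_session(schedule, rng, noise_sigma_deg=0.5)

archetypes = [
    {"kind": "itbf_coder", "gain": 0.05},
    {"kind": "null"},
    {"kind": "null"},
    {"kind": "null"},
]
fluo = synthgen.synth_neurons(truth, archetypes, rng, duration_s=trace.time_s[-1])

config = RunConfig(seed=3)
config.regression.n_perm = 999
results = run_encoding_pipeline(trace, fluo, config)

cols = ["roi_id", "alpha_itbf", "p_itbf", "sig_itbf", "alpha_itba", "p_itba", "r2"]
print(results["regression"][cols].round(4).to_string(index=False))
# ROI 0 was built to spike in proportion to iTBF: its iTBF coefficient is
# large and positive with the minimal permutation p (1/1000), while the null
# neurons' coefficients hover near zero with non-significant p-values.
# Significance requires alpha > 0 AND p < 0.05 under circular-shift
# permutations that preserve the calcium autocorrelation.
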