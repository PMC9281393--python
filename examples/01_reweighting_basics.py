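"""Reweight a small ensemble and inspect its statistical diagnostics.

Builds a 200-frame toy ensemble with Poisson bond counts, turns up the
strength of one hydrogen-bond type and watches the reweighted mean count of
that type rise while the Kish effective sample size shrinks.
"""

import numpy as np

from ghbfit import (
    compute_weights,
    expectation,
    kish_size,
    normalize,
    relative_entropy_reg,
    relative_kish_inverse,
)

rng = np.random.default_rng(0)
features = rng.poisson(1.5, size=(200, 12)).astype(float)
prior = normalize(rng.uniform(0.5, 1.0, 200))

print("lambda_3   <n_3>    Kish ESS   rel.Kish^-1   exp(KL)")
for strength in (0.0, 0.3, 0.6, 1.0):
    lam = np.zeros(12)
    lam[3] = strength
    w = compute_weights(features, lam, prior)
    print(
        f"{strength:7.1f} {expectation(w, features[:, 3]):8.3f}"
        f" {kish_size(w):10.1f} {relative_kish_inverse(w, prior):12.3f}"
        f" {relative_entropy_reg(w, prior):9.3f}"
    )

# <n_3> grows monotonically with lambda_3 (its derivative is a variance);
# the diagnostics all start at their identity values (ESS = 200 frames,
# relative measures = 1) and degrade as the ensemble departs from the prior.
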