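"""Parameter recovery from synthetic depletion-imaging studies.

Simulates noisy AMPT-style studies at a known dopamine level and checks
how well the closed-form estimator recovers it.
"""

import numpy as np

from frontostriatal import estimate_da_from_bp_increase, generate_synthetic_depletion_study

TRUE_Y = 0.266  # patient-level dopamine in units of K_DA

for cv in (0.10, 0.05, 0.01):
    obs = generate_synthetic_depletion_study(
        TRUE_Y, alpha=0.3, n_subjects=100, noise_cv=cv, seed=1
    )
    est = np.array([estimate_da_from_bp_increase(max(o.beta, 0.0), 0.3) for o in obs])
    print(
        f"noise CV {cv:4.2f}: mean Y = {est.mean():.3f}, "
        f"median |error| = {np.median(np.abs(est - TRUE_Y)):.4f}"
    )
# The estimator converges on the true dopamine level as imaging noise
# shrinks; at 10% BP noise the per-subject error is already dominated by
# measurement noise rather than the estimator itself.
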