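"""Forward-simulate a DEER trace and invert it model-free.

Builds a single-Gaussian distance ensemble (33 A, sigma 3 A), computes the
dipolar signal, then recovers the distribution by Tikhonov-regularized
nonnegative inversion with the smoothing weight chosen at the L-curve
corner.  The printed mode should sit on the true center.
"""

import numpy as np

from deerfret import (
    GaussianComponent,
    MixtureModel,
    default_distance_axis,
    default_time_axis,
    forward_signal,
    tikhonov_fit,
)

model = MixtureModel(
    components=[GaussianComponent(center=33.0, width=3.0)],
    populations={"demo": np.array([1.0])},
    modulation_depths={"demo": 0.5},
    concentrations={"grp": 50.0},
    condition_groups={"demo": "grp"},
)
time_axis = default_time_axis()          # 0..3.4 us, 16 ns steps
dist_axis = default_distance_axis()      # 15..100 A, 0.5 A grid

signal = forward_signal(model, "demo", time_axis, dist_axis)
rng = np.random.default_rng(1)
signal.amplitude = signal.amplitude + rng.normal(0, 0.003, len(time_axis))

result = tikhonov_fit(signal, dist_axis, lam=0.5, concentration=50.0)
mode = dist_axis.r[np.argmax(result.distribution)]

print(f"true center: 33.0 A")
print(f"model-free mode: {mode:.1f} A (alpha = {result.alpha:.3g})")
print("the mode of the regularized inversion recovers the spin-spin distance")
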