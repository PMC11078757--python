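"""Global Gaussian-mixture fit across conditions with bootstrap contrasts.

Simulates two conditions sharing the same two distance components (30 and
45 A) but with shifted populations — a transducer-style redistribution —
then fits both traces jointly, bootstraps 95% confidence intervals and
flags the population shift by the disjunct-interval criterion.
"""

import numpy as np

from deerfret import (
    GaussianComponent,
    GlobalFitSpec,
    MixtureModel,
    bootstrap_ci,
    compare_conditions,
    default_distance_axis,
    default_time_axis,
    forward_signal,
    global_fit,
)
from deerfret.deer.forward import DipolarSignal

truth = MixtureModel(
    components=[GaussianComponent(30.0, 3.0), GaussianComponent(45.0, 3.5)],
    populations={"apo": np.array([0.70, 0.30]),
                 "with_transducer": np.array([0.40, 0.60])},
    modulation_depths={"apo": 0.5, "with_transducer": 0.5},
    concentrations={"grp": 50.0},
    condition_groups={"apo": "grp", "with_transducer": "grp"},
)
t_ax, r_ax = default_time_axis(), default_distance_axis()
rng = np.random.default_rng(2)
datasets = [
    DipolarSignal(time=t_ax,
                  amplitude=forward_signal(truth, c, t_ax, r_ax).amplitude
                  + rng.normal(0, 0.003, len(t_ax)),
                  condition=c, group="grp")
    for c in truth.conditions
]

fit = global_fit(datasets, GlobalFitSpec(n_components=2, n_starts=6, seed=0))
boot = bootstrap_ci(datasets, fit, n_iter=200, seed=0)

print("fitted components (center A, width A):")
for comp in fit.model.components:
    print(f"  {comp.center:6.2f}  {comp.width:5.2f}")
for cond in truth.conditions:
    pops = fit.model.populations[cond]
    ci = boot.populations_ci[cond]
    text = ", ".join(f"{p:.2f} [{lo:.2f}, {hi:.2f}]"
                     for p, (lo, hi) in zip(pops, ci))
    print(f"{cond:16s}: {text}")
star = compare_conditions(boot, boot, component=1,
                          condition_a="apo", condition_b="with_transducer")
print(f"population shift of the 45 A component significant "
      f"(disjunct 95% CIs): {star}")
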