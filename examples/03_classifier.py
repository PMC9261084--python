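"""Clinical classification from psychometric slopes.

Each participant is reduced to two numbers — the slope of self-attribution
against alteration magnitude in the temporal and spatial aspects — and
held-out participants are assigned to the group with the nearer mean slope
vector.  The permutation null (labels shuffled every iteration) gives the
chance reference; a two-sample KS test quantifies the separation between
the real-label and null accuracy distributions.
"""

import soameta as sm
from soameta.classifier import ClassifierConfig

dataset, _ = sm.apply_exclusions(sm.build_cohort(seed=7))

cfg = ClassifierConfig(leave_out_fraction=0.2, n_iterations=2000, seed=1)
res = sm.run_classifier(dataset, cfg)
null = sm.permutation_null(dataset, ClassifierConfig(n_iterations=2000, seed=2))
D, p = sm.ks_two_sample(res.accuracy, null.accuracy)

print(f"accuracy    = {100 * res.mean_accuracy:.1f}%  (95% CI {res.ci95()[0]:.2f}-{res.ci95()[1]:.2f})")
print(f"sensitivity = {100 * res.mean_sensitivity:.1f}%  (patients correctly classified)")
print(f"specificity = {100 * res.mean_specificity:.1f}%  (controls correctly classified)")
print(f"null        = {100 * null.mean_accuracy:.1f}%   KS D = {D:.2f}, p = {p:.2g}")

print("\nRobustness: fewer trials per held-out participant")
grid = sm.robustness_grid(dataset, n_iterations=400, seed=3)
print(grid.pivot(index="leave_out_fraction", columns="n_trials_sampled", values="mean_accuracy").round(3))
print("-> accuracy degrades gracefully as held-out participants are "
      "classified from fewer trials: a handful of trials already separates "
      "the groups well above the ~50% permutation floor.")
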