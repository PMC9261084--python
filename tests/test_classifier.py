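"""Slope features, nearest-centroid assignment, resampling, permutation null."""

import copy

import numpy as np
import pandas as pd
import pytest

import soameta as sm
from soameta.classifier import ClassifierConfig, per_magnitude_proportions


def _trials(counts_identical, counts_total):
    """Build a minimal trial frame with given per-cell identical/total counts.

    counts keyed by (aspect, level); level 0 key uses aspect 'none'.
    """
    rows = []
    for (aspect, level), total in counts_total.items():
        k = counts_identical[(aspect, level)]
        for i in range(total):
            rows.append(
                {"aspect": aspect, "magnitude_level": level, "block": 1,
                 "response_identical": i < k}
            )
    return pd.DataFrame(rows)


def test_per_magnitude_proportions_counting():
    totals = {("none", 0): 10, ("temporal", 1): 10, ("temporal", 2): 10, ("temporal", 3): 10,
              ("spatial", 1): 4, ("spatial", 2): 4, ("spatial", 3): 4}
    ident = {("none", 0): 10, ("temporal", 1): 8, ("temporal", 2): 4, ("temporal", 3): 2,
             ("spatial", 1): 4, ("spatial", 2): 4, ("spatial", 3): 4}
    t = _trials(ident, totals)
    assert per_magnitude_proportions(t, "temporal") == pytest.approx([1.0, 0.8, 0.4, 0.2])
    assert per_magnitude_proportions(t, "spatial") == pytest.approx([1.0, 1.0, 1.0, 1.0])
    # duplicating every trial leaves proportions unchanged
    doubled = pd.concat([t, t], ignore_index=True)
    assert per_magnitude_proportions(doubled, "temporal") == pytest.approx([1.0, 0.8, 0.4, 0.2])


def test_proportions_require_every_level():
    totals = {("none", 0): 4, ("temporal", 1): 4, ("temporal", 2): 0, ("temporal", 3): 4}
    t = _trials({k: 0 for k in totals}, totals)
    with pytest.raises(ValueError, match="level 2"):
        per_magnitude_proportions(t, "temporal")


@pytest.mark.parametrize(
    "props,slope,intercept",
    [
        ((1.0, 0.8, 0.4, 0.2), -0.28, 1.02),
        ((0.5, 0.5, 0.5, 0.5), 0.0, 0.5),
        ((0.9, 0.7, 0.5, 0.3), -0.2, 0.9),
    ],
)
def test_fit_slope_ols_closed_form(props, slope, intercept):
    s, i = sm.fit_slope(props)
    assert s == pytest.approx(slope)
    assert i == pytest.approx(intercept)
    # exact-line case has zero residual
    if props == (0.9, 0.7, 0.5, 0.3):
        fitted = i + s * np.arange(4)
        assert np.allclose(fitted, props)


def test_classify_participant_distances():
    f = sm.SlopeFeatures("x", -0.27, -0.25, 0, 0, 240)
    assert sm.classify_participant(f, (-0.30, -0.28), (-0.10, -0.12)) == "control"
    at_centroid = sm.SlopeFeatures("y", -0.10, -0.12, 0, 0, 240)
    assert sm.classify_participant(at_centroid, (-0.30, -0.28), (-0.10, -0.12)) == "psychosis"


def test_classify_tie_rule_and_warning():
    f = sm.SlopeFeatures("z", 0.0, 0.0, 0, 0, 240)
    with pytest.warns(UserWarning, match="tie"):
        assert sm.classify_participant(f, (0.1, 0.0), (-0.1, 0.0)) == "control"
    with pytest.warns(UserWarning):
        assert sm.classify_participant(f, (0.1, 0.0), (-0.1, 0.0), tie_rule="psychosis") == "psychosis"


def test_classify_rejects_non_finite():
    f = sm.SlopeFeatures("w", np.nan, 0.0, 0, 0, 240)
    with pytest.raises(ValueError):
        sm.classify_participant(f, (0, 0), (1, 1))


def test_ks_two_sample_examples():
    assert sm.ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0
    assert sm.ks_two_sample([1, 2, 3], [4, 5, 6])[0] == 1.0
    assert sm.ks_two_sample([1, 3], [2, 4])[0] == 0.5
    with pytest.raises(ValueError):
        sm.ks_two_sample([], [1.0])


def test_run_classifier_deterministic(small_retained):
    cfg = ClassifierConfig(n_iterations=100, seed=5)
    a = sm.run_classifier(small_retained, cfg)
    b = sm.run_classifier(small_retained, cfg)
    assert np.array_equal(a.accuracy, b.accuracy)
    n = sm.permutation_null(small_retained, cfg)
    m = sm.permutation_null(small_retained, cfg)
    assert np.array_equal(n.accuracy, m.accuracy)


def test_id_relabeling_and_trial_order_invariance(small_retained):
    cfg = ClassifierConfig(n_iterations=60, seed=9)
    base = sm.run_classifier(small_retained, cfg)
    # order-preserving ID relabeling
    renamed = small_retained.copy()
    mapping = {pid: f"Z{idx:03d}" for idx, pid in enumerate(sorted(renamed.trials["participant_id"].unique()))}
    renamed.trials["participant_id"] = renamed.trials["participant_id"].map(mapping)
    renamed.participants["participant_id"] = renamed.participants["participant_id"].map(mapping)
    relabeled = sm.run_classifier(renamed, cfg)
    assert np.array_equal(base.accuracy, relabeled.accuracy)
    # shuffling trial rows leaves full-trial features unchanged
    shuffled = small_retained.copy()
    shuffled.trials = shuffled.trials.sample(frac=1.0, random_state=4).reset_index(drop=True)
    assert np.array_equal(base.accuracy, sm.run_classifier(shuffled, cfg).accuracy)


def test_separable_groups_classified_perfectly(default_params):
    p = copy.deepcopy(default_params)
    for g, slope in (("control", 3.0), ("psychosis", 0.05)):
        gp = getattr(p, g)
        gp.n_participants = 8
        gp.delta_mean = {a: [slope, 2 * slope, 3 * slope] for a in ("temporal", "spatial")}
        gp.delta_sd = 0.01
        gp.kappa_sd = 0.01
        gp.kappa_mean = 1.5
        gp.missing_rate = 0.0
    ds = sm.build_cohort(p, seed=21)
    res = sm.run_classifier(ds, ClassifierConfig(n_iterations=300, seed=2))
    assert res.mean_accuracy == 1.0


def test_same_distribution_groups_are_chance_across_cohorts(default_params):
    """With both groups drawn from one generative distribution, accuracy
    averaged across cohorts sits at chance (a single cohort is biased by its
    realized group-mean gap, which left-out members share with the
    centroids)."""
    p = copy.deepcopy(default_params)
    p.psychosis = copy.deepcopy(p.control)
    p.psychosis.missing_rate = p.control.missing_rate
    accs = []
    for seed in range(20):
        ds, _ = sm.apply_exclusions(sm.build_cohort(p, seed=1000 + seed))
        accs.append(sm.run_classifier(ds, ClassifierConfig(n_iterations=250, seed=seed)).mean_accuracy)
    assert np.mean(accs) == pytest.approx(0.5, abs=0.03)


def test_permutation_null_unbiased(retained_seed0):
    null = sm.permutation_null(retained_seed0, ClassifierConfig(n_iterations=2000, seed=17))
    # binomial-style bound on the mean of iteration accuracies
    se = null.accuracy.std() / np.sqrt(len(null.accuracy))
    assert abs(null.mean_accuracy - 0.5) < max(4 * se, 0.02)


def test_null_vs_real_distributions_separate(retained_seed0):
    cfg = ClassifierConfig(n_iterations=1000, seed=31)
    real = sm.run_classifier(retained_seed0, cfg)
    null = sm.permutation_null(retained_seed0, ClassifierConfig(n_iterations=1000, seed=32))
    D, p = sm.ks_two_sample(real.accuracy, null.accuracy)
    assert D > 0.8 and p < 1e-6


def test_first_block_pool_caps_trials(small_retained):
    with pytest.raises(ValueError, match="caps"):
        ClassifierConfig(trial_pool="first_block", n_trials_sampled=120)
    res = sm.run_classifier(
        small_retained,
        ClassifierConfig(n_iterations=50, trial_pool="first_block", n_trials_sampled=24, seed=3),
    )
    assert 0 <= res.mean_accuracy <= 1


def test_sensitivity_specificity_definitions(small_retained):
    res = sm.run_classifier(small_retained, ClassifierConfig(n_iterations=200, seed=8))
    # per-iteration accuracy is the left-out-size-weighted mean of sens/spec
    assert np.allclose(res.accuracy, (res.sensitivity + res.specificity) / 2)
    assert res.per_participant["n_left_out"].sum() > 0
    freq = res.per_participant.dropna(subset=["frac_classified_psychosis"])
    assert freq["frac_classified_psychosis"].between(0, 1).all()


def test_infeasible_config_raises(small_retained):
    with pytest.raises(ValueError, match="leave"):
        sm.run_classifier(small_retained, ClassifierConfig(leave_out_fraction=0.01, n_iterations=5))
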