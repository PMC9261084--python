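"""Design generator and observer-model behaviour of the synthetic cohort."""

import copy

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import soameta as sm
from soameta.cohort import ParticipantParams, draw_participant
from soameta.metacog import gamma_or_nan


@pytest.mark.parametrize("seed", [0, 1, 7, 123, 2**30])
def test_design_counts(seed):
    d = sm.generate_design(seed)
    assert len(d) == 240
    assert (d["magnitude_level"] == 0).sum() == 60  # 25% unaltered
    assert d["block"].value_counts().eq(48).all()
    cells = d[d["magnitude_level"] > 0].groupby(["aspect", "magnitude_level"]).size()
    assert cells.eq(30).all() and len(cells) == 6
    # conditions are balanced within every block
    per_block = d[d["magnitude_level"] > 0].groupby(["block", "aspect", "magnitude_level"]).size()
    assert per_block.eq(6).all()


def test_design_magnitude_values_consistent():
    d = sm.generate_design(5)
    temporal = d[d["aspect"] == "temporal"]
    assert set(zip(temporal["magnitude_level"], temporal["magnitude_value"])) == {(1, 100.0), (2, 200.0), (3, 300.0)}
    spatial = d[d["aspect"] == "spatial"]
    assert set(zip(spatial["magnitude_level"], spatial["magnitude_value"])) == {(1, 6.0), (2, 10.0), (3, 14.0)}
    assert (d.loc[d["aspect"] == "none", "magnitude_value"] == 0).all()


def test_design_order_differs_across_seeds():
    a, b = sm.generate_design(1), sm.generate_design(2)
    assert not a["aspect"].equals(b["aspect"])


def test_cohort_bit_identical_given_seed(default_params):
    p = copy.deepcopy(default_params)
    p.control.n_participants = 3
    p.psychosis.n_participants = 3
    a = sm.build_cohort(p, seed=99)
    b = sm.build_cohort(p, seed=99)
    pd.testing.assert_frame_equal(a.trials, b.trials)
    pd.testing.assert_frame_equal(a.participants, b.participants)
    c = sm.build_cohort(p, seed=100)
    assert not a.trials["response_identical"].equals(c.trials["response_identical"])


def _simulate(delta, kappa, sigma_meta=0.5, gain=1.0, n_designs=1, seed=11):
    params = ParticipantParams(
        delta={"temporal": np.asarray(delta, float), "spatial": np.asarray(delta, float)},
        kappa=kappa, sigma_meta=sigma_meta, gain=gain, offset=0.0,
    )
    design = pd.concat([sm.generate_design(seed + i) for i in range(n_designs)], ignore_index=True)
    return sm.simulate_responses(design, params, seed + 1000)


def test_separated_observer_near_perfect():
    trials = _simulate((10, 10, 10), kappa=5.0)
    H, FA, *_ = sm.compute_rates(trials)
    d, _ = sm.dprime_criterion(H, FA)
    assert H > 0.98 and FA < 0.02 and d > 4


def test_null_observer_near_chance():
    trials = _simulate((0, 0, 0), kappa=0.0, n_designs=1)
    H, FA, *_ = sm.compute_rates(trials)
    d, _ = sm.dprime_criterion(H, FA)
    assert abs(d) < 0.45  # ~3 SE at 240 trials


def test_rates_converge_to_analytic_values():
    """Realized hit/false-alarm rates approach Phi(kappa) and
    Phi(kappa - delta_l) as trial counts grow."""
    delta, kappa = (0.6, 1.2, 1.8), 1.0
    trials = _simulate(delta, kappa, n_designs=40)  # 9600 trials
    unalt = trials[trials["magnitude_level"] == 0]
    H = unalt["response_identical"].astype(bool).mean()
    assert H == pytest.approx(stats.norm.cdf(kappa), abs=0.02)
    for lvl, d in zip((1, 2, 3), delta):
        sub = trials[trials["magnitude_level"] == lvl]
        fa = sub["response_identical"].astype(bool).mean()
        assert fa == pytest.approx(stats.norm.cdf(kappa - d), abs=0.025)


def test_self_attribution_monotone_in_delta():
    rates = []
    for scale in (0.3, 0.8, 1.5, 2.5):
        trials = _simulate((scale, 1.5 * scale, 2 * scale), kappa=1.0, n_designs=20)
        altered = trials[trials["magnitude_level"] > 0]
        rates.append(altered["response_identical"].astype(bool).mean())
    assert all(a > b for a, b in zip(rates, rates[1:]))


def test_sigma_meta_spans_gamma_continuum():
    """No metacognitive noise -> strongly positive gamma; huge noise -> ~0."""
    lo = _simulate((1.0, 2.0, 3.0), kappa=1.35, sigma_meta=0.0, n_designs=10)
    hi = _simulate((1.0, 2.0, 3.0), kappa=1.35, sigma_meta=25.0, n_designs=10)
    def gam(trials):
        acc = sm.label_accuracy(trials).to_numpy()
        return gamma_or_nan(trials["confidence"].to_numpy(float), acc)
    assert gam(lo) > 0.3
    assert abs(gam(hi)) < 0.1


def test_participant_draws_respect_constraints(default_params, rng):
    for _ in range(200):
        pp = draw_participant(default_params.psychosis, rng)
        assert pp.sigma_meta >= 0
        for d in pp.delta.values():
            assert np.all(np.diff(d) >= 0) and np.all(d >= 0)


def test_zero_coupling_gives_null_correlation(default_params):
    p = copy.deepcopy(default_params)
    p.panss_positive_gamma_coupling = 0.0
    rs = []
    for seed in range(6):
        ds, _ = sm.apply_exclusions(sm.build_cohort(p, seed=800 + seed))
        summ = sm.participant_summary(ds)
        psy = summ[summ["group"] == "psychosis"]
        rs.append(stats.pearsonr(psy["gamma"], psy["panss_positive"]).statistic)
    assert abs(np.mean(rs)) < 0.15  # ~2 SE of a null mean over 6 cohorts of n=30


def test_shipped_coupling_recovers_analytic_target(default_params):
    """Mean recovered r(gamma, PANSS Positive) within +/-0.15 of the coupling."""
    rs = []
    for seed in range(6):
        ds, _ = sm.apply_exclusions(sm.build_cohort(seed=900 + seed))
        summ = sm.participant_summary(ds)
        psy = summ[summ["group"] == "psychosis"]
        rs.append(stats.pearsonr(psy["gamma"], psy["panss_positive"]).statistic)
    assert np.mean(rs) == pytest.approx(default_params.panss_positive_gamma_coupling, abs=0.15)


def test_clinical_scores_only_for_matching_scale(small_cohort):
    parts = small_cohort.participants
    ctl = parts[parts["group"] == "control"]
    psy = parts[parts["group"] == "psychosis"]
    assert ctl[["panss_positive", "panss_total"]].isna().all().all()
    assert psy[["spqb_cogper", "spqb_total"]].isna().all().all()
    assert psy["panss_positive"].notna().all() and (psy["panss_positive"] >= 0).all()
    assert np.allclose(
        psy["panss_total"], psy[["panss_positive", "panss_negative", "panss_general"]].sum(axis=1)
    )
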