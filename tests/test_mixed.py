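"""Mixed-model ladders: independent-oracle agreement, selection, coverage."""

import copy
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import soameta as sm
from soameta.mixed import (
    CONFIDENCE_LADDER,
    LogisticMixedModel,
    build_design,
    design_frame,
    evidence_grade,
    fit_confidence_ladder,
    fit_linear_mixed,
    fit_soa_ladder,
)
from soameta.correlations import clinical_correlations


@pytest.fixture(scope="module")
def oracle_cohort():
    p = copy.deepcopy(sm.default_params())
    p.control.n_participants = 8
    p.psychosis.n_participants = 8
    ds, _ = sm.apply_exclusions(sm.build_cohort(p, seed=7))
    return ds


def test_laplace_fit_matches_lme4_glmer(oracle_cohort, tmp_path):
    """The Laplace logistic mixed fit agrees with lme4::glmer (which uses the
    same approximation) on log-likelihood, BIC, coefficients and SEs."""
    frame = design_frame(oracle_cohort)
    X, names = build_design(frame, ["magnitude", "group", "magnitude:group"])
    y = frame["self_attribution"].to_numpy()
    z = frame["magnitude"].to_numpy()
    model = LogisticMixedModel(y, X, z, frame["participant_id"].to_numpy())
    fit = model.fit(names=names)

    csv = tmp_path / "glmm.csv"
    pd.DataFrame(
        {
            "pid": frame["participant_id"],
            "y": y.astype(int),
            "mag": z,
            "grp": frame["group_s"],
            "mg": z * frame["group_s"].to_numpy(),
        }
    ).to_csv(csv, index=False)
    rscript = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ mag + grp + mg + (1 + mag | pid), data = d, family = binomial)
        cat(sprintf("%.6f\\n", as.numeric(logLik(m))))
        cat(sprintf("%.6f\\n", BIC(m)))
        cat(sprintf("%.6f\\n", fixef(m)))
        cat(sprintf("%.6f\\n", sqrt(diag(as.matrix(vcov(m))))))
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    vals = [float(v) for v in out.stdout.split()]
    r_ll, r_bic, r_beta, r_se = vals[0], vals[1], vals[2:6], vals[6:10]
    assert fit.loglik == pytest.approx(r_ll, abs=0.02)
    assert fit.bic == pytest.approx(r_bic, abs=0.05)
    assert fit.params == pytest.approx(r_beta, abs=2e-3)
    theta = np.concatenate([fit.params, _chol_theta(fit.cov_re)])
    se = model._beta_se(theta)
    assert se == pytest.approx(r_se, rel=0.02)


def _chol_theta(Sigma):
    L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(2))
    return np.array([np.log(L[0, 0]), np.log(L[1, 1]), L[1, 0]])


def test_soa_ladder_selects_interaction_model(oracle_cohort):
    comp = fit_soa_ladder(oracle_cohort)
    assert comp.winner == "magnitude x group"
    co = comp.coefficients.set_index("term")
    assert co.loc["magnitude", "estimate"] < 0
    assert co.loc["magnitude:group", "estimate"] < 0
    assert (co["ci_low"] <= co["estimate"]).all() and (co["estimate"] <= co["ci_high"]).all()
    tab = comp.table.set_index("name")
    assert tab.loc[comp.winner, "delta_bic"] == 0
    assert (tab["delta_bic"] >= 0).all()


def test_bic_ordering_invariant_to_enumeration_order(oracle_cohort):
    forward = fit_soa_ladder(oracle_cohort, compute_se=False)
    reversed_candidates = dict(reversed(list(sm.SOA_LADDER.items())))
    backward = fit_soa_ladder(oracle_cohort, candidates=reversed_candidates, compute_se=False)
    assert forward.winner == backward.winner
    a = forward.table.set_index("name")["bic"]
    b = backward.table.set_index("name")["bic"]
    assert np.allclose(a.sort_index(), b.sort_index(), atol=0.05)


def test_group_free_data_rejects_group_models(default_params):
    """Without a group effect, BIC prefers the group-free model."""
    p = copy.deepcopy(default_params)
    p.psychosis = copy.deepcopy(p.control)
    p.psychosis.n_participants = 10
    p.control.n_participants = 10
    wins = 0
    n = 20
    for seed in range(n):
        ds, _ = sm.apply_exclusions(sm.build_cohort(p, seed=600 + seed))
        comp = fit_soa_ladder(ds, compute_se=False)
        wins += comp.winner == "magnitude"
    assert wins / n >= 0.9


def test_aspect_model_never_wins_decisively(oracle_cohort):
    """The generator has no aspect effect: adding aspect terms must not beat
    the winner by more than the positive-evidence threshold."""
    comp = fit_soa_ladder(oracle_cohort, compute_se=False)
    assert comp.delta_bic("magnitude x group + aspect") >= 0
    soa_bics = comp.table.set_index("name")["bic"]
    assert soa_bics["magnitude x group + aspect"] - soa_bics["magnitude x group"] > -2


def test_confidence_ladder_recovers_three_way(retained_seed0):
    """At the study size the full model wins and the three-way interaction is
    positive: confidence tracks accuracy more steeply with magnitude in the
    control group."""
    comp = fit_confidence_ladder(retained_seed0)
    assert comp.winner == "magnitude x group x accuracy"
    co = comp.coefficients.set_index("term")
    assert co.loc["magnitude:group:accuracy", "estimate"] > 0
    assert co.loc["accuracy", "estimate"] > 0  # confidence higher when correct


def test_independent_confidence_selects_intercept_only(oracle_cohort, rng):
    ds = oracle_cohort.copy()
    ds.trials = ds.trials.copy()
    ds.trials["confidence"] = rng.normal(0.5, 1.0, len(ds.trials)).clip(-3, 3)
    comp = fit_confidence_ladder(ds, compute_se=False)
    assert comp.winner == "intercept"


def test_near_noiseless_quadratic_confidence_recovered(oracle_cohort, rng):
    """Confidence that is an exact quadratic in magnitude (tiny jitter for
    numerical stability) is captured by the quadratic fixed effects with
    near-zero residual variance."""
    ds = oracle_cohort.copy()
    ds.trials = ds.trials.copy()
    lvl = ds.trials["magnitude_level"].to_numpy(float)
    truth = 0.3 * (lvl - 1.5) ** 2 - 0.2 * (lvl - 1.5) + 0.5
    ds.trials["confidence"] = truth + rng.normal(0, 0.01, len(lvl))
    frame = design_frame(ds)
    frame = frame[frame["confidence"].notna()]
    X, names = build_design(frame, ["magnitude", "magnitude2"])
    fit = fit_linear_mixed(
        frame["confidence"].to_numpy(float), X, frame["magnitude"].to_numpy(),
        frame["participant_id"].to_numpy(), names,
    )
    fitted = X @ fit.params
    resid = frame["confidence"].to_numpy(float) - fitted
    assert np.var(resid) < 1e-3


def test_ci_coverage_of_generative_slope(rng):
    """Wald CI of a linear mixed fixed effect covers the generative value at
    ~95% across simulations (reduced problem size)."""
    beta1 = 0.4
    covered = 0
    reps = 150
    for _ in range(reps):
        n_part, n_tr = 12, 40
        groups = np.repeat(np.arange(n_part), n_tr)
        x = rng.normal(size=n_part * n_tr)
        b0 = rng.normal(0, 0.5, n_part)[groups]
        b1 = rng.normal(0, 0.3, n_part)[groups]
        y = 1.0 + beta1 * x + b0 + b1 * x + rng.normal(0, 1.0, n_part * n_tr)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_linear_mixed(y, X, x, groups, ["intercept", "x"], compute_se=True)
        lo = fit.params[1] - 1.96 * fit.se[1]
        hi = fit.params[1] + 1.96 * fit.se[1]
        covered += lo <= beta1 <= hi
    assert 0.89 <= covered / reps <= 0.995


def test_evidence_grades():
    assert evidence_grade(1.0) == "weak"
    assert evidence_grade(3.9) == "positive"
    assert evidence_grade(7.0) == "strong"
    assert evidence_grade(70.0) == "very strong"


def test_clinical_correlations_perfect_and_null(rng):
    df = pd.DataFrame(
        {
            "group": ["psychosis"] * 10,
            "d_prime": np.arange(10, dtype=float),
            "criterion_c": rng.normal(size=10),
            "gamma": np.full(10, 0.3),
            "panss_positive": 2.0 * np.arange(10) + 5,
            "panss_negative": rng.normal(15, 5, 10),
            "panss_general": rng.normal(30, 7, 10),
            "panss_total": rng.normal(60, 10, 10),
        }
    )
    table = clinical_correlations(df)
    perfect = table[(table["measure"] == "d_prime") & (table["scale"] == "panss_positive")]
    assert perfect["r"].iloc[0] == pytest.approx(1.0)
    const = table[(table["measure"] == "gamma") & (table["scale"] == "panss_positive")]
    assert np.isnan(const["r"].iloc[0]) and "constant" in const["note"].iloc[0]


def test_null_correlation_rarely_large(rng):
    big = 0
    reps = 400
    for _ in range(reps):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = np.corrcoef(x, y)[0, 1]
        big += abs(r) >= 0.5
    assert big / reps <= 0.05
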