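"""Mixed-effects model ladders and BIC model selection.

Self-attribution (a binary outcome) is modelled with logistic mixed-effects
regressions and confidence (continuous) with linear mixed-effects
regressions, both with a per-participant random intercept and random slope
of alteration magnitude.  Candidate fixed-effect ladders over
{magnitude, group, aspect, accuracy} are compared by the Bayesian
Information Criterion, with delta-BIC of 2-6 / 6-10 / >10 graded as
positive / strong / very strong evidence for the lower-BIC model.

Coding conventions (recorded in every comparison's metadata):

* magnitude: ordinal level 0-3, centered (empirical mean removed); its
  quadratic expansion is Gram-Schmidt orthogonalized against the linear
  term, capturing the U-shaped confidence profile without collinearity;
* group: sum coding, control = +1, psychosis = -1 — so the magnitude main
  effect is the average of the group slopes and the magnitude x group
  interaction is half their difference (both negative when controls show
  the steeper decline of self-attribution with magnitude);
* aspect: spatial = +0.5, temporal = -0.5, unaltered = 0;
* accuracy: correct = +1, incorrect = -1.

The logistic fits use a Laplace approximation to the marginal likelihood
(the same approximation lme4::glmer uses by default), implemented here with
vectorized per-participant Newton mode-finding; linear fits use statsmodels
MixedLM by maximum likelihood.  BIC = -2 logLik + k log(n_obs) with k
counting fixed effects plus the three random-effect (co)variance
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm

from .datamodel import StudyDataset, label_accuracy

EVIDENCE_THRESHOLDS = (2.0, 6.0, 10.0)


def evidence_grade(delta_bic: float) -> str:
    """Grade a BIC difference: weak (<2), positive (2-6), strong (6-10),
    very strong (>10)."""
    if delta_bic < 2:
        return "weak"
    if delta_bic < 6:
        return "positive"
    if delta_bic < 10:
        return "strong"
    return "very strong"


# ---------------------------------------------------------------------------
# design construction

SOA_LADDER = {
    "magnitude": ["magnitude"],
    "magnitude + group": ["magnitude", "group"],
    "magnitude x group": ["magnitude", "group", "magnitude:group"],
    "magnitude x group + aspect": [
        "magnitude", "group", "magnitude:group",
        "aspect", "aspect:magnitude", "aspect:group",
    ],
}

CONFIDENCE_LADDER = {
    "intercept": [],
    "magnitude": ["magnitude", "magnitude2"],
    "magnitude x accuracy": [
        "magnitude", "magnitude2", "accuracy",
        "magnitude:accuracy", "magnitude2:accuracy",
    ],
    "magnitude x accuracy + group": [
        "magnitude", "magnitude2", "accuracy", "group",
        "magnitude:accuracy", "magnitude2:accuracy",
    ],
    "magnitude x group x accuracy": [
        "magnitude", "magnitude2", "group", "accuracy",
        "magnitude:group", "magnitude2:group",
        "magnitude:accuracy", "magnitude2:accuracy",
        "group:accuracy",
        "magnitude:group:accuracy", "magnitude2:group:accuracy",
    ],
}


def design_frame(dataset: StudyDataset) -> pd.DataFrame:
    """Trial-level modelling frame from retained trials.

    Adds centered/orthogonalized magnitude terms, sum-coded group, aspect
    and accuracy columns, and the binary self-attribution outcome.
    """
    t = dataset.retained().copy()
    t["self_attribution"] = t["response_identical"].astype(bool).astype(float)
    t["accuracy"] = np.where(label_accuracy(t), 1.0, -1.0)
    lvl = t["magnitude_level"].to_numpy(float)
    mag = lvl - lvl.mean()
    m2 = mag**2
    # Gram-Schmidt: orthogonalize the quadratic term against [1, mag]
    m2 = m2 - m2.mean() - (m2 @ mag) / (mag @ mag) * mag
    t["magnitude"] = mag
    t["magnitude2"] = m2
    t["group_s"] = np.where(t["group"] == "control", 1.0, -1.0)
    t["aspect_s"] = t["aspect"].map({"temporal": -0.5, "spatial": 0.5, "none": 0.0}).astype(float)
    return t


def _term_column(frame: pd.DataFrame, term: str) -> np.ndarray:
    col = np.ones(len(frame))
    for part in term.split(":"):
        name = {"group": "group_s", "aspect": "aspect_s", "accuracy": "accuracy"}.get(part, part)
        col = col * frame[name].to_numpy(float)
    return col


def build_design(frame: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(frame))] + [_term_column(frame, t) for t in terms]
    return np.column_stack(cols), ["intercept"] + list(terms)


# ---------------------------------------------------------------------------
# Laplace logistic mixed model

@dataclass
class MixedFitResult:
    names: list[str]
    params: np.ndarray
    loglik: float
    bic: float
    n_params: int
    n_obs: int
    cov_re: np.ndarray  # 2x2 random-effect covariance
    converged: bool
    singular: bool
    se: np.ndarray | None = None

    def coefficient_table(self) -> pd.DataFrame:
        if self.se is None:
            raise ValueError("standard errors not computed for this fit")
        z = self.params / self.se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.params,
                "se": self.se,
                "stat": z,
                "p": p,
                "ci_low": self.params - 1.959963984540054 * self.se,
                "ci_high": self.params + 1.959963984540054 * self.se,
            }
        )


class LogisticMixedModel:
    """Logistic mixed-effects model with per-participant random intercept
    and random magnitude slope, fit by Laplace-approximate ML.

    The marginal likelihood integrates the 2-D random effect per
    participant; the integral is approximated at the posterior mode found by
    damped Newton iterations, vectorized across participants.
    """

    def __init__(self, y, X, z_slope, groups):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        z = np.asarray(z_slope, float)
        codes, self.group_ids = pd.factorize(np.asarray(groups))
        self.n_groups = len(self.group_ids)
        self.n_obs = len(y)
        self.p = X.shape[1]
        counts = np.bincount(codes)
        T = counts.max()
        self.yp = np.zeros((self.n_groups, T))
        self.Xp = np.zeros((self.n_groups, T, self.p))
        self.Zp = np.zeros((self.n_groups, T, 2))
        self.mask = np.zeros((self.n_groups, T))
        pos = np.zeros(self.n_groups, dtype=int)
        for i in range(self.n_obs):
            g = codes[i]
            j = pos[g]
            self.yp[g, j] = y[i]
            self.Xp[g, j] = X[i]
            self.Zp[g, j] = (1.0, z[i])
            self.mask[g, j] = 1.0
            pos[g] += 1
        self._bhat = np.zeros((self.n_groups, 2))

    # -- inner Laplace machinery -------------------------------------------

    def _cond_terms(self, beta, b):
        eta = self.Xp @ beta + np.einsum("ntq,nq->nt", self.Zp, b)
        ll = (self.yp * eta - np.logaddexp(0.0, eta)) * self.mask
        mu = special.expit(eta)
        return ll.sum(axis=1), mu

    def _find_modes(self, beta, Sinv, tol=1e-9, max_iter=50):
        b = self._bhat.copy()
        obj, mu = self._cond_terms(beta, b)
        obj = obj - 0.5 * np.einsum("nq,qr,nr->n", b, Sinv, b)
        for _ in range(max_iter):
            w = mu * (1 - mu) * self.mask
            grad = np.einsum("ntq,nt->nq", self.Zp, (self.yp - mu) * self.mask) - b @ Sinv
            H00 = np.einsum("nt,nt->n", w, self.Zp[:, :, 0] ** 2) + Sinv[0, 0]
            H01 = np.einsum("nt,nt,nt->n", w, self.Zp[:, :, 0], self.Zp[:, :, 1]) + Sinv[0, 1]
            H11 = np.einsum("nt,nt->n", w, self.Zp[:, :, 1] ** 2) + Sinv[1, 1]
            det = H00 * H11 - H01**2
            step0 = (H11 * grad[:, 0] - H01 * grad[:, 1]) / det
            step1 = (H00 * grad[:, 1] - H01 * grad[:, 0]) / det
            step = np.column_stack([step0, step1])
            if np.max(np.abs(grad)) < tol:
                break
            # damped update
            scale = np.ones(self.n_groups)
            for _ in range(12):
                b_new = b + step * scale[:, None]
                ll_new, mu_new = self._cond_terms(beta, b_new)
                obj_new = ll_new - 0.5 * np.einsum("nq,qr,nr->n", b_new, Sinv, b_new)
                worse = obj_new < obj - 1e-12
                if not worse.any():
                    break
                scale[worse] *= 0.5
            b, obj, mu = b_new, obj_new, mu_new
        self._bhat = b
        w = mu * (1 - mu) * self.mask
        H00 = np.einsum("nt,nt->n", w, self.Zp[:, :, 0] ** 2) + Sinv[0, 0]
        H01 = np.einsum("nt,nt,nt->n", w, self.Zp[:, :, 0], self.Zp[:, :, 1]) + Sinv[0, 1]
        H11 = np.einsum("nt,nt->n", w, self.Zp[:, :, 1] ** 2) + Sinv[1, 1]
        logdetH = np.log(H00 * H11 - H01**2)
        return b, obj, logdetH

    @staticmethod
    def _sigma(theta_cov):
        t0, t1, t2 = theta_cov
        L = np.array([[np.exp(t0), 0.0], [t2, np.exp(t1)]])
        return L @ L.T

    def _neg_loglik(self, theta):
        beta, tc = theta[: self.p], theta[self.p:]
        Sigma = self._sigma(tc)
        try:
            Sinv = np.linalg.inv(Sigma)
            _, logdetS = np.linalg.slogdet(Sigma)
        except np.linalg.LinAlgError:
            return 1e10
        _, obj, logdetH = self._find_modes(beta, Sinv)
        ll = obj.sum() - 0.5 * self.n_groups * logdetS - 0.5 * logdetH.sum()
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def fit(self, start_beta=None, compute_se=False, names=None) -> MixedFitResult:
        if start_beta is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y = self.yp[self.mask > 0]
                X = self.Xp[self.mask > 0]
                start_beta = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        theta0 = np.concatenate([start_beta, [0.0, np.log(0.5), 0.0]])
        bounds = [(None, None)] * self.p + [(-4.0, 3.0), (-4.0, 3.0), (-20.0, 20.0)]
        res = optimize.minimize(
            self._neg_loglik, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-10},
        )
        beta = res.x[: self.p]
        Sigma = self._sigma(res.x[self.p:])
        loglik = -res.fun
        k = self.p + 3
        bic = -2 * loglik + k * np.log(self.n_obs)
        sds = np.sqrt(np.diag(Sigma))
        corr = Sigma[0, 1] / (sds[0] * sds[1]) if np.all(sds > 0) else 1.0
        singular = bool(np.any(sds < 2e-2) or abs(corr) > 0.999)
        se = self._beta_se(res.x) if compute_se else None
        return MixedFitResult(
            names=list(names) if names is not None else [f"x{i}" for i in range(self.p)],
            params=beta, loglik=float(loglik), bic=float(bic), n_params=k,
            n_obs=self.n_obs, cov_re=Sigma, converged=bool(res.success),
            singular=singular, se=se,
        )

    def _beta_se(self, theta_hat) -> np.ndarray:
        # central-difference Hessian of -loglik over the fixed-effect block
        p = self.p
        h = 1e-4 * np.maximum(np.abs(theta_hat[:p]), 1.0)
        H = np.zeros((p, p))
        f = {}

        def nll(d):
            key = tuple(np.round(d, 12))
            if key not in f:
                th = theta_hat.copy()
                th[:p] = th[:p] + d
                f[key] = self._neg_loglik(th)
            return f[key]

        for i in range(p):
            ei = np.zeros(p)
            ei[i] = h[i]
            for j in range(i, p):
                ej = np.zeros(p)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    nll(ei + ej) - nll(ei - ej) - nll(-ei + ej) + nll(-ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            return np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# linear mixed model (statsmodels backend)

def fit_linear_mixed(y, X, z_slope, groups, names, compute_se=False) -> MixedFitResult:
    exog_re = np.column_stack([np.ones(len(y)), np.asarray(z_slope, float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(np.asarray(y, float), np.asarray(X, float), groups=np.asarray(groups), exog_re=exog_re)
        # lbfgs is fast but occasionally stalls in a local optimum; powell is
        # slower but robust — fit both and keep the better likelihood
        fit = None
        for method in ("lbfgs", "powell", "bfgs", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            if np.isfinite(cand.llf) and (fit is None or cand.llf > fit.llf + 1e-8):
                fit = cand
            if method == "powell" and fit is not None and fit.converged:
                break  # only fall through to bfgs/cg when both primary fits failed
        if fit is None:
            raise RuntimeError("linear mixed model failed for every optimizer")
        converged = bool(fit.converged)
    p = X.shape[1]
    k = p + 3 + 1  # fixed effects + RE covariance (3) + residual variance
    loglik = float(fit.llf)
    bic = -2 * loglik + k * np.log(len(y))
    cov_re = np.asarray(fit.cov_re)
    sds = np.sqrt(np.maximum(np.diag(cov_re), 0.0))
    corr = cov_re[0, 1] / (sds[0] * sds[1]) if np.all(sds > 0) else 1.0
    singular = bool(np.any(sds < 2e-2 * np.std(np.asarray(y, float))) or abs(corr) > 0.999)
    se = np.asarray(fit.bse_fe) if compute_se else None
    return MixedFitResult(
        names=list(names), params=np.asarray(fit.fe_params), loglik=loglik,
        bic=float(bic), n_params=k, n_obs=len(y), cov_re=cov_re,
        converged=converged, singular=singular, se=se,
    )


# ---------------------------------------------------------------------------
# ladders

@dataclass
class ModelComparison:
    table: pd.DataFrame  # name, n_params, loglik, bic, delta_bic, evidence, converged, singular
    winner: str
    coefficients: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def delta_bic(self, name: str) -> float:
        return float(self.table.set_index("name").loc[name, "delta_bic"])


def _compare(fits: dict[str, MixedFitResult], refit_winner) -> ModelComparison:
    rows = []
    for name, f in fits.items():
        rows.append(
            {
                "name": name, "n_params": f.n_params, "loglik": f.loglik,
                "bic": f.bic, "converged": f.converged, "singular": f.singular,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["converged"] & np.isfinite(table["bic"])]
    if len(ok) == 0:
        ok = table[np.isfinite(table["bic"])]
        if len(ok) == 0:
            raise RuntimeError("no candidate model converged")
        warnings.warn("no candidate formally converged; comparing best finite-likelihood fits")
    best = ok.loc[ok["bic"].idxmin(), "name"]
    table["delta_bic"] = table["bic"] - float(table.loc[table["name"] == best, "bic"].iloc[0])
    table["evidence"] = [
        "winner" if n == best else evidence_grade(d)
        for n, d in zip(table["name"], table["delta_bic"])
    ]
    table = table.sort_values("bic", ignore_index=True)
    coeffs = refit_winner(best)
    return ModelComparison(table=table, winner=str(best), coefficients=coeffs)


def fit_soa_ladder(dataset: StudyDataset, candidates: dict | None = None,
                   compute_se: bool = True) -> ModelComparison:
    """Logistic mixed-model ladder for self-attribution.

    Fits each candidate fixed-effect set (default :data:`SOA_LADDER`) with a
    per-participant random intercept and magnitude slope, compares by BIC,
    and reports the winner's coefficient table (Wald z tests).  Models that
    fail to converge are recorded and skipped in the comparison; an error is
    raised only if all fail.
    """
    candidates = candidates or SOA_LADDER
    frame = design_frame(dataset)
    y = frame["self_attribution"].to_numpy()
    z = frame["magnitude"].to_numpy()
    groups = frame["participant_id"].to_numpy()
    fits: dict[str, MixedFitResult] = {}
    models: dict[str, tuple] = {}
    for name, terms in candidates.items():
        X, colnames = build_design(frame, terms)
        model = LogisticMixedModel(y, X, z, groups)
        models[name] = (model, colnames)
        try:
            fits[name] = model.fit(names=colnames)
        except Exception as exc:  # keep the ladder going
            warnings.warn(f"model {name!r} failed: {exc}")

    def refit_winner(name):
        model, colnames = models[name]
        if not compute_se:
            return pd.DataFrame({"term": colnames, "estimate": fits[name].params})
        se = model._beta_se(
            np.concatenate([fits[name].params, _cov_theta(fits[name].cov_re)])
        )
        fits[name].se = se
        return fits[name].coefficient_table()

    comp = _compare(fits, refit_winner)
    comp.metadata = {
        "outcome": "self_attribution (identical = 1)",
        "coding": "group control=+1; aspect spatial=+0.5; magnitude centered level",
        "random_effects": "per-participant intercept + magnitude slope",
        "backend": "Laplace logistic mixed model",
    }
    return comp


def _cov_theta(Sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(2))
    return np.array([np.log(L[0, 0]), np.log(L[1, 1]), L[1, 0]])


def fit_confidence_ladder(dataset: StudyDataset, candidates: dict | None = None,
                          compute_se: bool = True) -> ModelComparison:
    """Linear mixed-model ladder for confidence.

    Magnitude enters through its centered linear and orthogonalized
    quadratic terms (confidence is U-shaped in magnitude: high when the
    movement is clearly one's own or clearly altered).  The top candidate
    crosses magnitude with group and judgment accuracy; the three-way
    magnitude x group x accuracy interaction is the metacognitive signature
    (confidence tracks accuracy more steeply with magnitude in one group).
    Rows with missing confidence are dropped.
    """
    candidates = candidates or CONFIDENCE_LADDER
    frame = design_frame(dataset)
    frame = frame[frame["confidence"].notna()]
    y = frame["confidence"].to_numpy(float)
    z = frame["magnitude"].to_numpy()
    groups = frame["participant_id"].to_numpy()
    fits: dict[str, MixedFitResult] = {}
    designs: dict[str, tuple] = {}
    for name, terms in candidates.items():
        X, colnames = build_design(frame, terms)
        designs[name] = (X, colnames)
        try:
            fits[name] = fit_linear_mixed(y, X, z, groups, colnames)
        except Exception as exc:
            warnings.warn(f"model {name!r} failed: {exc}")

    def refit_winner(name):
        X, colnames = designs[name]
        res = fit_linear_mixed(y, X, z, groups, colnames, compute_se=compute_se)
        if not compute_se:
            return pd.DataFrame({"term": colnames, "estimate": res.params})
        return res.coefficient_table()

    comp = _compare(fits, refit_winner)
    comp.metadata = {
        "outcome": "confidence [-3, 3]",
        "coding": "group control=+1; accuracy correct=+1; magnitude centered + orthogonal quadratic",
        "random_effects": "per-participant intercept + magnitude slope",
        "backend": "statsmodels MixedLM (ML)",
    }
    return comp
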