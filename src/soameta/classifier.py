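"""Slope-based clinical classifier.

Each participant is summarized by the slope of the linear fit of their
self-attribution proportion against alteration magnitude level (0-3), one
slope per aspect; the shared unaltered pool supplies the level-0 point of
both aspects.  A held-out participant is assigned to the group whose mean
(temporal, spatial) slope vector — the centroid of the retained
participants — is nearer in Euclidean distance.

The resampling procedure repeatedly (default 10,000 iterations) leaves out
the same fraction of participants from each group, recomputes centroids
from the rest, and classifies the left-out participants, optionally from a
random subsample of their trials (drawn from the whole experiment or from
the first block only) to probe how little data suffices.  Chance level is
established by a permutation null — the same procedure with group labels
randomly permuted — compared to the real-label accuracy distribution with a
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import StudyDataset

LEVELS = np.arange(4.0)
# OLS slope weights for x = 0..3: (x - 1.5) / sum((x - 1.5)^2)
_SLOPE_W = (LEVELS - 1.5) / 5.0


@dataclass
class SlopeFeatures:
    participant_id: str
    slope_temporal: float
    slope_spatial: float
    intercept_temporal: float
    intercept_spatial: float
    n_trials_used: int

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.slope_temporal, self.slope_spatial])


@dataclass
class ClassifierConfig:
    """Resampling configuration.

    leave_out_fraction: fraction of each group's participants held out per
        iteration (must leave >=1 out and >=1 retained per group).
    n_trials_sampled: trials drawn without replacement per left-out
        participant, or "all".
    trial_pool: "whole_experiment" or "first_block" (block 1, i.e. the
        first 48 presented trials).
    subsample_retained: when True, centroid participants are subsampled the
        same way as left-out ones (default False: centroids always use full
        retained trials).
    tie_rule: group assigned on an exact distance tie.
    """

    leave_out_fraction: float = 0.2
    n_iterations: int = 10_000
    n_trials_sampled: int | str = "all"
    trial_pool: str = "whole_experiment"
    seed: int = 0
    tie_rule: str = "control"
    subsample_retained: bool = False
    max_resample_attempts: int = 100

    def __post_init__(self):
        if not 0 < self.leave_out_fraction < 1:
            raise ValueError("leave_out_fraction must be in (0,1)")
        if self.trial_pool not in ("whole_experiment", "first_block"):
            raise ValueError("trial_pool must be 'whole_experiment' or 'first_block'")
        if self.tie_rule not in ("control", "psychosis"):
            raise ValueError("tie_rule must be 'control' or 'psychosis'")
        if self.n_trials_sampled != "all":
            n = int(self.n_trials_sampled)
            if n < 7:
                raise ValueError("n_trials_sampled must cover the 7 (aspect x level) cells")
            if self.trial_pool == "first_block" and n > 48:
                raise ValueError("first_block pool caps n_trials_sampled at 48")


@dataclass
class ClassifierResult:
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    per_participant: pd.DataFrame
    config: ClassifierConfig

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificity.mean())

    def ci95(self, which: str = "accuracy") -> tuple[float, float]:
        v = getattr(self, which)
        return tuple(np.percentile(v, [2.5, 97.5]))

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "accuracy_ci95": list(self.ci95("accuracy")),
            "n_iterations": len(self.accuracy),
        }


def per_magnitude_proportions(trials: pd.DataFrame, aspect: str) -> np.ndarray:
    """Proportion of "identical" responses at levels 0..3 for one aspect.

    Level 0 is the shared unaltered pool (aspect "none"); levels 1-3 are the
    aspect's altered trials.  Every level must be represented.
    """
    resp = trials["response_identical"]
    if resp.isna().any():
        raise ValueError("exclude trials with missing responses first")
    props = np.empty(4)
    for lvl in range(4):
        m = (trials["aspect"] == "none") if lvl == 0 else (
            (trials["aspect"] == aspect) & (trials["magnitude_level"] == lvl)
        )
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"no trials at {aspect} level {lvl}")
        props[lvl] = resp[m].astype(bool).mean()
    return props


def fit_slope(proportions) -> tuple[float, float]:
    """OLS line of self-attribution proportion on magnitude level 0..3."""
    y = np.asarray(proportions, dtype=float)
    if y.shape != (4,) or not np.all(np.isfinite(y)):
        raise ValueError("need 4 finite proportions")
    slope = float(_SLOPE_W @ y)
    return slope, float(y.mean() - slope * 1.5)


def slope_features(trials: pd.DataFrame, participant_id: str = "") -> SlopeFeatures:
    """Per-aspect slope/intercept features from a participant's trials."""
    st, it = fit_slope(per_magnitude_proportions(trials, "temporal"))
    ss, is_ = fit_slope(per_magnitude_proportions(trials, "spatial"))
    return SlopeFeatures(participant_id, st, ss, it, is_, len(trials))


def classify_participant(features, centroid_control, centroid_psychosis, tie_rule="control") -> str:
    """Nearest-centroid assignment by Euclidean distance in slope space."""
    v = features.vector if isinstance(features, SlopeFeatures) else np.asarray(features, float)
    cc = np.asarray(centroid_control, float)
    cp = np.asarray(centroid_psychosis, float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(cc)) and np.all(np.isfinite(cp))):
        raise ValueError("non-finite features or centroids")
    dc, dp = np.linalg.norm(v - cc), np.linalg.norm(v - cp)
    if dc == dp:
        warnings.warn("exact centroid-distance tie; applying tie rule", stacklevel=2)
        return tie_rule
    return "control" if dc < dp else "psychosis"


# ---------------------------------------------------------------------------
# fast per-participant trial cache for the resampling loop

_N_CELLS = 7  # 0 = unaltered, 1-3 temporal, 4-6 spatial


@dataclass
class _Cache:
    pid: str
    group: str
    cells: np.ndarray  # int cell index per retained pooled trial
    resp: np.ndarray  # float 0/1 "identical" response
    full_feature: np.ndarray  # slope 2-vector from the full pool


def _cell_codes(trials: pd.DataFrame) -> np.ndarray:
    aspect = trials["aspect"].to_numpy()
    level = trials["magnitude_level"].to_numpy()
    codes = np.zeros(len(trials), dtype=np.intp)
    codes[aspect == "temporal"] = level[aspect == "temporal"]
    codes[aspect == "spatial"] = level[aspect == "spatial"] + 3
    return codes


def _feature_from_counts(counts: np.ndarray, resp_sums: np.ndarray) -> np.ndarray:
    p = resp_sums / counts
    temporal = np.array([p[0], p[1], p[2], p[3]])
    spatial = np.array([p[0], p[4], p[5], p[6]])
    return np.array([_SLOPE_W @ temporal, _SLOPE_W @ spatial])


def _build_caches(dataset: StudyDataset, pool: str) -> list[_Cache]:
    caches = []
    trials = dataset.retained()
    for pid, sub in trials.groupby("participant_id", sort=True):
        full = sub  # centroids always use the full retained trials
        pooled = sub[sub["block"] == 1] if pool == "first_block" else sub
        cells = _cell_codes(pooled)
        resp = pooled["response_identical"].astype(bool).to_numpy().astype(float)
        counts = np.bincount(_cell_codes(full), minlength=_N_CELLS)
        sums = np.bincount(_cell_codes(full), weights=full["response_identical"].astype(bool).to_numpy().astype(float), minlength=_N_CELLS)
        if (counts == 0).any():
            raise ValueError(f"participant {pid} lacks trials at some (aspect x level) cell")
        caches.append(_Cache(pid, sub["group"].iloc[0], cells, resp, _feature_from_counts(counts, sums)))
    return caches


def _pool_feature(cache: _Cache) -> np.ndarray:
    counts = np.bincount(cache.cells, minlength=_N_CELLS)
    if (counts == 0).any():
        raise ValueError(f"participant {cache.pid}: empty (aspect x level) cell in trial pool")
    sums = np.bincount(cache.cells, weights=cache.resp, minlength=_N_CELLS)
    return _feature_from_counts(counts, sums)


def _subsampled_feature(cache: _Cache, n: int, rng: np.random.Generator, max_attempts: int) -> np.ndarray:
    size = len(cache.cells)
    if n >= size:
        return _pool_feature(cache)
    for _ in range(max_attempts):
        idx = rng.choice(size, n, replace=False)
        counts = np.bincount(cache.cells[idx], minlength=_N_CELLS)
        if (counts == 0).any():
            continue
        sums = np.bincount(cache.cells[idx], weights=cache.resp[idx], minlength=_N_CELLS)
        return _feature_from_counts(counts, sums)
    raise ValueError(
        f"could not draw {n} trials covering all cells for {cache.pid} "
        f"after {max_attempts} attempts"
    )


def _run(dataset: StudyDataset, config: ClassifierConfig, permute_labels: bool) -> ClassifierResult:
    caches = _build_caches(dataset, config.trial_pool)
    groups = np.array([c.group for c in caches])
    n_ctl, n_psy = int((groups == "control").sum()), int((groups == "psychosis").sum())
    if n_ctl < 2 or n_psy < 2:
        raise ValueError("need >=2 participants per group")
    k_ctl = int(round(config.leave_out_fraction * n_ctl))
    k_psy = int(round(config.leave_out_fraction * n_psy))
    if min(k_ctl, k_psy) < 1 or k_ctl >= n_ctl or k_psy >= n_psy:
        raise ValueError("leave_out_fraction must leave >=1 out and >=1 retained per group")

    subsample = config.n_trials_sampled != "all"
    n_sub = None if not subsample else int(config.n_trials_sampled)
    ss_part, ss_trial = np.random.SeedSequence(config.seed).spawn(2)
    rng_part = np.random.default_rng(ss_part)
    rng_trial = np.random.default_rng(ss_trial)

    features_full = np.array([c.full_feature for c in caches])
    pool_features = None
    if not subsample and config.trial_pool == "first_block":
        pool_features = np.array([_pool_feature(c) for c in caches])
    elif not subsample:
        pool_features = features_full

    n = len(caches)
    acc = np.empty(config.n_iterations)
    sens = np.empty(config.n_iterations)
    spec = np.empty(config.n_iterations)
    left_out_count = np.zeros(n)
    psy_classified = np.zeros(n)

    idx_all = np.arange(n)
    tie_label = config.tie_rule
    for it in range(config.n_iterations):
        labels = groups
        if permute_labels:
            labels = groups[rng_part.permutation(n)]
        ctl_idx = idx_all[labels == "control"]
        psy_idx = idx_all[labels == "psychosis"]
        out_ctl = rng_part.choice(ctl_idx, k_ctl, replace=False)
        out_psy = rng_part.choice(psy_idx, k_psy, replace=False)
        kept_ctl = np.setdiff1d(ctl_idx, out_ctl, assume_unique=True)
        kept_psy = np.setdiff1d(psy_idx, out_psy, assume_unique=True)
        if config.subsample_retained and subsample:
            cen_ctl = np.mean([_subsampled_feature(caches[i], n_sub, rng_trial, config.max_resample_attempts) for i in kept_ctl], axis=0)
            cen_psy = np.mean([_subsampled_feature(caches[i], n_sub, rng_trial, config.max_resample_attempts) for i in kept_psy], axis=0)
        else:
            cen_ctl = features_full[kept_ctl].mean(axis=0)
            cen_psy = features_full[kept_psy].mean(axis=0)

        out_idx = np.concatenate([out_ctl, out_psy])
        if subsample:
            feats = np.array([
                _subsampled_feature(caches[i], n_sub, rng_trial, config.max_resample_attempts)
                for i in out_idx
            ])
        else:
            feats = pool_features[out_idx]
        dc = np.linalg.norm(feats - cen_ctl, axis=1)
        dp = np.linalg.norm(feats - cen_psy, axis=1)
        pred_psy = dp < dc
        tie = dp == dc
        if tie.any():
            pred_psy[tie] = tie_label == "psychosis"
        true_psy = labels[out_idx] == "psychosis"
        correct = pred_psy == true_psy
        acc[it] = correct.mean()
        sens[it] = correct[true_psy].mean()
        spec[it] = correct[~true_psy].mean()
        left_out_count[out_idx] += 1
        psy_classified[out_idx] += pred_psy

    with np.errstate(invalid="ignore"):
        freq = np.divide(psy_classified, left_out_count, out=np.full(n, np.nan), where=left_out_count > 0)
    per_part = pd.DataFrame(
        {
            "participant_id": [c.pid for c in caches],
            "group": groups,
            "n_left_out": left_out_count.astype(int),
            "frac_classified_psychosis": freq,
        }
    )
    return ClassifierResult(acc, sens, spec, per_part, config)


def run_classifier(dataset: StudyDataset, config: ClassifierConfig) -> ClassifierResult:
    """Leave-p-out nearest-centroid classification (see module docstring)."""
    return _run(dataset, config, permute_labels=False)


def permutation_null(dataset: StudyDataset, config: ClassifierConfig) -> ClassifierResult:
    """Chance reference: group labels permuted (sizes preserved) each
    iteration before centroid computation and scoring."""
    return _run(dataset, config, permute_labels=True)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_x - ECDF_y| with
    the asymptotic two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(x, y, mode="asymp")
    return float(res.statistic), float(res.pvalue)


def robustness_grid(
    dataset: StudyDataset,
    n_trials_grid=(240, 120, 48, 24),
    leave_out_grid=(0.2, 0.5, 0.8),
    trial_pool: str = "whole_experiment",
    n_iterations: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean accuracy over a (trials sampled x leave-out fraction) grid.

    All cells share the same seed, hence the same participant-sampling
    stream, so cells differ only in the classifier configuration.  In the
    first-block pool, trial counts above 48 are capped at 48.
    """
    rows = []
    for frac in leave_out_grid:
        for n_tr in n_trials_grid:
            n_eff = min(int(n_tr), 48) if trial_pool == "first_block" else int(n_tr)
            cfg = ClassifierConfig(
                leave_out_fraction=frac,
                n_iterations=n_iterations,
                n_trials_sampled=n_eff,
                trial_pool=trial_pool,
                seed=seed,
            )
            res = run_classifier(dataset, cfg)
            rows.append(
                {
                    "leave_out_fraction": frac,
                    "n_trials_sampled": int(n_tr),
                    "trial_pool": trial_pool,
                    "mean_accuracy": res.mean_accuracy,
                }
            )
    return pd.DataFrame(rows)
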