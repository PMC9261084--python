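"""Metacognition of agency: Goodman-Kruskal gamma between confidence and accuracy.

Gamma is a rank correlation over trial pairs: a pair is concordant when the
trial with the higher confidence is the correct one, discordant when it is
the incorrect one; pairs tied on either variable are excluded.
gamma = (C - D) / (C + D) in [-1, 1], with 0 meaning confidence carries no
information about accuracy.  It is the type-2 (metacognitive) measure used
when first-order performance is not equated across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import label_accuracy
from .sdt import GroupTestResult, group_compare


class UndefinedGammaError(ValueError):
    """No untied pairs (constant accuracy or constant confidence)."""

    def __init__(self, cause: str):
        self.cause = cause
        super().__init__(f"gamma undefined: {cause}")


@dataclass
class GammaResult:
    participant_id: str | None
    gamma: float
    n_concordant: int
    n_discordant: int

    @property
    def n_pairs_used(self) -> int:
        return self.n_concordant + self.n_discordant


def goodman_kruskal_gamma(confidence, accuracy, participant_id=None) -> GammaResult:
    """Gamma between confidence ratings and binary accuracy.

    With binary accuracy, concordant pairs are (incorrect, correct) pairs in
    which the correct trial has the strictly higher confidence; counting is
    done group-wise in O(n log n) via sorted ranks rather than explicit pair
    enumeration.
    """
    conf = np.asarray(confidence, dtype=float)
    acc = np.asarray(accuracy, dtype=bool)
    if conf.shape != acc.shape or conf.ndim != 1:
        raise ValueError("confidence and accuracy must be equal-length 1-D vectors")
    if len(conf) < 2:
        raise ValueError("need at least 2 trials")
    if np.isnan(conf).any():
        raise ValueError("confidence contains NaN; drop those trials first")
    c1 = np.sort(conf[acc])
    c0 = np.sort(conf[~acc])
    if len(c1) == 0 or len(c0) == 0:
        raise UndefinedGammaError("accuracy is constant")
    # for each correct-trial confidence, count incorrect trials strictly below/above
    below = np.searchsorted(c0, c1, side="left")
    above = len(c0) - np.searchsorted(c0, c1, side="right")
    C = int(below.sum())
    D = int(above.sum())
    if C + D == 0:
        raise UndefinedGammaError("confidence is constant across accuracy classes")
    return GammaResult(participant_id, (C - D) / (C + D), C, D)


def gamma_or_nan(confidence, accuracy) -> float:
    """Gamma, or NaN when undefined — convenience for per-participant tables."""
    try:
        return goodman_kruskal_gamma(confidence, accuracy).gamma
    except (UndefinedGammaError, ValueError):
        return float("nan")


def gamma_table(dataset, by_aspect: bool = False) -> pd.DataFrame:
    """Per-participant gamma on retained trials with confidence present.

    Trials from both aspects and all magnitudes, including unaltered trials,
    are pooled per participant.  With ``by_aspect=True``, adds per-aspect
    columns in which each aspect's altered trials are pooled with the shared
    unaltered pool.
    """
    trials = dataset.retained()
    trials = trials[trials["confidence"].notna()]
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        acc = label_accuracy(sub).to_numpy()
        conf = sub["confidence"].to_numpy(float)
        row = {
            "participant_id": pid,
            "group": sub["group"].iloc[0],
            "gamma": gamma_or_nan(conf, acc),
            "n_trials": len(sub),
        }
        if by_aspect:
            for aspect in ("temporal", "spatial"):
                m = (sub["aspect"] == aspect) | (sub["aspect"] == "none")
                row[f"gamma_{aspect}"] = gamma_or_nan(conf[m.to_numpy()], acc[m.to_numpy()])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class OneSampleResult:
    t: float
    df: float
    p: float
    cohens_d: float
    mean: float
    n: int


def one_sample_test(values) -> OneSampleResult:
    """One-sample Student's t of a vector against zero, with Cohen's d."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 finite values")
    res = stats.ttest_1samp(v, 0.0)
    sd = v.std(ddof=1)
    d = float(v.mean() / sd) if sd > 0 else float("inf")
    return OneSampleResult(float(res.statistic), float(len(v) - 1), float(res.pvalue), d, float(v.mean()), len(v))


def gamma_group_tests(gammas_control, gammas_psychosis) -> dict:
    """Between-group Welch t plus per-group one-sample t of gamma vs zero.

    Participants with undefined (NaN) gamma are dropped with a warning from
    the caller; here NaNs are silently excluded.
    """
    gc = np.asarray(gammas_control, dtype=float)
    gp = np.asarray(gammas_psychosis, dtype=float)
    gc, gp = gc[np.isfinite(gc)], gp[np.isfinite(gp)]
    between: GroupTestResult = group_compare(gc, gp)
    return {
        "between": between,
        "control_vs_zero": one_sample_test(gc),
        "psychosis_vs_zero": one_sample_test(gp),
    }
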