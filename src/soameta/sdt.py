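"""Signal-detection analysis of agency judgments.

The unaltered (veridical) trial is the signal: a hit is answering
"identical" on an unaltered trial, a false alarm is answering "identical"
on an altered trial, pooled across both aspects and all alteration
magnitudes.  Under this convention a NEGATIVE criterion c means a bias
toward self-attribution, so patients' stronger over-attribution shows up as
a more negative c.

Extreme rates are corrected with the log-linear rule
rate = (count + 0.5) / (n + 1), applied uniformly to every participant to
avoid conditional bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import StudyDataset


@dataclass
class SDTResult:
    participant_id: str | None
    n_signal: int
    n_noise: int
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float


@dataclass
class GroupTestResult:
    """Welch's unequal-variance t-test with pooled-SD Cohen's d."""

    t: float
    df: float
    p: float
    cohens_d: float
    group_means: tuple[float, float]
    group_ns: tuple[int, int]


def compute_rates(trials: pd.DataFrame) -> tuple[float, float, int, int]:
    """Log-linear corrected hit and false-alarm rates for one participant.

    Pools all altered magnitudes and both aspects ("across magnitudes of
    alteration").  Requires at least one unaltered and one altered trial
    with a recorded response.
    """
    resp = trials["response_identical"]
    if resp.isna().any():
        raise ValueError("trials with missing responses must be excluded before SDT")
    altered = trials["altered"].to_numpy(bool)
    identical = resp.to_numpy(bool)
    n_signal = int((~altered).sum())
    n_noise = int(altered.sum())
    if n_signal == 0 or n_noise == 0:
        raise ValueError("participant needs >=1 unaltered and >=1 altered trial")
    hits = int((identical & ~altered).sum())
    fas = int((identical & altered).sum())
    H = (hits + 0.5) / (n_signal + 1)
    FA = (fas + 0.5) / (n_noise + 1)
    return H, FA, n_signal, n_noise


def dprime_criterion(H: float, FA: float) -> tuple[float, float]:
    """Equal-variance d' and criterion c from corrected rates.

    d' = z(H) - z(FA);  c = -(z(H) + z(FA)) / 2, z the standard-normal
    quantile.  Rates must lie strictly inside (0, 1) — apply the log-linear
    correction first.
    """
    if not (0 < H < 1 and 0 < FA < 1):
        raise ValueError("H and FA must be strictly inside (0,1); apply rate correction first")
    zH, zFA = stats.norm.ppf(H), stats.norm.ppf(FA)
    return float(zH - zFA), float(-(zH + zFA) / 2)


def sdt_result(trials: pd.DataFrame, participant_id=None) -> SDTResult:
    H, FA, n_signal, n_noise = compute_rates(trials)
    d, c = dprime_criterion(H, FA)
    return SDTResult(participant_id, n_signal, n_noise, H, FA, d, c)


def sdt_table(dataset: StudyDataset, by_aspect: bool = False) -> pd.DataFrame:
    """Per-participant SDT measures on retained trials.

    The headline statistic pools both aspects; ``by_aspect=True`` adds
    optional per-aspect d' columns (each aspect's altered trials against the
    shared unaltered pool).
    """
    rows = []
    for pid, sub in dataset.retained().groupby("participant_id", sort=True):
        res = sdt_result(sub, pid)
        row = {
            "participant_id": pid,
            "group": sub["group"].iloc[0],
            "n_signal": res.n_signal,
            "n_noise": res.n_noise,
            "hit_rate": res.hit_rate,
            "fa_rate": res.fa_rate,
            "d_prime": res.d_prime,
            "criterion_c": res.criterion_c,
        }
        if by_aspect:
            for aspect in ("temporal", "spatial"):
                m = (sub["aspect"] == aspect) | (sub["aspect"] == "none")
                r = sdt_result(sub[m])
                row[f"d_prime_{aspect}"] = r.d_prime
                row[f"criterion_c_{aspect}"] = r.criterion_c
        rows.append(row)
    return pd.DataFrame(rows)


def group_compare(values_control, values_psychosis) -> GroupTestResult:
    """Welch's t-test (control vs psychosis) with pooled-SD Cohen's d.

    Positive t means the control mean is larger.  Degrees of freedom use the
    Welch-Satterthwaite approximation; Cohen's d divides the mean difference
    by the pooled standard deviation.
    """
    a = np.asarray(values_control, dtype=float)
    b = np.asarray(values_psychosis, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical constant samples: no effect by definition
            return GroupTestResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0,
                                   (float(a.mean()), float(b.mean())), (len(a), len(b)))
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    sp = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    d = float((a.mean() - b.mean()) / sp) if sp > 0 else float("inf")
    return GroupTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        cohens_d=d,
        group_means=(float(a.mean()), float(b.mean())),
        group_ns=(len(a), len(b)),
    )
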