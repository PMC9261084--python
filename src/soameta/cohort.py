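"""Synthetic cohort generator for the virtual-hand agency paradigm.

Emulates the study design — 2 groups x 30 participants, 240 trials each over
5 blocks (60 unaltered, 30 per alteration magnitude per aspect) — and an
equal-variance Gaussian signal-detection observer:

* latent evidence on a trial at magnitude level L is x ~ Normal(delta_L, 1)
  with delta_0 = 0 for unaltered trials;
* the participant answers "identical" (self-attributes) when x < kappa,
  their decision criterion;
* confidence is a gain g times the evidence margin |x - kappa| plus an
  offset b and Gaussian metacognitive noise with SD sigma_meta, clipped to
  the [-3, 3] slider.

Between-participant heterogeneity enters through Gaussian draws of kappa, a
shared additive shift of the per-level discriminability increments, and a
truncated-Gaussian draw of sigma_meta.  sigma_meta alone spans the continuum
from confidence tightly coupled to evidence quality (healthy controls) to
fully decoupled confidence (psychosis).  Trial missingness is injected
uniformly at a group-specific rate with exclusion reasons sampled from the
pre-registered removal categories.

Default parameters ship in ``config/default_params.yaml``, produced by
``scripts/calibrate.py`` against the published group statistics
(d' = 1.8 / 0.76, c = -0.43 / -0.73, gamma = 0.26 / -0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    MAGNITUDE_VALUES,
    StudyDataset,
    TRIAL_COLUMNS,
    label_accuracy,
)
from .metacog import gamma_or_nan

N_TRIALS = 240
N_BLOCKS = 5
N_PER_CELL = 30  # trials per (aspect x altered level)
N_UNALTERED = 60  # 25%

EXCLUSION_CHOICES = ("no_movement", "camera_malfunction", "no_response")


@dataclass
class GroupParams:
    """Generative parameters for one group.

    delta_mean: per-level mean discriminability increments (3 values,
        non-decreasing, standardized evidence units), per aspect.
    delta_sd: SD of the participant-level additive shift applied to all
        increments (clipped at zero, preserving the ordering).
    kappa_mean / kappa_sd: decision criterion distribution (evidence units).
    sigma_meta_mean / sigma_meta_sd: metacognitive noise distribution
        (truncated at zero).
    confidence_gain / confidence_offset: map from evidence margin to the
        [-3, 3] slider.
    missing_rate: per-trial probability of a pre-registered exclusion.
    n_participants: cohort size for the group.
    """

    delta_mean: dict = field(
        default_factory=lambda: {"temporal": [0.5, 1.0, 1.5], "spatial": [0.5, 1.0, 1.5]}
    )
    delta_sd: float = 0.3
    kappa_mean: float = 1.2
    kappa_sd: float = 0.3
    sigma_meta_mean: float = 1.0
    sigma_meta_sd: float = 0.3
    confidence_gain: float = 1.0
    confidence_offset: float = 0.0
    missing_rate: float = 0.02
    n_participants: int = 30

    def __post_init__(self):
        for aspect, deltas in self.delta_mean.items():
            d = np.asarray(deltas, dtype=float)
            if len(d) != 3 or np.any(np.diff(d) < 0):
                raise ValueError(f"delta_mean[{aspect}] must be 3 non-decreasing values")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("delta_sd", "kappa_sd", "sigma_meta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.confidence_gain <= 0:
            raise ValueError("confidence_gain must be > 0")


@dataclass
class GenerativeParams:
    """Cohort-level generative model: one :class:`GroupParams` per group plus
    the clinical-coupling parameters and clinical-score marginals."""

    control: GroupParams = field(default_factory=GroupParams)
    psychosis: GroupParams = field(default_factory=GroupParams)
    #: correlation between realized per-participant gamma and PANSS Positive
    panss_positive_gamma_coupling: float = 0.0
    clinical_marginals: dict = field(
        default_factory=lambda: {
            "panss_positive": [15.1, 3.2],
            "panss_negative": [15.2, 5.2],
            "panss_general": [32.5, 7.0],
            "spqb_cogper": [2.5, 1.8],
            "spqb_inter": [2.8, 2.0],
            "spqb_disorg": [1.7, 1.5],
        }
    )

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        d = dict(d)
        groups = {g: GroupParams(**d.pop(g)) for g in ("control", "psychosis") if g in d}
        return cls(**groups, **d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_params() -> GenerativeParams:
    """The calibrated defaults shipped with the package."""
    text = resources.files("soameta.config").joinpath("default_params.yaml").read_text()
    return GenerativeParams.from_dict(yaml.safe_load(text))


def generate_design(seed) -> pd.DataFrame:
    """One participant's trial skeleton: 240 trials in random order.

    30 trials per (aspect x magnitude level 1-3) = 180 altered plus 60
    unaltered, split into 5 blocks of 48.  Conditions are balanced across
    blocks (each block holds 6 trials of every altered cell and 12
    unaltered trials) and presented in uniformly random order within each
    block, so every condition is represented from the first block onward.
    Response and confidence fields are empty.
    """
    rng = np.random.default_rng(seed)
    per_block_cell = N_PER_CELL // N_BLOCKS
    per_block_unalt = N_UNALTERED // N_BLOCKS
    aspects_list: list = []
    levels_list: list = []
    for _ in range(N_BLOCKS):
        a = ["none"] * per_block_unalt
        l = [0] * per_block_unalt
        for aspect in ("temporal", "spatial"):
            for level in (1, 2, 3):
                a += [aspect] * per_block_cell
                l += [level] * per_block_cell
        order = rng.permutation(len(a))
        aspects_list += [a[i] for i in order]
        levels_list += [l[i] for i in order]
    aspects = np.asarray(aspects_list, dtype=object)
    levels = np.asarray(levels_list)
    values = np.array(
        [MAGNITUDE_VALUES[a][l] if l > 0 else 0.0 for a, l in zip(aspects, levels)]
    )
    trial_index = np.arange(1, N_TRIALS + 1)
    return pd.DataFrame(
        {
            "block": (trial_index - 1) // (N_TRIALS // N_BLOCKS) + 1,
            "trial_index": trial_index,
            "aspect": aspects,
            "magnitude_level": levels,
            "magnitude_value": values,
        }
    )


@dataclass
class ParticipantParams:
    """One participant's realized generative parameters."""

    delta: dict  # aspect -> 3 increments
    kappa: float
    sigma_meta: float
    gain: float
    offset: float


def draw_participant(group_params: GroupParams, rng: np.random.Generator) -> ParticipantParams:
    shift = rng.normal(0.0, group_params.delta_sd)
    delta = {
        aspect: np.maximum(np.asarray(d, dtype=float) + shift, 0.0)
        for aspect, d in group_params.delta_mean.items()
    }
    kappa = rng.normal(group_params.kappa_mean, group_params.kappa_sd)
    # truncate metacognitive noise at zero
    sigma = -1.0
    while sigma < 0:
        sigma = rng.normal(group_params.sigma_meta_mean, group_params.sigma_meta_sd)
    return ParticipantParams(
        delta=delta,
        kappa=kappa,
        sigma_meta=sigma,
        gain=group_params.confidence_gain,
        offset=group_params.confidence_offset,
    )


def simulate_responses(
    design: pd.DataFrame, params: ParticipantParams, seed
) -> pd.DataFrame:
    """Simulate the observer on a design skeleton.

    Evidence x ~ Normal(delta_level, 1); "identical" iff x < kappa;
    confidence = clip(gain * |x - kappa| + offset + eps, -3, 3) with
    eps ~ Normal(0, sigma_meta).  Bit-reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    levels = design["magnitude_level"].to_numpy()
    aspects = design["aspect"].to_numpy()
    delta = np.zeros(len(design))
    for aspect, incs in params.delta.items():
        for lvl in (1, 2, 3):
            delta[(aspects == aspect) & (levels == lvl)] = incs[lvl - 1]
    x = rng.normal(delta, 1.0)
    response = x < params.kappa
    eps = rng.normal(0.0, params.sigma_meta, size=len(design))
    confidence = np.clip(params.gain * np.abs(x - params.kappa) + params.offset + eps, -3.0, 3.0)
    out = design.copy()
    out["response_identical"] = response.astype(object)
    out["confidence"] = confidence
    out["altered"] = out["magnitude_level"] > 0
    return out


def _inject_missingness(trials: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    miss = rng.random(len(trials)) < rate
    reasons = np.asarray(EXCLUSION_CHOICES, dtype=object)[rng.integers(0, len(EXCLUSION_CHOICES), len(trials))]
    out = trials.copy()
    out["excluded"] = miss
    out["exclusion_reason"] = np.where(miss, reasons, "none")
    out.loc[miss, "response_identical"] = np.nan
    out.loc[miss, "confidence"] = np.nan
    return out


def _truncnorm_at_zero(mean, sd, size, rng):
    vals = rng.normal(mean, sd, size)
    while True:
        neg = vals < 0
        if not neg.any():
            return vals
        vals[neg] = rng.normal(mean, sd, int(neg.sum()))


def build_cohort(params: GenerativeParams | None = None, seed=0) -> StudyDataset:
    """Simulate a full two-group cohort as a validated :class:`StudyDataset`.

    Clinical scores use truncated-normal marginals; PANSS Positive is coupled
    to the participant's realized confidence-accuracy gamma (computed on the
    retained trials) with correlation ``panss_positive_gamma_coupling``, so
    the generative correlation target is exact.  Identical seeds give
    bit-identical datasets.
    """
    if params is None:
        params = default_params()
    root = np.random.default_rng(np.random.SeedSequence(seed))
    frames = []
    part_rows = []
    gammas: dict[str, list] = {"control": [], "psychosis": []}
    gamma_pids: dict[str, list] = {"control": [], "psychosis": []}
    for group in ("control", "psychosis"):
        gp: GroupParams = getattr(params, group)
        for i in range(gp.n_participants):
            pid = f"{'C' if group == 'control' else 'P'}{i + 1:02d}"
            pr = draw_participant(gp, root)
            design = generate_design(root.integers(2**31))
            trials = simulate_responses(design, pr, root.integers(2**31))
            trials = _inject_missingness(trials, gp.missing_rate, root)
            trials.insert(0, "participant_id", pid)
            trials.insert(1, "group", group)
            frames.append(trials)
            kept = trials[~trials["excluded"]]
            acc = label_accuracy(kept)
            gammas[group].append(gamma_or_nan(kept["confidence"].to_numpy(float), acc.to_numpy()))
            gamma_pids[group].append(pid)
            part_rows.append({"participant_id": pid, "group": group})

    participants = pd.DataFrame(part_rows)
    marg = params.clinical_marginals
    for col in ("panss_positive", "panss_negative", "panss_general",
                "spqb_cogper", "spqb_inter", "spqb_disorg"):
        participants[col] = np.nan
    is_psy = participants["group"] == "psychosis"
    n_psy, n_ctl = int(is_psy.sum()), int((~is_psy).sum())

    # PANSS Positive: linear in realized standardized gamma + noise
    rho = params.panss_positive_gamma_coupling
    g_psy = np.asarray(gammas["psychosis"], dtype=float)
    z = np.zeros(n_psy)
    ok = np.isfinite(g_psy)
    if ok.sum() >= 2 and np.std(g_psy[ok]) > 0:
        z[ok] = (g_psy[ok] - g_psy[ok].mean()) / g_psy[ok].std()
    mean, sd = marg["panss_positive"]
    noise = root.normal(0.0, 1.0, n_psy)
    participants.loc[is_psy, "panss_positive"] = np.maximum(
        mean + sd * (rho * z + np.sqrt(max(1 - rho**2, 0.0)) * noise), 0.0
    )
    for col in ("panss_negative", "panss_general"):
        m, s = marg[col]
        participants.loc[is_psy, col] = _truncnorm_at_zero(m, s, n_psy, root)
    participants["panss_total"] = (
        participants["panss_positive"] + participants["panss_negative"] + participants["panss_general"]
    )
    for col in ("spqb_cogper", "spqb_inter", "spqb_disorg"):
        m, s = marg[col]
        participants.loc[~is_psy, col] = _truncnorm_at_zero(m, s, n_ctl, root)
    participants["spqb_total"] = (
        participants["spqb_cogper"] + participants["spqb_inter"] + participants["spqb_disorg"]
    )

    from .datamodel import PARTICIPANT_COLUMNS

    participants = participants[PARTICIPANT_COLUMNS]
    trials = pd.concat(frames, ignore_index=True)
    trials["altered"] = trials["magnitude_level"] > 0
    trials = trials[TRIAL_COLUMNS + ["altered"]]
    return StudyDataset(
        trials=trials,
        participants=participants,
        provenance={"generator": "soameta.cohort.build_cohort", "seed": int(seed)},
    )
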