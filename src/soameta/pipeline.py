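"""One-command orchestration of the full analysis.

simulate (or ingest) -> pre-registered exclusions -> per-participant signal
detection -> metacognition (gamma) -> slope classifier (+ permutation null,
+ robustness grid) -> mixed-model ladders -> clinical correlations ->
summary report.  Every stage writes its artifact under the output
directory; a manifest records seeds, config and package version so an
identical config + seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    StudyDataset,
    apply_exclusions,
    exclude_participants,
    read_trials,
    write_trials,
)
from .cohort import GenerativeParams, build_cohort, default_params
from .sdt import group_compare, sdt_table
from .metacog import gamma_group_tests, gamma_table
from .classifier import (
    ClassifierConfig,
    ks_two_sample,
    permutation_null,
    robustness_grid,
    run_classifier,
)
from .mixed import fit_confidence_ladder, fit_soa_ladder
from .correlations import clinical_correlations

log = logging.getLogger("soameta")

#: published group statistics for this paradigm, used only to flag
#: calibration checks in the summary report
REFERENCE_STATISTICS = {
    "d_prime": {"control": 1.8, "psychosis": 0.76, "tolerance": 0.15},
    "gamma": {"control": 0.26, "psychosis": 0.0, "tolerance": 0.08},
    "criterion_c": {"control": -0.43, "psychosis": -0.73, "tolerance": 0.15},
    "classifier_accuracy_band": (0.80, 0.95),
    "null_accuracy_band": (0.47, 0.53),
}


@dataclass
class PipelineConfig:
    """Master configuration; the master seed deterministically derives all
    stage seeds."""

    mode: str = "simulate"  # or "ingest"
    trials_path: str | None = None
    participants_path: str | None = None
    generative_params: GenerativeParams | None = None
    classifier: ClassifierConfig = field(
        default_factory=lambda: ClassifierConfig(n_iterations=2000)
    )
    exclude_participants: list = field(default_factory=list)
    run_models: bool = True
    run_grid: bool = False
    grid_iterations: int = 400
    out_dir: str = "soameta_out"
    seed: int = 0


def _stage_seeds(master: int) -> dict:
    children = np.random.SeedSequence(master).spawn(4)
    names = ("cohort", "classifier", "null", "grid")
    return {k: int(s.generate_state(1)[0] % 2**31) for k, s in zip(names, children)}


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def participant_summary(dataset: StudyDataset) -> pd.DataFrame:
    """Merged per-participant table: SDT measures, gamma, clinical scores."""
    sdt = sdt_table(dataset)
    gam = gamma_table(dataset)[["participant_id", "gamma"]]
    return sdt.merge(gam, on="participant_id", how="left").merge(
        dataset.participants, on=["participant_id"] , how="left", suffixes=("", "_part")
    ).drop(columns=["group_part"], errors="ignore")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the summary dict (also written to
    ``summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "stage_seeds": seeds}

    stage = "input"
    try:
        if config.mode == "simulate":
            params = config.generative_params or default_params()
            dataset = build_cohort(params, seed=seeds["cohort"])
        else:
            if not config.trials_path:
                raise ValueError("ingest mode needs trials_path")
            dataset = read_trials(config.trials_path, config.participants_path)
        if config.exclude_participants:
            dataset = exclude_participants(dataset, config.exclude_participants)
        write_trials(dataset, out / "trials.csv", out / "participants.csv")

        stage = "preprocess"
        dataset, report = apply_exclusions(dataset)
        (out / "exclusion_report.json").write_text(json.dumps(report, indent=2))
        summary["exclusions"] = report

        stage = "sdt"
        sdt = sdt_table(dataset, by_aspect=True)
        sdt.to_csv(out / "sdt.csv", index=False)
        ctl = sdt[sdt["group"] == "control"]
        psy = sdt[sdt["group"] == "psychosis"]
        sdt_tests = {
            "d_prime": _to_jsonable(group_compare(ctl["d_prime"], psy["d_prime"])),
            "criterion_c": _to_jsonable(group_compare(ctl["criterion_c"], psy["criterion_c"])),
        }
        (out / "sdt_group_tests.json").write_text(json.dumps(sdt_tests, indent=2))
        summary["sdt"] = {
            "control_mean_d_prime": float(ctl["d_prime"].mean()),
            "psychosis_mean_d_prime": float(psy["d_prime"].mean()),
            "control_mean_criterion": float(ctl["criterion_c"].mean()),
            "psychosis_mean_criterion": float(psy["criterion_c"].mean()),
            "tests": sdt_tests,
        }

        stage = "metacog"
        gam = gamma_table(dataset, by_aspect=True)
        gam.to_csv(out / "gamma.csv", index=False)
        n_undef = int(gam["gamma"].isna().sum())
        if n_undef:
            log.warning("%d participant(s) with undefined gamma excluded from group tests", n_undef)
        gtests = gamma_group_tests(
            gam.loc[gam["group"] == "control", "gamma"],
            gam.loc[gam["group"] == "psychosis", "gamma"],
        )
        (out / "gamma_tests.json").write_text(json.dumps(_to_jsonable(gtests), indent=2))
        summary["metacognition"] = {
            "control_mean_gamma": float(gam.loc[gam["group"] == "control", "gamma"].mean()),
            "psychosis_mean_gamma": float(gam.loc[gam["group"] == "psychosis", "gamma"].mean()),
            "n_undefined": n_undef,
            "tests": _to_jsonable(gtests),
        }

        stage = "classifier"
        cfg = dataclasses.replace(config.classifier, seed=seeds["classifier"])
        result = run_classifier(dataset, cfg)
        null_cfg = dataclasses.replace(cfg, seed=seeds["null"])
        null = permutation_null(dataset, null_cfg)
        D, ks_p = ks_two_sample(result.accuracy, null.accuracy)
        pd.DataFrame(
            {
                "iteration": np.arange(len(result.accuracy)),
                "accuracy": result.accuracy,
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
                "null_accuracy": null.accuracy,
            }
        ).to_csv(out / "classifier_iterations.csv", index=False)
        clf_summary = {
            **result.summary(),
            "null_mean_accuracy": null.mean_accuracy,
            "ks_D": D,
            "ks_p": ks_p,
        }
        (out / "classifier.json").write_text(json.dumps(_to_jsonable(clf_summary), indent=2))
        summary["classifier"] = clf_summary

        if config.run_grid:
            stage = "grid"
            grids = []
            for pool in ("whole_experiment", "first_block"):
                grids.append(
                    robustness_grid(
                        dataset, trial_pool=pool, n_iterations=config.grid_iterations,
                        seed=seeds["grid"],
                    )
                )
            grid = pd.concat(grids, ignore_index=True)
            grid.to_csv(out / "robustness_grid.csv", index=False)
            summary["grid"] = grid.to_dict(orient="records")

        if config.run_models:
            stage = "models"
            soa = fit_soa_ladder(dataset)
            conf = fit_confidence_ladder(dataset)
            for name, comp in (("soa", soa), ("confidence", conf)):
                (out / f"models_{name}.json").write_text(
                    json.dumps(
                        {
                            "winner": comp.winner,
                            "table": comp.table.to_dict(orient="records"),
                            "coefficients": comp.coefficients.to_dict(orient="records"),
                            "metadata": comp.metadata,
                        },
                        indent=2,
                    )
                )
                comp.coefficients.to_csv(out / f"coefficients_{name}.csv", index=False)
            summary["models"] = {
                "soa_winner": soa.winner,
                "confidence_winner": conf.winner,
            }

        stage = "correlations"
        summaries = participant_summary(dataset)
        summaries.to_csv(out / "participant_summary.csv", index=False)
        corr = clinical_correlations(summaries)
        corr.to_csv(out / "correlations.csv", index=False)
        summary["correlations"] = corr.to_dict(orient="records")

        stage = "report"
        summary["calibration_checks"] = _calibration_checks(summary)
        manifest = {
            "soameta_version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "mode": config.mode,
            "classifier_config": _to_jsonable(config.classifier),
            "config_hash": hashlib.sha256(
                json.dumps(_to_jsonable(dataclasses.asdict(config)), sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "summary.json").write_text(json.dumps(_to_jsonable(summary), indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return summary


def _calibration_checks(summary: dict) -> dict:
    """PASS/FAIL flags of the obtained statistics against the published
    reference values (only meaningful for the calibrated simulate mode)."""
    ref = REFERENCE_STATISTICS
    checks = {}
    sdt = summary.get("sdt", {})
    checks["d_prime_control"] = _band(sdt.get("control_mean_d_prime"),
                                      ref["d_prime"]["control"], ref["d_prime"]["tolerance"])
    checks["d_prime_psychosis"] = _band(sdt.get("psychosis_mean_d_prime"),
                                        ref["d_prime"]["psychosis"], ref["d_prime"]["tolerance"])
    meta = summary.get("metacognition", {})
    checks["gamma_control"] = _band(meta.get("control_mean_gamma"),
                                    ref["gamma"]["control"], ref["gamma"]["tolerance"])
    checks["gamma_psychosis"] = _band(meta.get("psychosis_mean_gamma"),
                                      ref["gamma"]["psychosis"], ref["gamma"]["tolerance"])
    clf = summary.get("classifier", {})
    lo, hi = ref["classifier_accuracy_band"]
    acc = clf.get("mean_accuracy")
    checks["classifier_accuracy"] = "PASS" if acc is not None and lo <= acc <= hi else "FAIL"
    lo, hi = ref["null_accuracy_band"]
    nacc = clf.get("null_mean_accuracy")
    checks["null_accuracy"] = "PASS" if nacc is not None and lo <= nacc <= hi else "FAIL"
    return checks


def _band(value, center, tol) -> str:
    return "PASS" if value is not None and abs(value - center) <= tol else "FAIL"
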