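"""End-to-end analysis pipeline: simulate/load -> validate -> fit -> metacognition.

One seeded run executes the full analysis sequence on either a synthetic
dataset or user-supplied CSV tables and produces a report mirroring the
study's result tables:

1. design-balance report;
2. implicit accuracy GLMM (validity x congruency) plus post hoc fits split
   by congruency;
3. explicit accuracy GLMM (congruency);
4. two-stage transfer of per-subject implicit interaction coefficients
   into the explicit model, and the paired t test comparing implicit
   interaction vs explicit congruency individual coefficients;
5. AQ models: explicit congruency x AQ, implicit three-way with AQ, and
   the exploratory median-split AQ-group model;
6. confidence LMMs (accuracy x AQ) per task on z-scored confidence;
7. Type-2 ROC metacognition: per-subject AUROC2, Mahalanobis screening,
   Spearman correlations with AQ, median-split comparison.

Implicit accuracy/confidence analyses use object-present trials only and
continuous predictors are z-scored.  Every random draw derives from the
single run seed; reports are written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glmm import (ModelSpec, compare_coefficients_ttest,
                   extract_subject_effects, fit_linear_lmm,
                   fit_logistic_glmm, two_stage_transfer)
from .metacognition import analyze_metacognition
from .synthetic import GeneratorConfig, generate_dataset
from .trialdata import (assign_aq_group, filter_present_trials, load_subjects,
                        load_trials, validate_design)

__all__ = ["RunConfig", "run_pipeline", "render_tables"]

log = logging.getLogger("gazemeta")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` selects the input source: ``synthetic`` draws a dataset from
    ``generator`` (seeded by ``seed``); ``files`` reads the trial/subject
    CSV tables.  Exactly one mode is active.  ``alpha`` is the two-sided
    significance threshold recorded in the report; ``mahalanobis_alpha``
    the outlier-screening quantile.
    """

    mode: str = "synthetic"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    trials_path: str | None = None
    subjects_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    alpha: float = 0.05
    mahalanobis_alpha: float = 0.025

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown input mode {self.mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.get("generator", {})
        if not isinstance(gen, GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(gen)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# model specifications mirroring the reported analyses
_INTERACTION = "gaze_validity:body_head_congruency"

SPEC_IMPLICIT = ModelSpec(
    response="correct",
    fixed=["gaze_validity", "body_head_congruency", _INTERACTION],
    random=["1", "gaze_validity", "body_head_congruency", _INTERACTION],
    family="binomial")
SPEC_IMPLICIT_SPLIT = ModelSpec(
    response="correct", fixed=["gaze_validity"],
    random=["1", "gaze_validity"], family="binomial")
SPEC_EXPLICIT = ModelSpec(
    response="correct", fixed=["body_head_congruency"],
    random=["1", "body_head_congruency"], family="binomial")
SPEC_EXPLICIT_AQ = ModelSpec(
    response="correct",
    fixed=["body_head_congruency", "aq_score", "body_head_congruency:aq_score"],
    random=["1", "body_head_congruency"], family="binomial",
    standardize=["aq_score"])
SPEC_IMPLICIT_AQ = ModelSpec(
    response="correct",
    fixed=["gaze_validity", "body_head_congruency", "aq_score",
           _INTERACTION, "gaze_validity:aq_score",
           "body_head_congruency:aq_score",
           "gaze_validity:body_head_congruency:aq_score"],
    random=["1", "gaze_validity", "body_head_congruency", _INTERACTION],
    family="binomial", standardize=["aq_score"])
SPEC_AQ_GROUP = ModelSpec(
    response="correct",
    fixed=["gaze_validity", "body_head_congruency", "aq_group",
           _INTERACTION, "gaze_validity:aq_group",
           "body_head_congruency:aq_group",
           "gaze_validity:body_head_congruency:aq_group"],
    random=["1", "gaze_validity", "body_head_congruency", _INTERACTION],
    family="binomial")
SPEC_CONFIDENCE = ModelSpec(
    response="confidence",
    fixed=["correct", "aq_score", "correct:aq_score"],
    random=["1", "correct"], family="gaussian",
    standardize=["confidence", "aq_score"])


def _fit_table(name, fit):
    return {"name": name, "fit": fit}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage in order and return the run report.

    The report is a plain dict (JSON-serializable via
    :func:`render_tables`) whose keys are the analysis names; each model
    entry holds the :class:`~gazemeta.glmm.FitResult`.  A non-convergent
    model is flagged in its entry and the run continues; hard stage
    failures raise with a stage-tagged message.
    """
    t0 = time.time()
    report: dict = {
        "seed": int(config.seed),
        "alpha": config.alpha,
        "mahalanobis_alpha": config.mahalanobis_alpha,
        "software": {"gazemeta": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "coding": {
            "gaze_validity": "0=invalid, 1=valid",
            "body_head_congruency": "0=incongruent, 1=congruent",
            "aq_group": "0=low, 1=high (ties at median -> low)",
            "aq_score": "z-scored within sample",
            "confidence": "z-scored within task sample",
        },
    }

    def stage(name):
        log.info("stage: %s (t=%.1fs)", name, time.time() - t0)

    stage("input")
    if config.mode == "synthetic":
        gen = config.generator.with_seed(config.seed)
        subjects, trials = generate_dataset(gen)
        report["input"] = {"mode": "synthetic",
                           "generator": gen.to_dict()}
    else:
        if not config.trials_path or not config.subjects_path:
            raise ValueError(
                "stage input: file mode requires trials_path and "
                "subjects_path")
        trials = load_trials(config.trials_path)
        subjects = load_subjects(config.subjects_path)
        report["input"] = {"mode": "files",
                           "trials_path": str(config.trials_path),
                           "subjects_path": str(config.subjects_path)}
    subjects = assign_aq_group(subjects)
    if "aq_z" not in subjects.columns:
        sd = subjects["aq_score"].std(ddof=1)
        subjects["aq_z"] = (subjects["aq_score"]
                            - subjects["aq_score"].mean()) / sd
    report["n_subjects"] = int(len(subjects))
    report["aq"] = {
        "mean": float(subjects["aq_score"].mean()),
        "sd": float(subjects["aq_score"].std(ddof=1)),
        "min": int(subjects["aq_score"].min()),
        "max": int(subjects["aq_score"].max()),
        "median": float(subjects["aq_score"].median()),
    }

    stage("design validation")
    if config.mode == "synthetic":
        design = validate_design(
            trials,
            trials_per_implicit_cell=gen.trials_per_implicit_cell,
            trials_per_explicit_condition=gen.trials_per_explicit_condition)
    else:
        design = validate_design(trials)
    report["design"] = {"n_trials": design.n_trials,
                        "cell_counts": design.cell_counts,
                        "violations": design.violations}

    impl_all = trials[trials["task"] == "implicit"]
    expl = trials[trials["task"] == "explicit"].reset_index(drop=True)
    impl = filter_present_trials(impl_all).reset_index(drop=True)

    acc = impl["correct"].mean() * 100
    report["descriptives"] = {
        "implicit_present_accuracy_pct": float(acc),
        "implicit_absent_accuracy_pct": float(
            impl_all.loc[~impl_all["object_present"], "correct"].mean() * 100)
        if (~impl_all["object_present"]).any() else None,
        "implicit_overall_accuracy_pct": float(
            impl_all["correct"].mean() * 100),
        "explicit_accuracy_pct": float(expl["correct"].mean() * 100),
    }

    stage("implicit accuracy models")
    models: dict = {}
    fit_implicit = fit_logistic_glmm(impl, SPEC_IMPLICIT, subjects=subjects)
    models["implicit_accuracy"] = fit_implicit
    for level in ("congruent", "incongruent"):
        sub = impl[impl["body_head_congruency"] == level]
        models[f"implicit_accuracy_{level}"] = fit_logistic_glmm(
            sub, SPEC_IMPLICIT_SPLIT, subjects=subjects)

    stage("explicit accuracy models")
    fit_explicit = fit_logistic_glmm(expl, SPEC_EXPLICIT, subjects=subjects)
    models["explicit_accuracy"] = fit_explicit

    stage("two-stage transfer")
    models["transfer"] = two_stage_transfer(fit_implicit, expl,
                                            subjects=subjects)

    stage("coefficient comparison")
    impl_coefs = extract_subject_effects(fit_implicit, _INTERACTION)
    expl_coefs = extract_subject_effects(fit_explicit,
                                         "body_head_congruency")
    cmp_res = compare_coefficients_ttest(impl_coefs, expl_coefs)
    report["coefficient_comparison"] = dataclasses.asdict(cmp_res)

    stage("AQ models")
    models["explicit_accuracy_aq"] = fit_logistic_glmm(
        expl, SPEC_EXPLICIT_AQ, subjects=subjects)
    models["implicit_accuracy_aq"] = fit_logistic_glmm(
        impl, SPEC_IMPLICIT_AQ, subjects=subjects)
    models["implicit_accuracy_aq_group"] = fit_logistic_glmm(
        impl, SPEC_AQ_GROUP, subjects=subjects)

    stage("confidence models")
    models["confidence_implicit"] = fit_linear_lmm(
        impl, SPEC_CONFIDENCE, subjects=subjects)
    models["confidence_explicit"] = fit_linear_lmm(
        expl, SPEC_CONFIDENCE, subjects=subjects)
    report["models"] = models

    stage("metacognition")
    report["metacognition"] = {
        task: analyze_metacognition(
            trials, subjects, task,
            mahalanobis_alpha=config.mahalanobis_alpha)
        for task in ("implicit", "explicit")}

    report["elapsed_seconds"] = round(time.time() - t0, 2)
    stage("done")
    return report


# ---------------------------------------------------------------------------
# rendering

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "to_dict") and not isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def report_to_json(report: dict) -> str:
    return json.dumps(_jsonable(report), indent=2, sort_keys=True)


def render_tables(report: dict, out_dir) -> list:
    """Write the JSON report plus one text table per fitted model.

    Returns the list of files written.  Tables use the estimate (SE),
    z/t, df, p layout and note the factor coding in a footer.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    _atomic_write(out / "report.json", report_to_json(report))
    written.append(out / "report.json")
    coding = "; ".join(f"{k}: {v}" for k, v in report.get("coding", {}).items())
    for name, fit in report.get("models", {}).items():
        txt = fit.summary_text(title=name) + f"\nCoding: {coding}\n"
        _atomic_write(out / f"table_{name}.txt", txt)
        written.append(out / f"table_{name}.txt")
    return [str(p) for p in written]
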