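"""Seeded generator for synthetic gaze-perception datasets.

Produces subject and trial tables with the statistical structure the
downstream mixed models and metacognition analyses assume:

* 64 subjects by default, each completing both tasks;
* implicit task: 12 object-present trials per gaze-validity x body-head
  congruency cell plus matched object-absent fillers (96 trials total),
  correctness Bernoulli under a logistic model with per-subject random
  intercepts (and optional uncorrelated random slopes);
* explicit task: 48 trials per congruency level, all gaze-valid,
  correctness under a logistic model including a negative AQ slope;
* confidence: a latent Gaussian whose coupling to correctness weakens with
  AQ in the explicit task only, discretized to the 11-point rating grid;
* AQ: integer truncated-normal draws calibrated so the *truncated* mean
  matches the target descriptives.

Reproducibility contract: identical ``(config, seed)`` give byte-identical
tables, and random streams are keyed per subject (and per purpose), so
growing ``n_subjects`` never perturbs earlier subjects' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .trialdata import CONFIDENCE_GRID, validate_trials

__all__ = [
    "GeneratorConfig",
    "sample_subjects",
    "simulate_task",
    "simulate_confidence",
    "generate_dataset",
]

# stream ids: one SeedSequence child per (subject, purpose)
_STREAM_SUBJECT = 0
_STREAM_IMPLICIT = 1
_STREAM_EXPLICIT = 2
_STREAM_CONF_IMPLICIT = 3
_STREAM_CONF_EXPLICIT = 4


class ConfigError(ValueError):
    """A generator configuration value is unusable."""


def _task_dict(implicit, explicit):
    return {"implicit": implicit, "explicit": explicit}


@dataclass
class GeneratorConfig:
    """All simulation parameters.

    Fixed-effect vectors are on the log-odds scale with 0/1 factor coding
    (0 = invalid / incongruent): ``implicit_fixed`` is (intercept,
    gaze validity, congruency, validity x congruency); ``explicit_fixed``
    is (intercept, congruency, AQ slope per SD of AQ).

    The confidence model is latent-Gaussian:

        L = mu0 + (s0 + s_aq * z(AQ)) * correct + u_subject + eps

    discretized by equal-width cuts of ``latent_range`` onto the grid
    {0, 10, ..., 100}.  ``confidence_aq_slope`` is negative for the
    explicit task by default (type-2 coupling degrades with autistic
    traits) and zero for the implicit task.
    """

    n_subjects: int = 64
    trials_per_implicit_cell: int = 12
    trials_per_explicit_condition: int = 48

    implicit_fixed: tuple = (1.01, 0.96, 0.99, -1.04)
    explicit_fixed: tuple = (1.72, 0.07, -0.20)
    random_intercept_sd: dict = field(
        default_factory=lambda: _task_dict(0.5, 0.5))
    # uncorrelated (diagonal) random slopes; 0 disables a term
    random_slope_sd: dict = field(default_factory=lambda: _task_dict(
        {"gaze_validity": 0.0, "body_head_congruency": 0.0,
         "interaction": 0.0},
        {"body_head_congruency": 0.0}))
    # adds coupling * (implicit interaction deviation / its SD) to the
    # explicit linear predictor; used to induce cross-task transfer
    explicit_trait_coupling: float = 0.0
    absent_accuracy: float = 0.95

    confidence_slope: dict = field(default_factory=lambda: _task_dict(1.66, 1.17))
    confidence_aq_slope: dict = field(default_factory=lambda: _task_dict(0.0, -0.2))
    confidence_intercept: dict = field(default_factory=lambda: _task_dict(-1.38, -1.00))
    confidence_noise_sd: dict = field(default_factory=lambda: _task_dict(0.73, 0.86))
    confidence_subject_sd: float = 0.3
    latent_range: tuple = (-2.5, 2.5)

    aq_mean: float = 16.1
    aq_sd: float = 6.08
    aq_range: tuple = (2, 27)

    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.aq_sd <= 0:
            raise ConfigError("aq_sd must be > 0")
        lo, hi = self.aq_range
        if not lo < hi:
            raise ConfigError("aq_range must be increasing")
        if not self.latent_range[0] < self.latent_range[1]:
            raise ConfigError(
                "latent_range cuts must be monotone increasing")
        if not 0.0 < self.absent_accuracy < 1.0:
            raise ConfigError("absent_accuracy must be in (0,1)")
        for task in ("implicit", "explicit"):
            if self.random_intercept_sd[task] < 0:
                raise ConfigError("random_intercept_sd must be >= 0")
            if self.confidence_noise_sd[task] <= 0:
                raise ConfigError("confidence_noise_sd must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        cfg = cls(**d)
        for key in ("implicit_fixed", "explicit_fixed", "latent_range",
                    "aq_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


def _rng(seed: int, subject_index: int, purpose: int) -> np.random.Generator:
    # keyed stream: stable per subject regardless of n_subjects
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(subject_index), int(purpose)]))


def _truncnorm_location(target_mean, sd, lo, hi):
    """Pre-truncation location whose [lo,hi]-truncated mean hits the target.

    The reported AQ descriptives are moments of the *observed* (bounded)
    sample; with asymmetric bounds a naive truncnorm(loc=target) is biased.
    """
    def gap(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    span = hi - lo
    return optimize.brentq(gap, lo - span, hi + span, xtol=1e-10)


def sample_subjects(config: GeneratorConfig, seed: int | None = None):
    """Draw the subject table and the per-subject random effects.

    Returns ``(subjects, effects)``: a subject DataFrame with integer AQ
    scores (within the configured truncation bounds) and their within-sample
    z-scores, and an effects DataFrame holding each subject's random
    intercepts (per task), optional random slopes, and confidence-model
    intercepts.  AQ draws are rounded truncated-normal.
    """
    config.validate()
    seed = config.seed if seed is None else int(seed)
    n = config.n_subjects
    lo, hi = config.aq_range
    mu = _truncnorm_location(config.aq_mean, config.aq_sd, lo, hi)
    a, b = (lo - mu) / config.aq_sd, (hi - mu) / config.aq_sd

    rows, eff_rows = [], []
    for i in range(n):
        g = _rng(seed, i, _STREAM_SUBJECT)
        aq_raw = stats.truncnorm.rvs(
            a, b, loc=mu, scale=config.aq_sd, random_state=g)
        aq = int(np.clip(np.rint(aq_raw), lo, hi))
        slopes_i = {
            f"b_implicit_{term}": g.normal(0.0, sd) if sd > 0 else 0.0
            for term, sd in config.random_slope_sd["implicit"].items()}
        slopes_e = {
            f"b_explicit_{term}": g.normal(0.0, sd) if sd > 0 else 0.0
            for term, sd in config.random_slope_sd["explicit"].items()}
        eff_rows.append({
            "subject_id": f"S{i + 1:03d}",
            "b_implicit_intercept": g.normal(0.0, config.random_intercept_sd["implicit"]),
            "b_explicit_intercept": g.normal(0.0, config.random_intercept_sd["explicit"]),
            **slopes_i, **slopes_e,
            "u_conf_implicit": g.normal(0.0, config.confidence_subject_sd),
            "u_conf_explicit": g.normal(0.0, config.confidence_subject_sd),
        })
        rows.append({"subject_id": f"S{i + 1:03d}", "aq_score": aq})

    subjects = pd.DataFrame(rows)
    sd = subjects["aq_score"].std(ddof=1)
    if sd == 0:
        raise ConfigError("degenerate AQ sample: zero variance")
    subjects["aq_z"] = (subjects["aq_score"] - subjects["aq_score"].mean()) / sd
    return subjects, pd.DataFrame(eff_rows)


def _implicit_linear_predictor(config, eff_row):
    b0, bv, bc, bi = config.implicit_fixed
    cells = []
    for gv in (1, 0):
        for bc_ in (1, 0):
            eta = (b0
                   + (bv + eff_row["b_implicit_gaze_validity"]) * gv
                   + (bc + eff_row["b_implicit_body_head_congruency"]) * bc_
                   + (bi + eff_row["b_implicit_interaction"]) * gv * bc_
                   + eff_row["b_implicit_intercept"])
            cells.append((gv, bc_, eta))
    return cells


def simulate_task(config: GeneratorConfig, subjects: pd.DataFrame,
                  effects: pd.DataFrame, task: str,
                  seed: int | None = None) -> pd.DataFrame:
    """Simulate one task's trials for all subjects (confidence left unset).

    Correctness is Bernoulli under the task's logistic model conditional on
    the subject's random effects; trial order is shuffled within subject.
    Implicit object-absent fillers are generated at a fixed high accuracy
    and are meant to be removed by the object-present analysis filter.
    """
    config.validate()
    if task not in ("implicit", "explicit"):
        raise ValueError(f"unknown task {task!r}")
    seed = config.seed if seed is None else int(seed)
    stream = _STREAM_IMPLICIT if task == "implicit" else _STREAM_EXPLICIT

    eff = effects.set_index("subject_id")
    frames = []
    for i, srow in enumerate(subjects.itertuples(index=False)):
        sid = srow.subject_id
        erow = eff.loc[sid]
        g = _rng(seed, i, stream)
        recs = []
        if task == "implicit":
            k = config.trials_per_implicit_cell
            for gv, bc_, eta in _implicit_linear_predictor(config, erow):
                p = expit(eta)
                y = g.random(k) < p
                for t in range(k):
                    recs.append((
                        "valid" if gv else "invalid",
                        "congruent" if bc_ else "incongruent",
                        True, int(y[t])))
            # matched object-absent fillers: 2k per congruency level
            for bc_ in (1, 0):
                y = g.random(2 * k) < config.absent_accuracy
                for t in range(2 * k):
                    recs.append((
                        "not_applicable",
                        "congruent" if bc_ else "incongruent",
                        False, int(y[t])))
        else:
            b0, bc, baq = config.explicit_fixed
            n_per = config.trials_per_explicit_condition
            trait = 0.0
            if config.explicit_trait_coupling != 0.0:
                sd_i = config.random_slope_sd["implicit"]["interaction"]
                if sd_i <= 0:
                    raise ConfigError(
                        "explicit_trait_coupling needs a positive implicit "
                        "interaction random-slope SD")
                trait = (config.explicit_trait_coupling
                         * erow["b_implicit_interaction"] / sd_i)
            for bc_ in (1, 0):
                eta = (b0
                       + (bc + erow["b_explicit_body_head_congruency"]) * bc_
                       + baq * srow.aq_z
                       + erow["b_explicit_intercept"] + trait)
                p = expit(eta)
                y = g.random(n_per) < p
                for t in range(n_per):
                    recs.append((
                        "valid", "congruent" if bc_ else "incongruent",
                        True, int(y[t])))
        order = g.permutation(len(recs))
        df = pd.DataFrame(
            [recs[j] for j in order],
            columns=["gaze_validity", "body_head_congruency",
                     "object_present", "correct"])
        df.insert(0, "trial_index", np.arange(1, len(df) + 1))
        df.insert(0, "task", task)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["confidence"] = -1  # filled by simulate_confidence
    return out


def simulate_confidence(config: GeneratorConfig, trials: pd.DataFrame,
                        subjects: pd.DataFrame, effects: pd.DataFrame,
                        seed: int | None = None) -> pd.DataFrame:
    """Fill the ``confidence`` column of simulated trials.

    Latent confidence is ``mu0 + (s0 + s_aq*z(AQ))*correct + u + eps``;
    it is mapped to the 11-point grid by equal-width bins over
    ``latent_range`` (values beyond the range land in the end bins).
    """
    config.validate()
    seed = config.seed if seed is None else int(seed)
    lo, hi = config.latent_range
    edges = np.linspace(lo, hi, 12)[1:-1]  # 10 interior cut points

    eff = effects.set_index("subject_id")
    sub = subjects.set_index("subject_id")
    sid_to_index = {s: i for i, s in enumerate(subjects["subject_id"])}

    out = trials.reset_index(drop=True).copy()
    conf = np.empty(len(out), dtype=int)
    for (sid, task), idx in out.groupby(
            ["subject_id", "task"], sort=True).groups.items():
        i = sid_to_index[sid]
        stream = (_STREAM_CONF_IMPLICIT if task == "implicit"
                  else _STREAM_CONF_EXPLICIT)
        g = _rng(seed, i, stream)
        s0 = config.confidence_slope[task]
        s_aq = config.confidence_aq_slope[task]
        mu0 = config.confidence_intercept[task]
        sigma = config.confidence_noise_sd[task]
        u = eff.loc[sid, f"u_conf_{task}"]
        z = sub.loc[sid, "aq_z"]
        # draw in trial_index order for reproducibility, then scatter back
        ordered = out.loc[idx].sort_values("trial_index")
        y = ordered["correct"].to_numpy()
        latent = mu0 + (s0 + s_aq * z) * y + u + g.normal(0.0, sigma, len(y))
        levels = np.digitize(latent, edges)
        conf_vals = np.asarray(CONFIDENCE_GRID)[levels]
        conf[ordered.index.to_numpy()] = conf_vals
    out["confidence"] = conf
    return out


def generate_dataset(config: GeneratorConfig, seed: int | None = None):
    """Full dataset: subjects plus both tasks' trials with confidence.

    Returns ``(subjects, trials)``; the trial table passes
    :func:`gazemeta.trialdata.validate_trials` and, under default trial
    counts, :func:`gazemeta.trialdata.validate_design`.
    """
    seed = config.seed if seed is None else int(seed)
    subjects, effects = sample_subjects(config, seed=seed)
    impl = simulate_task(config, subjects, effects, "implicit", seed=seed)
    expl = simulate_task(config, subjects, effects, "explicit", seed=seed)
    trials = pd.concat([impl, expl], ignore_index=True)
    trials = simulate_confidence(config, trials, subjects, effects, seed=seed)
    validate_trials(trials)
    return subjects, trials
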