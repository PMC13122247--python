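"""Hierarchical accuracy and confidence models.

Two model families over subject-grouped trial data:

* logistic GLMM (binomial family, logit link) for binary correctness,
  estimated by maximizing the Laplace-approximated marginal likelihood
  over per-subject random effects (adaptive Gauss-Hermite quadrature is
  available for intercept-only models);
* linear mixed model (LMM) for standardized confidence ratings, estimated
  by restricted maximum likelihood (REML) with Satterthwaite degrees of
  freedom for the fixed-effect t tests.

Random-effect structure is a random intercept plus optional *uncorrelated*
(diagonal-covariance) random slopes per subject.  The maximal structure
with all predictors as correlated slopes is frequently singular at a dozen
trials per cell, so the diagonal parameterization is the default contract;
a term is included as a slope simply by listing it in ``ModelSpec.random``.

Factor coding is applied here, at model time, from the stored labels:
gaze validity 0 = invalid / 1 = valid, body-head congruency
0 = incongruent / 1 = congruent, AQ group 0 = low / 1 = high.  Continuous
covariates listed in ``ModelSpec.standardize`` are z-scored within the
analysis sample.

Per-subject coefficients ("individual fixed-effect estimates") are the
fixed estimate plus the subject's conditional mode (BLUP) for the matching
random slope; :func:`extract_subject_effects` exposes them and
:func:`two_stage_transfer` feeds the implicit-task interaction coefficients
into the explicit-task accuracy model as a standardized covariate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitError",
    "SeparationError",
    "standardize_covariates",
    "build_design",
    "fit_logistic_glmm",
    "fit_linear_lmm",
    "extract_subject_effects",
    "two_stage_transfer",
    "compare_coefficients_ttest",
    "PairedComparison",
]

FACTOR_CODING: dict[str, dict[str, float]] = {
    "gaze_validity": {"invalid": 0.0, "valid": 1.0},
    "body_head_congruency": {"incongruent": 0.0, "congruent": 1.0},
    "aq_group": {"low": 0.0, "high": 1.0},
    "gender": {"female": 0.0, "male": 1.0},
}

_SEP_BOUND = 15.0  # |beta| beyond this on the logit scale => separation


class FitError(RuntimeError):
    """Estimation failed (non-convergence, singular design, ...)."""


class SeparationError(FitError):
    """Complete or quasi-complete separation: a logit coefficient diverged."""


@dataclass
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed`` lists main-effect / covariate names and ``a:b`` interactions
    (an intercept is always included); ``random`` lists subject-grouped
    random terms, ``"1"`` for the intercept.  ``standardize`` names the
    continuous columns (possibly including the response) to z-score within
    the analysis sample.
    """

    response: str
    fixed: list = field(default_factory=list)
    random: list = field(default_factory=lambda: ["1"])
    family: str = "binomial"  # binomial-logit | gaussian-identity
    standardize: list = field(default_factory=list)
    group: str = "subject_id"

    def __post_init__(self):
        fam = self.family.split("-")[0]
        if fam not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        self.family = fam
        mains = set(self.fixed)
        for t in self.fixed:
            if ":" in t:
                for part in t.split(":"):
                    if part not in mains:
                        raise ValueError(
                            f"interaction {t!r} references undeclared main "
                            f"effect {part!r}")
        for t in self.random:
            if t != "1" and t not in self.fixed:
                raise ValueError(
                    f"random slope {t!r} has no matching fixed term")


# ---------------------------------------------------------------------------
# design construction

def standardize_covariates(values, name: str = "covariate") -> np.ndarray:
    """z-score a vector within the analysis sample (mean 0, SD 1, ddof=1)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise FitError(f"covariate {name!r} has zero variance; "
                       "cannot standardize")
    return (x - x.mean()) / sd


def _encode(data: pd.DataFrame, name: str) -> np.ndarray:
    if name == "1":
        return np.ones(len(data))
    if name not in data.columns:
        raise KeyError(f"model term {name!r} not in data columns")
    col = data[name]
    if name in FACTOR_CODING:
        coding = FACTOR_CODING[name]
        vals = col.astype(str).map(coding)
        if vals.isna().any():
            bad = sorted(set(col[vals.isna()].astype(str)))
            raise FitError(
                f"column {name!r} has levels {bad} outside its 0/1 coding "
                f"{sorted(coding)}")
        return vals.to_numpy(dtype=float)
    return pd.to_numeric(col).to_numpy(dtype=float)


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Materialize (y, X, Z, group index) for a model spec.

    Returns ``(y, X, Z, gidx, group_labels)`` with ``X``/``Z`` as
    column-named DataFrames (numpy under the hood), rows sorted by group.
    Interaction columns are products of their encoded parts, so for 0/1
    factors the ``a:b`` column is 1 exactly on the (1,1) cell.
    """
    data = data.reset_index(drop=True)
    cache: dict[str, np.ndarray] = {}

    def col(name: str) -> np.ndarray:
        if name not in cache:
            if ":" in name:
                parts = [col(p) for p in name.split(":")]
                cache[name] = np.prod(parts, axis=0)
            else:
                x = _encode(data, name)
                if name in spec.standardize:
                    x = standardize_covariates(x, name)
                cache[name] = x
        return cache[name]

    y = _encode(data, spec.response)
    if spec.response in spec.standardize:
        y = standardize_covariates(y, spec.response)
    if spec.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise FitError("binomial response must be binary 0/1")

    xcols = {"Intercept": np.ones(len(data))}
    for t in spec.fixed:
        xcols[t] = col(t)
    X = pd.DataFrame(xcols)

    zcols = {}
    for t in spec.random:
        zcols["Intercept" if t == "1" else t] = (
            np.ones(len(data)) if t == "1" else col(t))
    Z = pd.DataFrame(zcols) if zcols else pd.DataFrame(index=data.index)

    codes, labels = pd.factorize(data[spec.group], sort=True)
    order = np.argsort(codes, kind="stable")
    return (y[order], X.iloc[order].reset_index(drop=True),
            Z.iloc[order].reset_index(drop=True), codes[order], list(labels))


# ---------------------------------------------------------------------------
# results container

@dataclass
class FitResult:
    """Estimates, tests, variance components and conditional modes.

    ``params`` is a DataFrame indexed by term with columns
    ``estimate, se, stat, df, p`` (``df`` is NaN for Wald-z inference);
    ``vcomp`` maps random-term name to variance; ``conditional_modes`` is a
    subject-by-term DataFrame of BLUPs (they average to ~0 per term).
    """

    params: pd.DataFrame
    vcomp: dict
    conditional_modes: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    family: str
    method: str
    n_obs: int
    n_groups: int
    spec: ModelSpec | None = None

    def subject_coefficients(self, term: str) -> pd.Series:
        return extract_subject_effects(self, term)

    def to_dict(self) -> dict:
        d = {
            "params": {
                t: {k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()}
                for t, row in self.params.iterrows()},
            "vcomp": {k: float(v) for k, v in self.vcomp.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "family": self.family,
            "method": self.method,
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
        }
        if self.spec is not None:
            d["spec"] = asdict(self.spec)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **{"indent": 2, **kw})

    def summary_text(self, title: str = "") -> str:
        lines = []
        if title:
            lines.append(title)
        stat_name = "z" if self.family == "binomial" else "t"
        lines.append(f"{'Predictor':<42}{'Estimate (SE)':>18}"
                     f"{stat_name:>9}{'df':>9}{'p':>10}")
        for term, r in self.params.iterrows():
            df_s = "" if pd.isna(r.get("df", np.nan)) else f"{r['df']:.2f}"
            p = r["p"]
            p_s = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(f"{term:<42}"
                         f"{r['estimate']:>10.2f} ({r['se']:.2f})"
                         f"{r['stat']:>9.2f}{df_s:>9}{p_s:>10}")
        if self.vcomp:
            vs = ", ".join(f"{k}={v:.4f}" for k, v in self.vcomp.items())
            lines.append(f"Random-effect variances (by subject): {vs}")
        lines.append(f"logLik {self.loglik:.2f}  method {self.method}  "
                     f"converged {self.converged}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# numerical helpers

def _num_hess(f, x, rel_step=1e-5):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _group_starts(gidx: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.r_[True, np.diff(gidx) > 0])


def _logistic_irls(y, X, tol=1e-12, maxiter=100):
    """Plain logistic regression by Newton-Raphson (no random effects)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        if np.abs(beta).max() > _SEP_BOUND:
            raise SeparationError(
                "logit coefficient diverged (|beta| > 15): complete or "
                "quasi-complete separation in the data")
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise FitError(f"singular information matrix: {e}") from e
        beta = beta + delta
        ll = float(y @ eta - np.logaddexp(0, eta).sum())
        if abs(ll - ll_old) < tol * (1 + abs(ll)) and np.abs(delta).max() < 1e-10:
            break
        ll_old = ll
    eta = X @ beta
    mu = expit(eta)
    if np.abs(beta).max() > _SEP_BOUND:
        raise SeparationError(
            "logit coefficient diverged (|beta| > 15): complete or "
            "quasi-complete separation in the data")
    ll = float(y @ eta - np.logaddexp(0, eta).sum())
    cov = np.linalg.inv((X * (mu * (1 - mu))[:, None]).T @ X)
    return beta, cov, ll, it + 1


class _LaplaceObjective:
    """Negative Laplace-approximated marginal log-likelihood.

    Vectorized across subjects: the inner Newton solve for all conditional
    modes runs on stacked (m, q) arrays with grouped reductions, so one
    evaluation costs a handful of dense operations regardless of m.
    """

    def __init__(self, y, X, Z, gidx):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.Z = np.asarray(Z, dtype=float)
        self.gidx = np.asarray(gidx)
        self.starts = _group_starts(self.gidx)
        self.m = len(self.starts)
        self.q = self.Z.shape[1]
        self.p = self.X.shape[1]
        self._b = np.zeros((self.m, self.q))
        # per-row outer products reused in the grouped Hessian
        self._ZZ = self.Z[:, :, None] * self.Z[:, None, :]

    def _pll(self, eta, b, dinv):
        ll = float(self.y @ eta - np.logaddexp(0, eta).sum())
        return ll - 0.5 * float((b * b * dinv).sum())

    def modes(self, beta, dinv, tol=1e-11, maxiter=100):
        """Inner Newton for the conditional modes b-hat (all subjects)."""
        b = self._b.copy()
        eta_f = self.X @ beta
        eta = eta_f + (self.Z * b[self.gidx]).sum(axis=1)
        pll = self._pll(eta, b, dinv)
        H = None
        for _ in range(maxiter):
            mu = expit(eta)
            w = mu * (1 - mu)
            g = np.add.reduceat(self.Z * (self.y - mu)[:, None],
                                self.starts, axis=0) - b * dinv
            H = (np.add.reduceat(self._ZZ * w[:, None, None],
                                 self.starts, axis=0)
                 + np.diag(dinv))
            delta = np.linalg.solve(H, g[:, :, None])[:, :, 0]
            step = 1.0
            for _half in range(30):
                b_new = b + step * delta
                eta = eta_f + (self.Z * b_new[self.gidx]).sum(axis=1)
                pll_new = self._pll(eta, b_new, dinv)
                if pll_new >= pll - 1e-13 * (1 + abs(pll)):
                    break
                step *= 0.5
            gain = pll_new - pll
            b, pll = b_new, pll_new
            if np.abs(step * delta).max() < tol and gain < 1e-12 * (1 + abs(pll)):
                break
        # Hessian at the solution
        mu = expit(eta)
        w = mu * (1 - mu)
        H = (np.add.reduceat(self._ZZ * w[:, None, None],
                             self.starts, axis=0) + np.diag(dinv))
        self._b = b  # warm start for the next outer evaluation
        return b, H, pll, w

    def nll(self, x):
        beta, theta = x[:self.p], x[self.p:]
        dinv = 1.0 / theta ** 2
        b, H, pll, w = self.modes(beta, dinv)
        # -0.5 log|D H| = -0.5 log|I + D Z'WZ|, stable as theta -> 0
        ZWZ = H - np.diag(dinv)
        M = np.eye(self.q) + (theta ** 2)[:, None] * ZWZ
        _, logdet = np.linalg.slogdet(M)
        return -(pll - 0.5 * float(logdet.sum()))


def fit_logistic_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    subjects: pd.DataFrame | None = None,
    method: str = "laplace",
    n_aghq: int = 7,
    pin_zero_variance: bool = False,
    tol: float = 1e-9,
    maxiter: int = 200,
) -> FitResult:
    """Fit a logistic mixed model by Laplace (or AGHQ) marginal likelihood.

    ``data`` is the trial table, optionally left-joined with ``subjects``
    on the grouping column to pull in covariates such as the AQ score.
    Inference on the fixed effects is Wald-z.  With
    ``pin_zero_variance=True`` (or an empty random list) the random
    structure is dropped and the fit reduces to pooled logistic
    regression -- the degenerate-equivalence contract.

    Raises :class:`SeparationError` when a coefficient diverges beyond
    +/-15 on the logit scale, and flags (not hides) non-convergence in the
    returned :class:`FitResult`.
    """
    if subjects is not None:
        data = data.merge(subjects, on=spec.group, how="left",
                          validate="many_to_one")
    y, Xdf, Zdf, gidx, labels = build_design(data, spec)
    X = Xdf.to_numpy(dtype=float)
    if len(labels) < 2 and not pin_zero_variance:
        raise FitError("need >= 2 subjects for a mixed model")

    if pin_zero_variance or Zdf.shape[1] == 0:
        beta, cov, ll, nit = _logistic_irls(y, X)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        params = pd.DataFrame(
            {"estimate": beta, "se": se, "stat": z, "df": np.nan,
             "p": 2 * stats.norm.sf(np.abs(z))}, index=Xdf.columns)
        return FitResult(params, {}, pd.DataFrame(index=labels), ll, True,
                         nit, "binomial", "pooled-irls", len(y), len(labels),
                         spec)

    obj = _LaplaceObjective(y, X, Zdf.to_numpy(dtype=float), gidx)
    beta0, _, _, _ = _logistic_irls(y, X)
    x0 = np.r_[beta0, np.full(obj.q, 0.3)]
    bounds = [(None, None)] * obj.p + [(1e-6, 25.0)] * obj.q

    if method == "aghq":
        if obj.q != 1:
            raise FitError("adaptive Gauss-Hermite quadrature is supported "
                           "for intercept-only random structure (q=1)")
        nodes, weights = np.polynomial.hermite.hermgauss(int(n_aghq))
        nll = _make_aghq_nll(obj, nodes, weights)
    elif method == "laplace":
        nll = obj.nll
    else:
        raise ValueError(f"unknown method {method!r}")

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": tol})
    xhat = res.x
    beta, theta = xhat[:obj.p], xhat[obj.p:]
    if np.abs(beta).max() > _SEP_BOUND:
        raise SeparationError(
            "logit coefficient diverged (|beta| > 15): separation")
    if not res.success:
        warnings.warn(f"GLMM optimizer did not report convergence: "
                      f"{res.message}")

    # Wald covariance: numerical Hessian over beta at the converged theta
    def nll_beta(b):
        return nll(np.r_[b, theta])

    Hb = _num_hess(nll_beta, beta)
    try:
        cov = np.linalg.inv(Hb)
    except np.linalg.LinAlgError as e:
        raise FitError(f"singular fixed-effect Hessian: {e}") from e
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    if not np.all(se > 0):
        raise FitError("non-positive fixed-effect SE at the optimum")
    z = beta / se
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "stat": z, "df": np.nan,
         "p": 2 * stats.norm.sf(np.abs(z))}, index=Xdf.columns)

    bhat, _, _, _ = obj.modes(beta, 1.0 / theta ** 2)
    modes = pd.DataFrame(bhat, index=labels, columns=Zdf.columns)
    vcomp = {c: float(t ** 2) for c, t in zip(Zdf.columns, theta)}
    return FitResult(params, vcomp, modes, -float(res.fun), bool(res.success),
                     int(res.nit), "binomial", method, len(y), len(labels),
                     spec)


def _make_aghq_nll(obj: _LaplaceObjective, nodes, weights):
    """Adaptive Gauss-Hermite marginal NLL for a scalar random intercept."""
    y, Z, gidx, starts = obj.y, obj.Z[:, 0], obj.gidx, obj.starts

    def nll(x):
        beta, theta = x[:obj.p], x[obj.p]
        dinv = np.array([1.0 / theta ** 2])
        bhat, H, _, _ = obj.modes(beta, dinv)
        bhat = bhat[:, 0]
        s = 1.0 / np.sqrt(H[:, 0, 0])       # per-subject adaptive scale
        eta_f = obj.X @ beta
        vals = np.empty((obj.m, len(nodes)))
        for k, (xk, wk) in enumerate(zip(nodes, weights)):
            bk = bhat + np.sqrt(2.0) * s * xk
            eta = eta_f + Z * bk[gidx]
            ll_rows = y * eta - np.logaddexp(0, eta)
            ll_g = np.add.reduceat(ll_rows, starts)
            logint = (ll_g - 0.5 * bk ** 2 / theta ** 2
                      - np.log(theta) - 0.5 * np.log(2 * np.pi))
            vals[:, k] = np.log(wk) + xk ** 2 + logint
        mx = vals.max(axis=1)
        ll_i = mx + np.log(np.exp(vals - mx[:, None]).sum(axis=1))
        ll_i += np.log(np.sqrt(2.0) * s)
        return -float(ll_i.sum())

    return nll


# ---------------------------------------------------------------------------
# linear mixed model (REML)

class _RemlObjective:
    """Profiled REML deviance via per-group Woodbury identities.

    Sufficient statistics (Z'Z, Z'X, Z'y, X'X, X'y, y'y per subject) are
    precomputed once; each evaluation solves only q x q and p x p systems.
    Variance parameterization: theta = (residual SD, random SDs...).
    """

    def __init__(self, y, X, Z, gidx):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        starts = _group_starts(gidx)
        self.m = len(starts)
        self.sizes = np.diff(np.r_[starts, len(y)])
        self.ZtZ, self.ZtX, self.Zty = [], [], []
        self.XtX, self.Xty, self.yty = [], [], []
        bounds = np.r_[starts, len(y)]
        for i in range(self.m):
            sl = slice(bounds[i], bounds[i + 1])
            Zi, Xi, yi = Z[sl], X[sl], y[sl]
            self.ZtZ.append(Zi.T @ Zi)
            self.ZtX.append(Zi.T @ Xi)
            self.Zty.append(Zi.T @ yi)
            self.XtX.append(Xi.T @ Xi)
            self.Xty.append(Xi.T @ yi)
            self.yty.append(float(yi @ yi))

    def _assemble(self, theta):
        sig2 = theta[0] ** 2
        d = theta[1:] ** 2
        Sxx = np.zeros((self.p, self.p))
        Sxy = np.zeros(self.p)
        Syy = 0.0
        logdetV = 0.0
        for i in range(self.m):
            K = np.diag(sig2 / d) + self.ZtZ[i]
            sign, ld = np.linalg.slogdet(K)
            if sign <= 0:
                raise FitError("indefinite K matrix in REML evaluation")
            logdetV += (self.sizes[i] * np.log(sig2) + ld
                        + np.log(d / sig2).sum())
            Kinv_ZtX = np.linalg.solve(K, self.ZtX[i])
            Kinv_Zty = np.linalg.solve(K, self.Zty[i])
            Sxx += (self.XtX[i] - self.ZtX[i].T @ Kinv_ZtX) / sig2
            Sxy += (self.Xty[i] - self.ZtX[i].T @ Kinv_Zty) / sig2
            Syy += (self.yty[i] - self.Zty[i] @ Kinv_Zty) / sig2
        return Sxx, Sxy, Syy, logdetV

    def beta_cov(self, theta):
        Sxx, Sxy, _, _ = self._assemble(theta)
        cov = np.linalg.inv(Sxx)
        return cov @ Sxy, cov

    def nll(self, theta):
        Sxx, Sxy, Syy, logdetV = self._assemble(theta)
        sign, ld_xx = np.linalg.slogdet(Sxx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(Sxx, Sxy)
        rss = Syy - float(beta @ Sxy)
        return 0.5 * (logdetV + ld_xx + rss
                      + (self.n - self.p) * np.log(2 * np.pi))

    def conditional_modes(self, theta, beta, Z, X, y, gidx):
        sig2 = theta[0] ** 2
        d = theta[1:] ** 2
        starts = _group_starts(gidx)
        bounds = np.r_[starts, len(y)]
        modes = np.empty((self.m, self.q))
        for i in range(self.m):
            sl = slice(bounds[i], bounds[i + 1])
            Ztr = Z[sl].T @ (y[sl] - X[sl] @ beta)
            K = np.diag(sig2 / d) + self.ZtZ[i]
            # Z'V^-1 r = (Ztr - Z'Z K^-1 Ztr)/sig2 ; b = D Z'V^-1 r
            modes[i] = d * (Ztr - self.ZtZ[i] @ np.linalg.solve(K, Ztr)) / sig2
        return modes


def fit_linear_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    subjects: pd.DataFrame | None = None,
    pin_zero_variance: bool = False,
    tol: float = 1e-10,
    maxiter: int = 200,
) -> FitResult:
    """Fit a Gaussian linear mixed model by REML.

    Fixed-effect t tests use Satterthwaite degrees of freedom: for each
    coefficient, df = 2*var(beta_j)^2 / (g' A g) where g is the gradient of
    var(beta_j) with respect to the variance parameters and A their
    asymptotic covariance (inverse REML-deviance Hessian).  With
    ``pin_zero_variance=True`` the fit is exactly ordinary least squares
    with residual df.
    """
    if subjects is not None:
        data = data.merge(subjects, on=spec.group, how="left",
                          validate="many_to_one")
    if spec.family != "gaussian":
        raise FitError("fit_linear_lmm requires a gaussian-family spec")
    y, Xdf, Zdf, gidx, labels = build_design(data, spec)
    X = Xdf.to_numpy(dtype=float)
    n, p = X.shape

    if pin_zero_variance or Zdf.shape[1] == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfres = n - p
        sig2 = float(resid @ resid) / dfres
        cov = sig2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        t = beta / se
        params = pd.DataFrame(
            {"estimate": beta, "se": se, "stat": t, "df": float(dfres),
             "p": 2 * stats.t.sf(np.abs(t), dfres)}, index=Xdf.columns)
        ll = -0.5 * (dfres * np.log(2 * np.pi * sig2) + dfres
                     + np.linalg.slogdet(X.T @ X / sig2)[1]
                     - np.linalg.slogdet(X.T @ X)[1])
        return FitResult(params, {"residual": sig2}, pd.DataFrame(index=labels),
                         float(ll), True, 1, "gaussian", "ols", n,
                         len(labels), spec)

    Z = Zdf.to_numpy(dtype=float)
    obj = _RemlObjective(y, X, Z, gidx)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    s0 = float(np.std(y - X @ beta_ols, ddof=p))
    x0 = np.r_[s0, np.full(obj.q, max(s0 / 2, 1e-3))]
    bounds = [(1e-6, None)] * (1 + obj.q)
    res = optimize.minimize(
        obj.nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": tol})
    theta = res.x
    if not res.success:
        warnings.warn(f"LMM optimizer did not report convergence: "
                      f"{res.message}")
    beta, cov = obj.beta_cov(theta)
    se = np.sqrt(np.diag(cov))

    # Satterthwaite df
    A = None
    try:
        Ht = _num_hess(obj.nll, theta, rel_step=1e-4)
        A = np.linalg.inv(Ht)
    except np.linalg.LinAlgError:
        warnings.warn("singular variance-parameter Hessian; "
                      "falling back to residual df")
    dfs = np.empty(p)
    if A is not None:
        k = theta.size
        G = np.empty((p, k))
        for j in range(k):
            h = 1e-4 * (1 + theta[j])
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] = max(tm[j] - h, 1e-8)
            _, cp = obj.beta_cov(tp)
            _, cm = obj.beta_cov(tm)
            G[:, j] = (np.diag(cp) - np.diag(cm)) / (tp[j] - tm[j])
        for i in range(p):
            denom = float(G[i] @ A @ G[i])
            dfs[i] = (2 * np.diag(cov)[i] ** 2 / denom
                      if denom > 0 else n - p)
        dfs = np.clip(dfs, 1.0, n - p)
    else:
        dfs[:] = n - p

    t = beta / se
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "stat": t, "df": dfs,
         "p": 2 * stats.t.sf(np.abs(t), dfs)}, index=Xdf.columns)
    modes = obj.conditional_modes(theta, beta, Z, X, y, gidx)
    modes = pd.DataFrame(modes, index=labels, columns=Zdf.columns)
    vcomp = {"residual": float(theta[0] ** 2)}
    vcomp.update({c: float(t_ ** 2) for c, t_ in zip(Zdf.columns, theta[1:])})
    return FitResult(params, vcomp, modes, -float(res.fun), bool(res.success),
                     int(res.nit), "gaussian", "reml", n, len(labels), spec)


# ---------------------------------------------------------------------------
# individual differences

def extract_subject_effects(fit: FitResult, term: str) -> pd.Series:
    """Per-subject coefficient for ``term``: fixed estimate + BLUP.

    Requires the term to carry a random slope in the fit; the series is
    indexed by subject id.  With zero random-slope variance every subject
    collapses to the fixed estimate.
    """
    key = "Intercept" if term in ("1", "Intercept") else term
    if key not in fit.conditional_modes.columns:
        raise KeyError(
            f"term {term!r} has no random slope in this fit; available: "
            f"{list(fit.conditional_modes.columns)}")
    fixed = float(fit.params.loc[key, "estimate"])
    out = fixed + fit.conditional_modes[key]
    out.name = key
    return out


def two_stage_transfer(
    implicit_fit: FitResult,
    explicit_trials: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    term: str = "gaze_validity:body_head_congruency",
    group: str = "subject_id",
) -> FitResult:
    """Carry implicit-task interaction coefficients into the explicit model.

    Stage one extracts each subject's gaze-validity x congruency
    coefficient from the implicit accuracy GLMM; stage two z-scores them
    and refits the explicit accuracy model with that covariate
    (``implicit_accuracy``) plus a random intercept, reporting its
    beta/z/p.  Raises if explicit-task subjects are missing from stage one.
    """
    coefs = extract_subject_effects(implicit_fit, term)
    have = set(coefs.index)
    need = set(explicit_trials[group].unique())
    missing = sorted(need - have)
    if missing:
        raise FitError(
            f"subjects present in explicit trials but absent from the "
            f"implicit fit: {missing}")
    data = explicit_trials.copy()
    data["implicit_accuracy"] = data[group].map(coefs)
    spec = ModelSpec(response="correct", fixed=["implicit_accuracy"],
                     random=["1"], family="binomial",
                     standardize=["implicit_accuracy"], group=group)
    return fit_logistic_glmm(data, spec, subjects=subjects)


@dataclass
class PairedComparison:
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    t: float
    df: int
    p: float


def compare_coefficients_ttest(effects_a, effects_b) -> PairedComparison:
    """Paired t test on two per-subject coefficient vectors.

    Pairs are aligned by subject id when both inputs are indexed Series;
    df = n - 1.  A zero-variance nonzero difference (a = b + c) has no
    finite t and raises; identical vectors return t = 0.
    """
    a = pd.Series(effects_a).astype(float)
    b = pd.Series(effects_b).astype(float)
    if isinstance(effects_a, pd.Series) and isinstance(effects_b, pd.Series):
        common = a.index.intersection(b.index)
        if len(common) != len(a) or len(common) != len(b):
            raise ValueError("subject ids of the two coefficient vectors "
                             "do not align")
        b = b.loc[a.index]
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    d = a.to_numpy() - b.to_numpy()
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedComparison(
                float(a.mean()), float(a.std(ddof=1) / np.sqrt(n)),
                float(b.mean()), float(b.std(ddof=1) / np.sqrt(n)),
                0.0, n - 1, 1.0)
        raise ZeroDivisionError(
            "paired differences have zero variance but nonzero mean; "
            "t statistic is undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    return PairedComparison(
        float(a.mean()), float(a.std(ddof=1) / np.sqrt(n)),
        float(b.mean()), float(b.std(ddof=1) / np.sqrt(n)),
        t, n - 1, float(2 * stats.t.sf(abs(t), n - 1)))
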