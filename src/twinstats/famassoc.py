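"""Family-aggregation logistic models with Wald inference.

Two designs from the twin-family study are covered:

* **zygosity prevalence contrast** — affection of every responding twin
  individual regressed on an MZ indicator (DZ reference) with a family-level
  normal random intercept to absorb within-pair clustering, optionally
  adjusted for age and sex.
* **index-twin family scans** — one randomly selected twin per complete
  family regressed on co-twin / oldest-sibling / mother / father statuses,
  univariately (one member at a time) or multivariately (all four at once).
  With a single twin per family there is no repeated family membership, so
  these are plain logistic fits.

Fixed-effects fits use an in-house iteratively reweighted least squares
(IRLS) solver with a gradient-norm stopping rule; the random intercept is
integrated out by adaptive Gauss-Hermite quadrature.  Complete separation
is detected and raised rather than silently penalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from numpy.polynomial.hermite import hermgauss

from twinstats.errors import ConvergenceError, SeparationError, ValidationError

FAMILY_MEMBERS = ("cotwin", "sibling", "mother", "father")

_GH_NODES = 21  # Gauss-Hermite nodes for the random-intercept integral


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress on what.

    ``covariate_policy`` controls age/sex adjustment: ``always``, ``never``,
    or ``when_significant`` (include a covariate when its own Wald p < 0.05
    in a covariates-only model for the same outcome).
    """

    outcome: str
    predictors: tuple
    random_intercept: bool = False
    covariate_policy: str = "when_significant"

    def __post_init__(self):
        if not self.predictors:
            raise ValidationError("RegressionSpec needs at least one predictor")
        if self.outcome in self.predictors:
            raise ValidationError("outcome cannot appear among predictors")
        if self.covariate_policy not in ("always", "never", "when_significant"):
            raise ValidationError(
                f"unknown covariate_policy '{self.covariate_policy}'"
            )


@dataclass(frozen=True)
class TermResult:
    """Per-term Wald summary on the log-odds scale."""

    name: str
    coef: float
    se: float

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.coef))

    @property
    def wald_z(self) -> float:
        return self.coef / self.se

    @property
    def p_value(self) -> float:
        return float(2 * stats.norm.sf(abs(self.wald_z)))


@dataclass(frozen=True)
class RegressionFit:
    """A fitted (possibly mixed) logistic model."""

    terms: tuple  # of TermResult, intercept first
    n: int
    loglik: float
    converged: bool
    random_intercept_sd: float = 0.0
    n_iter: int = 0

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def coef(self) -> dict:
        return {t.name: t.coef for t in self.terms}


# ---------------------------------------------------------------------------
# plain logistic: IRLS
# ---------------------------------------------------------------------------

def _irls(X, y, tol=1e-8, max_iter=100):
    """Newton-Raphson / IRLS for the Bernoulli GLM with logit link.

    Converges when the max absolute score drops below ``tol``; linear
    predictors wandering past +-15 indicate (quasi-)separation.
    """
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError(
            "design matrix is rank deficient; drop collinear predictors"
        )
    beta = np.zeros(k)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix in IRLS")
        # step halving keeps the likelihood monotone on hard problems
        ll0 = _bernoulli_loglik(y, eta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _bernoulli_loglik(y, X @ cand) >= ll0:
                break
            scale /= 2
        beta = beta + scale * step
        if np.max(np.abs(X @ beta)) > 15:
            raise SeparationError(
                "complete or quasi-complete separation detected "
                "(fitted log-odds exceed +-15)"
            )
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    eta = X @ beta
    if np.max(np.abs(eta)) > 15:
        raise SeparationError(
            "complete or quasi-complete separation detected "
            "(fitted log-odds exceed +-15)"
        )
    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, cov, _bernoulli_loglik(y, eta), it


def _bernoulli_loglik(y, eta):
    # numerically stable: -log(1+exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    return float(-np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta))))


# ---------------------------------------------------------------------------
# random-intercept logistic: adaptive Gauss-Hermite
# ---------------------------------------------------------------------------

def _agq_loglik(beta, sigma, X, y, group_idx, n_groups, nodes, log_weights):
    """Marginal log-likelihood with family intercepts integrated out.

    Per family the integrand is maximised (Newton in the standardised
    intercept u), the quadrature grid is centred at the mode and scaled by
    the curvature, and the 21-node Gauss-Hermite rule is applied on the
    log scale.
    """
    eta0 = X @ beta
    u = np.zeros(n_groups)
    for _ in range(50):
        p = expit(eta0 + sigma * u[group_idx])
        g1 = sigma * np.bincount(group_idx, weights=y - p, minlength=n_groups) - u
        g2 = -(sigma ** 2) * np.bincount(
            group_idx, weights=p * (1 - p), minlength=n_groups
        ) - 1.0
        step = g1 / g2
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta0 + sigma * u[group_idx])
    g2 = -(sigma ** 2) * np.bincount(
        group_idx, weights=p * (1 - p), minlength=n_groups
    ) - 1.0
    s = 1.0 / np.sqrt(-g2)

    log_terms = np.empty((len(nodes), n_groups))
    sqrt2 = np.sqrt(2.0)
    for k, (z, lw) in enumerate(zip(nodes, log_weights)):
        uk = u + sqrt2 * s * z
        eta = eta0 + sigma * uk[group_idx]
        ll_obs = -np.logaddexp(0.0, np.where(y == 1, -eta, eta))
        h = np.bincount(group_idx, weights=ll_obs, minlength=n_groups)
        h += -0.5 * uk ** 2 - 0.5 * np.log(2 * np.pi)
        log_terms[k] = lw + z * z + h
    from scipy.special import logsumexp

    log_lik_g = np.log(sqrt2 * s) + logsumexp(log_terms, axis=0)
    return float(np.sum(log_lik_g))


def _fit_glmm(X, y, groups, tol=1e-8):
    codes, _ = pd.factorize(groups)
    n_groups = int(codes.max()) + 1
    nodes, weights = hermgauss(_GH_NODES)
    log_w = np.log(weights)

    beta0, _, _, _ = _irls(X, y)
    x0 = np.concatenate([beta0, [np.log(0.5)]])

    def nll(params):
        beta = params[:-1]
        sigma = np.exp(params[-1])
        return -_agq_loglik(beta, sigma, X, y, codes, n_groups, nodes, log_w)

    res = optimize.minimize(
        nll, x0, method="BFGS", options=dict(gtol=tol * 10, maxiter=500)
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        raise ConvergenceError(
            f"random-intercept fit failed: {res.message}", trace=res
        )
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    from twinstats.similarity import _num_hessian

    H = _num_hessian(nll, res.x, h=1e-4)
    try:
        cov_full = np.linalg.inv(H)
        cov = cov_full[:-1, :-1]
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), np.nan)
    return beta, cov, -float(res.fun), sigma, int(res.nit)


# ---------------------------------------------------------------------------
# public fitting surface
# ---------------------------------------------------------------------------

def _build_design(df: pd.DataFrame, predictors):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for p in predictors:
        if p not in df.columns:
            raise ValidationError(f"predictor '{p}' not found in data")
        cols.append(df[p].to_numpy(float))
        names.append(p)
    return np.column_stack(cols), names


def fit_logistic(df: pd.DataFrame, spec: RegressionSpec,
                 groups: str | None = None) -> RegressionFit:
    """Fit a logistic (or family random-intercept logistic) model.

    ``df`` holds one row per analysis unit with the outcome and predictor
    columns named by ``spec``; ``groups`` names the clustering column when
    ``spec.random_intercept`` is set.
    """
    y = df[spec.outcome].to_numpy(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1 with no missing values")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("outcome has no variation (all 0 or all 1)")
    X, names = _build_design(df, spec.predictors)

    if spec.random_intercept:
        if groups is None:
            raise ValidationError("random_intercept requires a grouping column")
        beta, cov, ll, sigma, nit = _fit_glmm(X, y, df[groups].to_numpy())
        terms = tuple(
            TermResult(n, float(b), float(np.sqrt(v)))
            for n, b, v in zip(names, beta, np.diag(cov))
        )
        return RegressionFit(terms, len(df), ll, True, sigma, nit)

    beta, cov, ll, nit = _irls(X, y)
    terms = tuple(
        TermResult(n, float(b), float(np.sqrt(v)))
        for n, b, v in zip(names, beta, np.diag(cov))
    )
    return RegressionFit(terms, len(df), ll, True, 0.0, nit)


def _significant_covariates(df, outcome, age_col, sex_col, policy) -> tuple:
    """Apply the adjust-when-significant rule for age and sex."""
    if policy == "never":
        return ()
    if policy == "always":
        return (age_col, sex_col)
    spec = RegressionSpec(outcome, (age_col, sex_col), covariate_policy="never")
    try:
        fit = fit_logistic(df, spec)
    except (ConvergenceError, ValidationError):
        return ()
    keep = []
    for col in (age_col, sex_col):
        if fit.term(col).p_value < 0.05:
            keep.append(col)
    return tuple(keep)


def univariate_scan(rows: pd.DataFrame,
                    members=FAMILY_MEMBERS,
                    covariate_policy: str = "when_significant") -> dict:
    """One logistic model per family member on index-twin rows.

    ``rows`` comes from :func:`twinstats.cohort.select_index_twins`.  Returns
    a dict mapping member name to a :class:`RegressionFit`; a member whose
    fit fails maps to the raised exception instead, so one separation does
    not abort the scan.
    """
    _check_rows(rows)
    covs = _significant_covariates(
        rows, "index_status", "index_age", "index_sex", covariate_policy
    )
    out = {}
    for member in members:
        pred = (f"{member}_status",) + covs
        spec = RegressionSpec("index_status", pred, covariate_policy=covariate_policy)
        try:
            out[member] = fit_logistic(rows, spec)
        except (ConvergenceError, ValidationError) as err:
            out[member] = err
    return out


def multivariate_model(rows: pd.DataFrame,
                       covariate_policy: str = "when_significant") -> RegressionFit:
    """All four family-member statuses as simultaneous predictors."""
    _check_rows(rows)
    covs = _significant_covariates(
        rows, "index_status", "index_age", "index_sex", covariate_policy
    )
    pred = tuple(f"{m}_status" for m in FAMILY_MEMBERS) + covs
    spec = RegressionSpec("index_status", pred, covariate_policy=covariate_policy)
    return fit_logistic(rows, spec)


def _check_rows(rows):
    needed = {f"{m}_status" for m in FAMILY_MEMBERS} | {
        "index_status", "index_age", "index_sex"
    }
    missing = needed - set(rows.columns)
    if missing:
        raise ValidationError(f"index-twin rows missing columns {sorted(missing)}")
    if len(rows) < 20:
        raise ValidationError(
            f"only {len(rows)} complete families; too few for a stable fit"
        )


def zygosity_prevalence_or(df: pd.DataFrame, condition: str,
                           covariate_policy: str = "when_significant",
                           random_intercept: bool = True) -> RegressionFit:
    """MZ-vs-DZ prevalence odds ratio with family clustering.

    Every twin individual with a non-missing status contributes one row;
    the predictor of interest is the MZ indicator (DZ reference) and a
    family-level random intercept absorbs the twin-pair correlation.
    """
    twins = df[df["role"].isin(("twin1", "twin2"))].copy()
    twins = twins[twins[condition].notna()]
    if twins.empty:
        raise ValidationError(f"no twin statuses for condition '{condition}'")
    twins["mz"] = (twins["zygosity"] == "MZ").astype(float)
    twins["sex_female"] = (twins["sex"] == "female").astype(float)
    twins[condition] = twins[condition].astype(int)
    covs = _significant_covariates(
        twins, condition, "age", "sex_female", covariate_policy
    )
    spec = RegressionSpec(
        condition, ("mz",) + covs, random_intercept=random_intercept,
        covariate_policy=covariate_policy,
    )
    return fit_logistic(twins, spec, groups="family_id" if random_intercept else None)
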