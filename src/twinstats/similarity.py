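"""Maximum-likelihood twin-pair similarity estimation.

Three association measures are supported, each embedded in the same
exchangeable pair likelihood so that MZ-vs-DZ contrasts can be tested by a
likelihood ratio:

* **casewise concordance** ``C`` — P(twin affected | co-twin affected), the
  standard genetic-epidemiology summary for binary traits.  Under the
  multinomial pair model its MLE is the closed form ``2*N_c / (2*N_c + N_d)``.
* **correlation** ``rho`` — the Pearson (phi) correlation of the two twins'
  binary statuses.  Parameterised through ``p11 = q^2 + rho*q*(1-q)``; the
  MLE is algebraically the phi coefficient of the double-entered 2x2 table.
* **pair odds ratio** ``psi`` — the odds of affection given an affected
  co-twin over the odds given an unaffected co-twin (a Plackett-type
  cross-product parameter).  Saturated-model MLE ``N_c*N_00 / (N_d/2)^2``.

Standard errors come from the delta method on the multinomial counts; the
Wald 95% interval is untransformed for C and rho (truncated to the natural
range) and on the log scale for psi.  Covariate-adjusted fits let each
twin's marginal affection probability depend on age and sex on the log-odds
scale while the association parameter stays common to all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from twinstats.cohort import PairCounts
from twinstats.errors import ConvergenceError, ValidationError

METHODS = ("casewise", "correlation", "odds_ratio")

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class SimilarityEstimate:
    """An association estimate with its Wald-type uncertainty."""

    method: str
    estimate: float
    se: float
    ci95: tuple
    n_pairs: int
    zygosity: str
    boundary: bool = False


@dataclass(frozen=True)
class PairModelFit:
    """Fitted pair model: marginal parameters, association, log-likelihood."""

    method: str
    association: float
    association_se: float
    marginal: dict
    loglik: float
    n_pairs: int
    adjusted: bool
    converged: bool
    boundary: bool = False


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio test of a shared association across zygosities."""

    statistic: float
    df: int
    p_value: float
    loglik_unconstrained: float
    loglik_constrained: float
    method: str = "casewise"
    adjusted: bool = False


# ---------------------------------------------------------------------------
# closed-form estimators with multinomial delta-method SEs
# ---------------------------------------------------------------------------

def _multinomial_delta_se(pc: PairCounts, func) -> float:
    """Delta-method SE of func(p11, pd) under the trinomial pair model.

    (p11, pd) are the concordant-affected and discordant cell probabilities
    of a single pair; their MLE covariance is the standard multinomial one.
    """
    n = pc.n_pairs
    p11 = pc.n_concordant / n
    pd_ = pc.n_discordant / n
    h = 1e-7
    g11 = (func(p11 + h, pd_) - func(p11 - h, pd_)) / (2 * h)
    gd = (func(p11, pd_ + h) - func(p11, pd_ - h)) / (2 * h)
    var = (
        g11 ** 2 * p11 * (1 - p11) / n
        + gd ** 2 * pd_ * (1 - pd_) / n
        - 2 * g11 * gd * p11 * pd_ / n
    )
    return float(np.sqrt(max(var, 0.0)))


def casewise_concordance(pc: PairCounts) -> SimilarityEstimate:
    """Casewise concordance ``C = 2*N_c / (2*N_c + N_d)`` with Wald CI.

    The Wald interval is on the untransformed scale, truncated to [0, 1].
    Undefined when no pair contains an affected twin.
    """
    nc, nd = pc.n_concordant, pc.n_discordant
    if nc + nd == 0:
        raise ValidationError(
            "casewise concordance undefined: no pair contains an affected twin"
        )
    c = 2 * nc / (2 * nc + nd)
    se = _multinomial_delta_se(pc, lambda p11, pd_: 2 * p11 / (2 * p11 + pd_))
    lo = max(0.0, c - _Z95 * se)
    hi = min(1.0, c + _Z95 * se)
    return SimilarityEstimate(
        "casewise", c, se, (lo, hi), pc.n_pairs, pc.zygosity,
        boundary=(nc == 0 or nd == 0),
    )


def _phi_from_probs(p11, pd_):
    q = p11 + pd_ / 2
    return (p11 - q * q) / (q * (1 - q))


def pair_correlation(pc: PairCounts) -> SimilarityEstimate:
    """Twin-pair correlation: MLE of rho in ``p11 = q^2 + rho*q*(1-q)``.

    Algebraically identical to the phi coefficient of the double-entered
    2x2 table. Requires a non-degenerate margin (0 < prevalence < 1).
    """
    n = pc.n_pairs
    q = pc.prevalence
    if not 0 < q < 1:
        raise ValidationError(
            "pair correlation undefined: all twins affected or none affected"
        )
    rho = _phi_from_probs(pc.n_concordant / n, pc.n_discordant / n)
    se = _multinomial_delta_se(pc, _phi_from_probs)
    lo = max(-1.0, rho - _Z95 * se)
    hi = min(1.0, rho + _Z95 * se)
    return SimilarityEstimate(
        "correlation", rho, se, (lo, hi), n, pc.zygosity,
        boundary=bool(abs(rho) >= 1),
    )


def pair_odds_ratio(pc: PairCounts) -> SimilarityEstimate:
    """Pair odds ratio: saturated MLE ``psi = N_c*N_00 / (N_d/2)^2``.

    The CI is a Wald interval on log(psi).  With no discordant pairs the
    estimate is infinite and flagged as a boundary case with no CI.
    """
    nc, nd, n00 = pc.n_concordant, pc.n_discordant, pc.n_neither
    if nd == 0:
        return SimilarityEstimate(
            "odds_ratio", np.inf, np.nan, (np.nan, np.nan),
            pc.n_pairs, pc.zygosity, boundary=True,
        )
    if nc == 0 or n00 == 0:
        psi = 0.0 if nc == 0 else np.inf
        return SimilarityEstimate(
            "odds_ratio", psi, np.nan, (np.nan, np.nan),
            pc.n_pairs, pc.zygosity, boundary=True,
        )
    psi = nc * n00 / (nd / 2) ** 2

    def log_psi(p11, pd_):
        p00 = 1 - p11 - pd_
        return np.log(p11) + np.log(p00) - 2 * np.log(pd_ / 2)

    se_log = _multinomial_delta_se(pc, log_psi)
    ci = (psi * np.exp(-_Z95 * se_log), psi * np.exp(_Z95 * se_log))
    return SimilarityEstimate("odds_ratio", psi, se_log * psi, ci, pc.n_pairs, pc.zygosity)


# ---------------------------------------------------------------------------
# Plackett cell solver
# ---------------------------------------------------------------------------

def plackett_cell(p1, p2, psi):
    """Joint cell probability p11 of a bivariate binary law with margins
    ``p1``, ``p2`` and cross-product (Plackett) odds ratio ``psi``.

    For psi != 1 this is the root of the quadratic
    ``p11*(1-p1-p2+p11) = psi*(p1-p11)*(p2-p11)`` lying within the Frechet
    bounds; for psi == 1 it is the independence product.  Accepts scalars or
    arrays (broadcast).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(p1 <= 0) or np.any(p1 >= 1) or np.any(p2 <= 0) or np.any(p2 >= 1):
        raise ValidationError("plackett_cell: margins must lie in (0, 1)")
    if np.any(psi <= 0):
        raise ValidationError("plackett_cell: odds ratio must be positive")

    with np.errstate(invalid="ignore", divide="ignore"):
        s = 1 + (p1 + p2) * (psi - 1)
        disc = s * s - 4 * psi * (psi - 1) * p1 * p2
        root = (s - np.sqrt(np.maximum(disc, 0.0))) / (2 * (psi - 1))
    p11 = np.where(np.isclose(psi, 1.0), p1 * p2, root)
    # clip tiny numerical excursions outside the Frechet bounds
    lower = np.maximum(0.0, p1 + p2 - 1)
    upper = np.minimum(p1, p2)
    p11 = np.clip(p11, lower, upper)
    if p11.ndim == 0:
        return float(p11)
    return p11


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _assoc_transform(method):
    """Map the association parameter to an unconstrained working scale."""
    if method == "casewise":
        return logit, expit
    if method == "correlation":
        return np.arctanh, np.tanh
    if method == "odds_ratio":
        return np.log, np.exp
    raise ValidationError(f"unknown method '{method}'; expected one of {METHODS}")


def _cells_exchangeable(q, assoc, method):
    """(p11, pd, p00) of an exchangeable pair with marginal q."""
    if method == "casewise":
        p11 = q * assoc
    elif method == "correlation":
        p11 = q * q + assoc * q * (1 - q)
    else:
        p11 = plackett_cell(q, q, assoc)
    return p11, 2 * (q - p11), 1 - 2 * q + p11


def _cell_general(p1, p2, assoc, method):
    """p11 for possibly unequal margins, per association kind.

    casewise uses ``p11 = C*(p1+p2)/2`` (the exchangeable form ``q*C``
    generalised so that C remains the affected-co-twin conditional
    probability averaged over the two orderings).
    """
    if method == "casewise":
        return assoc * (p1 + p2) / 2
    if method == "correlation":
        return p1 * p2 + assoc * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return plackett_cell(p1, p2, assoc)


def _saturated_loglik(pc: PairCounts) -> float:
    """Trinomial log-likelihood at the empirical cell frequencies."""
    n = pc.n_pairs
    ll = 0.0
    for k in (pc.n_concordant, pc.n_discordant, pc.n_neither):
        if k > 0:
            ll += k * np.log(k / n)
    return ll


def _counts_nll(theta, pc: PairCounts, method):
    _, inv = _assoc_transform(method)
    q = expit(theta[0])
    assoc = inv(theta[1])
    p11, pd_, p00 = _cells_exchangeable(q, assoc, method)
    if min(p11, pd_, p00) <= 0:
        return np.inf
    return -(
        pc.n_concordant * np.log(p11)
        + pc.n_discordant * np.log(pd_)
        + pc.n_neither * np.log(p00)
    )


def _plugin_assoc(pc: PairCounts, method) -> float:
    if method == "casewise":
        return casewise_concordance(pc).estimate
    if method == "correlation":
        return pair_correlation(pc).estimate
    est = pair_odds_ratio(pc).estimate
    return est


def _minimize(nll, x0, args=(), maxiter=20000):
    res = optimize.minimize(
        nll, x0, args=args, method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=maxiter, maxfev=maxiter),
    )
    if not res.success:
        raise ConvergenceError(f"pair-likelihood fit failed: {res.message}", trace=res)
    return res


def _num_hessian(f, x, h=1e-5):
    x = np.asarray(x, dtype=float)
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def _pairs_nll(params, X, y1, y2, method):
    _, inv = _assoc_transform(method)
    beta = params[:-1]
    assoc = inv(params[-1])
    eta = X @ beta  # shape (n_pairs, 2)
    p1 = expit(eta[:, 0])
    p2 = expit(eta[:, 1])
    try:
        p11 = _cell_general(p1, p2, assoc, method)
    except ValidationError:
        return np.inf
    lower = np.maximum(0.0, p1 + p2 - 1)
    upper = np.minimum(p1, p2)
    if np.any(p11 <= lower + 1e-300) or np.any(p11 >= upper - 1e-300):
        # association pushes some pair outside the Frechet bounds
        if method != "odds_ratio":  # plackett cell is always interior
            return np.inf
    cell = np.where(
        (y1 == 1) & (y2 == 1), p11,
        np.where((y1 == 0) & (y2 == 0), 1 - p1 - p2 + p11,
                 np.where(y1 == 1, p1 - p11, p2 - p11)),
    )
    if np.any(cell <= 0):
        return np.inf
    return -float(np.sum(np.log(cell)))


def _design(pairs: pd.DataFrame):
    """Stack per-twin design matrices: columns (1, age, sex_female)."""
    n = len(pairs)
    X = np.empty((n, 2, 3))
    X[:, 0, 0] = X[:, 1, 0] = 1.0
    X[:, 0, 1] = pairs["age1"].to_numpy(float)
    X[:, 1, 1] = pairs["age2"].to_numpy(float)
    X[:, 0, 2] = pairs["sex1"].to_numpy(float)
    X[:, 1, 2] = pairs["sex2"].to_numpy(float)
    return X


def _counts_from_pairs(pairs: pd.DataFrame, method_tag="pairs") -> PairCounts:
    s = pairs["y1"].to_numpy(int) + pairs["y2"].to_numpy(int)
    return PairCounts(
        zygosity=method_tag, condition="", n_concordant=int((s == 2).sum()),
        n_discordant=int((s == 1).sum()), n_neither=int((s == 0).sum()),
    )


def fit_pair_model(pairs, method="casewise", adjusted=False) -> PairModelFit:
    """Fit the exchangeable pair likelihood by maximum likelihood.

    ``pairs`` is either a :class:`PairCounts` (unadjusted only) or a
    DataFrame from :func:`twinstats.cohort.build_pair_table`.  Unadjusted
    fits estimate a constant marginal affection probability ``q`` and the
    association parameter; adjusted fits give each twin a marginal
    ``expit(b0 + b_age*age + b_sex*female)``.  SEs come from the observed
    information (numerical Hessian on the working scale, delta-transformed).
    """
    if isinstance(pairs, PairCounts):
        if adjusted:
            raise ValidationError("adjusted fits need per-twin covariates, not counts")
        pc = pairs
    elif not adjusted:
        pc = _counts_from_pairs(pairs)
    else:
        pc = None

    trans, inv = _assoc_transform(method)

    if pc is not None:
        a0 = _plugin_assoc(pc, method)
        if not np.isfinite(a0) or (method == "odds_ratio" and a0 <= 0):
            raise ValidationError("boundary association; no interior MLE to fit")
        x0 = np.array([logit(pc.prevalence), trans(a0)])
        res = _minimize(_counts_nll, x0, args=(pc, method))
        theta = res.x
        nll = lambda t: _counts_nll(t, pc, method)  # noqa: E731
        marginal = {"q": float(expit(theta[0]))}
        n_pairs = pc.n_pairs
    else:
        X = _design(pairs)
        y1 = pairs["y1"].to_numpy(int)
        y2 = pairs["y2"].to_numpy(int)
        pc0 = _counts_from_pairs(pairs)
        a0 = _plugin_assoc(pc0, method)
        if not np.isfinite(a0) or (method == "odds_ratio" and a0 <= 0):
            raise ValidationError("boundary association; no interior MLE to fit")
        x0 = np.array([logit(pc0.prevalence), 0.0, 0.0, trans(a0)])
        res = _minimize(_pairs_nll, x0, args=(X, y1, y2, method))
        theta = res.x
        nll = lambda t: _pairs_nll(t, X, y1, y2, method)  # noqa: E731
        marginal = {
            "intercept": float(theta[0]),
            "beta_age": float(theta[1]),
            "beta_sex": float(theta[2]),
        }
        n_pairs = len(pairs)

    H = _num_hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
        var_w = max(float(cov[-1, -1]), 0.0)
    except np.linalg.LinAlgError:
        var_w = np.nan
    assoc = float(inv(theta[-1]))
    # delta method back to the natural scale
    if method == "casewise":
        deriv = assoc * (1 - assoc)
    elif method == "correlation":
        deriv = 1 - assoc ** 2
    else:
        deriv = assoc
    se = float(np.sqrt(var_w) * abs(deriv)) if np.isfinite(var_w) else np.nan
    return PairModelFit(
        method=method, association=assoc, association_se=se, marginal=marginal,
        loglik=-float(res.fun), n_pairs=n_pairs, adjusted=adjusted,
        converged=bool(res.success),
    )


def lr_test_zygosity(mz, dz, method="casewise", adjusted=False) -> LRTestResult:
    """LR test of a common association parameter across MZ and DZ pairs.

    The unconstrained model fits each zygosity its own marginal parameters
    and association; the constrained model shares the association while
    keeping separate marginals (1 df).  Inputs are :class:`PairCounts`
    (unadjusted) or pair tables from ``build_pair_table``.
    """
    trans, inv = _assoc_transform(method)

    if isinstance(mz, PairCounts) and isinstance(dz, PairCounts) and not adjusted:
        ll_u = _saturated_loglik(mz) + _saturated_loglik(dz)

        def nll_c(theta):
            return _counts_nll(theta[[0, 2]], mz, method) + _counts_nll(
                theta[[1, 2]], dz, method
            )

        a_mz = _plugin_assoc(mz, method)
        a_dz = _plugin_assoc(dz, method)
        if method == "odds_ratio":
            a0 = np.sqrt(max(a_mz, 1e-6) * max(a_dz, 1e-6))
            if not np.isfinite(a0):
                a0 = max(a_mz, a_dz, 1.0)
                if not np.isfinite(a0):
                    a0 = 1.0
        else:
            a0 = (a_mz + a_dz) / 2
        x0 = np.array([logit(mz.prevalence), logit(dz.prevalence), trans(a0)])
        res = _minimize(lambda t: nll_c(np.asarray(t)), x0)
        ll_c = -float(res.fun)
    else:
        if isinstance(mz, PairCounts) or isinstance(dz, PairCounts):
            raise ValidationError("adjusted LR tests need pair tables, not counts")
        fit_mz = fit_pair_model(mz, method, adjusted)
        fit_dz = fit_pair_model(dz, method, adjusted)
        ll_u = fit_mz.loglik + fit_dz.loglik

        X_mz, X_dz = _design(mz), _design(dz)
        ym1, ym2 = mz["y1"].to_numpy(int), mz["y2"].to_numpy(int)
        yd1, yd2 = dz["y1"].to_numpy(int), dz["y2"].to_numpy(int)
        k = 3 if adjusted else 1

        if adjusted:
            def nll_c(theta):
                tm = np.concatenate([theta[:k], theta[[-1]]])
                td = np.concatenate([theta[k:2 * k], theta[[-1]]])
                return _pairs_nll(tm, X_mz, ym1, ym2, method) + _pairs_nll(
                    td, X_dz, yd1, yd2, method
                )
            m_mz, m_dz = fit_mz.marginal, fit_dz.marginal
            x0 = np.array([
                m_mz["intercept"], m_mz["beta_age"], m_mz["beta_sex"],
                m_dz["intercept"], m_dz["beta_age"], m_dz["beta_sex"],
                trans((fit_mz.association + fit_dz.association) / 2)
                if method != "odds_ratio"
                else trans(np.sqrt(fit_mz.association * fit_dz.association)),
            ])
        else:
            pc_mz, pc_dz = _counts_from_pairs(mz), _counts_from_pairs(dz)

            def nll_c(theta):
                t = np.asarray(theta)
                return _counts_nll(t[[0, 2]], pc_mz, method) + _counts_nll(
                    t[[1, 2]], pc_dz, method
                )
            a0 = (
                trans((fit_mz.association + fit_dz.association) / 2)
                if method != "odds_ratio"
                else trans(np.sqrt(fit_mz.association * fit_dz.association))
            )
            x0 = np.array([logit(pc_mz.prevalence), logit(pc_dz.prevalence), a0])

        res = _minimize(lambda t: nll_c(np.asarray(t)), x0)
        ll_c = -float(res.fun)

    stat = max(2 * (ll_u - ll_c), 0.0)
    if 2 * (ll_u - ll_c) < -1e-6:
        raise ConvergenceError(
            f"constrained log-likelihood exceeds unconstrained by {ll_c - ll_u:.2e}"
        )
    p = float(stats.chi2.sf(stat, 1))
    return LRTestResult(
        statistic=float(stat), df=1, p_value=p,
        loglik_unconstrained=float(ll_u), loglik_constrained=float(ll_c),
        method=method, adjusted=adjusted,
    )
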