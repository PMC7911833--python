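"""Liability-threshold ACE simulation of twin-family cohorts.

Each family member carries a standard-normal latent liability per condition,
decomposed into additive-genetic (A), shared-environment (C) and unique-
environment (E) fractions ``a2 + c2 + e2 = 1``.  Between-member liability
correlations follow the classical twin-family kinship structure:

* additive-genetic correlation 1 between MZ co-twins; 0.5 between DZ
  co-twins, between a twin and the sibling, and between parent and child;
  0 between spouses;
* shared-environment correlation 1 among the co-resident children, a
  configurable value (default 0) between parents and children, 0 between
  the parents themselves.

An individual is affected when liability (plus optional probit-scale age
and sex shifts) exceeds the threshold set by the condition's lifetime
prevalence ``K``.  The equal-environments assumption of the classical twin
design is built in: MZ and DZ pairs receive the same ``c2``, so any excess
MZ similarity is attributable to A.

The module also provides closed-form oracles — expected casewise
concordance from the bivariate-normal orthant probability, and its numeric
inverse (a tetrachoric-style correlation estimate) — used to validate the
generator and the estimators against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from twinstats.cohort import CONDITIONS
from twinstats.errors import ValidationError

#: family member order used in all covariance matrices
MEMBERS = ("twin1", "twin2", "oldest_sibling", "mother", "father")

# demographic anchors for cosmetic realism (volunteer twin-family registry):
# twins 3-18y, mothers ~N(42.6, 6.3) on 24-64, fathers ~N(44.8, 6.5) on 26-69
_TWIN_AGE_RANGE = (3.0, 18.0)
_MOTHER_AGE = (42.6, 6.3, 24.0, 64.0)
_FATHER_AGE = (44.8, 6.5, 26.0, 69.0)
_FEMALE_FRACTION = 0.512
_PROP_MZ = 0.495


@dataclass(frozen=True)
class ACEParams:
    """Variance fractions and prevalence for one condition's liability.

    ``beta_age`` and ``beta_sex`` shift the threshold on the probit scale
    per centred year of age and for females respectively; they default to
    zero (no calibrated covariate effects are assumed).
    """

    a2: float
    c2: float
    prevalence: float
    beta_age: float = 0.0
    beta_sex: float = 0.0

    def __post_init__(self):
        if self.a2 < 0 or self.c2 < 0 or self.a2 + self.c2 > 1 + 1e-12:
            raise ValidationError("need a2, c2 >= 0 and a2 + c2 <= 1")
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must lie in (0, 1)")

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level settings: size, composition, missingness, seed."""

    n_families: int = 1000
    prop_mz: float = _PROP_MZ
    female_fraction: float = _FEMALE_FRACTION
    missing_rate: float = 0.0
    parent_child_c: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("SimConfig requires an explicit seed")
        for name in ("prop_mz", "female_fraction", "missing_rate", "parent_child_c"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_families < 1:
            raise ValidationError("n_families must be positive")


def _kinship_matrix(zygosity: str) -> np.ndarray:
    k = np.array(
        [
            [1.0, 0.5, 0.5, 0.5, 0.5],
            [0.5, 1.0, 0.5, 0.5, 0.5],
            [0.5, 0.5, 1.0, 0.5, 0.5],
            [0.5, 0.5, 0.5, 1.0, 0.0],
            [0.5, 0.5, 0.5, 0.0, 1.0],
        ]
    )
    if zygosity == "MZ":
        k[0, 1] = k[1, 0] = 1.0
    elif zygosity != "DZ":
        raise ValidationError(f"zygosity must be MZ or DZ, got '{zygosity}'")
    return k


def _shared_env_matrix(parent_child_c: float) -> np.ndarray:
    c = np.eye(5)
    c[np.ix_(range(3), range(3))] = 1.0  # co-resident children share C fully
    for child in range(3):
        for parent in (3, 4):
            c[child, parent] = c[parent, child] = parent_child_c
    return c


def kinship_liability_cov(params: ACEParams, zygosity: str,
                          parent_child_c: float = 0.0) -> np.ndarray:
    """5x5 liability correlation matrix over (twin1, twin2, sibling, mother,
    father) implied by the ACE fractions and the kinship structure."""
    cov = (
        params.a2 * _kinship_matrix(zygosity)
        + params.c2 * _shared_env_matrix(parent_child_c)
        + params.e2 * np.eye(5)
    )
    if np.linalg.eigvalsh(cov).min() < -1e-9:
        raise ValidationError("liability covariance is not positive semidefinite")
    return cov


def threshold_from_prevalence(prevalence: float) -> float:
    """Upper-tail normal quantile: affected iff liability > tau."""
    if not 0 < prevalence < 1:
        raise ValidationError("prevalence must lie in (0, 1)")
    return float(stats.norm.isf(prevalence))


def _orthant_both_above(tau: float, r: float) -> float:
    """P(X > tau, Y > tau) for standard bivariate normal with correlation r."""
    r = min(max(r, -1.0), 1.0)
    if r >= 1 - 1e-12:
        return float(stats.norm.sf(tau))
    if r <= -1 + 1e-12:
        return float(max(0.0, 1 - 2 * stats.norm.cdf(tau)))
    bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    # P(X>tau, Y>tau) = P(-X < -tau... ) = CDF at (-tau, -tau) by symmetry
    return float(bvn.cdf([-tau, -tau]))


def liability_correlation(params: ACEParams, zygosity: str) -> float:
    """Co-twin liability correlation: a2 * kinship + c2."""
    kin = 1.0 if zygosity == "MZ" else 0.5
    if zygosity not in ("MZ", "DZ"):
        raise ValidationError(f"zygosity must be MZ or DZ, got '{zygosity}'")
    return params.a2 * kin + params.c2


def expected_casewise(params: ACEParams, zygosity: str) -> float:
    """Model-implied casewise concordance ``P(both affected)/K``.

    Computed from the bivariate-normal upper-orthant probability at the
    co-twin liability correlation; no covariate shifts.
    """
    k = params.prevalence
    tau = threshold_from_prevalence(k)
    r = liability_correlation(params, zygosity)
    return _orthant_both_above(tau, r) / k


def tetrachoric_from_concordance(concordance: float, prevalence: float) -> float:
    """Invert the orthant oracle: liability correlation from an observed
    casewise concordance at known prevalence."""
    if not 0 < prevalence < 1:
        raise ValidationError("prevalence must lie in (0, 1)")
    tau = threshold_from_prevalence(prevalence)

    def f(r):
        return _orthant_both_above(tau, r) / prevalence - concordance

    lo, hi = -0.999, 0.999
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError("concordance outside the attainable range")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _as_params_dict(params) -> dict:
    if isinstance(params, ACEParams):
        return {c: params for c in CONDITIONS}
    if not params:
        raise ValidationError("no conditions given")
    return dict(params)


def _liability_cov_multi(params_list, zygosity, parent_child_c, genetic_corr):
    """(5m x 5m) covariance across m conditions and 5 members.

    The additive-genetic block couples conditions through ``genetic_corr``;
    shared- and unique-environment components stay condition-specific.
    """
    m = len(params_list)
    kin = _kinship_matrix(zygosity)
    cmat = _shared_env_matrix(parent_child_c)
    a = np.array([p.a2 for p in params_list])
    c = np.array([p.c2 for p in params_list])
    e = np.array([p.e2 for p in params_list])
    g = np.asarray(genetic_corr, dtype=float)
    cov = np.kron(g * np.sqrt(np.outer(a, a)), kin)
    cov += np.kron(np.diag(c), cmat)
    cov += np.kron(np.diag(e), np.eye(5))
    if np.linalg.eigvalsh(cov).min() < -1e-9:
        raise ValidationError("cross-condition liability covariance is not PSD")
    return cov + 1e-12 * np.eye(5 * m)


def simulate_cohort(params, config: SimConfig, genetic_corr=None) -> pd.DataFrame:
    """Generate a synthetic twin-family cohort in the long cohort dialect.

    ``params`` is one :class:`ACEParams` applied to every default condition,
    or a mapping condition -> ACEParams.  ``genetic_corr`` optionally couples
    the conditions' additive-genetic components (symmetric PSD matrix with
    unit diagonal, default identity).  Output is deterministic given
    ``config.seed``.
    """
    pdict = _as_params_dict(params)
    conds = list(pdict)
    plist = [pdict[c] for c in conds]
    m = len(conds)
    if genetic_corr is None:
        genetic_corr = np.eye(m)
    genetic_corr = np.asarray(genetic_corr, dtype=float)
    if genetic_corr.shape != (m, m) or not np.allclose(genetic_corr, genetic_corr.T):
        raise ValidationError("genetic_corr must be a symmetric m x m matrix")
    if not np.allclose(np.diag(genetic_corr), 1.0):
        raise ValidationError("genetic_corr must have unit diagonal")

    rng = np.random.default_rng(config.seed)
    nf = config.n_families
    is_mz = rng.random(nf) < config.prop_mz

    # demographics ---------------------------------------------------------
    lo, hi = _TWIN_AGE_RANGE
    twin_age = np.round(rng.uniform(lo, hi, nf), 1)
    sib_age = np.round(twin_age + rng.uniform(1.0, 8.0, nf), 1)
    mo_age = np.round(
        np.clip(rng.normal(_MOTHER_AGE[0], _MOTHER_AGE[1], nf),
                _MOTHER_AGE[2], _MOTHER_AGE[3]), 1)
    fa_age = np.round(
        np.clip(rng.normal(_FATHER_AGE[0], _FATHER_AGE[1], nf),
                _FATHER_AGE[2], _FATHER_AGE[3]), 1)

    twin1_fem = rng.random(nf) < config.female_fraction
    twin2_fem_dz = rng.random(nf) < config.female_fraction
    twin2_fem = np.where(is_mz, twin1_fem, twin2_fem_dz)  # MZ pairs same-sex
    sib_fem = rng.random(nf) < config.female_fraction

    ages = np.column_stack([twin_age, twin_age, sib_age, mo_age, fa_age])
    female = np.column_stack(
        [twin1_fem, twin2_fem, sib_fem, np.ones(nf, bool), np.zeros(nf, bool)]
    ).astype(float)

    # liabilities ----------------------------------------------------------
    chol = {
        z: np.linalg.cholesky(
            _liability_cov_multi(plist, z, config.parent_child_c, genetic_corr)
        )
        for z in ("MZ", "DZ")
    }
    zvals = rng.standard_normal((nf, 5 * m))
    liab = np.empty_like(zvals)
    mz_mask = is_mz
    liab[mz_mask] = zvals[mz_mask] @ chol["MZ"].T
    liab[~mz_mask] = zvals[~mz_mask] @ chol["DZ"].T
    liab = liab.reshape(nf, m, 5)

    # covariate shifts on the probit scale, ages centred per role so that
    # marginal prevalence stays at K when betas are zero-mean over the cohort
    age_centred = ages - ages.mean(axis=0, keepdims=True)
    status = np.empty((nf, m, 5), dtype=np.int8)
    for j, p in enumerate(plist):
        tau = threshold_from_prevalence(p.prevalence)
        shift = p.beta_age * age_centred + p.beta_sex * (female - 0.5)
        status[:, j, :] = (liab[:, j, :] + shift > tau).astype(np.int8)

    # missingness ----------------------------------------------------------
    miss = (
        rng.random((nf, m, 5)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((nf, m, 5), bool)
    )

    # assemble long table --------------------------------------------------
    width = len(str(nf))
    fam_ids = np.array([f"F{i:0{width}d}" for i in range(1, nf + 1)])
    zyg = np.where(is_mz, "MZ", "DZ")
    frames = []
    for r, role in enumerate(MEMBERS):
        rec = {
            "family_id": fam_ids,
            "role": role,
            "zygosity": zyg if role in ("twin1", "twin2") else "NA",
            "sex": np.where(female[:, r] == 1, "female", "male"),
            "age": ages[:, r],
        }
        for j, cond in enumerate(conds):
            col = status[:, j, r].astype("float")
            col[miss[:, j, r]] = np.nan
            rec[cond] = col
        frames.append(pd.DataFrame(rec))
    out = pd.concat(frames, ignore_index=True)
    order = {role: i for i, role in enumerate(MEMBERS)}
    out = out.sort_values(
        ["family_id", "role"], key=lambda s: s.map(order) if s.name == "role" else s
    ).reset_index(drop=True)
    for cond in conds:
        out[cond] = out[cond].astype("Int8")
    return out
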