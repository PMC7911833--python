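"""Cohort data model and reductions.

A cohort is a long-format table with one row per family member.  Columns:

    family_id, role, zygosity, sex, age, <one 0/1/NA column per condition>

Roles are ``twin1``, ``twin2``, ``oldest_sibling``, ``mother``, ``father``;
zygosity is ``MZ``/``DZ`` for twins and ``NA`` for everyone else.  Condition
statuses are lifetime binary indicators; ``NA`` marks a missing response and
is never imputed — each analysis deletes incomplete units on its own terms
(complete pairs for twin-similarity work, complete five-member families for
the aggregation models), which is why sample sizes legitimately differ
between analyses.

This module reduces individual records to the two structures the estimators
consume: per-zygosity pair counts ``(N_c, N_d, N_00)`` and one-row-per-family
index-twin tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from twinstats.errors import ValidationError

logger = logging.getLogger(__name__)

#: Default condition identifiers: growing pains, migraine, non-migraine
#: headache, recurrent abdominal pain, low back pain, persistent pain (NOS).
CONDITIONS = ("gp", "migraine", "headache", "rap", "lbp", "pp")

ROLES = ("twin1", "twin2", "oldest_sibling", "mother", "father")
TWIN_ROLES = ("twin1", "twin2")
ZYGOSITIES = ("MZ", "DZ")
SEXES = ("female", "male")

_BASE_COLUMNS = ("family_id", "role", "zygosity", "sex", "age")


@dataclass(frozen=True)
class MemberRecord:
    """One family member: identity, demographics, and per-condition status.

    ``status`` maps condition id to 1 (affected), 0 (unaffected) or None
    (missing).
    """

    family_id: str
    role: str
    zygosity: str
    sex: str
    age: float
    status: dict


@dataclass(frozen=True)
class PairCounts:
    """Per-zygosity trio of twin-pair counts for one condition.

    ``n_concordant`` (N_c) pairs have both twins affected, ``n_discordant``
    (N_d) exactly one, ``n_neither`` (N_00) neither.  Pairs with a missing
    status in either twin are excluded and tallied in ``n_excluded``.
    """

    zygosity: str
    condition: str
    n_concordant: int
    n_discordant: int
    n_neither: int
    n_excluded: int = 0

    def __post_init__(self):
        if min(self.n_concordant, self.n_discordant, self.n_neither) < 0:
            raise ValidationError("pair counts must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.n_concordant + self.n_discordant + self.n_neither

    @property
    def prevalence(self) -> float:
        """Individual-level affection probability among complete pairs."""
        return (2 * self.n_concordant + self.n_discordant) / (2 * self.n_pairs)


@dataclass(frozen=True)
class DoubleEntryTable:
    """Symmetric twin-by-co-twin 2x2 table with every pair entered twice.

    Cell ``a`` counts (affected, affected) orderings, ``b`` and ``c`` the two
    discordant orderings, ``d`` (unaffected, unaffected); b == c by
    construction.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _validate_frame(df: pd.DataFrame, conditions) -> pd.DataFrame:
    for col in _BASE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column '{col}'")
    extra = [c for c in df.columns if c not in _BASE_COLUMNS and c not in conditions]
    if extra:
        raise ValidationError(
            f"unknown condition column(s) {extra}; declared schema is {list(conditions)}"
        )
    for cond in conditions:
        if cond not in df.columns:
            raise ValidationError(f"missing condition column '{cond}'")

    df = df.copy()
    df["family_id"] = df["family_id"].astype(str)
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        if row["role"] not in ROLES:
            raise ValidationError(f"row {rowno}: invalid role '{row['role']}'")
        if row["role"] in TWIN_ROLES:
            if row["zygosity"] not in ZYGOSITIES:
                raise ValidationError(
                    f"row {rowno}: twin zygosity must be MZ or DZ, got '{row['zygosity']}'"
                )
        elif row["zygosity"] != "NA":
            raise ValidationError(
                f"row {rowno}: non-twin zygosity must be 'NA', got '{row['zygosity']}'"
            )
        if row["sex"] not in SEXES:
            raise ValidationError(f"row {rowno}: invalid sex '{row['sex']}'")
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValidationError(f"row {rowno}: age '{row['age']}' is not a number")
        if not np.isfinite(age) or age < 0:
            raise ValidationError(f"row {rowno}: age must be a non-negative number")

    dup = df.duplicated(subset=["family_id", "role"])
    if dup.any():
        fam, role = df.loc[dup.idxmax(), ["family_id", "role"]]
        raise ValidationError(f"duplicate record for family '{fam}' role '{role}'")

    # twins of a family must agree on zygosity
    twins = df[df["role"].isin(TWIN_ROLES)]
    nzyg = twins.groupby("family_id")["zygosity"].nunique()
    bad = nzyg[nzyg > 1]
    if len(bad):
        raise ValidationError(
            f"family '{bad.index[0]}': twin1 and twin2 disagree on zygosity"
        )

    df["age"] = df["age"].astype(float)
    for cond in conditions:
        vals = df[cond]
        mask = vals.notna()
        ok = vals[mask].isin([0, 1, 0.0, 1.0, "0", "1"])
        if not ok.all():
            rowno = ok[~ok].index[0] + 2
            raise ValidationError(
                f"row {rowno}: condition '{cond}' must be 0, 1 or NA, got "
                f"'{vals[ok[~ok].index[0]]}'"
            )
        df[cond] = vals.astype("Float64").astype("Int8")
    return df.reset_index(drop=True)


def read_cohort(path, conditions=CONDITIONS) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    ``conditions`` declares the expected condition columns; columns outside
    the schema are rejected.  Pass ``None`` to take every non-core column as
    a condition.  Returns a DataFrame with one row per member; condition
    columns use the nullable ``Int8`` dtype so missing responses stay
    missing.
    """
    try:
        df = pd.read_csv(
            path, keep_default_na=False, na_values=["NA"], dtype={"family_id": str}
        )
    except FileNotFoundError:
        raise ValidationError(f"cohort file not found: {path}")
    if "zygosity" in df.columns:
        # 'NA' in the zygosity column is a category, not missingness
        df["zygosity"] = df["zygosity"].fillna("NA")
    if conditions is None:
        conditions = [c for c in df.columns if c not in _BASE_COLUMNS]
        if not conditions:
            raise ValidationError("cohort file declares no condition columns")
    return _validate_frame(df, conditions)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV in the canonical dialect (0/1/NA cells)."""
    out = df.copy()
    conds = [c for c in out.columns if c not in _BASE_COLUMNS]
    for cond in conds:
        out[cond] = out[cond].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, lineterminator="\n")


def cohort_to_records(df: pd.DataFrame, conditions=None) -> list[MemberRecord]:
    """Explode a cohort frame into one ``MemberRecord`` per row."""
    conditions = conditions or [c for c in df.columns if c not in _BASE_COLUMNS]
    records = []
    for _, row in df.iterrows():
        status = {
            c: (None if pd.isna(row[c]) else int(row[c])) for c in conditions
        }
        records.append(
            MemberRecord(
                family_id=row["family_id"],
                role=row["role"],
                zygosity=row["zygosity"],
                sex=row["sex"],
                age=float(row["age"]),
                status=status,
            )
        )
    return records


def _twin_wide(df: pd.DataFrame, condition: str, zygosity: str) -> pd.DataFrame:
    """One row per twin pair of the requested zygosity, statuses side by side."""
    twins = df[(df["role"].isin(TWIN_ROLES)) & (df["zygosity"] == zygosity)]
    if twins.empty:
        raise ValidationError(f"no twin pairs with zygosity '{zygosity}'")
    wide = twins.pivot(index="family_id", columns="role", values=condition)
    for role in TWIN_ROLES:
        if role not in wide.columns:
            wide[role] = pd.array([pd.NA] * len(wide), dtype="Int8")
    return wide[list(TWIN_ROLES)]


def build_pair_counts(df: pd.DataFrame, condition: str, zygosity: str) -> PairCounts:
    """Classify complete twin pairs into (N_c, N_d, N_00) for one condition.

    A pair is complete when both twins have a non-missing status; incomplete
    pairs (including singleton twins) are excluded and counted separately.
    """
    wide = _twin_wide(df, condition, zygosity)
    complete = wide.dropna()
    s = complete["twin1"].astype(int) + complete["twin2"].astype(int)
    return PairCounts(
        zygosity=zygosity,
        condition=condition,
        n_concordant=int((s == 2).sum()),
        n_discordant=int((s == 1).sum()),
        n_neither=int((s == 0).sum()),
        n_excluded=int(len(wide) - len(complete)),
    )


def double_enter(pc: PairCounts) -> DoubleEntryTable:
    """Expand pair counts into the symmetric double-entry 2x2 table."""
    return DoubleEntryTable(
        a=2 * pc.n_concordant,
        b=pc.n_discordant,
        c=pc.n_discordant,
        d=2 * pc.n_neither,
    )


def build_pair_table(df: pd.DataFrame, condition: str, zygosity: str) -> pd.DataFrame:
    """One row per complete twin pair with statuses and per-twin covariates.

    Columns: family_id, y1, y2, age1, age2, sex1, sex2 (sex coded female=1).
    This is the input for covariate-adjusted pair-likelihood fits.
    """
    twins = df[(df["role"].isin(TWIN_ROLES)) & (df["zygosity"] == zygosity)]
    if twins.empty:
        raise ValidationError(f"no twin pairs with zygosity '{zygosity}'")
    cols = {}
    for value, name in ((condition, "y"), ("age", "age"), ("sex", "sex")):
        wide = twins.pivot(index="family_id", columns="role", values=value)
        for i, role in enumerate(TWIN_ROLES, start=1):
            cols[f"{name}{i}"] = wide[role] if role in wide.columns else pd.NA
    out = pd.DataFrame(cols)
    out = out.dropna(subset=["y1", "y2"])
    out = out.reset_index()
    out["y1"] = out["y1"].astype(int)
    out["y2"] = out["y2"].astype(int)
    out["sex1"] = (out["sex1"] == "female").astype(int)
    out["sex2"] = (out["sex2"] == "female").astype(int)
    out["age1"] = out["age1"].astype(float)
    out["age2"] = out["age2"].astype(float)
    return out


def select_index_twins(df: pd.DataFrame, condition: str, seed: int) -> pd.DataFrame:
    """Pick one index twin per complete family, uniformly at random.

    Only families in which all five members (both twins, oldest sibling,
    mother, father) have a non-missing status for ``condition`` are eligible;
    the number of dropped families is logged and stored in
    ``result.attrs['n_dropped']``.  The same seed always yields the same
    selection.
    """
    if seed is None:
        raise ValidationError("select_index_twins requires an explicit seed")
    rng = np.random.default_rng(seed)

    status = df.pivot(index="family_id", columns="role", values=condition)
    for role in ROLES:
        if role not in status.columns:
            status[role] = pd.array([pd.NA] * len(status), dtype="Int8")
    complete = status[list(ROLES)].dropna()
    n_dropped = len(status) - len(complete)
    logger.info(
        "select_index_twins(%s): %d complete families, %d dropped",
        condition, len(complete), n_dropped,
    )

    complete = complete.sort_index()
    pick_twin2 = rng.random(len(complete)) < 0.5

    meta = df[df["role"].isin(TWIN_ROLES)].set_index(["family_id", "role"])
    rows = []
    for (fam, statuses), second in zip(complete.iterrows(), pick_twin2):
        idx_role, co_role = ("twin2", "twin1") if second else ("twin1", "twin2")
        m = meta.loc[(fam, idx_role)]
        rows.append(
            {
                "family_id": fam,
                "index_role": idx_role,
                "zygosity": m["zygosity"],
                "index_status": int(statuses[idx_role]),
                "cotwin_status": int(statuses[co_role]),
                "sibling_status": int(statuses["oldest_sibling"]),
                "mother_status": int(statuses["mother"]),
                "father_status": int(statuses["father"]),
                "index_sex": int(m["sex"] == "female"),
                "index_age": float(m["age"]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped
    out.attrs["condition"] = condition
    return out


@dataclass(frozen=True)
class PrevalenceResult:
    """Lifetime prevalence among twin individuals of one zygosity."""

    condition: str
    zygosity: str
    n_affected: int
    n_unaffected: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_affected / (self.n_affected + self.n_unaffected)


def prevalence_table(df: pd.DataFrame, condition: str, zygosity: str) -> PrevalenceResult:
    """Count affected/unaffected twin individuals of one zygosity.

    Individuals are counted regardless of whether their co-twin responded,
    so singleton responders contribute here even though they are excluded
    from pair analyses.  Missing statuses are excluded from the denominator.
    """
    twins = df[(df["role"].isin(TWIN_ROLES)) & (df["zygosity"] == zygosity)]
    vals = twins[condition].dropna()
    n_aff = int((vals == 1).sum())
    n_un = int((vals == 0).sum())
    if n_aff + n_un == 0:
        raise ValidationError(
            f"no non-missing '{condition}' statuses for {zygosity} twins"
        )
    return PrevalenceResult(condition, zygosity, n_aff, n_un)


def pair_counts_from_tuple(nc: int, nd: int, n00: int,
                           zygosity: str = "MZ", condition: str = "gp") -> PairCounts:
    """Convenience constructor from a bare (N_c, N_d, N_00) triple."""
    return PairCounts(zygosity, condition, nc, nd, n00)
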