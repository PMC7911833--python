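"""End-to-end pipeline and table rendering.

``run_pipeline`` drives a whole analysis (load or simulate a cohort, compute
prevalence contrasts, twin-similarity estimates with LR tests, and family
association scans) and writes the four standard table layouts plus a run
manifest.  Rendering follows the conventions of the study's tables:
percentages to 3 significant figures, estimates to 2 decimals, odds ratios
to 3 significant figures, p-values to 3 decimals with "<0.001" below that.
Rounding is half-away-from-zero.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from twinstats import cohort as cio
from twinstats import famassoc, similarity, simulate
from twinstats.errors import PipelineError, ValidationError

LAYOUTS = ("t1", "t3", "t4", "t5")

ANALYSES = ("prevalence", "similarity", "family_association")


# ---------------------------------------------------------------------------
# formatting
# ---------------------------------------------------------------------------

def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (5 always rounds outward)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def fmt_decimals(x, nd=2) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "inf" if x == math.inf else ""
    return f"{round_half_away(float(x), nd):.{nd}f}"


def fmt_sig3(x) -> str:
    """Three significant figures, half-away-from-zero (e.g. 16.4, 6.95)."""
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "inf" if x == math.inf else ""
    x = float(x)
    if x == 0:
        return "0.00"
    nd = 2 - int(math.floor(math.log10(abs(x))))
    r = round_half_away(x, nd)
    # re-derive in case rounding bumped the magnitude (9.99 -> 10.0)
    nd = max(2 - int(math.floor(math.log10(abs(r)))), 0)
    return f"{round_half_away(x, nd):.{nd}f}"


def fmt_p(p) -> str:
    if p is None or not math.isfinite(p):
        return ""
    if p < 0.001:
        return "<0.001"
    return f"{round_half_away(float(p), 3):.3f}"


def fmt_ci(lo, hi, nd=2) -> str:
    return f"({fmt_decimals(lo, nd)}, {fmt_decimals(hi, nd)})"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_T1_COLS = ["condition", "mz_yes", "mz_no", "mz_pct", "dz_yes", "dz_no",
            "dz_pct", "or", "ci95", "p"]
_T3_COLS = ["condition", "mz_nc", "mz_nd", "mz_n00", "c_mz", "ci95_mz",
            "dz_nc", "dz_nd", "dz_n00", "c_dz", "ci95_dz", "p"]
_T4_COLS = ["condition", "corr_mz", "corr_ci_mz", "corr_dz", "corr_ci_dz",
            "corr_p_unadj", "corr_p_adj", "or_mz", "or_ci_mz", "or_dz",
            "or_ci_dz", "or_p_unadj", "or_p_adj"]
_T5_COLS = ["condition", "analysis", "n", "cotwin_or", "cotwin_p",
            "sibling_or", "sibling_p", "mother_or", "mother_p",
            "father_or", "father_p"]


def _render_t1(rows):
    out = []
    for r in rows:
        out.append({
            "condition": r["condition"],
            "mz_yes": r["mz_yes"], "mz_no": r["mz_no"],
            "mz_pct": fmt_sig3(r["mz_pct"]),
            "dz_yes": r["dz_yes"], "dz_no": r["dz_no"],
            "dz_pct": fmt_sig3(r["dz_pct"]),
            "or": fmt_sig3(r.get("or")),
            "ci95": fmt_ci(*r["ci95"]) if r.get("ci95") else "",
            "p": fmt_p(r.get("p")),
        })
    return out


def _render_t3(rows):
    out = []
    for r in rows:
        out.append({
            "condition": r["condition"],
            "mz_nc": r["mz_counts"][0], "mz_nd": r["mz_counts"][1],
            "mz_n00": r["mz_counts"][2],
            "c_mz": fmt_decimals(r["c_mz"]), "ci95_mz": fmt_ci(*r["ci95_mz"]),
            "dz_nc": r["dz_counts"][0], "dz_nd": r["dz_counts"][1],
            "dz_n00": r["dz_counts"][2],
            "c_dz": fmt_decimals(r["c_dz"]), "ci95_dz": fmt_ci(*r["ci95_dz"]),
            "p": fmt_p(r["p"]),
        })
    return out


def _render_t4(rows):
    out = []
    for r in rows:
        out.append({
            "condition": r["condition"],
            "corr_mz": fmt_decimals(r["corr_mz"]),
            "corr_ci_mz": fmt_ci(*r["corr_ci_mz"]),
            "corr_dz": fmt_decimals(r["corr_dz"]),
            "corr_ci_dz": fmt_ci(*r["corr_ci_dz"]),
            "corr_p_unadj": fmt_p(r["corr_p_unadj"]),
            "corr_p_adj": fmt_p(r.get("corr_p_adj")),
            "or_mz": fmt_sig3(r["or_mz"]),
            "or_ci_mz": fmt_ci(*map(float, r["or_ci_mz"]), nd=1)
            if all(map(math.isfinite, r["or_ci_mz"])) else "",
            "or_dz": fmt_sig3(r["or_dz"]),
            "or_ci_dz": fmt_ci(*map(float, r["or_ci_dz"]), nd=1)
            if all(map(math.isfinite, r["or_ci_dz"])) else "",
            "or_p_unadj": fmt_p(r["or_p_unadj"]),
            "or_p_adj": fmt_p(r.get("or_p_adj")),
        })
    return out


def _render_t5(rows):
    out = []
    for r in rows:
        rec = {"condition": r["condition"], "analysis": r["analysis"], "n": r["n"]}
        for m in famassoc.FAMILY_MEMBERS:
            rec[f"{m}_or"] = fmt_sig3(r.get(f"{m}_or"))
            rec[f"{m}_p"] = fmt_p(r.get(f"{m}_p"))
        out.append(rec)
    return out


_RENDERERS = {
    "t1": (_T1_COLS, _render_t1),
    "t3": (_T3_COLS, _render_t3),
    "t4": (_T4_COLS, _render_t4),
    "t5": (_T5_COLS, _render_t5),
}


def render_table(rows, layout: str) -> str:
    """Render analysis results in one of the four study table layouts."""
    if layout not in _RENDERERS:
        raise ValidationError(f"unknown layout '{layout}'; expected one of {LAYOUTS}")
    cols, renderer = _RENDERERS[layout]
    try:
        rendered = renderer(rows)
    except (KeyError, TypeError) as err:
        raise ValidationError(f"results do not match layout '{layout}': {err!r}")
    buf = io.StringIO()
    w = csv.DictWriter(buf, fieldnames=cols, lineterminator="\n")
    w.writeheader()
    for rec in rendered:
        w.writerow(rec)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    seed: int
    out_dir: str
    input: str | None = None
    simulate: dict | None = None
    conditions: tuple = cio.CONDITIONS
    analyses: tuple = ANALYSES
    covariate_policy: str = "when_significant"
    adjusted: bool = False

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        self.analyses = tuple(self.analyses)
        if not self.analyses:
            raise ValidationError("config must request at least one analysis")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValidationError(f"unknown analyses {sorted(unknown)}")
        if not self.conditions:
            raise ValidationError("config must list at least one condition")
        if (self.input is None) == (self.simulate is None):
            raise ValidationError("config needs exactly one of 'input' or 'simulate'")
        if self.seed is None:
            raise ValidationError("config requires a seed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError("config YAML must be a mapping")
        return cls(**raw)


def _load_cohort(config: RunConfig) -> tuple:
    if config.input is not None:
        df = cio.read_cohort(config.input, config.conditions)
        with open(config.input, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        return df, digest
    sim = dict(config.simulate)
    cond_params = {
        c: simulate.ACEParams(**p) for c, p in sim.pop("conditions").items()
    }
    sc = simulate.SimConfig(seed=config.seed, **sim)
    df = simulate.simulate_cohort(cond_params, sc)
    buf = io.StringIO()
    cio.write_cohort(df, buf)
    digest = hashlib.sha256(buf.getvalue().encode()).hexdigest()
    return df, digest


def _stage_prevalence(df, config):
    rows = []
    for cond in config.conditions:
        mz = cio.prevalence_table(df, cond, "MZ")
        dz = cio.prevalence_table(df, cond, "DZ")
        row = {
            "condition": cond,
            "mz_yes": mz.n_affected, "mz_no": mz.n_unaffected, "mz_pct": mz.percent,
            "dz_yes": dz.n_affected, "dz_no": dz.n_unaffected, "dz_pct": dz.percent,
        }
        try:
            fit = famassoc.zygosity_prevalence_or(
                df, cond, covariate_policy=config.covariate_policy
            )
            term = fit.term("mz")
            row["or"] = term.odds_ratio
            row["ci95"] = (
                math.exp(term.coef - 1.96 * term.se),
                math.exp(term.coef + 1.96 * term.se),
            )
            row["p"] = term.p_value
        except Exception:
            row["or"] = None
        rows.append(row)
    return rows


def _stage_similarity(df, config):
    t3, t4 = [], []
    for cond in config.conditions:
        mz = cio.build_pair_counts(df, cond, "MZ")
        dz = cio.build_pair_counts(df, cond, "DZ")
        c_mz = similarity.casewise_concordance(mz)
        c_dz = similarity.casewise_concordance(dz)
        lr_c = similarity.lr_test_zygosity(mz, dz, "casewise")
        t3.append({
            "condition": cond,
            "mz_counts": (mz.n_concordant, mz.n_discordant, mz.n_neither),
            "dz_counts": (dz.n_concordant, dz.n_discordant, dz.n_neither),
            "c_mz": c_mz.estimate, "ci95_mz": c_mz.ci95,
            "c_dz": c_dz.estimate, "ci95_dz": c_dz.ci95,
            "p": lr_c.p_value,
        })
        r_mz = similarity.pair_correlation(mz)
        r_dz = similarity.pair_correlation(dz)
        o_mz = similarity.pair_odds_ratio(mz)
        o_dz = similarity.pair_odds_ratio(dz)
        row = {
            "condition": cond,
            "corr_mz": r_mz.estimate, "corr_ci_mz": r_mz.ci95,
            "corr_dz": r_dz.estimate, "corr_ci_dz": r_dz.ci95,
            "corr_p_unadj": similarity.lr_test_zygosity(mz, dz, "correlation").p_value,
            "or_mz": o_mz.estimate, "or_ci_mz": o_mz.ci95,
            "or_dz": o_dz.estimate, "or_ci_dz": o_dz.ci95,
            "or_p_unadj": similarity.lr_test_zygosity(mz, dz, "odds_ratio").p_value,
        }
        if config.adjusted:
            pm = cio.build_pair_table(df, cond, "MZ")
            pdz = cio.build_pair_table(df, cond, "DZ")
            row["corr_p_adj"] = similarity.lr_test_zygosity(
                pm, pdz, "correlation", adjusted=True
            ).p_value
            row["or_p_adj"] = similarity.lr_test_zygosity(
                pm, pdz, "odds_ratio", adjusted=True
            ).p_value
        t4.append(row)
    return t3, t4


def _stage_famassoc(df, config):
    rows = []
    for cond in config.conditions:
        fam_rows = cio.select_index_twins(df, cond, seed=config.seed)
        if len(fam_rows) < 20:
            continue
        uni = famassoc.univariate_scan(
            fam_rows, covariate_policy=config.covariate_policy
        )
        rec = {"condition": cond, "analysis": "Univ", "n": len(fam_rows)}
        for m, fit in uni.items():
            if isinstance(fit, famassoc.RegressionFit):
                t = fit.term(f"{m}_status")
                rec[f"{m}_or"] = t.odds_ratio
                rec[f"{m}_p"] = t.p_value
        rows.append(rec)
        try:
            mult = famassoc.multivariate_model(
                fam_rows, covariate_policy=config.covariate_policy
            )
            rec = {"condition": cond, "analysis": "Mult", "n": len(fam_rows)}
            for m in famassoc.FAMILY_MEMBERS:
                t = mult.term(f"{m}_status")
                rec[f"{m}_or"] = t.odds_ratio
                rec[f"{m}_p"] = t.p_value
            rows.append(rec)
        except Exception:
            pass
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses and write the report bundle.

    Returns a mapping of output filename to its text content.  On any stage
    failure nothing is written (partial bundles never appear on disk).
    """
    outputs = {}
    try:
        df, digest = _load_cohort(config)
    except Exception as err:
        raise PipelineError("load_cohort", str(err))

    if "prevalence" in config.analyses:
        try:
            outputs["table1.csv"] = render_table(_stage_prevalence(df, config), "t1")
        except Exception as err:
            raise PipelineError("prevalence", str(err))
    if "similarity" in config.analyses:
        try:
            t3, t4 = _stage_similarity(df, config)
            outputs["table3.csv"] = render_table(t3, "t3")
            outputs["table4.csv"] = render_table(t4, "t4")
        except Exception as err:
            raise PipelineError("similarity", str(err))
    if "family_association" in config.analyses:
        try:
            outputs["table5.csv"] = render_table(_stage_famassoc(df, config), "t5")
        except Exception as err:
            raise PipelineError("family_association", str(err))

    manifest = {
        "seed": config.seed,
        "conditions": list(config.conditions),
        "analyses": list(config.analyses),
        "covariate_policy": config.covariate_policy,
        "adjusted": config.adjusted,
        "input_sha256": digest,
        "n_members": int(len(df)),
        "package": "twinstats",
        "version": __import__("twinstats").__version__,
    }
    outputs["manifest.json"] = json.dumps(manifest, indent=2, sort_keys=True) + "\n"

    os.makedirs(config.out_dir, exist_ok=True)
    for name, text in outputs.items():
        with open(os.path.join(config.out_dir, name), "w") as fh:
            fh.write(text)
    return outputs
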