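"""End-to-end study orchestration.

Wires the stages together: phenotype derivation, instrument screening
and scoring, the observational category regressions (the linearity
check), the quartiled-IV run over all nine lipid outcomes, the
drinker-category sensitivity reruns, and report rendering.  Every fit
emits one structured log line (outcome, scenario, n, F, partial R²)
so printed sample sizes are auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import instruments, iv2sls, phenotypes

logger = logging.getLogger(__name__)

#: outcome name -> (column in the derived cohort, log-scale flag, visit)
OUTCOME_SPECS = {
    "tg": ("derived_ln_tg", True, "baseline"),
    "total_chol": ("total_chol", False, "baseline"),
    "hdl": ("derived_ln_hdl", True, "baseline"),
    "hdl2": ("derived_ln_hdl2", True, "baseline"),
    "hdl3": ("hdl3", False, "baseline"),
    "ldl": ("derived_ldl", False, "baseline"),
    "sdldl": ("derived_ln_sdldl", True, "visit4"),
    "apob": ("derived_ln_apob", True, "visit4"),
    "lpa": ("derived_ln_lpa", True, "baseline"),
}

SCENARIOS = {
    "full": (),
    "exclude_heavy": ("heavy",),
    "exclude_never": ("never",),
    "exclude_never_and_heavy": ("never", "heavy"),
    "exclude_never_and_former": ("never", "former"),
}

DEFAULT_OUTCOMES = tuple(OUTCOME_SPECS)


@dataclass
class AnalysisPlan:
    outcomes: tuple = DEFAULT_OUTCOMES
    covariates: tuple = ("sex_male", "age", "PC1", "PC2")
    scenarios: tuple = ("exclude_heavy", "exclude_never",
                        "exclude_never_and_heavy", "exclude_never_and_former")
    cov_type: str = "HC1"
    quartiles_per_outcome: bool = True
    adjusted_observational: bool = True
    min_scenario_n: int = 100
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        for o in self.outcomes:
            if o not in OUTCOME_SPECS:
                raise ValueError(f"unknown outcome {o!r}")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("outcomes", "covariates", "scenarios"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d) -> "AnalysisPlan":
        d = dict(d)
        for key in ("outcomes", "covariates", "scenarios"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def prepare_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derived columns plus the numeric sex indicator the models use."""
    df = phenotypes.derive_cohort(cohort)
    if "sex_male" not in df.columns:
        df["sex_male"] = (df["sex"] == "M").astype(float)
    return df


def select_instruments(
    cohort: pd.DataFrame,
    roster=None,
    lipid_locus_dosages: pd.DataFrame | None = None,
    thresholds=instruments.DEFAULT_THRESHOLDS,
):
    """Orient, screen and score the candidate SNPs on a derived cohort.

    Returns ``(cohort_with_score, report, score, survivors)``; the
    score is appended as ``score_unweighted`` (missing where any
    contributing dosage is missing).
    """
    roster = roster if roster is not None else instruments.default_roster()
    x = cohort["derived_log_alcohol"] if "derived_log_alcohol" in cohort.columns \
        else cohort["log_alcohol"]
    oriented = {}
    records = []
    for v in roster:
        dos, rec = instruments.orient_alleles(v, cohort[v.snp_id], x)
        oriented[v.snp_id] = dos
        records.append(rec)
    oriented = pd.DataFrame(oriented, index=cohort.index)
    conf = cohort[list(instruments.CONFOUNDER_COLUMNS)]
    report, survivors = instruments.screen_candidates(
        records, oriented, lipid_locus_dosages, conf, thresholds)
    score = instruments.build_score(
        oriented, survivors, conf, lipid_locus_dosages, thresholds)
    out = cohort.copy()
    out["score_unweighted"] = score.values
    return out, report, score, survivors


def _age_col(df: pd.DataFrame, visit: str) -> str:
    if visit == "visit4" and "age_v4" in df.columns:
        return "age_v4"
    return "age"


def run_mr(
    cohort: pd.DataFrame,
    plan: AnalysisPlan | None = None,
    scenario: str = "full",
) -> list:
    """Quartiled-IV analysis of every planned outcome.

    Per outcome: restrict to that outcome's complete cases, refit the
    first stage there, cut its fitted exposure into quartiles and fit
    the second stage.  Returns a list of IVResultRows.
    """
    plan = plan or AnalysisPlan()
    results = []
    shared_fs = None
    for outcome in plan.outcomes:
        ycol, log_scale, visit = OUTCOME_SPECS[outcome]
        covs = tuple(
            _age_col(cohort, visit) if c == "age" else c for c in plan.covariates
        )
        cols = ["derived_log_alcohol", "score_unweighted", ycol, *covs]
        frame = cohort[cols].dropna()
        try:
            if plan.quartiles_per_outcome or shared_fs is None:
                fs = iv2sls.fit_first_stage(
                    frame, "derived_log_alcohol", "score_unweighted", covs)
                if not plan.quartiles_per_outcome:
                    shared_fs = fs
            else:
                fs = shared_fs
            qa = iv2sls.assign_quartiles(fs)
            row = iv2sls.fit_second_stage(
                frame, ycol, qa, covs, cov_type=plan.cov_type,
                lipid_name=outcome, log_scale=log_scale)
        except Exception as err:
            raise RuntimeError(f"outcome {outcome!r} ({scenario}): {err}") from err
        row.partial_r2 = fs.partial_r2
        row.f_statistic = fs.f_statistic
        row.weak_instrument = fs.weak
        row.visit = visit
        results.append(row)
        logger.info(
            "fit outcome=%s scenario=%s n=%d F=%.3f partial_r2=%.5f p_overall=%.4g",
            outcome, scenario, row.n, fs.f_statistic, fs.partial_r2, row.p_overall)
    return results


def apply_scenario(cohort: pd.DataFrame, scenario: str) -> pd.DataFrame:
    excluded = SCENARIOS[scenario]
    if not excluded:
        return cohort
    return cohort[~cohort["derived_category"].isin(excluded)]


def run_sensitivity(cohort: pd.DataFrame, plan: AnalysisPlan | None = None) -> dict:
    """Re-run the full IV analysis on each drinker-category subset."""
    plan = plan or AnalysisPlan()
    out = {}
    for scenario in plan.scenarios:
        sub = apply_scenario(cohort, scenario)
        if len(sub) < plan.min_scenario_n:
            raise ValueError(
                f"scenario {scenario!r} leaves only {len(sub)} individuals "
                f"(< {plan.min_scenario_n})")
        out[scenario] = run_mr(sub, plan, scenario=scenario)
    return out


OBS_CATEGORIES = ("former_infrequent", "low_to_moderate", "heavy")


def observational_association(
    cohort: pd.DataFrame,
    outcome: str,
    covariates=("sex_male", "age"),
    adjusted: bool = True,
) -> pd.DataFrame:
    """Lipid ~ drinker-category indicators, never drinkers the reference.

    Former and infrequent drinkers are merged into one category, as the
    observational table prints them.  ``adjusted=False`` drops the
    covariates (bare-category regression).
    """
    import statsmodels.api as sm
    from scipy import stats

    ycol, log_scale, visit = OUTCOME_SPECS[outcome]
    covs = tuple(_age_col(cohort, visit) if c == "age" else c for c in covariates) \
        if adjusted else ()
    cat = cohort["derived_category"].replace(
        {"former": "former_infrequent", "infrequent": "former_infrequent"})
    frame = cohort[[ycol, *covs]].copy()
    frame["_cat"] = cat
    frame = frame.dropna()
    if not (frame["_cat"] == "never").any():
        raise ValueError("empty reference category (never drinkers)")
    X = pd.DataFrame(index=frame.index)
    X["intercept"] = 1.0
    for c in OBS_CATEGORIES:
        X[c] = (frame["_cat"] == c).astype(float)
    for c in covs:
        X[c] = frame[c].astype(float)
    fit = sm.OLS(frame[ycol].astype(float), X).fit(cov_type="HC1")
    rows = [{"lipid": outcome, "category": "never", "n": int((frame["_cat"] == "never").sum()),
             "beta": 0.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
             "log_scale": log_scale}]
    z975 = stats.norm.ppf(0.975)
    for c in OBS_CATEGORIES:
        b, se = float(fit.params[c]), float(fit.bse[c])
        rows.append({"lipid": outcome, "category": c,
                     "n": int((frame["_cat"] == c).sum()),
                     "beta": b, "ci_low": b - z975 * se, "ci_high": b + z975 * se,
                     "p": float(2 * stats.norm.sf(abs(b / se))),
                     "log_scale": log_scale})
    return pd.DataFrame(rows)


def results_to_frame(rows) -> pd.DataFrame:
    return pd.concat([r.to_frame() for r in rows], ignore_index=True)


def make_report(
    main_results,
    sensitivity: dict | None = None,
    observational: pd.DataFrame | None = None,
    out_dir=None,
) -> str:
    """Render result tables plus a plain-text summary.

    Log-scale quartile effects are additionally reported as percent
    changes (100·(e^β − 1)); first-stage F ≤ 10 rows carry a
    weak-instrument flag.  When ``out_dir`` is given, TSVs and the
    summary are written there; regeneration from the same tables is
    byte-identical.
    """
    lines = ["Quartiled instrumental-variable analysis", "=" * 41, ""]
    main = results_to_frame(main_results)
    for row in main_results:
        flag = "  [weak instrument: F <= 10]" if row.weak_instrument else ""
        lines.append(
            f"{row.lipid}: n={row.n}, first-stage F={row.f_statistic:.2f}, "
            f"partial R2={100 * row.partial_r2:.2f}%, overall Wald p={row.p_overall:.3g}{flag}")
        for e in row.effects:
            extra = (f" ({phenotypes.percent_change(e.beta):+.1f}%)"
                     if row.log_scale else "")
            lines.append(
                f"  q{e.quartile} vs q1: beta={e.beta:+.3f}{extra} "
                f"[{e.ci_low:+.3f}, {e.ci_high:+.3f}], p={e.p:.3g}")
        lines.append("")
    tables = {"iv_main.tsv": main}
    if sensitivity:
        for name, rows in sensitivity.items():
            tables[f"iv_{name}.tsv"] = results_to_frame(rows)
            lines.append(f"sensitivity {name}: " + ", ".join(
                f"{r.lipid} p_overall={r.p_overall:.3g}" for r in rows))
        lines.append("")
    if observational is not None and len(observational):
        tables["observational.tsv"] = observational
    text = "\n".join(lines) + "\n"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out / name, sep="\t", index=False, float_format="%.6g")
        (out / "summary.txt").write_text(text)
    return text
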