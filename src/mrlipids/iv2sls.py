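"""Two-stage least squares with a quartiled nonlinear second stage.

The estimator mirrors the study design this package implements:

* **first stage** — OLS of the recorded log exposure on the unweighted
  allele score plus sex, age and two ancestry PCs, with the
  weak-instrument diagnostics (nested-model F for the score and its
  partial R²);
* **quartiling** — the fitted (predicted) exposure is cut at its
  empirical quartiles on the analysis set;
* **second stage** — OLS of each lipid on indicators for quartiles
  2–4 (quartile 1 the reference) plus the covariates, with per-quartile
  Wald tests and a 3-df overall Wald test;
* a **continuous 2SLS** estimator with the proper residual correction,
  used for linear-effect estimation and as the oracle-checked core.

Wald tests use the large-sample normal/χ² reference.  The default
second-stage covariance is heteroskedasticity-robust (HC1); note the
reported intervals are conditional on the estimated quartile
assignment — the quartiled design has no closed-form
generated-regressor correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COVARIATES = ("sex_male", "age", "PC1", "PC2")
F_WEAK_THRESHOLD = 10.0


@dataclass
class FirstStageFit:
    """Exposure ~ score + covariates, with weak-instrument diagnostics."""

    coefficients: pd.Series
    fitted: pd.Series          # indexed like the analysis rows
    rss_full: float
    rss_reduced: float
    n: int
    k: int                     # full-model column count
    f_statistic: float
    partial_r2: float

    @property
    def weak(self) -> bool:
        return self.f_statistic <= F_WEAK_THRESHOLD


@dataclass
class QuartileAssignment:
    labels: pd.Series          # integers 1..4
    boundaries_log: tuple      # 25/50/75 percentiles of fitted exposure
    range_log: tuple           # (min, max) fitted exposure

    @property
    def boundaries_g_wk(self) -> tuple:
        """Cut-points back-transformed to grams/week via exp(x) − 1."""
        return tuple(float(np.expm1(b)) for b in self.boundaries_log)

    @property
    def range_g_wk(self) -> tuple:
        return tuple(float(np.expm1(b)) for b in self.range_log)


@dataclass
class QuartileEffect:
    quartile: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class IVResultRow:
    """One lipid's worth of the quartiled-IV results table."""

    lipid: str
    n: int
    effects: list              # QuartileEffect for q2..q4 (q1 is the 0 reference)
    p_overall: float
    partial_r2: float
    f_statistic: float
    log_scale: bool
    visit: str = "baseline"
    weak_instrument: bool = False
    quartiles: QuartileAssignment | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"lipid": self.lipid, "n": self.n, "quartile": "q1", "beta": 0.0,
                 "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                 "p_overall": self.p_overall, "partial_r2": self.partial_r2,
                 "f_value": self.f_statistic, "log_scale": self.log_scale,
                 "weak_instrument": self.weak_instrument}]
        for e in self.effects:
            rows.append({"lipid": self.lipid, "n": self.n, "quartile": f"q{e.quartile}",
                         "beta": e.beta, "ci_low": e.ci_low, "ci_high": e.ci_high,
                         "p": e.p, "p_overall": np.nan, "partial_r2": np.nan,
                         "f_value": np.nan, "log_scale": self.log_scale,
                         "weak_instrument": self.weak_instrument})
        return pd.DataFrame(rows)


def _design(df: pd.DataFrame, cols) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols])
    return X


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}): columns {list(names)}"
        )


def fit_first_stage(
    df: pd.DataFrame,
    exposure_col: str = "log_alcohol",
    score_col: str = "score_unweighted",
    covariates=DEFAULT_COVARIATES,
) -> FirstStageFit:
    """First-stage OLS with nested-model F and partial R² for the score.

    ``df`` must already be restricted to the analysis set (complete
    cases); rows with missing values in any used column are dropped
    here as a safety net.
    """
    cols = [exposure_col, score_col, *covariates]
    data = df[cols].dropna()
    n = len(data)
    names = ["intercept", score_col, *covariates]
    X_full = _design(data, [score_col, *covariates])
    X_red = _design(data, list(covariates))
    k = X_full.shape[1]
    if n <= k:
        raise ValueError(f"too few complete cases (n={n}) for {k} coefficients")
    _check_rank(X_full, names)
    y = data[exposure_col].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    fitted = X_full @ beta
    rss_full = float(np.sum((y - fitted) ** 2))
    beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_red = float(np.sum((y - X_red @ beta_r) ** 2))
    f_stat = ((rss_red - rss_full) / 1.0) / (rss_full / (n - k))
    partial_r2 = (rss_red - rss_full) / rss_red if rss_red > 0 else 0.0
    return FirstStageFit(
        coefficients=pd.Series(beta, index=names),
        fitted=pd.Series(fitted, index=data.index),
        rss_full=rss_full,
        rss_reduced=rss_red,
        n=n,
        k=k,
        f_statistic=float(f_stat),
        partial_r2=float(partial_r2),
    )


def assign_quartiles(first_stage: FirstStageFit) -> QuartileAssignment:
    """Quartile labels of the fitted exposure (boundary ties go low)."""
    fitted = first_stage.fitted
    if len(fitted) < 8:
        raise ValueError("need at least 8 individuals to form quartiles")
    vals = fitted.to_numpy(dtype=float)
    q = np.quantile(vals, [0.25, 0.5, 0.75])
    if np.ptp(vals) == 0:
        raise ValueError("degenerate quartiles: all fitted values identical")
    labels = 1 + (vals > q[0]).astype(int) + (vals > q[1]).astype(int) + (vals > q[2]).astype(int)
    return QuartileAssignment(
        labels=pd.Series(labels, index=fitted.index),
        boundaries_log=tuple(float(v) for v in q),
        range_log=(float(vals.min()), float(vals.max())),
    )


def fit_second_stage(
    df: pd.DataFrame,
    lipid_col: str,
    quartiles: QuartileAssignment,
    covariates=DEFAULT_COVARIATES,
    cov_type: str = "HC1",
    lipid_name: str | None = None,
    log_scale: bool = False,
) -> IVResultRow:
    """Lipid ~ quartile indicators (q1 reference) + covariates.

    Per-quartile Wald z tests and 95% CIs, plus the 3-df overall Wald
    χ² on the three quartile coefficients jointly.  ``cov_type`` is
    "HC1" (default) or "nonrobust".
    """
    import statsmodels.api as sm

    data = df.loc[quartiles.labels.index, [lipid_col, *covariates]].copy()
    data["_q"] = quartiles.labels
    data = data.dropna()
    n = len(data)
    for q in (1, 2, 3, 4):
        if not (data["_q"] == q).any():
            raise ValueError(f"quartile q{q} empty after missing-data removal")
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    for q in (2, 3, 4):
        X[f"q{q}"] = (data["_q"] == q).astype(float)
    for c in covariates:
        X[c] = data[c].astype(float)
    _check_rank(X.to_numpy(), X.columns)
    model = sm.OLS(data[lipid_col].astype(float), X)
    fit = model.fit() if cov_type == "nonrobust" else model.fit(
        cov_type=cov_type)
    z975 = stats.norm.ppf(0.975)
    effects = []
    for q in (2, 3, 4):
        b = float(fit.params[f"q{q}"])
        se = float(fit.bse[f"q{q}"])
        z = b / se
        effects.append(QuartileEffect(
            quartile=q, beta=b, se=se,
            ci_low=b - z975 * se, ci_high=b + z975 * se,
            p=float(2 * stats.norm.sf(abs(z))),
        ))
    idx = [list(X.columns).index(f"q{q}") for q in (2, 3, 4)]
    c = fit.params.to_numpy()[idx]
    V = np.asarray(fit.cov_params())[np.ix_(idx, idx)]
    wald = float(c @ np.linalg.solve(V, c))
    p_overall = float(stats.chi2.sf(wald, df=3))
    return IVResultRow(
        lipid=lipid_name or lipid_col,
        n=n,
        effects=effects,
        p_overall=p_overall,
        partial_r2=np.nan,
        f_statistic=np.nan,
        log_scale=log_scale,
        quartiles=quartiles,
    )


@dataclass
class Linear2SLSFit:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    first_stage: FirstStageFit
    coefficients: pd.Series = field(default=None)


def fit_linear_2sls(
    df: pd.DataFrame,
    lipid_col: str,
    exposure_col: str = "log_alcohol",
    score_col: str = "score_unweighted",
    covariates=DEFAULT_COVARIATES,
) -> Linear2SLSFit:
    """Continuous-exposure 2SLS with a single score instrument.

    Explicit two-step estimate; the standard error uses the proper
    2SLS correction (second-stage residuals recomputed with the
    observed exposure).  The point estimate equals the closed-form
    just-identified IV solution.
    """
    cols = [lipid_col, exposure_col, score_col, *covariates]
    data = df[cols].dropna()
    n = len(data)
    fs = fit_first_stage(data, exposure_col, score_col, covariates)
    xhat = fs.fitted.to_numpy()
    W = _design(data, list(covariates))
    X2 = np.column_stack([W, xhat])
    names = ["intercept", *covariates, exposure_col]
    _check_rank(X2, names)
    y = data[lipid_col].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X2, y, rcond=None)
    # residuals with the observed exposure, not the first-stage fit
    X_obs = np.column_stack([W, data[exposure_col].to_numpy(dtype=float)])
    resid = y - X_obs @ beta
    k = X2.shape[1]
    sigma2 = float(resid @ resid) / (n - k)
    XtX_inv = np.linalg.inv(X2.T @ X2)
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    b = float(beta[-1])
    z975 = stats.norm.ppf(0.975)
    z = b / se
    return Linear2SLSFit(
        beta=b, se=se, ci_low=b - z975 * se, ci_high=b + z975 * se,
        p=float(2 * stats.norm.sf(abs(z))), n=n, first_stage=fs,
        coefficients=pd.Series(beta, index=names),
    )


def closed_form_iv(y, x, z, W=None) -> float:
    """Just-identified IV coefficient by the closed form
    (Z̃'X̃)⁻¹Z̃'ỹ after partialling covariates out of y, x and z.
    Independent of the two-step path; used as an oracle."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    if W is None:
        W = np.ones((len(y), 1))
    P = W @ np.linalg.lstsq(W, np.column_stack([y, x, z]), rcond=None)[0]
    ry, rx, rz = (np.column_stack([y, x, z]) - P).T
    return float((rz @ ry) / (rz @ rx))


def compute_pcs(genotypes: np.ndarray, n_components: int = 2):
    """Leading principal components of a genotype dosage matrix.

    Columns are centred at 2p̂ and scaled by √(2p̂(1−p̂)); constant
    columns are dropped with a warning.  Returns an (n, k) array of
    unit-norm left singular vectors with each component's sign fixed
    so its largest-magnitude SNP loading is positive (stable under
    row permutation up to the permutation itself).
    """
    import logging

    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 3 or G.shape[1] < 2:
        raise ValueError("need at least 3 individuals and 2 SNPs")
    p = G.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1) & (G.std(axis=0) > 0)
    if not keep.any():
        raise ValueError("all SNP columns are constant")
    if not keep.all():
        logging.getLogger(__name__).warning(
            "dropping %d constant SNP columns", int((~keep).sum()))
    G = G[:, keep]
    p = p[keep]
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, Vt.shape[0])
    pcs = U[:, :k].copy()
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
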