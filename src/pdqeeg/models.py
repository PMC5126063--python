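"""Prognostic statistical chain.

Univariate screening, multivariate backward elimination, LMG
relative-importance decomposition of the explained variance, confounder
checks, ROC analysis on the dichotomised follow-up MMSE, and random-forest
importances.  Linear models go through statsmodels OLS; the LMG shares, the
elimination loop and the per-tree out-of-bag permutation importances are
implemented here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

QEEG_COLUMNS = ("grmp_delta", "grmp_theta", "grmp_alpha1", "grmp_alpha2",
                "grmp_beta", "occipital_mf_hz")
COGNITIVE_COLUMNS = ("attention", "executive", "fluency", "long_term_memory",
                     "working_memory", "visuospatial")
CLINICAL_COLUMNS = ("age", "sex_male", "education_years", "disease_duration_years",
                    "observation_years", "ledd_mg", "updrs3")


def build_predictor_matrix(
    features: pd.DataFrame,
    profile_baseline: pd.DataFrame,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the baseline predictor matrix (complete cases only).

    Columns: five GRMP fractions, occipital median frequency, six cognitive
    domain scores, and the clinical covariates.  Rows with any missing value
    are dropped and logged.
    """
    clin = clinical.copy()
    if "observation_years" not in clin.columns and "observation_months" in clin.columns:
        clin["observation_years"] = clin["observation_months"] / 12.0
    parts = [
        features[list(QEEG_COLUMNS)],
        profile_baseline[list(COGNITIVE_COLUMNS)],
        clin[list(CLINICAL_COLUMNS)],
    ]
    x = pd.concat(parts, axis=1, join="inner")
    complete = x.notna().all(axis=1)
    if not complete.all():
        logger.warning("dropping %d incomplete case(s)", int((~complete).sum()))
    return x.loc[complete]


def provenance(column: str) -> str:
    if column in QEEG_COLUMNS:
        return "qEEG"
    if column in COGNITIVE_COLUMNS:
        return "cognitive"
    return "clinical"


# ---------------------------------------------------------------------------
# Normality
# ---------------------------------------------------------------------------

def normality_check(values: np.ndarray | pd.Series) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value (descriptive only, never a gate)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Regression screen + backward elimination
# ---------------------------------------------------------------------------

def univariate_screen(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """One OLS per predictor; returns the β/p table and the p ≤ alpha set."""
    if len(outcome) <= 2:
        raise ValueError("need more than 2 observations")
    if outcome.std(ddof=1) == 0:
        logger.warning("constant outcome: degenerate univariate fits")
    rows = []
    for col in predictors.columns:
        x = predictors[col]
        if x.std(ddof=1) == 0:
            logger.warning("skipping constant predictor %r", col)
            continue
        fit = sm.OLS(outcome, sm.add_constant(x)).fit()
        rows.append({"predictor": col, "beta": fit.params[col],
                     "p": fit.pvalues[col], "r2": fit.rsquared})
    table = pd.DataFrame(rows).set_index("predictor")
    selected = table.index[table["p"] <= alpha].tolist()
    return table, selected


@dataclass
class FinalModel:
    predictors: list[str]
    beta: dict[str, float]
    pvalues: dict[str, float]
    adj_r2: float
    r2: float
    conf_int: dict[str, tuple[float, float]]
    nobs: int


def _check_collinearity(x: pd.DataFrame, limit: float = 1e10) -> None:
    xs = (x - x.mean()) / x.std(ddof=1)
    cond = np.linalg.cond(xs.to_numpy())
    if cond > limit:
        raise ValueError(
            f"near-collinear predictors (condition number {cond:.2e}): {list(x.columns)}"
        )


def backward_eliminate(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    alpha: float = 0.05,
) -> FinalModel:
    """Drop the highest-p predictor until all partial-t p-values are ≤ alpha.

    Exact p ties are broken by removing the alphabetically later column, so
    the result does not depend on input column order.
    """
    cols = sorted(predictors.columns)
    if not cols:
        raise ValueError("empty predictor set")
    if len(outcome) <= len(cols) + 2:
        raise ValueError("too few observations for the predictor count")
    _check_collinearity(predictors[cols])
    while cols:
        fit = sm.OLS(outcome, sm.add_constant(predictors[cols])).fit()
        pvals = fit.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p <= alpha:
            ci = fit.conf_int()
            return FinalModel(
                predictors=cols,
                beta={c: float(fit.params[c]) for c in cols},
                pvalues={c: float(pvals[c]) for c in cols},
                adj_r2=float(fit.rsquared_adj),
                r2=float(fit.rsquared),
                conf_int={c: (float(ci.loc[c, 0]), float(ci.loc[c, 1])) for c in cols},
                nobs=int(fit.nobs),
            )
        ties = sorted(pvals.index[pvals == worst_p])
        cols.remove(ties[-1])
    return FinalModel(predictors=[], beta={}, pvalues={}, adj_r2=0.0, r2=0.0,
                      conf_int={}, nobs=len(outcome))


# ---------------------------------------------------------------------------
# LMG variance decomposition
# ---------------------------------------------------------------------------

def _subset_r2(outcome: np.ndarray, x: np.ndarray) -> dict[frozenset, float]:
    """R² of every predictor subset (exact enumeration)."""
    p = x.shape[1]
    r2 = {frozenset(): 0.0}
    for k in range(1, p + 1):
        for s in combinations(range(p), k):
            xs = sm.add_constant(x[:, s])
            r2[frozenset(s)] = sm.OLS(outcome, xs).fit().rsquared
    return r2


def lmg_decomposition(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    percent: bool = True,
) -> dict[str, float]:
    """LMG relative importance: average sequential R² gain over all orderings.

    Computed by exact enumeration over predictor subsets with combinatorial
    weights; limited to 12 predictors.  Shares are *non-normalised*: they sum
    to the model's total explained variance (percentage scale when
    ``percent``), not to 100%.
    """
    cols = list(predictors.columns)
    p = len(cols)
    if p == 0:
        raise ValueError("no predictors")
    if p > 12:
        raise ValueError("more than 12 predictors: exact LMG enumeration refused "
                         "(a sampling approximation is out of scope)")
    y = outcome.to_numpy(dtype=float)
    x = predictors.to_numpy(dtype=float)
    r2 = _subset_r2(y, x)
    shares = {}
    for j in range(p):
        others = [i for i in range(p) if i != j]
        total = 0.0
        for k in range(p):
            w = factorial(k) * factorial(p - k - 1) / factorial(p)
            for s in combinations(others, k):
                total += w * (r2[frozenset(s) | {j}] - r2[frozenset(s)])
        shares[cols[j]] = total * (100.0 if percent else 1.0)
    return shares


# ---------------------------------------------------------------------------
# Confounder check
# ---------------------------------------------------------------------------

def confound_check(
    outcome: pd.Series,
    key_predictors: list[str],
    data: pd.DataFrame,
    confounders: tuple[str, ...] = ("age", "sex_male", "education_years"),
    rel_threshold: float = 0.2,
) -> pd.DataFrame:
    """Explained-variance share of each key predictor with/without confounders.

    For each key predictor the unadjusted share is the R² of the
    predictor-only model; the adjusted share is the predictor's LMG share in
    the predictor+confounders model.  ``no_confounding`` is flagged when the
    relative change is below ``rel_threshold``.
    """
    rows = []
    for pred in key_predictors:
        unadj = sm.OLS(outcome, sm.add_constant(data[[pred]])).fit().rsquared * 100
        block = data[[pred, *confounders]]
        _check_collinearity(block)
        adj = lmg_decomposition(outcome, block)[pred]
        delta = adj - unadj
        rows.append({
            "predictor": pred,
            "share_unadjusted_pct": unadj,
            "share_adjusted_pct": adj,
            "delta_pct": delta,
            "no_confounding": bool(abs(delta) < rel_threshold * unadj),
        })
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocSummary:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr: list[float] = field(default_factory=list, repr=False)
    tpr: list[float] = field(default_factory=list, repr=False)


def roc_analysis(marker: pd.Series | np.ndarray, outcome: pd.Series | np.ndarray) -> RocSummary:
    """Empirical ROC with trapezoidal AUC and the Youden-optimal operating point.

    ``outcome`` is the binary event indicator (e.g. follow-up MMSE < 24).
    Ties in Youden's J are resolved toward higher specificity.
    """
    y = np.asarray(outcome).astype(int)
    m = np.asarray(marker, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thresholds = roc_curve(y, m, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    pick = best[np.argmin(fpr[best])]          # ties -> higher specificity
    return RocSummary(
        auc=auc,
        sensitivity=float(tpr[pick]),
        specificity=float(1 - fpr[pick]),
        threshold=float(thresholds[pick]),
        fpr=fpr.tolist(),
        tpr=tpr.tolist(),
    )


def dichotomize_mmse(mmse_followup: pd.Series, cutoff: float = 24.0) -> pd.Series:
    """Event indicator: severe impairment at follow-up (MMSE below cutoff)."""
    return (mmse_followup < cutoff).astype(int)


# ---------------------------------------------------------------------------
# Random forest importances
# ---------------------------------------------------------------------------

def _bootstrap_indices(random_state: int, n: int) -> np.ndarray:
    # replicates sklearn's per-tree bootstrap draw
    return np.random.RandomState(random_state).randint(0, n, n)


def rf_importance(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Regression-forest importances: permutation MDA and impurity MDGC.

    MDA is the mean over trees of the out-of-bag MSE increase when one
    predictor column is permuted.  MDGC is the node-variance decrease (the
    regression analogue of Gini impurity) attributed to the predictor,
    summed over all splits and trees and scaled per sample.  Both are
    deterministic for a fixed seed.
    """
    y = outcome.to_numpy(dtype=float)
    x = predictors.to_numpy(dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("random forest needs at least 20 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=1.0 / 3.0, bootstrap=True,
        random_state=seed, n_jobs=1,
    )
    forest.fit(x, y)
    rng = np.random.default_rng(seed)
    p = x.shape[1]
    mda = np.zeros(p)
    mdgc = np.zeros(p)
    used = np.zeros(p)
    for tree in forest.estimators_:
        oob = np.setdiff1d(np.arange(n), _bootstrap_indices(tree.random_state, n))
        mdgc += tree.tree_.compute_feature_importances(normalize=False)
        if oob.size == 0:
            continue
        base_mse = np.mean((y[oob] - tree.predict(x[oob])) ** 2)
        for j in range(p):
            xp = x[oob].copy()
            xp[:, j] = xp[rng.permutation(oob.size), j]
            perm_mse = np.mean((y[oob] - tree.predict(xp)) ** 2)
            mda[j] += perm_mse - base_mse
            used[j] += 1
    mda = np.divide(mda, used, out=np.zeros_like(mda), where=used > 0)
    return pd.DataFrame(
        {"mda": mda, "mdgc": mdgc},
        index=pd.Index(predictors.columns, name="predictor"),
    ).sort_values("mda", ascending=False)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    univariate: pd.DataFrame
    selected: list[str]
    final_model: FinalModel
    lmg_shares: dict[str, float]
    confounds: pd.DataFrame | None
    roc: RocSummary | None
    rf: pd.DataFrame | None
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "univariate": self.univariate.reset_index().to_dict(orient="records"),
            "selected": self.selected,
            "final_model": asdict(self.final_model),
            "lmg_shares_pct": self.lmg_shares,
            "explained_variance_pct": float(sum(self.lmg_shares.values())),
            "confounds": None if self.confounds is None
                else self.confounds.reset_index().to_dict(orient="records"),
            "roc": None if self.roc is None else {
                "auc": self.roc.auc, "sensitivity": self.roc.sensitivity,
                "specificity": self.roc.specificity, "threshold": self.roc.threshold,
            },
            "rf": None if self.rf is None else self.rf.reset_index().to_dict(orient="records"),
            "normality": {k: list(v) for k, v in self.normality.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def summary(self) -> str:
        lines = ["Final multivariate model"]
        fm = self.final_model
        for c in fm.predictors:
            lines.append(f"  {c:24s} beta={fm.beta[c]: .3f}  p={fm.pvalues[c]:.2g}")
        lines.append(f"  adjusted R2 = {fm.adj_r2:.3f}  (n = {fm.nobs})")
        lines.append(f"Explained variance (LMG, non-normalised) = "
                     f"{sum(self.lmg_shares.values()):.1f}%")
        for c, s in sorted(self.lmg_shares.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {c:24s} {s:5.1f}%")
        if self.roc is not None:
            lines.append(f"ROC: AUC={self.roc.auc:.2f} sens={self.roc.sensitivity:.2f} "
                         f"spec={self.roc.specificity:.2f}")
        if self.rf is not None and len(self.rf):
            top = self.rf.index[0]
            lines.append(f"Random forest: top predictor {top} "
                         f"(MDA={self.rf.loc[top, 'mda']:.3g}, MDGC={self.rf.loc[top, 'mdgc']:.3g})")
        return "\n".join(lines)


def fit_model_report(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    mmse_followup: pd.Series | None = None,
    alpha: float = 0.05,
    rf_trees: int = 500,
    seed: int = 0,
    roc_marker: str = "grmp_theta",
) -> ModelReport:
    """The full statistical chain on one cohort."""
    table, selected = univariate_screen(outcome, predictors, alpha=alpha)
    if not selected:
        raise ValueError("no predictor passed the univariate screen")
    final = backward_eliminate(outcome, predictors[selected], alpha=alpha)
    lmg = lmg_decomposition(outcome, predictors[final.predictors]) if final.predictors else {}
    confounds = None
    if final.predictors:
        confounders = tuple(c for c in ("age", "sex_male", "education_years")
                            if c in predictors.columns)
        keys = [c for c in final.predictors if c not in confounders]
        if confounders and keys:
            confounds = confound_check(outcome, keys, predictors, confounders=confounders)
    roc = None
    if mmse_followup is not None:
        y = dichotomize_mmse(mmse_followup.loc[predictors.index])
        if y.nunique() == 2 and roc_marker in predictors.columns:
            # higher theta power marks decline, so the marker is used as-is
            roc = roc_analysis(predictors[roc_marker], y)
    rf = rf_importance(outcome, predictors, n_trees=rf_trees, seed=seed)
    normality = {"ci_ocs": normality_check(outcome)}
    return ModelReport(
        univariate=table, selected=selected, final_model=final, lmg_shares=lmg,
        confounds=confounds, roc=roc, rf=rf, normality=normality,
    )
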