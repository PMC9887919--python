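"""Quartile construction and association analyses.

Reproduces the analysis-table machinery of a cross-sectional
beverage-quality study: exposure quartiles of the Healthy Beverage
Index (fixed printed cutpoints 63/65/68 by default, or data-driven
sample quartiles), descriptive ANOVA/ANCOVA/chi-square comparisons
across quartiles, and crude/adjusted binary logistic regression for
sarcopenic obesity with Wald odds ratios, 95% confidence intervals and
a median-score trend test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "QuartileScheme",
    "ModelSpec",
    "MODEL_SPECS",
    "LogisticFit",
    "SeparationWarning",
    "assign_quartiles",
    "fit_logistic",
    "odds_ratios",
    "p_trend",
    "percent_odds_reduction",
    "anova_across_quartiles",
    "ancova_adjusted_means",
    "chi_square",
    "association_table",
    "descriptive_table",
]

log = logging.getLogger(__name__)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

#: Ordered categorical levels used when dummy-coding adjustment covariates.
CATEGORICAL_LEVELS = {
    "education": ("illiterate", "under_diploma", "diploma", "bachelor_plus"),
    "economic_class": ("poor", "moderate", "good"),
    "marital": ("single", "married"),
    "job": ("employed", "unemployed"),
}

#: Absolute-coefficient threshold flagging quasi/complete separation.
SEPARATION_THRESHOLD = 15.0


class SeparationWarning(UserWarning):
    """Emitted when a logistic fit shows signs of (quasi-)separation."""


@dataclass(frozen=True)
class QuartileScheme:
    """Three cutpoints partitioning scores into Q1..Q4.

    Intervals are half-open, right-inclusive at the top:
    [min, c1), [c1, c2), [c2, c3), [c3, max] — so a score exactly on a
    cutpoint falls in the higher quartile (63 -> Q2, 65 -> Q3, 68 -> Q4).
    """

    cutpoints: tuple[float, float, float] = (63.0, 65.0, 68.0)
    mode: str = "fixed"

    def __post_init__(self) -> None:
        c1, c2, c3 = self.cutpoints
        if not c1 < c2 < c3:
            raise ValueError("cutpoints must be strictly increasing")
        if self.mode not in ("fixed", "data_driven"):
            raise ValueError(f"unknown quartile mode {self.mode!r}")

    @classmethod
    def from_scores(cls, scores) -> "QuartileScheme":
        """Data-driven scheme: sample 25/50/75 percentiles of the scores."""
        arr = np.asarray(scores, dtype=float)
        cuts = tuple(float(np.quantile(arr, q)) for q in (0.25, 0.50, 0.75))
        return cls(cutpoints=cuts, mode="data_driven")


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic-regression adjustment set."""

    name: str
    covariates: tuple[str, ...] = ()


MODEL_SPECS: dict[str, ModelSpec] = {
    "crude": ModelSpec("crude", ()),
    "model1": ModelSpec("model1", ("age", "energy", "pa")),
    "model2": ModelSpec("model2", ("age", "energy", "pa", "education", "economic_class")),
}


def assign_quartiles(scores, scheme: QuartileScheme, max_valid: float | None = None) -> pd.Categorical:
    """Map each score to Q1..Q4 by the half-open interval convention.

    Scores must be finite and within [0, ``max_valid``] when a maximum
    is given (e.g. the config's attainable maximum).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size and (np.any(~np.isfinite(arr)) or np.any(arr < 0)):
        raise ValueError("scores must be finite and >= 0")
    if max_valid is not None and arr.size and np.any(arr > max_valid):
        raise ValueError(f"scores exceed the attainable maximum {max_valid}")
    idx = np.digitize(arr, scheme.cutpoints, right=False)  # 0..3
    labels = pd.Categorical.from_codes(idx, categories=list(QUARTILE_LABELS), ordered=True)
    counts = pd.Series(labels).value_counts().reindex(QUARTILE_LABELS, fill_value=0)
    log.debug("quartile counts: %s", counts.to_dict())
    return labels


@dataclass(frozen=True)
class LogisticFit:
    """A fitted binary logistic regression (Newton MLE)."""

    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    separation: bool
    n: int
    term_names: tuple[str, ...] = ()


def _dummy_code(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric design columns: continuous as float, categoricals as
    first-level-reference dummies with declared level order."""
    parts = []
    for col in columns:
        s = df[col]
        if col in CATEGORICAL_LEVELS or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = CATEGORICAL_LEVELS.get(col)
            cat = pd.Categorical(s, categories=levels) if levels else pd.Categorical(s)
            dummies = pd.get_dummies(pd.Series(cat, index=df.index), prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float).rename(col))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns involved in the deficiency
        keep, bad = [], []
        for j, name in enumerate(X.columns):
            sub = arr[:, keep + [j]]
            if np.linalg.matrix_rank(sub) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(name)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_logistic(outcome, design: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``design`` holds the numeric regressors (quartile dummies and/or
    covariate columns); an intercept is added here.  Newton iterations
    stop at |delta log-likelihood| < 1e-8 or 100 iterations.  A fit in
    which any coefficient exceeds 15 in absolute value is flagged as
    separated (non-reportable) with a :class:`SeparationWarning`.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size == 0 or len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = sm.add_constant(design.astype(float), has_constant="add")
    _check_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            # Newton's Hessian goes singular under (quasi-)separation;
            # BFGS still yields the diverging MLE path for flagging.
            res = model.fit(method="bfgs", maxiter=200, disp=0)
    separation = bool(np.any(np.abs(res.params.values) > SEPARATION_THRESHOLD))
    if separation:
        warnings.warn(
            "possible quasi/complete separation: a coefficient exceeds "
            f"{SEPARATION_THRESHOLD}; odds ratios are non-reportable",
            SeparationWarning,
            stacklevel=2,
        )
    return LogisticFit(
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        n=int(y.size),
        term_names=tuple(design.columns),
    )


def odds_ratios(fit: LogisticFit, level: float = 0.95, terms=None) -> pd.DataFrame:
    """Wald odds ratios, CIs and p-values for the requested terms.

    OR = exp(b); CI = exp(b +/- z*SE); p = two-sided normal tail of b/SE.
    Refuses a non-converged fit.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to report odds ratios")
    z = stats.norm.ppf(0.5 + level / 2.0)
    terms = list(terms) if terms is not None else [t for t in fit.term_names]
    rows = []
    for t in terms:
        b, se = float(fit.params[t]), float(fit.bse[t])
        rows.append(
            {
                "term": t,
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
                "p": float(2.0 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def p_trend(outcome, labels, scores, covariates: pd.DataFrame | None = None) -> float:
    """Trend test across quartiles.

    Replaces the quartile factor with a single continuous regressor —
    each participant's within-quartile median score — refits the
    logistic model with the same covariates, and returns the Wald p for
    that regressor.
    """
    labels = pd.Series(pd.Categorical(labels), name="quartile").reset_index(drop=True)
    scores = pd.Series(np.asarray(scores, dtype=float), name="score")
    populated = labels[~labels.isna()].unique()
    if len(populated) < 2:
        raise ValueError("need at least two populated quartiles for a trend test")
    medians = scores.groupby(labels, observed=True).median()
    trend = labels.map(medians).astype(float).rename("trend")
    design = trend.to_frame()
    if covariates is not None and len(covariates.columns):
        design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
    fit = fit_logistic(outcome, design)
    return float(odds_ratios(fit, terms=["trend"]).loc["trend", "p"])


def percent_odds_reduction(or_: float) -> float:
    """(1 - OR) * 100 for a protective odds ratio in (0, 1]."""
    if not 0.0 < or_ <= 1.0:
        raise ValueError("odds reduction is defined only for 0 < OR <= 1")
    return (1.0 - or_) * 100.0


def anova_across_quartiles(values, labels) -> tuple[float, float, pd.DataFrame]:
    """Classical one-way ANOVA of a continuous variable across quartiles.

    Groups with fewer than 2 observations are excluded with a warning.
    Returns (F, p, per-group n/mean/sd table).
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": pd.Categorical(labels)})
    df = df.dropna()
    groups, kept = [], []
    for name, sub in df.groupby("g", observed=True):
        if len(sub) < 2:
            warnings.warn(f"group {name} has < 2 observations; excluded from ANOVA", UserWarning)
            continue
        groups.append(sub["y"].to_numpy())
        kept.append(name)
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    f, p = stats.f_oneway(*groups)
    summary = pd.DataFrame(
        {
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
            "sd": [float(np.std(g, ddof=1)) for g in groups],
        },
        index=pd.Index(kept, name="group"),
    )
    return float(f), float(p), summary


def ancova_adjusted_means(values, labels, covariates: pd.DataFrame | None = None):
    """Covariate-adjusted group means and the group-effect p-value.

    Fits OLS of the variable on quartile dummies plus covariates;
    the adjusted mean of each group is the model prediction at the
    grand mean of every covariate; p is the partial F-test of the
    quartile dummies.  With zero covariates this reduces to one-way
    ANOVA.
    """
    y = pd.Series(np.asarray(values, dtype=float), name="y").reset_index(drop=True)
    g = pd.Series(pd.Categorical(labels)).reset_index(drop=True)
    data = pd.DataFrame({"y": y, "g": g})
    if covariates is not None and len(covariates.columns):
        cov = _dummy_code(covariates.reset_index(drop=True), covariates.columns)
    else:
        cov = pd.DataFrame(index=data.index)
    data = pd.concat([data, cov], axis=1).dropna()
    if data["g"].nunique() < 2:
        raise ValueError("need at least two populated groups")
    gdum = pd.get_dummies(data["g"], prefix="g", drop_first=True, dtype=float)
    X = sm.add_constant(pd.concat([gdum, data[cov.columns]], axis=1).astype(float), has_constant="add")
    _check_rank(X)
    res = sm.OLS(data["y"], X).fit()
    cov_means = data[cov.columns].mean()
    levels = list(data["g"].cat.categories) if hasattr(data["g"], "cat") else sorted(data["g"].unique())
    levels = [lv for lv in levels if (data["g"] == lv).any()]
    ref = levels[0]
    adj = {}
    for lv in levels:
        mu = float(res.params["const"])
        if lv != ref:
            mu += float(res.params[f"g_{lv}"])
        mu += float(np.dot(cov_means.values, res.params[cov.columns].values)) if len(cov.columns) else 0.0
        adj[lv] = mu
    if len(gdum.columns):
        fres = res.f_test(np.eye(len(X.columns))[[X.columns.get_loc(c) for c in gdum.columns]])
        p = float(fres.pvalue)
    else:  # pragma: no cover - guarded by nunique check
        p = np.nan
    return pd.Series(adj, name="adjusted_mean"), p


def chi_square(categorical, labels) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) of a categorical
    variable against quartile labels; warns on expected counts < 1."""
    table = pd.crosstab(pd.Series(categorical), pd.Series(pd.Categorical(labels)), dropna=True)
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.size == 0 or min(table.shape) < 1:
        raise ValueError("empty contingency table")
    if min(table.shape) == 1:
        return 0.0, 1.0
    chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if np.any(expected < 1):
        warnings.warn("expected cell counts < 1; chi-square approximation is poor", UserWarning)
    return float(chi2), float(p)


def _model_frame(cohort: pd.DataFrame, spec: ModelSpec, outcome_col: str, label_col: str, score_col: str):
    """Complete-case frame for one model, with per-model n logged."""
    used = [outcome_col, label_col, score_col, *spec.covariates]
    frame = cohort[used].dropna().reset_index(drop=True)
    if len(frame) < len(cohort):
        log.info("model %s: %d of %d rows complete-case", spec.name, len(frame), len(cohort))
    return frame


def association_table(
    cohort: pd.DataFrame,
    models=("crude", "model1", "model2"),
    outcome_col: str = "so",
    label_col: str = "hbi_quartile",
    score_col: str = "hbi_total",
    level: float = 0.95,
) -> pd.DataFrame:
    """Odds-ratio table: per model, Q2-Q4 vs Q1 with Wald CI/p and p-trend.

    Returns a long-format frame with columns model, quartile, n_cases,
    n_total, or, ci_low, ci_high, p, p_trend and a ``reportable`` flag
    (False when the fit shows separation).
    """
    rows = []
    lab = pd.Categorical(cohort[label_col], categories=list(QUARTILE_LABELS), ordered=True)
    cohort = cohort.assign(**{label_col: lab})
    counts = (
        cohort.groupby(label_col, observed=False)[outcome_col]
        .agg(n_cases="sum", n_total="count")
        .astype(int)
    )
    for model_name in models:
        spec = MODEL_SPECS[model_name] if isinstance(model_name, str) else model_name
        frame = _model_frame(cohort, spec, outcome_col, label_col, score_col)
        qdum = pd.get_dummies(frame[label_col], prefix="q", drop_first=True, dtype=float)
        qdum.columns = [c.replace("q_", "") for c in qdum.columns]
        cov = _dummy_code(frame, spec.covariates)
        design = pd.concat([qdum, cov], axis=1)
        fit = fit_logistic(frame[outcome_col].astype(float), design)
        if fit.converged:
            ors = odds_ratios(fit, level=level, terms=list(qdum.columns))
        else:
            warnings.warn(
                f"model {spec.name} did not converge; odds ratios are non-reportable",
                UserWarning, stacklevel=2,
            )
            ors = pd.DataFrame(index=pd.Index([], name="term"))
        try:
            ptr = p_trend(frame[outcome_col].astype(float), frame[label_col], frame[score_col], cov)
        except (ValueError, np.linalg.LinAlgError):
            ptr = np.nan
        for q in QUARTILE_LABELS[1:]:
            r = ors.loc[q] if q in ors.index else None
            rows.append(
                {
                    "model": spec.name,
                    "quartile": q,
                    "n_cases": int(counts.loc[q, "n_cases"]) if q in counts.index else 0,
                    "n_total": int(counts.loc[q, "n_total"]) if q in counts.index else 0,
                    "or": float(r["or"]) if r is not None else np.nan,
                    "ci_low": float(r["ci_low"]) if r is not None else np.nan,
                    "ci_high": float(r["ci_high"]) if r is not None else np.nan,
                    "p": float(r["p"]) if r is not None else np.nan,
                    "p_trend": ptr,
                    "reportable": fit.converged and not fit.separation,
                }
            )
    return pd.DataFrame(rows)


def descriptive_table(
    cohort: pd.DataFrame,
    continuous: list[str],
    categorical: list[str] | None = None,
    label_col: str = "hbi_quartile",
    ancova_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Table 1/2-style summary: per-quartile mean +/- SD with ANOVA and
    (optionally covariate-adjusted) ANCOVA p-values for continuous
    variables, and chi-square p for categorical ones."""
    labels = cohort[label_col]
    rows = []
    for col in continuous:
        f, p_anova, grp = anova_across_quartiles(cohort[col], labels)
        cov_cols = [c for c in (ancova_covariates or []) if c != col]
        cov = cohort[cov_cols] if cov_cols else None
        _, p_ancova = ancova_adjusted_means(cohort[col], labels, cov)
        row = {"variable": col, "type": "continuous", "p_anova": p_anova, "p_ancova": p_ancova}
        for q in grp.index:
            row[f"{q}_mean"] = grp.loc[q, "mean"]
            row[f"{q}_sd"] = grp.loc[q, "sd"]
        rows.append(row)
    for col in categorical or []:
        chi2, p = chi_square(cohort[col], labels)
        rows.append({"variable": col, "type": "categorical", "p_chi2": p, "chi2": chi2})
    return pd.DataFrame(rows)
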