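"""Longitudinal cohort statistics for serial sectional measurements.

The workflow mirrors a four-timepoint perioperative study design:

* serial paired t-tests between consecutive examinations (pre vs 1 month,
  1 vs 6 months, 1 vs 12 months);
* later-minus-earlier period differences ``Dif.pre.1mo``, ``Dif.1.12mo``,
  ``Dif.pre.12mo`` and Pearson correlations between them (so an early
  post-operative drop gives negative ``Dif.pre.1mo``);
* one ordinary-least-squares multiple regression per outcome difference on
  the twelve clinical/demographic covariates;
* two-way random-effects, absolute-agreement, single-measure intraclass
  correlation (ICC(2,1)) for interobserver reproducibility.

All tests are two-sided with no multiple-testing correction; missing
timepoints are handled pairwise-complete with no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import COVARIATE_COLUMNS, TIMEPOINTS, encode_covariates

__all__ = [
    "PERIODS",
    "PairedTestResult",
    "CorrelationResult",
    "RegressionResult",
    "ICCResult",
    "paired_ttest",
    "cohort_from_measurements",
    "build_differences",
    "filter_key",
    "correlate_periods",
    "fit_covariate_model",
    "icc_two_rater",
    "serial_change_table",
    "difference_correlation_table",
    "regression_table",
]

#: Period name -> (earlier, later) timepoint; values are later - earlier.
PERIODS = {
    "Dif.pre.1mo": ("pre", "1mo"),
    "Dif.1.12mo": ("1mo", "12mo"),
    "Dif.pre.12mo": ("pre", "12mo"),
}

_KEY_COLUMNS = ["muscle", "section", "metric"]


@dataclass
class PairedTestResult:
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    degenerate: bool = False


@dataclass
class CorrelationResult:
    n: int
    r: float
    p: float
    degenerate: bool = False


@dataclass
class RegressionResult:
    outcome: dict
    params: pd.Series
    pvalues: pd.Series
    n: int
    r_squared: float
    rank_deficient: bool = False
    aliased: list = field(default_factory=list)


@dataclass
class ICCResult:
    icc: float
    ci95: tuple
    var_subject: float
    var_rater: float
    var_error: float
    n_subjects: int
    k_raters: int
    form: str = "ICC2"  # two-way random, absolute agreement, single measure


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def paired_ttest(values_a, values_b) -> PairedTestResult:
    """Classical paired t-test on later-vs-earlier measurement pairs.

    Incomplete pairs (NaN in either vector) are dropped.  A zero-variance
    difference vector is flagged degenerate: t=0, p=1 when all differences are
    zero, otherwise t=+/-inf, p=0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    d = a - b
    sd_d = d.std(ddof=1)
    if sd_d == 0.0:
        if np.all(d == 0.0):
            t_stat, p, degen = 0.0, 1.0, True
        else:
            t_stat = float(np.inf * np.sign(d.mean()))
            p, degen = 0.0, True
    else:
        t_stat, p = scipy.stats.ttest_rel(a, b)
        t_stat, p, degen = float(t_stat), float(p), False
    return PairedTestResult(
        n=int(n),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t=t_stat, p=p, degenerate=degen,
    )


# ---------------------------------------------------------------------------
# cohort assembly and period differences
# ---------------------------------------------------------------------------


def cohort_from_measurements(measurements: pd.DataFrame,
                             ratios: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Long cohort table from a sectional-measurement table (and ratios).

    Output columns: subject_id, timepoint, rater_id, muscle, section, metric,
    value with metric in {volume, mean_hu} (plus {vr, ct_dr} rows carrying
    muscle="Ssc/Isp+TM" when ``ratios`` is given).
    """
    m = measurements.copy()
    if "rater_id" not in m.columns:
        m["rater_id"] = None
    long = m.melt(
        id_vars=["subject_id", "timepoint", "rater_id", "muscle", "section"],
        value_vars=["volume_cm3", "mean_hu"],
        var_name="metric", value_name="value",
    )
    long["metric"] = long["metric"].map({"volume_cm3": "volume", "mean_hu": "mean_hu"})
    frames = [long]
    if ratios is not None and len(ratios):
        r = ratios.copy()
        if "rater_id" not in r.columns:
            r["rater_id"] = None
        rlong = r.melt(
            id_vars=["subject_id", "timepoint", "rater_id", "section"],
            value_vars=["vr", "ct_dr"], var_name="metric", value_name="value",
        )
        rlong["muscle"] = "Ssc/Isp+TM"
        frames.append(rlong)
    cohort = pd.concat(frames, ignore_index=True)
    dup = cohort.duplicated(
        subset=["subject_id", "timepoint", "rater_id", *_KEY_COLUMNS])
    if dup.any():
        raise ValueError("duplicate (subject, timepoint, rater, key) rows in cohort")
    return cohort[["subject_id", "timepoint", "rater_id", *_KEY_COLUMNS, "value"]]


def _collapse_raters(cohort: pd.DataFrame) -> pd.DataFrame:
    """Average over raters when more than one measured the same exam."""
    return (cohort.groupby(["subject_id", "timepoint", *_KEY_COLUMNS],
                           dropna=False, as_index=False)["value"].mean())


def build_differences(cohort: pd.DataFrame) -> pd.DataFrame:
    """Later-minus-earlier period differences per subject and metric key.

    Subjects missing a period's timepoint simply contribute no record for that
    period.  When all three timepoints are present, ``Dif.pre.12mo`` is formed
    as ``Dif.pre.1mo + Dif.1.12mo`` so the additivity identity holds exactly
    (the two expressions agree mathematically; summing fixes the floating-point
    representation too).
    """
    flat = _collapse_raters(cohort)
    wide = flat.pivot_table(index=["subject_id", *_KEY_COLUMNS],
                            columns="timepoint", values="value",
                            aggfunc="first")
    records = []
    for idx, row in wide.iterrows():
        subject, muscle, section, metric = idx
        vals = {tp: row.get(tp, np.nan) for tp in TIMEPOINTS}
        diffs = {}
        for period, (earlier, later) in PERIODS.items():
            if np.isfinite(vals[earlier]) and np.isfinite(vals[later]):
                diffs[period] = vals[later] - vals[earlier]
        if "Dif.pre.1mo" in diffs and "Dif.1.12mo" in diffs:
            diffs["Dif.pre.12mo"] = diffs["Dif.pre.1mo"] + diffs["Dif.1.12mo"]
        for period, value in diffs.items():
            records.append({
                "subject_id": subject, "muscle": muscle, "section": section,
                "metric": metric, "period": period, "value": value,
            })
    return pd.DataFrame(records,
                        columns=["subject_id", *_KEY_COLUMNS, "period", "value"])


def filter_key(df: pd.DataFrame, metric: str, muscle: str,
               section: str) -> pd.DataFrame:
    """Restrict a cohort/difference table to one (metric, muscle, section) key."""
    sel = ((df["metric"] == metric) & (df["muscle"] == muscle)
           & (df["section"] == section))
    return df.loc[sel]


def correlate_periods(diffs: pd.DataFrame, period_x: str,
                      period_y: str) -> CorrelationResult:
    """Pearson correlation between two period differences of a single key.

    ``diffs`` must be restricted to one (metric, muscle, section) key (see
    :func:`filter_key`).  Constant vectors yield a flagged-undefined result.
    """
    keys = diffs[_KEY_COLUMNS].drop_duplicates()
    if len(keys) != 1:
        raise ValueError(
            f"diffs spans {len(keys)} metric keys; filter to one first"
        )
    x = diffs[diffs["period"] == period_x].set_index("subject_id")["value"]
    y = diffs[diffs["period"] == period_y].set_index("subject_id")["value"]
    joined = pd.concat({"x": x, "y": y}, axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 paired subjects, got {n}")
    if joined["x"].nunique() == 1 or joined["y"].nunique() == 1:
        return CorrelationResult(n=n, r=float("nan"), p=float("nan"),
                                 degenerate=True)
    r, p = scipy.stats.pearsonr(joined["x"], joined["y"])
    return CorrelationResult(n=n, r=float(r), p=float(p))


# ---------------------------------------------------------------------------
# covariate regression
# ---------------------------------------------------------------------------


def fit_covariate_model(diffs: pd.DataFrame, covariates: pd.DataFrame,
                        outcome: dict) -> RegressionResult:
    """OLS regression of one outcome difference on the 12 covariates.

    ``outcome`` identifies the dependent variable, e.g. ``{"metric":
    "volume", "muscle": "Ssc", "section": "Y", "period": "Dif.pre.1mo"}``.
    ``covariates`` is a subject-indexed table with the raw (string-coded)
    covariate columns; coding to a numeric design matrix is done here (see
    :func:`musclesect.io.encode_covariates`).  A rank-deficient design is
    flagged and the aliased columns reported; coefficients are then the
    minimum-norm solution and their p-values are not interpretable.
    """
    sel = diffs
    for col in ("metric", "muscle", "section", "period"):
        sel = sel[sel[col] == outcome[col]]
    y = sel.set_index("subject_id")["value"]
    x_raw = covariates.loc[covariates.index.intersection(y.index)]
    x = encode_covariates(x_raw)
    joined = x.join(y.rename("__y__"), how="inner").dropna()
    n = len(joined)
    n_pred = len(COVARIATE_COLUMNS)
    if n <= n_pred:
        rank_hint = True
    else:
        rank_hint = False
    design = sm.add_constant(joined[list(COVARIATE_COLUMNS)], has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    rank_deficient = rank < design.shape[1] or rank_hint
    aliased: list = []
    if rank_deficient:
        # pivoted QR: columns beyond the numerical rank are aliased
        from scipy.linalg import qr

        _, r_mat, piv = qr(design.to_numpy(), mode="economic", pivoting=True)
        diag = np.abs(np.diag(r_mat))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0
        aliased = [design.columns[piv[i]] for i in range(len(diag))
                   if diag[i] <= tol] + [design.columns[j]
                                         for j in piv[len(diag):]]
    fit = sm.OLS(joined["__y__"], design).fit()
    params = fit.params.drop("const")
    pvalues = fit.pvalues.drop("const")
    return RegressionResult(
        outcome=dict(outcome), params=params, pvalues=pvalues,
        n=n, r_squared=float(fit.rsquared),
        rank_deficient=bool(rank_deficient), aliased=aliased,
    )


# ---------------------------------------------------------------------------
# interobserver agreement
# ---------------------------------------------------------------------------


def icc_two_rater(matrix) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``matrix`` is subjects x raters, complete, with >= 5 subjects and >= 2
    raters.  The point estimate and variance components come from the
    two-way ANOVA mean squares; the 95% CI is the standard F-based interval
    (delegated to :func:`pingouin.intraclass_corr`).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be subjects x raters")
    n, k = x.shape
    if n < 5:
        raise ValueError(f"need >= 5 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need >= 2 raters, got {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("rating matrix must be complete (no missing cells)")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    var_subject = max((msr - mse) / k, 0.0)
    var_rater = max((msc - mse) / n, 0.0)
    var_error = mse

    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "rating": x.ravel(),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="rating").set_index("Type")
    # absolute-agreement single-measure row; label differs across versions
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    row = table.loc[key]
    ci = tuple(float(v) for v in row[ci_col])
    return ICCResult(
        icc=float(icc), ci95=ci,
        var_subject=float(var_subject), var_rater=float(var_rater),
        var_error=float(var_error), n_subjects=n, k_raters=k,
    )


# ---------------------------------------------------------------------------
# report-shaped tables
# ---------------------------------------------------------------------------

_SERIAL_TESTS = (("p_a", "pre", "1mo"), ("p_b", "1mo", "6mo"),
                 ("p_c", "1mo", "12mo"))


def serial_change_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Serial-change summary: per key, mean +/- sd at each timepoint and the
    three paired p-values (a: pre vs 1mo, b: 1mo vs 6mo, c: 1mo vs 12mo).
    """
    flat = _collapse_raters(cohort)
    rows = []
    for (muscle, section, metric), grp in flat.groupby(_KEY_COLUMNS, sort=True):
        wide = grp.pivot_table(index="subject_id", columns="timepoint",
                               values="value", aggfunc="first")
        row: dict = {"muscle": muscle, "section": section, "metric": metric}
        for tp in TIMEPOINTS:
            if tp in wide.columns:
                col = wide[tp].dropna()
                row[f"mean_{tp}"] = float(col.mean())
                row[f"sd_{tp}"] = float(col.std(ddof=1))
                row[f"n_{tp}"] = int(col.size)
            else:
                row[f"mean_{tp}"] = np.nan
                row[f"sd_{tp}"] = np.nan
                row[f"n_{tp}"] = 0
        for label, earlier, later in _SERIAL_TESTS:
            if earlier in wide.columns and later in wide.columns:
                pair = wide[[earlier, later]].dropna()
                if len(pair) >= 3:
                    res = paired_ttest(pair[later], pair[earlier])
                    row[label] = res.p
                    row[f"{label}_degenerate"] = res.degenerate
                    continue
            row[label] = np.nan
            row[f"{label}_degenerate"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def difference_correlation_table(diffs: pd.DataFrame) -> pd.DataFrame:
    """Period-difference summary with between-period Pearson correlations.

    Per key: mean +/- sd of each period difference, plus r and p for
    Dif.pre.1mo vs Dif.1.12mo (``r_a``/``p_a``) and Dif.pre.1mo vs
    Dif.pre.12mo (``r_b``/``p_b``).
    """
    rows = []
    for (muscle, section, metric), grp in diffs.groupby(_KEY_COLUMNS, sort=True):
        row: dict = {"muscle": muscle, "section": section, "metric": metric}
        for period in PERIODS:
            vals = grp.loc[grp["period"] == period, "value"]
            row[f"mean_{period}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{period}"] = (float(vals.std(ddof=1))
                                   if len(vals) > 1 else np.nan)
        for label, px, py in (("a", "Dif.pre.1mo", "Dif.1.12mo"),
                              ("b", "Dif.pre.1mo", "Dif.pre.12mo")):
            try:
                res = correlate_periods(grp, px, py)
                row[f"r_{label}"], row[f"p_{label}"] = res.r, res.p
            except ValueError:
                row[f"r_{label}"] = row[f"p_{label}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def regression_table(diffs: pd.DataFrame, covariates: pd.DataFrame,
                     metric: str, muscle: str,
                     sections: Sequence[str] = ("Y", "Y+5")) -> pd.DataFrame:
    """Covariate-regression report for one metric/muscle: RC and p per
    covariate, for every period x section combination."""
    rows = []
    for covariate in COVARIATE_COLUMNS:
        row: dict = {"covariate": covariate}
        for period in PERIODS:
            for section in sections:
                res = fit_covariate_model(
                    diffs, covariates,
                    {"metric": metric, "muscle": muscle,
                     "section": section, "period": period},
                )
                row[f"RC[{period}][{section}]"] = res.params[covariate]
                row[f"p[{period}][{section}]"] = res.pvalues[covariate]
        rows.append(row)
    return pd.DataFrame(rows)
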