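"""Land-use intensity index and metric-vs-intensity mixed models.

The intensity index is the first principal component of the standardized
field x criterion management table, sign-oriented so an intensity-positive
anchor criterion loads positively.  Each network metric is then modelled as
metric ~ LUI with a random site intercept; the standardized effect size (SES)
is the same slope after z-scoring response and predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LUIResult:
    scores: pd.Series                 # field -> score, mean 0
    loadings: pd.Series               # criterion -> axis-1 loading
    variance_explained_axis1: float


def lui_index(criteria: pd.DataFrame, anchor: str | None = None) -> LUIResult:
    """First-PCA-axis field scores from a field x criterion table.

    Columns are z-scored (zero-variance columns dropped with a warning), the
    first right singular vector gives the loadings and the scores are the
    projections, oriented so the anchor criterion (default: ``mineral_n``
    when present, else the first column) has a positive loading.
    """
    if criteria.shape[0] < 2:
        raise ValueError("need at least 2 fields")
    X = criteria.astype(float).copy()
    sd = X.std(ddof=1)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"dropping zero-variance criteria: {constant}")
        X = X.drop(columns=constant)
    if X.shape[1] < 1:
        raise ValueError("all criteria constant")
    Z = (X - X.mean()) / X.std(ddof=1)
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loadings = pd.Series(vt[0], index=X.columns)
    scores = pd.Series(u[:, 0] * s[0], index=criteria.index)
    if anchor is None:
        anchor = "mineral_n" if "mineral_n" in X.columns else X.columns[0]
    if anchor not in loadings.index:
        raise ValueError(f"anchor criterion {anchor!r} not in table")
    if loadings[anchor] < 0:
        loadings, scores = -loadings, -scores
    var1 = float(s[0] ** 2 / np.sum(s ** 2))
    return LUIResult(scores=scores, loadings=loadings,
                     variance_explained_axis1=var1)


@dataclass
class MixedModelResult:
    metric_name: str
    slope: float
    slope_se: float
    p_value: float
    ses: float
    site_variance: float
    residual_variance: float
    n: int


def _fit_slope(y: np.ndarray, x: np.ndarray, site: np.ndarray, reml: bool):
    """Random-intercept fit returning (slope, se, site_var, resid_var).

    Falls back through optimizers and finally to OLS on degenerate data
    (perfect fits break the mixed-model likelihood).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "x": x, "site": site})
    X = sm.add_constant(df["x"])
    ols = sm.OLS(df["y"], X).fit()
    if np.sqrt(ols.scale) < 1e-10 * max(np.abs(y).max(), 1.0):
        return (float(ols.params["x"]), float(ols.bse["x"]), 0.0,
                float(ols.scale))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ x", df, groups=df["site"])
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=reml, method=method)
            except Exception:
                continue
            slope = float(fit.params["x"])
            se = float(fit.bse["x"])
            if np.isfinite(slope) and np.isfinite(se) and se > 0:
                return (slope, se, float(fit.cov_re.iloc[0, 0]),
                        float(fit.scale))
    return (float(ols.params["x"]), float(ols.bse["x"]), 0.0,
            float(ols.scale))


def fit_mixed_model(y, lui, site, metric_name: str = "",
                    reml: bool = True) -> MixedModelResult:
    """Gaussian mixed model ``y ~ lui + (1 | site)`` for one metric.

    Rows with missing y are dropped (n reported); fewer than 4 complete
    fields is an error.  The slope p-value is a Wald t-test with the
    within-group denominator degrees of freedom n - n_sites - 1 (the normal
    reference is badly anti-conservative at 16 fields).  SES is the fixed
    slope refitted on z-scored y and lui.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(lui, dtype=float)
    site = np.asarray(list(site))
    if not (len(y) == len(x) == len(site)):
        raise ValueError("y, lui and site must have equal length")
    ok = np.isfinite(y) & np.isfinite(x)
    y, x, site = y[ok], x[ok], site[ok]
    if len(y) < 4:
        raise ValueError(f"fewer than 4 complete fields (n={len(y)})")
    n_sites = len(np.unique(site))
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    slope, se, site_var, resid_var = _fit_slope(y, x, site, reml)
    ddof = max(len(y) - n_sites - 1, 1)
    if se > 0:
        p = float(2 * stats.t.sf(abs(slope / se), ddof))
    else:
        p = 0.0
    sd_y, sd_x = y.std(ddof=1), x.std(ddof=1)
    if sd_y > 0 and sd_x > 0:
        zs, _, _, _ = _fit_slope((y - y.mean()) / sd_y,
                                 (x - x.mean()) / sd_x, site, reml)
    else:
        zs = 0.0
    return MixedModelResult(
        metric_name=metric_name, slope=slope, slope_se=se, p_value=p,
        ses=zs, site_variance=max(site_var, 0.0),
        residual_variance=max(resid_var, 0.0), n=len(y),
    )


def correlate(axis_scores, covariate):
    """Pearson correlation with its t-test p-value."""
    x = np.asarray(axis_scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def metric_lui_tests(field_metrics: pd.DataFrame, lui: pd.Series,
                     site: pd.Series, reml: bool = True) -> pd.DataFrame:
    """One mixed model per metric column; adds a BH-adjusted p column.

    ``field_metrics`` is field x metric (fields indexing rows); lui and site
    are aligned on the same field index.  Metrics that cannot be fitted
    (too few complete fields) yield an all-NaN row.
    """
    rows = []
    for metric in field_metrics.columns:
        y = field_metrics[metric].reindex(lui.index)
        try:
            res = fit_mixed_model(y.to_numpy(), lui.to_numpy(),
                                  site.reindex(lui.index).to_numpy(),
                                  metric_name=metric, reml=reml)
            rows.append({
                "metric": metric, "slope": res.slope, "se": res.slope_se,
                "p": res.p_value, "ses": res.ses,
                "site_variance": res.site_variance,
                "residual_variance": res.residual_variance, "n": res.n,
            })
        except ValueError:
            rows.append({"metric": metric, "slope": np.nan, "se": np.nan,
                         "p": np.nan, "ses": np.nan, "site_variance": np.nan,
                         "residual_variance": np.nan, "n": 0})
    out = pd.DataFrame(rows).set_index("metric")
    pvals = out["p"].to_numpy()
    mask = np.isfinite(pvals)
    bh = np.full(len(pvals), np.nan)
    if mask.sum() > 0:
        from statsmodels.stats.multitest import multipletests

        bh[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    out["p_bh"] = bh  # informational only; tests are reported per metric
    return out
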