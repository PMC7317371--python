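"""Temporal trend analyses.

* Median (quantile) regression of per-article topic loads on
  field x bias x year, with pair-resampling bootstrap inference — the
  three-way interaction is the statistic of interest: it asks whether
  the fields' own- versus other-field topic loads diverge over time.
* Polynomial count-trend models (orders 1–3 on centered year) selected
  jointly by AIC and a nested F-test; a quadratic winner with an
  interior vertex reports its peak year.
* Shannon diversity of discretized topic occurrences with percentile
  bootstrap confidence intervals (article-level resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


def check_loss(u: np.ndarray, q: float) -> float:
    """Asymmetric absolute ('pinball') loss ρ_q summed over residuals."""
    u = np.asarray(u, dtype=float)
    return float(np.sum(u * (q - (u < 0))))


@dataclass
class QuantRegFit:
    q: float
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    B: int
    seed: int | None
    check_loss: float
    formula: str | None = None
    bootstrap_params: pd.DataFrame | None = dc_field(default=None, repr=False)


def _bootstrap_quantreg(fit_fn, n_rows: int, B: int, seed, point: pd.Series):
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(B):
        idx = rng.integers(0, n_rows, size=n_rows)
        try:
            draws.append(fit_fn(idx))
        except Exception:  # singular resample: drop it
            continue
    boot = pd.DataFrame(draws)
    bse = boot.std(ddof=1)
    # two-sided sign-crossing p-value with the +1 finite-B adjustment
    below = (boot < 0).sum()
    above = (boot > 0).sum()
    nb = len(boot)
    pvals = (2 * np.minimum(below + 1, above + 1) / (nb + 1)).clip(upper=1.0)
    return bse.reindex(point.index), pd.Series(pvals).reindex(point.index), boot


def quantile_regression(y, X, q: float = 0.5, B: int = 1000, seed=None,
                        names=None) -> QuantRegFit:
    """Minimize the check loss Σ ρ_q(y − Xb); bootstrap SEs and p-values.

    X must include its own intercept column and have full column rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per observation")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]

    def point_fit(idx=None):
        Xi = X if idx is None else X[idx]
        yi = y if idx is None else y[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.QuantReg(yi, Xi).fit(q=q, max_iter=2000)
        return pd.Series(np.asarray(res.params), index=names)

    point = point_fit()
    bse, pvals, boot = _bootstrap_quantreg(point_fit, len(y), B, seed, point)
    loss = check_loss(y - X @ point.values, q)
    return QuantRegFit(q=q, params=point, bse=bse, pvalues=pvals, B=B,
                       seed=seed, check_loss=loss, bootstrap_params=boot)


def bias_trend_quantreg(theta, field_labels, years, eco_set, cons_set,
                        q: float = 0.5, B: int = 1000, seed=None) -> QuantRegFit:
    """The field:bias:year quantile regression on per-article loads.

    Every article contributes two rows: its summed probability over the
    ecology-biased topic set and over the conservation-biased set, with
    ``bias`` labeling the set.  Year is centered at its mean.  With
    treatment coding (baseline level ``conservation`` for both factors)
    the planted divergence — conservation's own-topic load rising while
    its ecology-topic load falls, ecology stationary — puts a positive
    sign on the three-way interaction.
    """
    from .field_bias import bias_load

    theta = np.asarray(theta)
    years = np.asarray(years, dtype=float)
    labels = np.asarray(field_labels)
    frames = []
    for bias_name, topic_set in (("ecology", eco_set), ("conservation", cons_set)):
        frames.append(pd.DataFrame({
            "load": bias_load(theta, topic_set),
            "field": labels,
            "bias": bias_name,
            "year_c": years - years.mean(),
        }))
    df = pd.concat(frames, ignore_index=True)

    def fit_idx(idx=None):
        di = df if idx is None else df.iloc[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.quantreg("load ~ field * bias * year_c", di).fit(q=q, max_iter=2000)
        return res.params

    point = fit_idx()
    bse, pvals, boot = _bootstrap_quantreg(fit_idx, len(df), B, seed, point)
    design = smf.quantreg("load ~ field * bias * year_c", df)
    loss = check_loss(df["load"].values - design.exog @ point.values, q)
    return QuantRegFit(q=q, params=point, bse=bse, pvalues=pvals, B=B, seed=seed,
                       check_loss=loss, formula="load ~ field * bias * year_c",
                       bootstrap_params=boot)


INTERACTION_TERM = "field[T.ecology]:bias[T.ecology]:year_c"


@dataclass
class PolyTrendFit:
    chosen_order: int
    coefficients: np.ndarray        # of the chosen model, ascending powers of centered year
    aic: dict
    f_pvalues: dict                 # order o vs the previously accepted order
    year_mean: float
    peak_year: float | None
    models: dict = dc_field(default_factory=dict, repr=False)

    def predict(self, years) -> np.ndarray:
        x = np.asarray(years, dtype=float) - self.year_mean
        return sum(c * x ** p for p, c in enumerate(self.coefficients))


def fit_polynomial_trends(years, values, max_order: int = 3) -> PolyTrendFit:
    """OLS polynomial trends on centered year, orders 1..max_order.

    A higher order is accepted only when it both lowers the AIC and its
    nested F-test against the currently accepted model has p < 0.05.
    A chosen quadratic with an interior vertex reports the peak year.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape:
        raise ValueError("years and values must align")
    n = len(years)
    cap = max_order
    if n < max_order + 2:
        cap = max(1, n - 2)
        warnings.warn(f"only {n} points: polynomial order capped at {cap}")
    xc = years - years.mean()
    models, aic = {}, {}
    for order in range(1, cap + 1):
        X = np.vander(xc, order + 1, increasing=True)
        models[order] = sm.OLS(values, X).fit()
        aic[order] = float(models[order].aic)
    chosen = 1
    f_pvalues = {}
    tss = float(np.sum((values - values.mean()) ** 2))
    for order in range(2, cap + 1):
        if chosen != order - 1:  # hierarchical: order o only reachable from o-1
            break
        if models[chosen].ssr <= 1e-12 * max(tss, 1.0):
            break  # current model is already an exact fit
        lo, hi = models[chosen], models[order]
        df_num = hi.df_model - lo.df_model
        f = (lo.ssr - hi.ssr) / df_num / (hi.ssr / hi.df_resid)
        p = float(stats.f.sf(f, df_num, hi.df_resid))
        f_pvalues[order] = p
        if aic[order] < aic[chosen] and p < 0.05:
            chosen = order
    coefs = np.asarray(models[chosen].params)
    peak = None
    if chosen == 2 and coefs[2] != 0:
        vertex = -coefs[1] / (2 * coefs[2]) + years.mean()
        if years.min() < vertex < years.max() and coefs[2] < 0:
            peak = float(vertex)
    return PolyTrendFit(chosen_order=chosen, coefficients=coefs, aic=aic,
                        f_pvalues=f_pvalues, year_mean=float(years.mean()),
                        peak_year=peak, models=models)


def shannon_diversity(about: np.ndarray, subset=None, base: float = np.e) -> float:
    """H = −Σ p ln p over topic about-occurrence frequencies in a subset."""
    about = np.asarray(about, dtype=bool)
    if subset is not None:
        about = about[np.asarray(subset)]
    counts = about.sum(axis=0).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no about-occurrences in subset")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def bootstrap_ci(statistic, data, B: int = 1000, level: float = 0.95, seed=None):
    """Percentile bootstrap interval, resampling rows (articles)."""
    if B < 100:
        raise ValueError("B must be >= 100")
    data = np.asarray(data)
    if data.shape[0] == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, data.shape[0], size=data.shape[0])
        try:
            vals.append(statistic(data[idx]))
        except ValueError:
            continue
    vals = np.asarray(vals, dtype=float)
    if np.ptp(vals) == 0:
        warnings.warn("degenerate statistic: zero-width bootstrap interval")
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def diversity_series(about: np.ndarray, years, field_labels, window: int = 1,
                     B: int = 1000, level: float = 0.95, seed=None) -> pd.DataFrame:
    """Shannon H per year-bin x field with bootstrap CIs.

    ``window`` pools consecutive years into bins (annual by default).
    Bins without any about-occurrence are skipped with a warning.
    """
    about = np.asarray(about, dtype=bool)
    years = np.asarray(years)
    labels = np.asarray(field_labels)
    bins = (years - years.min()) // window
    rows = []
    for b in np.unique(bins):
        for fi, f in enumerate(sorted(set(labels))):
            mask = (bins == b) & (labels == f)
            sub = about[mask]
            if sub.shape[0] == 0 or sub.sum() == 0:
                warnings.warn(f"bin {b} field {f}: no about-occurrences, skipped")
                continue
            h = shannon_diversity(sub)
            lo, hi = bootstrap_ci(
                lambda d: shannon_diversity(d), sub, B=B, level=level,
                seed=None if seed is None else seed + int(b) * 31 + fi,
            )
            rows.append({
                "year_bin": int(years.min() + b * window), "field": f,
                "H": h, "ci_low": lo, "ci_high": hi, "n_articles": int(mask.sum()),
            })
    return pd.DataFrame(rows)
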