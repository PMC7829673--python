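"""Group-level channelwise statistics with multiple-comparison correction.

Every model is fitted as a channelwise general linear model on the
subjects x channels matrix of individual indices (betas, contrasts, ALFF
maps, Fisher-z connectivity values, ...): one-sample / two-sample / paired
t-tests, correlation with an external variable, one-way ANOVA (independent
groups or repeated measures), and plain averaging.  Nuisance covariates
(age, gender, training time, ...) are partialled out.  Benjamini-Hochberg
FDR and Bonferroni corrections operate within an optional channel mask.

Missing values (NaN) are handled channelwise: each channel's test uses its
complete subjects, with per-channel degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ChannelStatMap", "group_test", "correct_multiple", "fisher_z"]


@dataclass
class ChannelStatMap:
    stat: np.ndarray            # per-channel t or F (or mean for mean_only)
    p: np.ndarray               # two-sided p-values (NaN for mean_only)
    df: np.ndarray              # per-channel dof (denominator dof for F)
    model: str
    mask: np.ndarray | None = None
    correction: dict = field(default_factory=dict)  # method, q, flags

    @property
    def n_channels(self) -> int:
        return self.stat.size


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh transform for correlation values before group testing."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -1 + 1e-16, 1 - 1e-16))


def _residualize(y: np.ndarray, covs: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Partial centered covariates out of y; returns residual and dof spent."""
    if covs is None:
        return y, 0
    C = covs - covs.mean(axis=0)
    keep = C.std(axis=0) > 0
    C = C[:, keep]
    if C.shape[1] == 0:
        return y, 0
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ beta, C.shape[1]


def _prep_covariates(covariates, n_subj: int) -> np.ndarray | None:
    if covariates is None:
        return None
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n_subj:
        C = C.T
    if C.shape[0] != n_subj:
        raise ValueError("covariates must have one row per subject")
    return C


def _two_sided_t(t: float, df: float) -> float:
    return 2.0 * stats.t.sf(abs(t), df) if df > 0 else np.nan


def group_test(data: np.ndarray, model: str, *, mu0: float = 0.0,
               groups: np.ndarray | None = None, data2: np.ndarray | None = None,
               x: np.ndarray | None = None, covariates=None) -> ChannelStatMap:
    """Channelwise group-level test on a subjects x channels matrix.

    Models: ``one_sample`` (vs mu0), ``two_sample`` (grouping vector or a
    second matrix ``data2``), ``paired`` (``data2`` required),
    ``correlation`` (external variable ``x``), ``anova_indep`` (grouping
    vector), ``anova_rm`` (subjects x channels x conditions array), and
    ``mean_only``.
    """
    data = np.asarray(data, dtype=float)
    if model == "anova_rm":
        return _anova_rm(data)
    if data.ndim == 1:
        data = data[:, None]
    n_subj, n_ch = data.shape
    covs = _prep_covariates(covariates, n_subj)

    stat = np.full(n_ch, np.nan)
    p = np.full(n_ch, np.nan)
    df = np.full(n_ch, np.nan)

    if model == "mean_only":
        stat = np.nanmean(data, axis=0)
        return ChannelStatMap(stat=stat, p=p, df=df, model=model)

    if model == "paired":
        if data2 is None:
            raise ValueError("paired model needs data2")
        data2 = np.asarray(data2, dtype=float)
        if data2.shape != data.shape:
            raise ValueError("paired samples must have identical shape")
        return group_test(data - data2, "one_sample", mu0=0.0, covariates=covariates)

    for j in range(n_ch):
        y = data[:, j]
        ok = ~np.isnan(y)
        if model == "one_sample":
            if ok.sum() < 3:
                continue
            # intercept test of (y - mu0) on [1, centered covariates]
            X = [np.ones(n_subj)]
            if covs is not None:
                X.extend((covs - covs.mean(axis=0)).T)
            stat[j], p[j], df[j] = _ols_t(np.column_stack(X)[ok], y[ok] - mu0, 0)
        elif model == "two_sample":
            if groups is None:
                raise ValueError("two_sample model needs a grouping vector")
            g = np.asarray(groups)
            levels = np.unique(g)
            if levels.size != 2:
                raise ValueError("two_sample needs exactly 2 groups")
            ind = (g == levels[1]).astype(float)
            X = [np.ones(n_subj), ind]
            if covs is not None:
                X.extend((covs - covs.mean(axis=0)).T)
            stat[j], p[j], df[j] = _ols_t(np.column_stack(X)[ok], y[ok], 1)
        elif model == "correlation":
            if x is None:
                raise ValueError("correlation model needs x")
            xv = np.asarray(x, dtype=float)
            X = [np.ones(n_subj), xv]
            if covs is not None:
                X.extend((covs - covs.mean(axis=0)).T)
            stat[j], p[j], df[j] = _ols_t(np.column_stack(X)[ok], y[ok], 1)
        elif model == "anova_indep":
            if groups is None:
                raise ValueError("anova_indep model needs a grouping vector")
            stat[j], p[j], df[j] = _anova_oneway(y[ok], np.asarray(groups)[ok],
                                                 covs[ok] if covs is not None else None)
        else:
            raise ValueError(f"unknown model {model!r}")
    return ChannelStatMap(stat=stat, p=p, df=df, model=model)


def _ols_t(X: np.ndarray, y: np.ndarray, coef_idx: int) -> tuple[float, float, float]:
    """t-test of one coefficient in an OLS fit."""
    n, k = X.shape
    if n <= k:
        return np.nan, np.nan, np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    if dof <= 0:
        return np.nan, np.nan, np.nan
    s2 = (resid @ resid) / dof
    se = np.sqrt(s2 * xtx_inv[coef_idx, coef_idx])
    if se == 0:
        t = 0.0 if beta[coef_idx] == 0 else np.inf
    else:
        t = beta[coef_idx] / se
    return float(t), _two_sided_t(t, dof), float(dof)


def _anova_oneway(y: np.ndarray, g: np.ndarray, covs: np.ndarray | None) -> tuple[float, float, float]:
    """One-way independent-groups F (covariates partialled out first)."""
    if covs is not None:
        y, _ = _residualize(y - y.mean(), covs)
    levels = np.unique(g)
    k = levels.size
    n = y.size
    if k < 2 or n <= k:
        return np.nan, np.nan, np.nan
    grand = y.mean()
    ss_between = sum(((y[g == lv].mean() - grand) ** 2) * (g == lv).sum() for lv in levels)
    ss_within = sum(((y[g == lv] - y[g == lv].mean()) ** 2).sum() for lv in levels)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        return np.inf, 0.0, float(df2)
    F = (ss_between / df1) / (ss_within / df2)
    return float(F), float(stats.f.sf(F, df1, df2)), float(df2)


def _anova_rm(data: np.ndarray) -> ChannelStatMap:
    """One-way repeated-measures ANOVA (no sphericity correction).

    ``data`` is subjects x channels x conditions.
    """
    if data.ndim != 3:
        raise ValueError("anova_rm needs a subjects x channels x conditions array")
    n, n_ch, k = data.shape
    stat = np.full(n_ch, np.nan)
    p = np.full(n_ch, np.nan)
    df = np.full(n_ch, np.nan)
    for j in range(n_ch):
        Y = data[:, j, :]
        ok = ~np.isnan(Y).any(axis=1)
        Y = Y[ok]
        nj = Y.shape[0]
        if nj < 3:
            continue
        grand = Y.mean()
        ss_cond = nj * ((Y.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((Y - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        df1, df2 = k - 1, (nj - 1) * (k - 1)
        if ss_err <= 0:
            stat[j], p[j], df[j] = np.inf, 0.0, df2
            continue
        F = (ss_cond / df1) / (ss_err / df2)
        stat[j], p[j], df[j] = F, stats.f.sf(F, df1, df2), df2
    return ChannelStatMap(stat=stat, p=p, df=df, model="anova_rm")


# ----------------------------------------------------------------------
# multiple-comparison correction
# ----------------------------------------------------------------------

def correct_multiple(result: ChannelStatMap, method: str = "fdr_bh", q: float = 0.05,
                     mask: np.ndarray | None = None) -> ChannelStatMap:
    """Flag significant channels under Bonferroni or Benjamini-Hochberg FDR.

    Correction is computed only over in-mask channels (m = mask size):
    Bonferroni flags p <= q/m; BH sorts the in-mask p ascending and flags
    all p <= p(k*) with k* = max{k : p(k) <= k q / m}.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = result.p
    n = p.size
    if mask is None:
        mask = ~np.isnan(p)
    else:
        mask = np.asarray(mask, dtype=bool) & ~np.isnan(p)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("mask selects no channels with valid p-values")

    flags = np.zeros(n, dtype=bool)
    pm = p[mask]
    if method == "bonferroni":
        flags[mask] = pm <= q / m
    elif method == "fdr_bh":
        order = np.argsort(pm, kind="stable")
        sorted_p = pm[order]
        thresh = (np.arange(1, m + 1) * q) / m
        below = sorted_p <= thresh
        if below.any():
            k_star = int(np.nonzero(below)[0].max())
            flags[mask] = pm <= sorted_p[k_star]
    else:
        raise ValueError(f"unknown correction method {method!r}")

    out = ChannelStatMap(stat=result.stat, p=result.p, df=result.df, model=result.model,
                         mask=mask, correction={"method": method, "q": q, "m": m,
                                                "flags": flags})
    return out
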