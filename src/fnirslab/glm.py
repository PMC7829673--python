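"""Channelwise general linear model for task activation.

Regressors of interest are condition boxcars convolved with the canonical
double-gamma hemodynamic response function (peak at ~5 s, undershoot at
~15 s, 1/6 undershoot ratio, 32 s support), sampled at the acquisition
rate.  Estimation is plain ordinary least squares per channel; effects of
interest are user-defined contrast vectors c with

    t = c' beta / sqrt( sigma^2 * c' (X'X)^-1 c ).

No prewhitening or temporal-derivative regressors are used; serially
correlated noise therefore inflates the nominal t under strong
autocorrelation (see docs/methods.md).  Individual-level inference is out
of scope: contrasts feed group-level statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .recording import Recording, TaskDesign

__all__ = [
    "canonical_hrf",
    "DesignMatrix",
    "build_design",
    "GLMResult",
    "fit_glm",
    "contrast",
]


def _gamma_pdf(t: np.ndarray, shape: float, scale: float = 1.0) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp - gammaln(shape)) / scale
    return out


def canonical_hrf(fs: float, duration_s: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at 1/fs, peak-normalized to 1.

    h(t) = g(t; 6, 1) - g(t; 16, 1) / 6 with g a gamma density; the
    defaults are the standard canonical parameters.  Length is
    round(duration_s * fs) + 1 samples (t = 0 included, h(0) = 0).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = np.arange(int(round(duration_s * fs)) + 1) / fs
    h = (_gamma_pdf(t, peak_delay / peak_disp, peak_disp)
         - _gamma_pdf(t, undershoot_delay / undershoot_disp, undershoot_disp) / ratio)
    return h / h.max()


@dataclass
class DesignMatrix:
    X: np.ndarray           # T x P
    labels: list[str]       # condition names, covariate names, "constant"
    fs: float
    hrf_params: dict


def build_design(design: TaskDesign, n_times: int, fs: float,
                 covariates: dict[str, np.ndarray] | None = None,
                 hrf_kwargs: dict | None = None) -> DesignMatrix:
    """Boxcar (x) HRF design matrix at acquisition resolution.

    Each condition contributes a unit boxcar over [onset, onset+duration)
    — a single-sample impulse when duration is 0 — convolved with the
    canonical HRF and truncated to ``n_times``.  Onsets are rounded to the
    nearest sample.  Covariates are z-scored; the constant column is last.
    """
    hrf_kwargs = hrf_kwargs or {}
    h = canonical_hrf(fs, **hrf_kwargs)
    duration_s = n_times / fs
    cols, labels = [], []
    for name, onsets, durations in design.conditions:
        if not onsets:
            raise ValueError(f"condition {name!r} has no events")
        box = np.zeros(n_times)
        for onset, dur in zip(onsets, durations):
            if onset + dur >= duration_s:
                raise ValueError(f"condition {name!r}: event at {onset}s extends past "
                                 f"the recording ({duration_s}s)")
            i0 = int(round(onset * fs))
            i1 = max(i0 + 1, i0 + int(round(dur * fs)))
            if np.any(box[i0:i1] > 0):
                warnings.warn(f"condition {name!r}: overlapping events are summed")
            box[i0:i1] += 1.0
        cols.append(np.convolve(box, h)[:n_times])
        labels.append(name)

    covariates = covariates or (design.covariates or {})
    for cname, cvec in covariates.items():
        cvec = np.asarray(cvec, dtype=float).ravel()
        if cvec.size != n_times:
            raise ValueError(f"covariate {cname!r} must have length {n_times}")
        sd = cvec.std()
        cols.append((cvec - cvec.mean()) / sd if sd > 0 else cvec - cvec.mean())
        labels.append(cname)

    cols.append(np.ones(n_times))
    labels.append("constant")
    return DesignMatrix(X=np.column_stack(cols), labels=labels, fs=fs,
                        hrf_params={"duration_s": 32.0, **hrf_kwargs})


@dataclass
class GLMResult:
    beta: np.ndarray        # P x C
    sigma2: np.ndarray      # residual variance per channel
    dof: int
    xtx_inv: np.ndarray     # (X'X)^-1 (pseudoinverse when rank deficient)
    labels: list[str]
    rank: int


def fit_glm(rec_or_data: "Recording | np.ndarray", design: DesignMatrix,
            chromophore: str | None = "HbO") -> GLMResult:
    """Ordinary least squares per channel."""
    if isinstance(rec_or_data, Recording):
        if rec_or_data.signal_kind == "hb" and chromophore is not None:
            Y = rec_or_data.chrom_block(chromophore)
        else:
            Y = rec_or_data.data
    else:
        Y = np.asarray(rec_or_data, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("data and design have different numbers of time points")
    rank = int(np.linalg.matrix_rank(X))
    if n <= rank:
        raise ValueError("more parameters than time points")
    if rank < p:
        warnings.warn(f"design matrix rank deficient ({rank} < {p}); using pseudoinverse")
        xtx_inv = np.linalg.pinv(X.T @ X)
    else:
        xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    return GLMResult(beta=beta, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv,
                     labels=list(design.labels), rank=rank)


def contrast(res: GLMResult, c: np.ndarray) -> dict[str, np.ndarray]:
    """Effect c'beta, its variance, and the t statistic per channel."""
    c = np.asarray(c, dtype=float).ravel()
    if c.size != res.beta.shape[0]:
        raise ValueError(f"contrast length {c.size} != {res.beta.shape[0]} parameters")
    effect = c @ res.beta
    quad = float(c @ res.xtx_inv @ c)
    if quad < 0:
        quad = 0.0
    var = res.sigma2 * quad
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), np.where(effect == 0, 0.0, np.inf))
    return {"effect": effect, "variance": var, "t": t, "dof": res.dof}
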