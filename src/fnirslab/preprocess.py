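"""Composable preprocessing stages for fNIRS recordings.

Seven stage families are provided — time-point trimming, polynomial
detrending, motion correction (CBSI and TDDR), digital filtering
(Butterworth IIR, Hamming-window FIR, FFT ideal), nuisance regression on
short-separation channels or external series, rational resampling, and
user-registered custom steps.  Parameters and order are free: a pipeline
is just an ordered list of (step name, parameter map) pairs, serializable
to YAML and re-runnable bit-for-bit.

All stages require NaN-free input: missing samples must first be linearly
interpolated (:func:`interpolate_missing`) or the channel excluded — an
explicit, logged choice rather than a silent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
import warnings

import numpy as np
import scipy.signal as sps
import yaml

from .recording import Recording

__all__ = [
    "trim",
    "detrend",
    "motion_correct_cbsi",
    "motion_correct_tddr",
    "FilterSpec",
    "design_filter",
    "apply_filter",
    "frequency_response",
    "fir_taps",
    "regress_noise",
    "resample",
    "interpolate_missing",
    "register_custom_step",
    "apply_custom_step",
    "PipelineSpec",
    "run_pipeline",
]


def _check_nan_free(rec: Recording, step: str) -> None:
    if np.isnan(rec.data).any():
        raise ValueError(
            f"{step}: data contain NaN; interpolate_missing() or drop the channel first"
        )


# ----------------------------------------------------------------------
# trimming
# ----------------------------------------------------------------------

def trim(rec: Recording, drop_start_s: float = 0.0, drop_end_s: float = 0.0) -> Recording:
    """Delete the specified initial and/or final time periods."""
    if drop_start_s < 0 or drop_end_s < 0:
        raise ValueError("trim amounts must be nonnegative")
    if drop_start_s + drop_end_s >= rec.duration_s:
        raise ValueError("trim would remove the entire recording")
    n0 = int(round(drop_start_s * rec.fs))
    n1 = int(round(drop_end_s * rec.fs))
    data = rec.data[n0: rec.n_times - n1]
    out = rec.with_data(data, "trim", drop_start_s=drop_start_s, drop_end_s=drop_end_s)
    if out.task is not None and drop_start_s > 0:
        shifted = out.task.shifted(-drop_start_s)
        dropped = sum(len(o) for _, o, _ in out.task.conditions) - sum(
            len(o) for _, o, _ in shifted.conditions)
        if dropped:
            warnings.warn(f"trim dropped {dropped} task event(s) now before time zero")
        out.task = shifted
    return out


# ----------------------------------------------------------------------
# detrending
# ----------------------------------------------------------------------

def detrend(rec: Recording, order: int = 1) -> Recording:
    """Fit and subtract a polynomial trend of the given order per channel.

    The fit includes the intercept, so the output channel means are zero.
    The time axis is normalized to [-1, 1] for conditioning.
    """
    _check_nan_free(rec, "detrend")
    if order < 0:
        raise ValueError("order must be >= 0")
    if rec.n_times <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} samples")
    t = np.linspace(-1.0, 1.0, rec.n_times)
    # Vandermonde least squares; polyvander is well conditioned on [-1, 1]
    V = np.polynomial.polynomial.polyvander(t, order)
    coef, *_ = np.linalg.lstsq(V, rec.data, rcond=None)
    out = rec.with_data(rec.data - V @ coef, "detrend", order=order)
    out.recompute_hbt()
    return out


# ----------------------------------------------------------------------
# motion correction
# ----------------------------------------------------------------------

def motion_correct_cbsi(rec: Recording) -> Recording:
    """Correlation-based signal improvement.

    Assumes neural HbO and HbR are strongly anticorrelated while motion
    artifacts move both in the same direction.  Per channel, with
    alpha = sd(HbO)/sd(HbR):

        HbO' = (HbO - alpha * HbR) / 2
        HbR' = -HbO' / alpha

    so the corrected pair is perfectly anticorrelated by construction and a
    pure common-mode artifact (HbO = HbR) is annihilated.
    """
    _check_nan_free(rec, "cbsi")
    if rec.signal_kind != "hb" or not {"HbO", "HbR"} <= set(rec.chromophores):
        raise ValueError("CBSI requires both HbO and HbR")
    hbo = rec.chrom_block("HbO").copy()
    hbr = rec.chrom_block("HbR").copy()
    skipped = []
    for j in range(rec.n_channels):
        sd_r = hbr[:, j].std()
        if sd_r == 0:
            skipped.append(j + 1)
            continue
        alpha = hbo[:, j].std() / sd_r
        corrected = (hbo[:, j] - alpha * hbr[:, j]) / 2.0
        hbo[:, j] = corrected
        hbr[:, j] = -corrected / alpha if alpha > 0 else corrected
    if skipped:
        warnings.warn(f"CBSI skipped zero-variance HbR channel(s): {skipped}")
    out = rec.with_data(rec.data.copy(), "motion_correct_cbsi", skipped=skipped)
    out.set_chrom_block("HbO", hbo)
    out.set_chrom_block("HbR", hbr)
    out.recompute_hbt()
    return out


def _tddr_channel(x: np.ndarray, fs: float, tune: float = 4.685,
                  max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Temporal derivative distribution repair of one series.

    The signal is split at 0.5 Hz (skipped when fs <= 1 Hz); the
    low-frequency part's temporal derivative is iteratively reweighted with
    Tukey's biweight (tuning constant 4.685 on the 1.4826*MAD robust scale),
    the weighted, centered derivative is re-integrated, and mean and
    high-frequency part are restored.
    """
    if fs > 1.0:
        # zero-phase low-pass split at 0.5 Hz
        sos = sps.butter(3, 0.5, btype="low", fs=fs, output="sos")
        low = sps.sosfiltfilt(sos, x)
    else:
        low = x.copy()
    high = x - low

    deriv = np.diff(low)
    w = np.ones_like(deriv)
    mu = 0.0
    for _ in range(max_iter):
        mu = np.sum(w * deriv) / np.sum(w)
        dev = deriv - mu
        sigma = 1.4826 * np.median(np.abs(dev))
        if sigma == 0:
            w_new = np.ones_like(w)
        else:
            r = dev / (tune * sigma)
            w_new = np.where(np.abs(r) < 1, (1 - r**2) ** 2, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    new_deriv = w * (deriv - mu)
    low_corr = np.concatenate(([0.0], np.cumsum(new_deriv)))
    low_corr += low.mean() - low_corr.mean()
    return low_corr + high


def motion_correct_tddr(rec: Recording) -> Recording:
    """Robust-regression repair of spikes and baseline shifts, per channel."""
    _check_nan_free(rec, "tddr")
    if rec.n_times < 10:
        raise ValueError("TDDR needs at least 10 samples")
    data = np.column_stack([_tddr_channel(rec.data[:, j], rec.fs)
                            for j in range(rec.data.shape[1])])
    out = rec.with_data(data, "motion_correct_tddr")
    out.recompute_hbt()
    return out


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

@dataclass
class FilterSpec:
    kind: str            # iir_butter | fir_hamming | fft_ideal
    mode: str            # low | high | band
    cutoffs_hz: tuple[float, ...]
    order: int
    keep_dc: bool = False  # fft_ideal band/high: re-add the mean afterwards


_DEFAULT_ORDERS = {"iir_butter": 3, "fir_hamming": 34, "fft_ideal": 0}


def design_filter(kind: str, mode: str, cutoffs_hz, order: int | None = None,
                  keep_dc: bool = False) -> FilterSpec:
    if kind not in _DEFAULT_ORDERS:
        raise ValueError(f"unknown filter kind {kind!r}")
    if mode not in ("low", "high", "band"):
        raise ValueError(f"unknown filter mode {mode!r}")
    cutoffs = tuple(float(c) for c in np.atleast_1d(cutoffs_hz))
    if mode == "band":
        if len(cutoffs) != 2 or cutoffs[0] >= cutoffs[1]:
            raise ValueError("band mode needs two strictly increasing cutoffs")
    elif len(cutoffs) != 1:
        raise ValueError(f"{mode} mode needs exactly one cutoff")
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    return FilterSpec(kind, mode, cutoffs, _DEFAULT_ORDERS[kind] if order is None else int(order),
                      keep_dc)


def _fft_ideal(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    n = x.shape[0]
    X = np.fft.rfft(x, axis=0)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    if spec.mode == "low":
        lo, hi = 0.0, spec.cutoffs_hz[0]
    elif spec.mode == "high":
        lo, hi = spec.cutoffs_hz[0], np.inf
    else:
        lo, hi = spec.cutoffs_hz
    keep = (f >= lo) & (f <= hi)
    # DC is zeroed for band/high-pass unless keep_dc re-adds the mean
    keep[0] = (spec.mode == "low") or spec.keep_dc
    X[~keep] = 0.0
    return np.fft.irfft(X, n=n, axis=0)


def _butter_sos(spec: FilterSpec, fs: float):
    btype = {"low": "lowpass", "high": "highpass", "band": "bandpass"}[spec.mode]
    wn = spec.cutoffs_hz if spec.mode == "band" else spec.cutoffs_hz[0]
    return sps.butter(spec.order, wn, btype=btype, fs=fs, output="sos")


def fir_taps(spec: FilterSpec, fs: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR taps (numtaps = order + 1)."""
    numtaps = spec.order + 1
    pass_zero = {"low": True, "high": False, "band": False}[spec.mode]
    if spec.mode == "high" and numtaps % 2 == 0:
        numtaps += 1  # type-I filter needed for high-pass
    return sps.firwin(numtaps, spec.cutoffs_hz, window="hamming",
                      pass_zero=pass_zero, fs=fs)


def frequency_response(spec: FilterSpec, fs: float, freqs_hz) -> np.ndarray:
    """Single-pass magnitude response |H(f)| of a designed filter.

    For the Butterworth IIR this is the one-pass response; the zero-phase
    application in :func:`apply_filter` realizes |H|^2.  The FFT-ideal
    filter's response is the 0/1 indicator of the passband.
    """
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if spec.kind == "iir_butter":
        _, h = sps.sosfreqz(_butter_sos(spec, fs), worN=2 * np.pi * freqs / fs)
        return np.abs(h)
    if spec.kind == "fir_hamming":
        _, h = sps.freqz(fir_taps(spec, fs), worN=2 * np.pi * freqs / fs)
        return np.abs(h)
    if spec.mode == "low":
        lo, hi = 0.0, spec.cutoffs_hz[0]
    elif spec.mode == "high":
        lo, hi = spec.cutoffs_hz[0], np.inf
    else:
        lo, hi = spec.cutoffs_hz
    return ((freqs >= lo) & (freqs <= hi)).astype(float)


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Apply a designed filter to every column.

    Butterworth IIR runs forward-backward (zero-phase; effective magnitude
    response |H|^2).  FIR runs single-pass with group-delay compensation of
    order/2 samples.  The FFT-ideal filter zeroes every bin strictly
    outside the passband.
    """
    _check_nan_free(rec, "filter")
    nyq = rec.fs / 2.0
    if any(c >= nyq for c in spec.cutoffs_hz):
        raise ValueError(f"cutoff at or above Nyquist ({nyq} Hz)")
    x = rec.data
    if spec.kind == "fft_ideal":
        y = _fft_ideal(x, rec.fs, spec)
    elif spec.kind == "iir_butter":
        y = sps.sosfiltfilt(_butter_sos(spec, rec.fs), x, axis=0)
    elif spec.kind == "fir_hamming":
        taps = fir_taps(spec, rec.fs)
        delay = (len(taps) - 1) // 2
        # pad with edge values so the delay compensation has real samples
        padded = np.concatenate([x, x[-1:].repeat(delay, axis=0)], axis=0)
        y = sps.lfilter(taps, 1.0, padded, axis=0)[delay:]
    else:
        raise ValueError(f"unknown filter kind {spec.kind!r}")
    out = rec.with_data(y, "filter", kind=spec.kind, mode=spec.mode,
                        cutoffs_hz=list(spec.cutoffs_hz), order=spec.order)
    out.recompute_hbt()
    return out


# ----------------------------------------------------------------------
# nuisance regression
# ----------------------------------------------------------------------

def regress_noise(rec: Recording, regressor_channels: list[int] | None = None,
                  external_series: np.ndarray | None = None) -> Recording:
    """Remove superficial/systemic noise by ordinary least squares.

    Regressors are the time series of designated short-separation channels
    (1-based ids) and/or external series.  Each remaining channel is
    regressed on [intercept + regressors]; the residual plus intercept is
    returned.  Collinear regressor columns are dropped with a warning.
    Per-column R^2 values are recorded in the history.
    """
    _check_nan_free(rec, "regress_noise")
    regs = []
    short_cols: set[int] = set()
    if regressor_channels:
        n = rec.n_channels
        n_blocks = rec.data.shape[1] // n
        for cid in regressor_channels:
            if not 1 <= cid <= n:
                raise ValueError(f"no channel {cid}")
            for b in range(n_blocks):
                short_cols.add(b * n + cid - 1)
        regs.append(rec.data[:, sorted(short_cols)])
    if external_series is not None:
        ext = np.atleast_2d(np.asarray(external_series, dtype=float))
        if ext.shape[0] != rec.n_times:
            ext = ext.T
        if ext.shape[0] != rec.n_times:
            raise ValueError("external regressors must have length T")
        regs.append(ext)
    if not regs:
        raise ValueError("no regressors given")
    R = np.hstack(regs)

    # drop collinear columns via rank-revealing QR on the centered regressors
    Rc = R - R.mean(axis=0)
    keep: list[int] = []
    for j in range(Rc.shape[1]):
        cand = Rc[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-10 * max(1.0, np.abs(cand).max())) > len(keep):
            keep.append(j)
    if len(keep) < R.shape[1]:
        warnings.warn(f"dropped {R.shape[1] - len(keep)} collinear regressor column(s)")
    X = np.column_stack([np.ones(rec.n_times), R[:, keep]])

    data = rec.data.copy()
    target_cols = [j for j in range(data.shape[1]) if j not in short_cols]
    Y = data[:, target_cols]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    resid = Y - fitted
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    ss_res = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    data[:, target_cols] = resid + beta[0]  # residual + intercept
    out = rec.with_data(data, "regress_noise",
                        regressor_channels=list(regressor_channels or []),
                        n_external=0 if external_series is None else X.shape[1] - 1,
                        r2=[float(v) for v in r2])
    out.recompute_hbt()
    return out


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------

def resample(rec: Recording, new_fs: float) -> Recording:
    """Polyphase anti-aliased rational resampling to ``new_fs``."""
    _check_nan_free(rec, "resample")
    if new_fs <= 0:
        raise ValueError("new_fs must be positive")
    if new_fs / rec.fs > 100:
        raise ValueError("refusing upsampling factor > 100")
    if np.isclose(new_fs, rec.fs):
        return rec.with_data(rec.data.copy(), "resample", new_fs=new_fs)
    frac = Fraction(new_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    y = sps.resample_poly(rec.data, up, down, axis=0)
    t_expect = int(round(rec.n_times * new_fs / rec.fs))
    y = y[:t_expect] if y.shape[0] >= t_expect else np.pad(
        y, ((0, t_expect - y.shape[0]), (0, 0)), mode="edge")
    out = rec.with_data(y, "resample", new_fs=new_fs)
    out.fs = float(new_fs)
    out.recompute_hbt()
    return out


# ----------------------------------------------------------------------
# missing data
# ----------------------------------------------------------------------

def interpolate_missing(rec: Recording) -> Recording:
    """Linearly interpolate NaN samples per column (edges held constant)."""
    data = rec.data.copy()
    t = np.arange(rec.n_times)
    n_filled = 0
    for j in range(data.shape[1]):
        bad = np.isnan(data[:, j])
        if bad.all():
            raise ValueError(f"column {j} is entirely missing; drop the channel instead")
        if bad.any():
            data[bad, j] = np.interp(t[bad], t[~bad], data[~bad, j])
            n_filled += int(bad.sum())
    return rec.with_data(data, "interpolate_missing", n_filled=n_filled)


# ----------------------------------------------------------------------
# custom steps + pipelines
# ----------------------------------------------------------------------

_BUILTINS = {
    "trim": trim,
    "detrend": detrend,
    "motion_correct_cbsi": motion_correct_cbsi,
    "motion_correct_tddr": motion_correct_tddr,
    "regress_noise": regress_noise,
    "resample": resample,
    "interpolate_missing": interpolate_missing,
}

_CUSTOM_STEPS: dict[str, object] = {}


def register_custom_step(name: str, func) -> None:
    """Register a user processing step.

    ``func`` maps ``(data: T x C array, fs: float, params: dict) -> array``
    of the same shape.  The step becomes invocable from a pipeline by name
    and is logged in the history like built-ins.
    """
    if name in _BUILTINS or name == "filter":
        raise ValueError(f"{name!r} shadows a built-in step")
    if not callable(func):
        raise TypeError("custom step must be callable")
    _CUSTOM_STEPS[name] = func


def apply_custom_step(rec: Recording, name: str, **params) -> Recording:
    func = _CUSTOM_STEPS[name]
    out_data = np.asarray(func(rec.data.copy(), rec.fs, dict(params)), dtype=float)
    if out_data.shape != rec.data.shape:
        raise ValueError(
            f"custom step {name!r} changed the data shape "
            f"{rec.data.shape} -> {out_data.shape}"
        )
    out = rec.with_data(out_data, name, **params)
    out.recompute_hbt()
    return out


@dataclass
class PipelineSpec:
    """Ordered preprocessing recipe, serializable to YAML and back."""

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def to_yaml(self) -> str:
        return yaml.safe_dump({"steps": [{"name": n, "params": p} for n, p in self.steps]},
                              sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineSpec":
        obj = yaml.safe_load(text)
        return cls([(s["name"], dict(s.get("params") or {})) for s in obj["steps"]])

    def validate(self) -> None:
        for name, _ in self.steps:
            if name not in _BUILTINS and name != "filter" and name not in _CUSTOM_STEPS:
                raise ValueError(f"unknown step {name!r}")


def default_resting_pipeline() -> PipelineSpec:
    """Trim, linear detrend, TDDR, 0.01-0.08 Hz third-order Butterworth band-pass."""
    return PipelineSpec([
        ("trim", {"drop_start_s": 10.0}),
        ("detrend", {"order": 1}),
        ("motion_correct_tddr", {}),
        ("filter", {"kind": "iir_butter", "mode": "band",
                    "cutoffs_hz": [0.01, 0.08], "order": 3}),
    ])


def run_pipeline(rec: Recording, spec: PipelineSpec) -> Recording:
    """Left-to-right composition of the pipeline's steps."""
    spec.validate()
    out = rec
    for name, params in spec.steps:
        if name == "filter":
            fspec = design_filter(params["kind"], params["mode"], params["cutoffs_hz"],
                                  params.get("order"), params.get("keep_dc", False))
            out = apply_filter(out, fspec)
        elif name in _BUILTINS:
            out = _BUILTINS[name](out, **params)
        else:
            out = apply_custom_step(out, name, **params)
    return out
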