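"""Individual-level resting-state indices.

Amplitude spectra via the finite Fourier series

    x(t) = a0 + sum_k [ a_k cos(2 pi f_k t) + b_k sin(2 pi f_k t) ]
         = a0 + sum_k A_k cos(2 pi f_k t - phi_k),    f_k = k fs / N,

ALFF (mean in-band amplitude, band default 0.01-0.08 Hz inclusive), fALFF
(in-band amplitude over total amplitude, DC excluded from both sums), their
channelwise z-standardized maps, Pearson functional-connectivity matrices
in three modes (whole-brain channelwise, ROI-to-ROI, ROI-to-whole-brain),
and absolute / sparsity thresholding with plain-text network export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

__all__ = [
    "SpectrumResult",
    "ALFFResult",
    "ConnectivityMatrix",
    "amplitude_spectrum",
    "compute_alff",
    "fc_matrix",
    "threshold_matrix",
    "export_network",
]


# ----------------------------------------------------------------------
# amplitude spectrum
# ----------------------------------------------------------------------

@dataclass
class SpectrumResult:
    fk: np.ndarray    # Hz, k = 1 .. floor(N/2)
    Ak: np.ndarray    # amplitude per bin, signal units
    phik: np.ndarray  # phase per bin, radians
    a0: float         # DC component (signal mean)
    N: int
    fs: float


def amplitude_spectrum(x: np.ndarray, fs: float) -> SpectrumResult:
    """One-sided amplitude spectrum of a real series.

    A_k = 2 |X_k| / N for interior bins; the Nyquist bin (even N) carries
    |X_k| / N.  Phases follow the cosine convention: the bin contributes
    A_k cos(2 pi f_k t - phi_k).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    X = np.fft.rfft(x)
    k_max = n // 2
    fk = np.arange(1, k_max + 1) * fs / n
    scale = np.full(k_max, 2.0 / n)
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    Ak = np.abs(X[1: k_max + 1]) * scale
    # X_k = (N/2)(a_k - i b_k); phi_k = atan2(b_k, a_k)
    phik = np.arctan2(-X[1: k_max + 1].imag, X[1: k_max + 1].real)
    return SpectrumResult(fk=fk, Ak=Ak, phik=phik, a0=float(x.mean()), N=n, fs=fs)


# ----------------------------------------------------------------------
# ALFF / fALFF
# ----------------------------------------------------------------------

@dataclass
class ALFFResult:
    alff: np.ndarray
    falff: np.ndarray
    zalff: np.ndarray
    zfalff: np.ndarray
    band: tuple[float, float]
    n_bins: int  # number of in-band frequency components


def _zscore_population(v: np.ndarray) -> np.ndarray:
    """Z-scores with the population (divide-by-n) standard deviation."""
    valid = ~np.isnan(v)
    sd = np.std(v[valid])
    if sd == 0:
        raise ValueError("cannot z-standardize: all channel values identical (sd = 0)")
    out = np.full_like(v, np.nan, dtype=float)
    out[valid] = (v[valid] - v[valid].mean()) / sd
    return out


def compute_alff(rec: Recording, band: tuple[float, float] = (0.01, 0.08),
                 chromophore: str | None = "HbO") -> ALFFResult:
    """ALFF and fALFF per channel, with z-standardized maps.

    ALFF is the mean amplitude over bins with f_lo <= f_k <= f_hi
    (inclusive); fALFF is the in-band amplitude sum over the total sum
    across all non-DC bins, so it lies in [0, 1].  Note fALFF is only
    meaningful on wide-band data: band-passed input drives it toward 1.
    z-maps use the population standard deviation across channels.
    """
    lo, hi = band
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError("band must satisfy 0 < f_lo < f_hi < fs/2")
    if rec.signal_kind == "hb" and chromophore is not None:
        data = rec.chrom_block(chromophore)
    else:
        data = rec.data
    n_ch = data.shape[1]
    alff = np.empty(n_ch)
    falff = np.empty(n_ch)
    n_bins = 0
    for j in range(n_ch):
        spec = amplitude_spectrum(data[:, j], rec.fs)
        in_band = (spec.fk >= lo) & (spec.fk <= hi)
        n_bins = int(in_band.sum())
        if n_bins == 0:
            raise ValueError("no frequency bins inside the requested band")
        alff[j] = spec.Ak[in_band].mean()
        total = spec.Ak.sum()
        falff[j] = spec.Ak[in_band].sum() / total if total > 0 else np.nan
    if np.isnan(falff).any():
        warnings.warn("fALFF undefined for zero-amplitude channel(s); reported as NaN")
    return ALFFResult(alff=alff, falff=falff,
                      zalff=_zscore_population(alff),
                      zfalff=_zscore_population(falff),
                      band=(lo, hi), n_bins=n_bins)


# ----------------------------------------------------------------------
# functional connectivity
# ----------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    values: np.ndarray
    mode: str                       # roi2roi | roi2whole | wholebrain
    channel_ids: list[int] = field(default_factory=list)
    fisher_z: bool = False
    threshold_state: tuple | None = None  # ("absolute", tau) | ("sparsity", s, attained)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _pearson_matrix(series: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlation; zero-variance columns give NaN rows."""
    sd = series.std(axis=0)
    # effectively-constant columns (allow for round-off in the mean)
    bad = sd <= 1e-12 * np.maximum(1.0, np.abs(series).max(axis=0))
    if bad.any():
        warnings.warn(f"zero-variance series at index(es) {np.where(bad)[0].tolist()}; "
                      "their correlations are reported as NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(series, rowvar=False)
    r = np.atleast_2d(r)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    # clip rounding excursions outside [-1, 1]
    return np.clip(r, -1.0, 1.0, out=r)


def fc_matrix(rec: Recording, chromophore: str | None = "HbO", mode: str = "wholebrain",
              roi_sets: list[list[int]] | None = None, fisher_z: bool = False) -> ConnectivityMatrix:
    """Pearson functional connectivity.

    - ``wholebrain``: channels x channels correlation matrix.
    - ``roi2roi``: ROI time series are the unweighted means of their member
      channels; correlations between ROI series.
    - ``roi2whole``: the first ROI is the seed; a 1 x C correlation map.

    ``fisher_z`` applies z = arctanh(r) to off-diagonal entries (recommended
    before group-level statistics on FC values).
    """
    if rec.signal_kind == "hb" and chromophore is not None:
        data = rec.chrom_block(chromophore)
    else:
        data = rec.data
    if data.shape[1] < 2:
        raise ValueError("need at least 2 channels")

    if mode == "wholebrain":
        values = _pearson_matrix(data)
        ids = [c.id for c in rec.channels]
    elif mode in ("roi2roi", "roi2whole"):
        if not roi_sets or any(len(s) == 0 for s in roi_sets):
            raise ValueError("ROI modes need nonempty roi_sets of channel ids")
        roi_series = np.column_stack([data[:, [cid - 1 for cid in s]].mean(axis=1)
                                      for s in roi_sets])
        if mode == "roi2roi":
            values = _pearson_matrix(roi_series)
            ids = list(range(1, len(roi_sets) + 1))
        else:
            seed = roi_series[:, 0]
            full = _pearson_matrix(np.column_stack([seed, data]))
            values = full[0:1, 1:]
            ids = [c.id for c in rec.channels]
    else:
        raise ValueError(f"unknown FC mode {mode!r}")

    if fisher_z:
        v = values.copy()
        off = ~np.eye(v.shape[0], v.shape[1], dtype=bool) if mode != "roi2whole" \
            else np.ones_like(v, dtype=bool)
        with np.errstate(divide="ignore"):
            v[off] = np.arctanh(np.clip(v[off], -1 + 1e-16, 1 - 1e-16))
        values = v
    return ConnectivityMatrix(values=values, mode=mode, channel_ids=ids, fisher_z=fisher_z)


# ----------------------------------------------------------------------
# thresholding & export
# ----------------------------------------------------------------------

def threshold_matrix(cm: ConnectivityMatrix, method: str, value: float) -> ConnectivityMatrix:
    """Threshold a square connectivity matrix for network analysis.

    - ``absolute``: keep off-diagonal entries strictly greater than tau.
    - ``sparsity``: keep the floor(s * C(C-1)/2) largest off-diagonal
      entries (upper triangle); ties at the cutoff are all kept and the
      attained sparsity is reported.
    """
    if cm.threshold_state is not None:
        raise ValueError("matrix is already thresholded")
    v = cm.values
    n = v.shape[0]
    if v.shape != (n, n):
        raise ValueError("thresholding needs a square matrix")
    out = v.copy()
    np.fill_diagonal(out, 0.0)
    if method == "absolute":
        tau = float(value)
        out[out <= tau] = 0.0
        state: tuple = ("absolute", tau)
    elif method == "sparsity":
        s = float(value)
        if not 0 < s <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        iu = np.triu_indices(n, k=1)
        vals = out[iu]
        m = len(vals)
        k = int(np.floor(s * m))
        if k == 0:
            cutoff = np.inf
        else:
            cutoff = np.sort(vals)[::-1][k - 1]
        keep = vals >= cutoff
        new_vals = np.where(keep, vals, 0.0)
        out[:] = 0.0
        out[iu] = new_vals
        out += out.T
        state = ("sparsity", s, float(keep.sum()) / m if m else 0.0)
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return ConnectivityMatrix(values=out, mode=cm.mode, channel_ids=list(cm.channel_ids),
                              fisher_z=cm.fisher_z, threshold_state=state)


def export_network(cm: ConnectivityMatrix, path) -> None:
    """Write the (thresholded) matrix as a plain-text square matrix,
    loadable by common graph-metric toolkits."""
    v = cm.values
    if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
        raise ValueError("export_network needs a symmetric square matrix")
    np.savetxt(path, v, fmt="%.10g", delimiter="\t")
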