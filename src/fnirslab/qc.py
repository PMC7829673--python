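"""Quality-control computations behind data previewing.

Periodograms (squared amplitude spectra, sharing the amplitude-spectrum
code path of the resting module), per-channel quality metrics to support
exclusion decisions (variance, robust spike count, flatline and missing
fractions), task reference time series with their periodograms, and
optional static plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import build_design
from .recording import Recording, TaskDesign
from .resting import SpectrumResult, amplitude_spectrum

__all__ = ["QCReport", "periodogram", "qc_summary", "task_reference", "plot_channels"]


def periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(frequencies, power) with power_k = A_k^2 / 2, DC excluded."""
    spec = amplitude_spectrum(np.nan_to_num(np.asarray(x, dtype=float)), fs)
    power = spec.Ak**2 / 2.0
    if spec.N % 2 == 0:
        power[-1] = spec.Ak[-1] ** 2  # Nyquist bin carries no conjugate partner
    return spec.fk, power


@dataclass
class QCReport:
    variance: np.ndarray
    spike_count: np.ndarray
    flatline_fraction: np.ndarray
    missing_fraction: np.ndarray
    duration_s: float
    fs: float
    spectra: dict[int, SpectrumResult]


def qc_summary(rec: Recording, spike_k: float = 5.0,
               spectrum_channels: list[int] | None = None) -> QCReport:
    """Deterministic per-channel quality metrics.

    A spike is a sample more than ``spike_k`` times the median absolute
    deviation (MAD) away from the channel median; flatline fraction is the
    share of zero first differences; missing fraction counts NaNs.
    """
    data = rec.data
    t, c = data.shape
    variance = np.empty(c)
    spikes = np.empty(c, dtype=int)
    flat = np.empty(c)
    missing = np.empty(c)
    for j in range(c):
        x = data[:, j]
        ok = ~np.isnan(x)
        missing[j] = 1.0 - ok.mean()
        xv = x[ok]
        if xv.size == 0:
            variance[j], spikes[j], flat[j] = np.nan, 0, 0.0
            continue
        variance[j] = xv.var()
        med = np.median(xv)
        mad = np.median(np.abs(xv - med))
        if mad == 0:
            spikes[j] = int((xv != med).sum())
        else:
            spikes[j] = int((np.abs(xv - med) > spike_k * mad).sum())
        flat[j] = float((np.diff(xv) == 0).mean()) if xv.size > 1 else 1.0

    spectra = {}
    for cid in spectrum_channels or []:
        x = data[:, cid - 1]
        spectra[cid] = amplitude_spectrum(np.nan_to_num(x), rec.fs)
    return QCReport(variance=variance, spike_count=spikes, flatline_fraction=flat,
                    missing_fraction=missing, duration_s=rec.duration_s, fs=rec.fs,
                    spectra=spectra)


def task_reference(design: TaskDesign, n_times: int, fs: float,
                   conditions: list[str] | None = None) -> dict[str, dict]:
    """HRF-convolved reference series and periodogram per selected condition."""
    if conditions is None:
        conditions = design.condition_names
    out: dict[str, dict] = {}
    if not conditions:
        return out
    dm = build_design(design, n_times, fs)
    for name in conditions:
        idx = dm.labels.index(name)
        series = dm.X[:, idx]
        f, power = periodogram(series, fs)
        out[name] = {"series": series, "freq": f, "power": power}
    return out


def plot_channels(rec: Recording, channel_ids: list[int], path, kind: str = "time") -> None:
    """Static time-series or periodogram plot to PNG/SVG (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for cid in channel_ids:
        x = rec.data[:, cid - 1]
        if kind == "time":
            ax.plot(rec.times, x, lw=0.8, label=f"ch {cid}")
            ax.set_xlabel("time (s)")
        else:
            f, p = periodogram(x, rec.fs)
            ax.plot(f, p, lw=0.8, label=f"ch {cid}")
            ax.set_xlabel("frequency (Hz)")
            ax.set_ylabel("power")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
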