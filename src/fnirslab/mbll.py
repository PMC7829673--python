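"""Modified Beer-Lambert law: optical intensity -> optical density -> hemoglobin.

The conversion chain for continuous-wave fNIRS is

    OD(t, lambda) = -log10( I(t, lambda) / I0(lambda) )
    OD(t, lambda) = d * DPF(lambda) * [ eps_HbO(lambda) * dHbO(t)
                                        + eps_HbR(lambda) * dHbR(t) ]

where ``d`` is the source-detector separation (mm), DPF the dimensionless
differential pathlength factor, and ``eps`` molar extinction coefficients in
mm^-1 mM^-1.  With two wavelengths the 2x2 system is inverted per sample,
yielding concentration changes in mM (times mm of pathlength when DPF*d is
left at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MBLLParams",
    "extinction_table",
    "extinction_for_wavelengths",
    "intensity_to_od",
    "od_to_hb",
    "hb_to_od",
]

_DEFAULT_DPF = 6.0


def extinction_table() -> np.ndarray:
    """Packaged compiled extinction spectrum as (n, 3) array.

    Columns: wavelength_nm, eps_HbO, eps_HbR in mm^-1 mM^-1.
    """
    with resources.files("fnirslab.data").joinpath("extinction.tsv").open() as fh:
        raw = np.loadtxt(fh, comments="#", ndmin=2, delimiter="\t")
    out = raw.copy()
    out[:, 1:] *= 1e-4  # cm^-1 M^-1 -> mm^-1 mM^-1
    return out


def extinction_for_wavelengths(wavelengths_nm) -> np.ndarray:
    """2x2 extinction matrix [[eps(l1,HbO), eps(l1,HbR)], [eps(l2,...)]].

    Nearest-nm lookup into the packaged table.
    """
    table = extinction_table()
    rows = []
    for wl in wavelengths_nm:
        i = int(np.argmin(np.abs(table[:, 0] - wl)))
        rows.append(table[i, 1:3])
    return np.asarray(rows)


@dataclass
class MBLLParams:
    wavelengths: tuple[float, float] = (760.0, 850.0)
    extinction: np.ndarray | None = None  # 2x2, rows=wavelength, cols=(HbO, HbR)
    dpf: tuple[float, float] = (_DEFAULT_DPF, _DEFAULT_DPF)
    distance_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.extinction is None:
            self.extinction = extinction_for_wavelengths(self.wavelengths)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if not np.isfinite(np.linalg.cond(self.extinction)) or (
            np.linalg.cond(self.extinction) > 1e12
        ):
            raise ValueError("extinction matrix is singular")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF must be positive")
        if self.distance_mm <= 0:
            raise ValueError("source-detector distance must be positive")

    @property
    def pathlength(self) -> np.ndarray:
        """Effective pathlength d * DPF per wavelength, in mm."""
        return self.distance_mm * np.asarray(self.dpf, dtype=float)


def intensity_to_od(intensity: np.ndarray, i0: np.ndarray | None = None) -> np.ndarray:
    """Decadic optical density relative to a per-wavelength baseline.

    Parameters
    ----------
    intensity : (T, W) positive array of raw light intensities.
    i0 : per-wavelength baseline; defaults to the temporal mean of each column.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        bad = np.argwhere(intensity <= 0)
        raise ValueError(
            f"intensity must be positive; offending (sample, wavelength) indices: "
            f"{bad[:10].tolist()}{'...' if len(bad) > 10 else ''}"
        )
    if i0 is None:
        i0 = intensity.mean(axis=0)
    i0 = np.asarray(i0, dtype=float)
    return -np.log10(intensity / i0)


def od_to_hb(od: np.ndarray, params: MBLLParams | None = None) -> np.ndarray:
    """Invert the two-wavelength system; returns (T, 2) [dHbO, dHbR] in mM."""
    params = params or MBLLParams()
    od = np.asarray(od, dtype=float)
    if od.ndim != 2 or od.shape[1] != 2:
        raise ValueError("od must be T x 2 (one column per wavelength)")
    # A[w, c] = eps(w, c) * d * dpf(w);  OD = hb @ A.T  =>  hb = OD @ inv(A).T
    A = params.extinction * params.pathlength[:, None]
    return np.linalg.solve(A, od.T).T


def hb_to_od(hb: np.ndarray, params: MBLLParams | None = None) -> np.ndarray:
    """Forward model: concentration changes -> optical density (oracle of od_to_hb)."""
    params = params or MBLLParams()
    hb = np.asarray(hb, dtype=float)
    A = params.extinction * params.pathlength[:, None]
    return hb @ A.T
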