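"""Read and write SNIRF (Shared Near-Infrared Spectroscopy Format) files.

SNIRF is the fNIRS community's HDF5-based exchange standard.  Only the
single-data-block layout is supported: ``/nirs/data1`` with one
``measurementList`` entry per data column.  Continuous-wave amplitude
(dataType 1) maps to ``signal_kind="intensity"``; processed data
(dataType 99999) map to optical density (label ``dOD``) or hemoglobin
concentration (labels ``HbO``/``HbR``/``HbT``).

Time must be uniformly sampled: either the compact ``[start, dt]`` form or
a full time vector with relative jitter below 1e-6.  Nonuniform files are
rejected rather than silently resampled, since resampling would corrupt
downstream spectral analyses.
"""

from __future__ import annotations

import numpy as np
import h5py

from .recording import ChannelInfo, Recording

__all__ = ["read_snirf", "write_snirf", "SnirfFormatError"]

_DT_CW_AMPLITUDE = 1
_DT_PROCESSED = 99999

# relative jitter above which a full time vector is considered nonuniform
_JITTER_TOL = 1e-6


class SnirfFormatError(ValueError):
    """Raised when a file does not follow the expected SNIRF layout."""


def _read_str(ds) -> str:
    v = ds[()]
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.ndarray):
        v = v.item()
        if isinstance(v, bytes):
            return v.decode()
    return str(v)


def _require(group, name: str):
    if name not in group:
        raise SnirfFormatError(f"missing required SNIRF group or dataset: {name!r}")
    return group[name]


def _fs_from_time(time: np.ndarray) -> float:
    time = np.asarray(time, dtype=float).ravel()
    if time.size == 2:
        # compact [start, dt] form
        if time[1] <= 0:
            raise SnirfFormatError("time step must be positive")
        return 1.0 / time[1]
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise SnirfFormatError("time vector must be strictly increasing")
    jitter = (dt.max() - dt.min()) / dt.mean()
    if jitter > _JITTER_TOL:
        raise SnirfFormatError(
            f"nonuniform sampling (relative jitter {jitter:.3g} > {_JITTER_TOL}); "
            "resample externally before import"
        )
    return 1.0 / dt.mean()


def read_snirf(path) -> Recording:
    """Load a single-block SNIRF file into a :class:`Recording`."""
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs")
        data1 = _require(nirs, "data1")
        dts = np.asarray(_require(data1, "dataTimeSeries")[()], dtype=float)
        fs = _fs_from_time(_require(data1, "time")[()])

        n_cols = dts.shape[1]
        ml = []
        for i in range(1, n_cols + 1):
            g = _require(data1, f"measurementList{i}")
            entry = {
                "source": int(_require(g, "sourceIndex")[()]),
                "detector": int(_require(g, "detectorIndex")[()]),
                "dataType": int(_require(g, "dataType")[()]),
                "wavelengthIndex": int(g["wavelengthIndex"][()]) if "wavelengthIndex" in g else 1,
                "label": _read_str(g["dataTypeLabel"]) if "dataTypeLabel" in g else None,
            }
            ml.append(entry)

        probe = _require(nirs, "probe")
        wavelengths = tuple(np.atleast_1d(np.asarray(_require(probe, "wavelengths")[()],
                                                     dtype=float)).tolist())
        src_pos = None
        for key in ("sourcePos3D", "sourcePos2D"):
            if key in probe:
                src_pos = np.atleast_2d(np.asarray(probe[key][()], dtype=float))
                break
        det_pos = None
        for key in ("detectorPos3D", "detectorPos2D"):
            if key in probe:
                det_pos = np.atleast_2d(np.asarray(probe[key][()], dtype=float))
                break

    # classify signal kind from the measurement list
    dtypes = {e["dataType"] for e in ml}
    labels = {e["label"] for e in ml if e["label"] is not None}
    if dtypes == {_DT_CW_AMPLITUDE}:
        kind, chromophores = "intensity", ()
    elif dtypes == {_DT_PROCESSED} and labels <= {"dOD"}:
        kind, chromophores = "optical_density", ()
    elif dtypes == {_DT_PROCESSED} and labels <= {"HbO", "HbR", "HbT"}:
        kind = "hb"
        order = [c for c in ("HbO", "HbR", "HbT") if c in labels]
        chromophores = tuple(order)
    else:
        raise SnirfFormatError(f"unsupported mix of data types {dtypes} / labels {labels}")

    # unique (source, detector) pairs in order of first appearance
    pairs: list[tuple[int, int]] = []
    for e in ml:
        p = (e["source"], e["detector"])
        if p not in pairs:
            pairs.append(p)
    channels = []
    for cid, (s, d) in enumerate(pairs, start=1):
        layout = mni = None
        if src_pos is not None and det_pos is not None:
            mid = (src_pos[s - 1] + det_pos[d - 1]) / 2.0
            if mid.size >= 3 and np.any(mid[2:] != 0):
                mni = tuple(float(x) for x in mid[:3])
            layout = (float(mid[0]), float(mid[1]))
        channels.append(ChannelInfo(id=cid, source_idx=s, detector_idx=d,
                                    layout_xy=layout, mni_xyz=mni))

    # reorder columns into block layout: block-major over chromophore (hb) or
    # wavelength index (intensity / OD), channel-minor
    pair_index = {p: i for i, p in enumerate(pairs)}
    n_ch = len(pairs)
    if kind == "hb":
        blocks = {c: k for k, c in enumerate(chromophores)}
        col_order = np.empty(len(ml), dtype=int)
        for src_col, e in enumerate(ml):
            col_order[blocks[e["label"]] * n_ch + pair_index[(e["source"], e["detector"])]] = src_col
    else:
        col_order = np.empty(len(ml), dtype=int)
        for src_col, e in enumerate(ml):
            w = e["wavelengthIndex"] - 1
            col_order[w * n_ch + pair_index[(e["source"], e["detector"])]] = src_col
    data = dts[:, col_order]

    return Recording(data=data, fs=fs, signal_kind=kind, channels=channels,
                     chromophores=chromophores, wavelengths=wavelengths)


def write_snirf(rec: Recording, path) -> None:
    """Write a :class:`Recording` to a SNIRF file readable by :func:`read_snirf`."""
    if rec.n_channels == 0:
        raise ValueError("cannot write a recording with no channels")
    n_ch = rec.n_channels
    if rec.signal_kind == "hb":
        n_blocks = len(rec.chromophores)
    else:
        n_blocks = rec.data.shape[1] // n_ch
        if n_blocks * n_ch != rec.data.shape[1]:
            raise ValueError("column count is not a multiple of the channel count")

    wavelengths = rec.wavelengths or (760.0, 850.0)

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=np.asarray(rec.data, dtype=np.float64))
        data1.create_dataset("time", data=np.array([0.0, 1.0 / rec.fs]))

        col = 0
        for b in range(n_blocks):
            for ch in rec.channels:
                col += 1
                g = data1.create_group(f"measurementList{col}")
                g.create_dataset("sourceIndex", data=ch.source_idx)
                g.create_dataset("detectorIndex", data=ch.detector_idx)
                if rec.signal_kind == "intensity":
                    g.create_dataset("dataType", data=_DT_CW_AMPLITUDE)
                    g.create_dataset("wavelengthIndex", data=b + 1)
                    g.create_dataset("dataTypeIndex", data=1)
                else:
                    g.create_dataset("dataType", data=_DT_PROCESSED)
                    g.create_dataset("dataTypeIndex", data=1)
                    if rec.signal_kind == "optical_density":
                        g.create_dataset("dataTypeLabel", data="dOD")
                        g.create_dataset("wavelengthIndex", data=b + 1)
                    else:
                        g.create_dataset("dataTypeLabel", data=rec.chromophores[b])
                        g.create_dataset("wavelengthIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=float))
        n_src = max(ch.source_idx for ch in rec.channels)
        n_det = max(ch.detector_idx for ch in rec.channels)
        src3 = np.zeros((n_src, 3))
        det3 = np.zeros((n_det, 3))
        for ch in rec.channels:
            if ch.mni_xyz is not None:
                src3[ch.source_idx - 1] = ch.mni_xyz
                det3[ch.detector_idx - 1] = ch.mni_xyz
            elif ch.layout_xy is not None:
                src3[ch.source_idx - 1, :2] = ch.layout_xy
                det3[ch.detector_idx - 1, :2] = ch.layout_xy
        probe.create_dataset("sourcePos3D", data=src3)
        probe.create_dataset("detectorPos3D", data=det3)
        probe.create_dataset("sourceLabels", data=[f"S{i}" for i in range(1, n_src + 1)])
        probe.create_dataset("detectorLabels", data=[f"D{i}" for i in range(1, n_det + 1)])

        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="anonymous")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
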