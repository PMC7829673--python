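"""Plain-text I/O: manual CSV time series, probe setups, task designs,
node/edge connectome export.

The manual CSV dialect is the escape hatch for recording systems without a
dedicated reader: comma-separated, ``.`` decimal, UTF-8, one header row of
column labels, one row per sample.  For hemoglobin data the columns are
chromophore blocks — all HbO channels first, then all HbR channels — which
the header makes explicit (``HbO_1 ... HbO_n, HbR_1 ... HbR_n``).  HbT is
always derived as HbO + HbR, never stored.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .recording import ChannelInfo, ProbeSetup, Recording, TaskDesign, make_channels

__all__ = [
    "read_csv_manual",
    "write_csv_manual",
    "load_probe_setup",
    "save_probe_setup",
    "probe_to_channels",
    "standard_probe_3x5",
    "load_task_design",
    "save_task_design",
    "load_mni_table",
    "export_node_edge",
    "read_edge_file",
]


# ----------------------------------------------------------------------
# manual CSV dialect
# ----------------------------------------------------------------------

def read_csv_manual(path, fs: float, signal_kind: str = "hb",
                    chromophores: tuple[str, ...] = ("HbO", "HbR")) -> Recording:
    """Read the manual CSV dialect into a :class:`Recording`.

    ``NaN`` cells are accepted and stored as missing; the count is recorded
    in the recording's history (and surfaces in the QC summary).
    """
    rows: list[list[str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if row:
                rows.append(row)
    if len(rows) < 2:
        raise ValueError("CSV must contain a header row and at least 2 data rows")
    header, data_rows = rows[0], rows[1:]
    ncols = len(header)
    for i, row in enumerate(data_rows):
        if len(row) != ncols:
            raise ValueError(f"ragged CSV: row {i + 2} has {len(row)} cells, expected {ncols}")

    try:
        data = np.array([[float(c) for c in row] for row in data_rows], dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in CSV: {exc}") from None

    if signal_kind == "hb":
        n_chrom = len(chromophores)
        if ncols % n_chrom:
            raise ValueError(
                f"column count {ncols} not divisible by chromophore count {n_chrom}"
            )
        n_channels = ncols // n_chrom
    else:
        chromophores = ()
        n_channels = ncols

    rec = Recording(data=data, fs=fs, signal_kind=signal_kind,
                    channels=make_channels(n_channels), chromophores=chromophores)
    rec.log_step("read_csv_manual", path=str(path), fs=fs,
                 n_missing=int(np.isnan(data).sum()))
    return rec


def write_csv_manual(rec: Recording, path) -> None:
    """Write the data matrix in the manual CSV dialect (HbT omitted)."""
    if rec.signal_kind == "hb":
        chroms = [c for c in rec.chromophores if c != "HbT"]
        blocks = [rec.chrom_block(c) for c in chroms]
        data = np.hstack(blocks)
        header = [f"{c}_{ch.id}" for c in chroms for ch in rec.channels]
    else:
        data = rec.data
        n_blocks = data.shape[1] // rec.n_channels
        header = [f"col{b + 1}_{ch.id}" for b in range(n_blocks) for ch in rec.channels]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in data:
            w.writerow([repr(float(v)) for v in row])


# ----------------------------------------------------------------------
# probe setup
# ----------------------------------------------------------------------

def load_probe_setup(path) -> ProbeSetup:
    """Probe setup from JSON text: {"sources": [[label,x,y]...], "detectors": ..., "pairs": [[s,d]...]}"""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return ProbeSetup(
        sources=[(str(l), float(x), float(y)) for l, x, y in obj["sources"]],
        detectors=[(str(l), float(x), float(y)) for l, x, y in obj["detectors"]],
        channel_pairs=[(int(s), int(d)) for s, d in obj["pairs"]],
    )


def save_probe_setup(probe: ProbeSetup, path) -> None:
    obj = {
        "sources": [[l, x, y] for l, x, y in probe.sources],
        "detectors": [[l, x, y] for l, x, y in probe.detectors],
        "pairs": [[s, d] for s, d in probe.channel_pairs],
    }
    Path(path).write_text(json.dumps(obj, indent=1), encoding="utf-8")


def probe_to_channels(probe: ProbeSetup) -> list[ChannelInfo]:
    """Channel list with layout coordinates at source-detector midpoints."""
    channels = []
    for cid, (s, d) in enumerate(probe.channel_pairs, start=1):
        sx, sy = probe.sources[s - 1][1:]
        dx, dy = probe.detectors[d - 1][1:]
        channels.append(ChannelInfo(id=cid, source_idx=s, detector_idx=d,
                                    layout_xy=((sx + dx) / 2, (sy + dy) / 2)))
    return channels


def standard_probe_3x5(x_offset: float = 0.0, spacing: float = 30.0) -> ProbeSetup:
    """A standard 3x5 optode grid: 8 sources and 7 detectors alternating on a
    3-row by 5-column lattice, with one channel per adjacent optode pair.

    Yields 22 measurement channels; two such probes (e.g. one per hemisphere,
    offset in x) give the common 44-channel montage.
    """
    sources, detectors = [], []
    grid: dict[tuple[int, int], tuple[str, int]] = {}
    for r in range(3):
        for c in range(5):
            x, y = x_offset + c * spacing, -r * spacing
            if (r + c) % 2 == 0:
                sources.append((f"S{len(sources) + 1}", x, y))
                grid[(r, c)] = ("s", len(sources))
            else:
                detectors.append((f"D{len(detectors) + 1}", x, y))
                grid[(r, c)] = ("d", len(detectors))
    pairs = []
    for r in range(3):
        for c in range(5):
            for r2, c2 in ((r, c + 1), (r + 1, c)):
                if (r2, c2) in grid:
                    a, b = grid[(r, c)], grid[(r2, c2)]
                    if a[0] == "s":
                        pairs.append((a[1], b[1]))
                    else:
                        pairs.append((b[1], a[1]))
    return ProbeSetup(sources=sources, detectors=detectors, channel_pairs=pairs)


# ----------------------------------------------------------------------
# task design
# ----------------------------------------------------------------------

def load_task_design(path) -> TaskDesign:
    """Task design from TSV with columns: condition, onset_s, duration_s."""
    conds: dict[str, tuple[list[float], list[float]]] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if [h.strip().lower() for h in header[:3]] != ["condition", "onset_s", "duration_s"]:
            raise ValueError("task design TSV must have header: condition\tonset_s\tduration_s")
        for row in reader:
            if not row or not row[0].strip():
                continue
            name, onset, dur = row[0].strip(), float(row[1]), float(row[2])
            conds.setdefault(name, ([], []))
            conds[name][0].append(onset)
            conds[name][1].append(dur)
    return TaskDesign([(name, on, du) for name, (on, du) in conds.items()])


def save_task_design(design: TaskDesign, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["condition", "onset_s", "duration_s"])
        for name, onsets, durations in design.conditions:
            for o, d in zip(onsets, durations):
                w.writerow([name, repr(float(o)), repr(float(d))])


def load_mni_table(path) -> np.ndarray:
    """Per-channel MNI coordinates from TSV: channel, x, y, z (mm)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            if row and row[0].strip():
                rows.append((int(row[0]), float(row[1]), float(row[2]), float(row[3])))
    rows.sort()
    if [r[0] for r in rows] != list(range(1, len(rows) + 1)):
        raise ValueError("MNI table must list channels 1..n exactly once")
    return np.array([r[1:] for r in rows], dtype=float)


# ----------------------------------------------------------------------
# node / edge connectome export
# ----------------------------------------------------------------------

def export_node_edge(matrix: np.ndarray, coords: np.ndarray, path_prefix,
                     labels: list[str] | None = None) -> tuple[Path, Path]:
    """Write BrainNet-style ``.node`` and ``.edge`` text files.

    The node file has one line per channel: ``x y z color size label``;
    the edge file is the full symmetric matrix, whitespace-delimited.
    """
    matrix = np.asarray(matrix, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    if coords.shape != (n, 3):
        raise ValueError(f"need {n} x 3 MNI coordinates, got {coords.shape}")
    labels = labels or [f"CH{i}" for i in range(1, n + 1)]

    node_path = Path(f"{path_prefix}.node")
    edge_path = Path(f"{path_prefix}.edge")
    with open(node_path, "w", encoding="utf-8") as fh:
        for (x, y, z), lab in zip(coords, labels):
            fh.write(f"{x:.6g}\t{y:.6g}\t{z:.6g}\t1\t1\t{lab}\n")
    np.savetxt(edge_path, matrix, fmt="%.10g", delimiter="\t")
    return node_path, edge_path


def read_edge_file(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))
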