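"""Core data model for multi-channel fNIRS recordings.

A :class:`Recording` holds a uniformly sampled T x C matrix of either raw
optical intensity, optical density, or hemoglobin concentration changes
(HbO / HbR / HbT), together with channel metadata and an append-only
processing history.  When the signal kind is ``hb`` the columns are laid
out in chromophore blocks: all channels of the first chromophore, then all
channels of the second, and so on.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SignalKind",
    "ChannelInfo",
    "ProbeSetup",
    "TaskDesign",
    "HistoryRecord",
    "Recording",
]

VALID_SIGNAL_KINDS = ("intensity", "optical_density", "hb")
VALID_CHROMOPHORES = ("HbO", "HbR", "HbT")

# HbT must equal HbO + HbR to this absolute tolerance after any step that
# recomputes it.
HBT_ATOL = 1e-9


class SignalKind:
    INTENSITY = "intensity"
    OPTICAL_DENSITY = "optical_density"
    HB = "hb"


@dataclass
class ChannelInfo:
    """One source-detector pair.  All indices are 1-based (user-facing)."""

    id: int
    source_idx: int
    detector_idx: int
    layout_xy: tuple[float, float] | None = None
    mni_xyz: tuple[float, float, float] | None = None
    is_short: bool = False


@dataclass
class ProbeSetup:
    """Planar probe geometry: labeled source/detector points and channel pairs."""

    sources: list[tuple[str, float, float]]
    detectors: list[tuple[str, float, float]]
    channel_pairs: list[tuple[int, int]]  # 1-based (source, detector)

    def __post_init__(self) -> None:
        ns, nd = len(self.sources), len(self.detectors)
        for s, d in self.channel_pairs:
            if not (1 <= s <= ns):
                raise ValueError(f"channel pair references missing source {s}")
            if not (1 <= d <= nd):
                raise ValueError(f"channel pair references missing detector {d}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_pairs)


@dataclass
class TaskDesign:
    """Named experimental conditions with onsets and durations in seconds."""

    conditions: list[tuple[str, list[float], list[float]]]
    covariates: dict[str, np.ndarray] | None = None
    per_subject: bool = False

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        for name, onsets, durations in self.conditions:
            if len(onsets) != len(durations):
                raise ValueError(f"condition {name!r}: onsets/durations length mismatch")
            if any(o < 0 for o in onsets):
                raise ValueError(f"condition {name!r}: onsets must be nonnegative")
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise ValueError(f"condition {name!r}: onsets must be strictly increasing")
            if any(d < 0 for d in durations):
                raise ValueError(f"condition {name!r}: durations must be >= 0")

    @property
    def condition_names(self) -> list[str]:
        return [name for name, _, _ in self.conditions]

    def shifted(self, offset_s: float) -> "TaskDesign":
        """Return a copy with all onsets shifted by ``offset_s`` seconds.

        Events whose shifted onset falls before time zero are dropped.
        """
        new_conditions = []
        for name, onsets, durations in self.conditions:
            kept = [(o + offset_s, d) for o, d in zip(onsets, durations) if o + offset_s >= 0]
            new_conditions.append((name, [o for o, _ in kept], [d for _, d in kept]))
        return TaskDesign(new_conditions, self.covariates, self.per_subject)


@dataclass
class HistoryRecord:
    name: str
    params: dict
    timestamp: str = field(default_factory=lambda: _dt.datetime.now().isoformat())


@dataclass
class Recording:
    data: np.ndarray  # T x C, float64
    fs: float
    signal_kind: str
    channels: list[ChannelInfo]
    chromophores: tuple[str, ...] = ()
    wavelengths: tuple[float, ...] = ()  # for intensity / optical_density data
    task: TaskDesign | None = None
    history: list[HistoryRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x C matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal_kind not in VALID_SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.signal_kind!r}")
        if self.signal_kind == "hb":
            if not self.chromophores:
                raise ValueError("hb recordings must declare chromophores")
            for c in self.chromophores:
                if c not in VALID_CHROMOPHORES:
                    raise ValueError(f"unknown chromophore {c!r}")
            expected = len(self.channels) * len(self.chromophores)
            if self.data.shape[1] != expected:
                raise ValueError(
                    f"hb data has {self.data.shape[1]} columns, expected "
                    f"{len(self.channels)} channels x {len(self.chromophores)} chromophores"
                )
        ids = [c.id for c in self.channels]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("channel ids must be contiguous from 1")
        pairs = [(c.source_idx, c.detector_idx) for c in self.channels]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (source, detector) pairs")

    # ------------------------------------------------------------------
    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    # ------------------------------------------------------------------
    def chrom_block(self, chromophore: str) -> np.ndarray:
        """T x n_channels view of one chromophore's block (hb recordings)."""
        if self.signal_kind != "hb":
            raise ValueError("chromophore blocks only exist for hb recordings")
        try:
            i = self.chromophores.index(chromophore)
        except ValueError:
            raise KeyError(f"chromophore {chromophore!r} not present") from None
        n = self.n_channels
        return self.data[:, i * n : (i + 1) * n]

    def set_chrom_block(self, chromophore: str, values: np.ndarray) -> None:
        i = self.chromophores.index(chromophore)
        n = self.n_channels
        self.data[:, i * n : (i + 1) * n] = values

    def recompute_hbt(self) -> None:
        """Refresh HbT = HbO + HbR when all three chromophores are present."""
        if "HbT" in self.chromophores and {"HbO", "HbR"} <= set(self.chromophores):
            self.set_chrom_block("HbT", self.chrom_block("HbO") + self.chrom_block("HbR"))

    def check_hbt(self, atol: float = HBT_ATOL) -> bool:
        if "HbT" not in self.chromophores:
            return True
        return bool(
            np.allclose(
                self.chrom_block("HbT"),
                self.chrom_block("HbO") + self.chrom_block("HbR"),
                atol=atol,
                rtol=0.0,
            )
        )

    # ------------------------------------------------------------------
    def with_data(self, data: np.ndarray, step: str, **params) -> "Recording":
        """Copy with new data and exactly one appended history record."""
        out = replace(
            self,
            data=np.asarray(data, dtype=np.float64),
            channels=list(self.channels),
            history=self.history + [HistoryRecord(step, params)],
        )
        return out

    def log_step(self, step: str, **params) -> None:
        self.history.append(HistoryRecord(step, params))

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), channels=list(self.channels),
                       history=list(self.history))


def make_channels(n: int, *, short_ids: set[int] | None = None) -> list[ChannelInfo]:
    """Convenience constructor: n channels with synthetic source/detector pairs."""
    short_ids = short_ids or set()
    return [
        ChannelInfo(id=i, source_idx=i, detector_idx=i, is_short=i in short_ids)
        for i in range(1, n + 1)
    ]
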