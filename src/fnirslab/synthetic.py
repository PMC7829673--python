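"""Synthetic fNIRS recordings with known ground truth.

Every stage of the suite is testable offline against recordings built from
explicit ingredients: polynomial drifts, oscillatory physiology (Mayer
waves near 0.1 Hz, respiration near 0.3 Hz, cardiac pulsation near 1 Hz),
band-limited "neural" fluctuations with an optional true inter-channel
covariance, white sensor noise, motion spikes and baseline steps shared
across chromophores, a superficial (scalp) component shared with
designated short-separation channels, and HRF-convolved task responses
with known betas.

HbR is generated as a negatively scaled copy of the neural + task HbO
component (default ratio -1/3) plus independent noise, while motion
artifacts and the superficial component enter both chromophores with the
same sign — the anticorrelation premise that makes CBSI meaningful.

Everything is driven by one integer seed: the same spec and seed give a
bitwise-identical recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal as sps

from .io import probe_to_channels, standard_probe_3x5
from .glm import build_design
from .recording import ChannelInfo, Recording, TaskDesign

__all__ = [
    "Oscillator",
    "ScenarioSpec",
    "GroundTruth",
    "generate",
    "generate_subject",
    "standard_scenarios",
]


@dataclass
class Oscillator:
    freq_hz: float
    amplitude: float
    phase: float | None = None  # None: random phase per channel


@dataclass
class ScenarioSpec:
    name: str = "custom"
    n_channels: int = 8
    fs: float = 10.0
    duration_s: float = 120.0
    seed: int = 0
    n_subjects: int = 1
    # slow drifts: coefficient of t and t^2 (t in units of total duration)
    trend_linear: float = 0.0
    trend_quadratic: float = 0.0
    oscillators: list[Oscillator] = field(default_factory=list)
    # band-limited neural fluctuations
    neural_sd: float = 0.0
    neural_band: tuple[float, float] = (0.01, 0.08)
    neural_cov: np.ndarray | None = None  # true channels x channels covariance
    noise_sd: float = 0.0
    # motion artifacts, applied to every channel and both chromophores
    spike_times_s: list[float] = field(default_factory=list)
    spike_amplitudes: list[float] = field(default_factory=list)
    step_times_s: list[float] = field(default_factory=list)
    step_sizes: list[float] = field(default_factory=list)
    # superficial/systemic component
    short_channel_ids: list[int] = field(default_factory=list)
    superficial_amplitude: float = 0.0
    superficial_weight_range: tuple[float, float] = (0.3, 0.7)
    # task
    task: TaskDesign | None = None
    task_betas: dict[str, float] = field(default_factory=dict)
    active_channels: list[int] = field(default_factory=list)
    hbr_ratio: float = -1.0 / 3.0

    @property
    def n_times(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    spec: ScenarioSpec
    clean_hbo: np.ndarray      # HbO without motion artifacts (T x channels)
    clean_hbr: np.ndarray
    artifact: np.ndarray       # the injected artifact series per channel
    neural: np.ndarray         # band-limited neural component (HbO scale)
    superficial: np.ndarray | None
    superficial_weights: np.ndarray | None
    task_component: np.ndarray | None
    betas: dict[str, float]


def _bandlimited_noise(rng: np.random.Generator, n: int, n_ch: int, fs: float,
                       band: tuple[float, float], sd: float,
                       cov: np.ndarray | None) -> np.ndarray:
    if sd == 0 and cov is None:
        return np.zeros((n, n_ch))
    if cov is not None:
        L = np.linalg.cholesky(cov)
        white = rng.standard_normal((n, n_ch)) @ L.T
    else:
        white = rng.standard_normal((n, n_ch)) * sd
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white, axis=0)
    # restore the requested standard deviation channelwise
    cur = shaped.std(axis=0)
    target = np.sqrt(np.diag(cov)) if cov is not None else np.full(n_ch, sd)
    scale = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
    return shaped * scale


def generate(spec: ScenarioSpec) -> tuple[Recording, GroundTruth]:
    """Build one synthetic recording (HbO + HbR) with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n, n_ch, fs = spec.n_times, spec.n_channels, spec.fs
    t = np.arange(n) / fs
    tau = t / max(spec.duration_s, 1e-9)

    trend = (spec.trend_linear * tau + spec.trend_quadratic * tau**2)[:, None] \
        * np.ones((1, n_ch))

    osc = np.zeros((n, n_ch))
    for o in spec.oscillators:
        phases = (np.full(n_ch, o.phase) if o.phase is not None
                  else rng.uniform(0, 2 * np.pi, n_ch))
        osc += o.amplitude * np.cos(2 * np.pi * o.freq_hz * t[:, None] - phases[None, :])

    neural = _bandlimited_noise(rng, n, n_ch, fs, spec.neural_band,
                                spec.neural_sd, spec.neural_cov)

    superficial = weights = None
    sup_term = np.zeros((n, n_ch))
    if spec.superficial_amplitude > 0:
        sos = sps.butter(4, 0.12, btype="low", fs=fs, output="sos")
        superficial = sps.sosfiltfilt(sos, rng.standard_normal(n))
        superficial *= spec.superficial_amplitude / max(superficial.std(), 1e-12)
        lo_w, hi_w = spec.superficial_weight_range
        weights = rng.uniform(lo_w, hi_w, n_ch)
        for cid in spec.short_channel_ids:
            weights[cid - 1] = 1.0
        sup_term = superficial[:, None] * weights[None, :]

    task_term = None
    if spec.task is not None:
        dm = build_design(spec.task, n, fs)
        task_term = np.zeros((n, n_ch))
        active = spec.active_channels or list(range(1, n_ch + 1))
        for name, beta in spec.task_betas.items():
            col = dm.X[:, dm.labels.index(name)]
            for cid in active:
                task_term[:, cid - 1] += beta * col

    artifact = np.zeros((n, n_ch))
    ch_scale = rng.uniform(0.5, 1.5, n_ch)  # artifacts hit channels unevenly
    for ts, amp in zip(spec.spike_times_s, spec.spike_amplitudes):
        i = int(round(ts * fs))
        if 0 <= i < n:
            # short biphasic spike, ~0.5 s wide
            width = max(1, int(round(0.25 * fs)))
            for k in range(-width, width + 1):
                if 0 <= i + k < n:
                    artifact[i + k] += amp * ch_scale * np.exp(-0.5 * (k / (width / 2)) ** 2)
    for ts, size in zip(spec.step_times_s, spec.step_sizes):
        i = int(round(ts * fs))
        if 0 <= i < n:
            artifact[i:] += size * ch_scale

    neural_like = neural + osc + (task_term if task_term is not None else 0.0)
    noise_hbo = rng.standard_normal((n, n_ch)) * spec.noise_sd
    noise_hbr = rng.standard_normal((n, n_ch)) * spec.noise_sd * abs(spec.hbr_ratio)

    clean_hbo = trend + neural_like + sup_term + noise_hbo
    clean_hbr = trend * 0.3 + spec.hbr_ratio * neural_like + 0.3 * sup_term + noise_hbr
    hbo = clean_hbo + artifact
    hbr = clean_hbr + artifact

    short = set(spec.short_channel_ids)
    channels = _scenario_channels(spec, short)
    rec = Recording(data=np.hstack([hbo, hbr]), fs=fs, signal_kind="hb",
                    channels=channels, chromophores=("HbO", "HbR"), task=spec.task)
    rec.log_step("synthetic_generate", scenario=spec.name, seed=spec.seed)
    gt = GroundTruth(spec=spec, clean_hbo=clean_hbo, clean_hbr=clean_hbr,
                     artifact=artifact, neural=neural, superficial=superficial,
                     superficial_weights=weights, task_component=task_term,
                     betas=dict(spec.task_betas))
    return rec, gt


def _scenario_channels(spec: ScenarioSpec, short: set[int]) -> list[ChannelInfo]:
    """44-channel scenarios get the two-probe 3x5 montage geometry."""
    if spec.n_channels == 44:
        left = standard_probe_3x5(x_offset=0.0)
        right = standard_probe_3x5(x_offset=200.0)
        chans = probe_to_channels(left)
        n_s, n_d = len(left.sources), len(left.detectors)
        for ch in probe_to_channels(right):
            chans.append(ChannelInfo(
                id=len(chans) + 1, source_idx=ch.source_idx + n_s,
                detector_idx=ch.detector_idx + n_d, layout_xy=ch.layout_xy))
        for ch in chans:
            ch.is_short = ch.id in short
        return chans
    return [ChannelInfo(id=i, source_idx=i, detector_idx=i, is_short=i in short)
            for i in range(1, spec.n_channels + 1)]


def generate_subject(spec: ScenarioSpec, subject: int) -> tuple[Recording, GroundTruth]:
    """Subject-specific draw: the seed is offset by the subject index (0-based)."""
    if not 0 <= subject < spec.n_subjects:
        raise ValueError(f"subject must be in [0, {spec.n_subjects})")
    return generate(replace(spec, seed=spec.seed + subject))


def _finger_tapping_design() -> TaskDesign:
    # 10 s baseline then 20 s tap / 20 s rest blocks
    onsets = [10.0 + 40.0 * k for k in range(7)]
    durations = [20.0] * 7
    return TaskDesign([("tapping", onsets, durations)])


def standard_scenarios(seed: int = 2024) -> dict[str, ScenarioSpec]:
    """Named reference scenarios used across tests and examples.

    - ``rest44``: 7 min of resting-state data at 10 Hz on the 44-channel
      two-probe 3x5 montage, with Mayer/respiratory/cardiac oscillations
      and band-limited neural fluctuations.
    - ``task_finger``: a 9-subject block-design finger-tapping study on the
      same montage.
    - ``motion_heavy``: resting data contaminated with large spikes and
      baseline steps.
    - ``short_channel``: a montage whose last two channels are
      short-separation references carrying the shared scalp component.
    """
    physio = [Oscillator(0.1, 0.08), Oscillator(0.3, 0.04), Oscillator(1.0, 0.02)]
    rest44 = ScenarioSpec(
        name="rest44", n_channels=44, fs=10.0, duration_s=420.0, seed=seed,
        n_subjects=9, trend_linear=0.3, oscillators=list(physio),
        neural_sd=0.1, noise_sd=0.02,
    )
    task = ScenarioSpec(
        name="task_finger", n_channels=44, fs=10.0, duration_s=330.0, seed=seed + 1000,
        n_subjects=9, trend_linear=0.2, oscillators=list(physio),
        neural_sd=0.05, noise_sd=0.02,
        task=_finger_tapping_design(), task_betas={"tapping": 0.6},
        active_channels=list(range(1, 11)),
    )
    motion = ScenarioSpec(
        name="motion_heavy", n_channels=8, fs=10.0, duration_s=300.0, seed=seed + 2000,
        oscillators=[Oscillator(0.05, 0.5)], neural_sd=0.05, noise_sd=0.01,
        spike_times_s=[40.0, 95.0, 170.0, 240.0], spike_amplitudes=[5.0, -4.0, 6.0, 5.0],
        step_times_s=[120.0, 210.0], step_sizes=[2.0, -1.5],
    )
    short = ScenarioSpec(
        name="short_channel", n_channels=22, fs=10.0, duration_s=300.0, seed=seed + 3000,
        oscillators=[Oscillator(0.1, 0.05)], neural_sd=0.08, noise_sd=0.02,
        short_channel_ids=[21, 22], superficial_amplitude=0.2,
    )
    return {s.name: s for s in (rest44, task, motion, short)}
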