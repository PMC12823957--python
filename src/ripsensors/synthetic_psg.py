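"""Synthetic overnight polysomnography with labelled ground truth.

The generator emits the six channels the sensor models consume, coupled the
way the models assume real physiology is coupled:

* a latent respiratory drive r(t) = a(t) * sin(phi(t)), where the breathing
  frequency f(t) wanders slowly (Ornstein-Uhlenbeck, clipped to 0.1-0.4 Hz)
  and the effort amplitude a(t) wanders slowly and log-normally;
* both RIP belts follow the drive (the thoracic belt with a short phase
  lag), plus a small cardiac-frequency ballistocardiographic component and
  white measurement noise;
* nasal pneumoflow follows the time derivative of the drive through a flow
  gate that obstructive events close while effort persists, and central
  events close together with effort; oral pneumoflow is a small fraction of
  nasal flow;
* esophageal pressure tracks the drive with negative deflections (cmH2O);
* heart rate combines within-breath respiratory sinus arrhythmia (slower
  while the drive is high) with slow autonomic couplings: deeper breathing
  lowers, faster breathing raises, the epoch-scale rate.  The pulse channel
  is the 1-s average of instantaneous heart rate at 1 Hz.

Scripted artifacts (flat belt segments, esophageal spike bursts, pulse
steps) are overwritten onto scheduled intervals and the epochs they should
invalidate — under matching cleaning thresholds — are recorded in the
ground truth, so artifact screening can be tested with exact labels.

``make_linear_cohort`` is the separate exact-recovery harness: it draws
feature tables directly and builds targets from known coefficients, so
least-squares correctness can be tested independently of the mechanistic
simulation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ScheduleError, ValidationError
from .preprocessing import CleaningConfig
from .sensor_models import MODEL_DESIGNS, ModelKind
from .signal_io import ChannelKind, ChannelSignal, Recording, write_edf

__all__ = [
    "EventType",
    "ArtifactType",
    "ApneaEvent",
    "Artifact",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_recording",
    "make_linear_cohort",
    "write_cohort",
]


class EventType(str, enum.Enum):
    OSA = "OSA"  # airflow suppressed, effort maintained (even ramped up)
    CENTRAL = "CENTRAL"  # airflow and effort both suppressed


class ArtifactType(str, enum.Enum):
    FLAT = "FLAT"
    SPIKE = "SPIKE"
    PULSE_JUMP = "PULSE_JUMP"


@dataclass(frozen=True)
class ApneaEvent:
    start_s: float
    duration_s: float
    type: EventType

    def __post_init__(self) -> None:
        object.__setattr__(self, "type", EventType(self.type))
        if self.duration_s <= 0 or self.start_s < 0:
            raise ValidationError("event must have non-negative start and positive duration")


@dataclass(frozen=True)
class Artifact:
    start_s: float
    duration_s: float
    channel: ChannelKind
    type: ArtifactType

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", ChannelKind(self.channel))
        object.__setattr__(self, "type", ArtifactType(self.type))
        if self.duration_s <= 0 or self.start_s < 0:
            raise ValidationError("artifact must have non-negative start and positive duration")


# White measurement noise per channel, in channel units.  Mask and catheter
# sensors are clean relative to their signals; the full-band mean-magnitude
# statistic integrates broadband noise over thousands of bins, so these
# levels correspond to a noise floor comparable to the respiratory peak.
_DEFAULT_NOISE = {
    ChannelKind.AB: 0.02,
    ChannelKind.TH: 0.02,
    ChannelKind.NPF: 0.002,
    ChannelKind.OPF: 0.001,
    ChannelKind.PES: 0.02,
    ChannelKind.PULSE: 0.2,
}

_LATENT_FS = 10.0  # Hz; latent processes vary on >= 1 s scales


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of one simulated overnight recording.

    Defaults describe an unremarkable sleeper: ~0.25 Hz breathing with a
    slow +/-0.03 Hz wander, effort amplitude drifting by ~20% on a
    two-minute scale, 65 bpm baseline pulse with 4 bpm of respiratory sinus
    arrhythmia, a 2% ballistocardiographic leak into the belts, ~1 cmH2O
    esophageal swings and modest white sensor noise.
    """

    duration_s: float = 3600.0
    fs_belt: float = 200.0
    fs_flow: float = 250.0
    fs_pes: float = 250.0
    breath_rate_hz: float = 0.25
    breath_rate_sd_hz: float = 0.03
    breath_rate_tau_s: float = 60.0
    breath_jitter_sd_hz: float = 0.035
    breath_jitter_tau_s: float = 3.0
    amp_sd: float = 0.3
    amp_tau_s: float = 120.0
    belt_gain_ab: float = 1.0
    belt_gain_th: float = 0.8
    belt_phase_lag_s: float = 0.15
    texture_gain: float = 0.3
    hr_baseline_bpm: float = 65.0
    rsa_amplitude_bpm: float = 4.0
    hr_amp_gain_bpm: float = 5.0
    hr_freq_gain_bpm: float = 0.5
    bcg_amplitude: float = 0.02
    pes_gain_cmH2O: float = 0.8
    pes_gain_wander_sd: float = 0.15
    pes_gain_wander_tau_s: float = 180.0
    pes_soft_limit_cmH2O: float = 1.8
    pes_cardiac_cmH2O: float = 0.05
    flow_gain: float = 0.6
    opf_fraction: float = 0.15
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    spike_amplitude_cmH2O: float = 5.0
    pulse_step_bpm: float = 50.0
    event_schedule: tuple[ApneaEvent, ...] = ()
    artifact_schedule: tuple[Artifact, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration_s", "fs_belt", "fs_flow", "fs_pes", "breath_rate_hz",
            "belt_gain_ab", "belt_gain_th", "hr_baseline_bpm", "pes_gain_cmH2O",
            "flow_gain",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        object.__setattr__(self, "event_schedule",
                           tuple(self.event_schedule))
        object.__setattr__(self, "artifact_schedule",
                           tuple(self.artifact_schedule))
        for ev in self.event_schedule:
            if ev.start_s + ev.duration_s > self.duration_s:
                raise ScheduleError(f"event at {ev.start_s}s extends past the recording")
        per_channel: dict[ChannelKind, list[tuple[float, float]]] = {}
        for art in self.artifact_schedule:
            if art.start_s + art.duration_s > self.duration_s:
                raise ScheduleError(f"artifact at {art.start_s}s extends past the recording")
            spans = per_channel.setdefault(art.channel, [])
            for (s0, s1) in spans:
                if art.start_s < s1 and s0 < art.start_s + art.duration_s:
                    raise ScheduleError(
                        f"overlapping artifacts on channel {art.channel.value}"
                    )
            spans.append((art.start_s, art.start_s + art.duration_s))


@dataclass
class SyntheticGroundTruth:
    """Latent signals and labels aligned with the emitted channels."""

    times_s: np.ndarray
    instantaneous_hr_bpm: np.ndarray
    effort: np.ndarray
    breath_rate_hz: np.ndarray
    amplitude: np.ndarray
    event_intervals: tuple[ApneaEvent, ...]
    corrupted_epoch_indices: dict[ChannelKind, set[int]]
    true_linear_coefficients: dict | None = None


def _ou_process(
    rng: np.random.Generator, n: int, dt: float, mean: float, sd: float, tau: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path via its exact discretization."""
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    if tau <= 0:
        x[1:] = mean + sd * rng.standard_normal(n - 1)
        return x
    a = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mean + (x[i - 1] - mean) * a + innov_sd * eps[i - 1]
    return x


def _smooth_gate(
    t: np.ndarray, intervals: Sequence[tuple[float, float]], inside: float, ramp_s: float = 2.0
) -> np.ndarray:
    """1 outside the intervals, ``inside`` within, cosine-ramped at the edges."""
    gate = np.ones_like(t)
    for (s0, s1) in intervals:
        up = np.clip((t - s0) / ramp_s, 0.0, 1.0)
        down = np.clip((s1 - t) / ramp_s, 0.0, 1.0)
        w = np.minimum(up, down) * ((t >= s0) & (t <= s1))
        depth = 0.5 - 0.5 * np.cos(np.pi * w)  # 0 at edges, 1 deep inside
        gate = gate * (1.0 + (inside - 1.0) * depth)
    return gate


def _interp(t_target: np.ndarray, t_source: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.interp(t_target, t_source, values)


def _corrupted_epochs(
    config: SyntheticConfig, cleaning: CleaningConfig
) -> dict[ChannelKind, set[int]]:
    """Epochs each scheduled artifact invalidates under matching thresholds.

    FLAT segments trip the near-zero rule only when they cover at least
    ``flat_fraction`` of an epoch; SPIKE bursts trip the corrupt-fraction
    rule when they cover more than ``pes_corrupt_fraction``; a pulse step
    produces one > 40 bpm jump at its onset and one at its offset, each
    flagged in the epoch that contains the jump (jumps landing exactly on an
    epoch boundary are invisible to per-epoch differencing).
    """
    T = cleaning.epoch_seconds
    n_epochs = int(config.duration_s // T)
    out: dict[ChannelKind, set[int]] = {k: set() for k in ChannelKind}

    def overlap(i: int, s0: float, s1: float) -> float:
        return max(0.0, min(s1, (i + 1) * T) - max(s0, i * T))

    for art in config.artifact_schedule:
        s0, s1 = art.start_s, art.start_s + art.duration_s
        first, last = int(s0 // T), min(int(math.ceil(s1 / T)), n_epochs)
        if art.type == ArtifactType.FLAT:
            for i in range(first, last):
                if overlap(i, s0, s1) / T >= cleaning.flat_fraction:
                    out[art.channel].add(i)
        elif art.type == ArtifactType.SPIKE:
            for i in range(first, last):
                if overlap(i, s0, s1) / T > cleaning.pes_corrupt_fraction:
                    out[art.channel].add(i)
        else:  # PULSE_JUMP: steps at the interval edges (1 Hz pulse series)
            for edge in (round(s0), round(s1)):
                if 0 < edge < config.duration_s and edge % int(T) != 0:
                    i = int(edge // T)
                    if i < n_epochs:
                        out[art.channel].add(i)
    return out


def generate_recording(
    config: SyntheticConfig,
    subject_id: str = "synthetic",
    cleaning: CleaningConfig | None = None,
) -> tuple[Recording, SyntheticGroundTruth]:
    """Simulate one recording and its ground truth.

    ``cleaning`` (default :class:`CleaningConfig`) only determines which
    epochs the scheduled artifacts are labelled as corrupting; it does not
    alter the signals.  Identical config and seed give bit-identical output.
    """
    cleaning = cleaning or CleaningConfig()
    rng = np.random.default_rng(config.seed)
    n_lat = int(round(config.duration_s * _LATENT_FS)) + 1
    t = np.arange(n_lat) / _LATENT_FS

    f = _ou_process(rng, n_lat, 1.0 / _LATENT_FS, config.breath_rate_hz,
                    config.breath_rate_sd_hz, config.breath_rate_tau_s)
    f = np.clip(f, 0.1, 0.4)
    # breath-to-breath cycle-length variability broadens the respiratory
    # spectral peak over several bins, as in real breathing; without it the
    # near-pure tone makes the l1 magnitude feature leakage-dominated
    if config.breath_jitter_sd_hz > 0:
        jitter = _ou_process(rng, n_lat, 1.0 / _LATENT_FS, 0.0,
                             config.breath_jitter_sd_hz, config.breath_jitter_tau_s)
        f_inst = np.clip(f + jitter, 0.08, 0.45)
    else:
        f_inst = f
    log_amp = _ou_process(rng, n_lat, 1.0 / _LATENT_FS, 0.0, config.amp_sd,
                          config.amp_tau_s)
    amp = np.clip(np.exp(log_amp), 0.3, 3.0)

    osa = [(e.start_s, e.start_s + e.duration_s) for e in config.event_schedule
           if e.type == EventType.OSA]
    central = [(e.start_s, e.start_s + e.duration_s) for e in config.event_schedule
               if e.type == EventType.CENTRAL]
    effort_gate = _smooth_gate(t, osa, 1.2) * _smooth_gate(t, central, 0.05)
    flow_gate = _smooth_gate(t, osa, 0.0) * _smooth_gate(t, central, 0.0)

    phi0 = rng.uniform(0.0, 2.0 * math.pi)
    phi = 2.0 * math.pi * cumulative_trapezoid(f_inst, t, initial=0.0) + phi0
    drive_amp = amp * effort_gate
    r = drive_amp * np.sin(phi)

    # Broadband motion texture shared by effort-driven channels.  The same
    # thoracoabdominal movement shows up in both belts, the esophageal
    # pressure and (as its time derivative) the airflow; texture scales with
    # effort.  It also keeps the full-band l1 magnitude self-averaging:
    # a pure tone's l1 spectrum is dominated by window-edge leakage, which
    # would decorrelate channels that real physiology couples tightly.
    tex = _ou_process(rng, n_lat, 1.0 / _LATENT_FS, 0.0, 1.0, 0.2)
    tex_d = np.gradient(tex, 1.0 / _LATENT_FS)
    tex_d = tex_d / max(float(tex_d.std()), 1e-12)
    g_tex = config.texture_gain
    motion = drive_amp * (np.sin(phi) + g_tex * tex)

    zf = (f - config.breath_rate_hz) / max(config.breath_rate_sd_hz, 1e-12)
    hr = (
        config.hr_baseline_bpm
        - config.rsa_amplitude_bpm * r
        - config.hr_amp_gain_bpm * (drive_amp - 1.0)
        + config.hr_freq_gain_bpm * zf
    )
    psi0 = rng.uniform(0.0, 2.0 * math.pi)
    psi = 2.0 * math.pi * cumulative_trapezoid(hr / 60.0, t, initial=0.0) + psi0

    noise = {ChannelKind(k): v for k, v in config.noise_sd.items()}

    def belt(kind: ChannelKind, gain: float, lag_s: float, fs: float) -> np.ndarray:
        tc = np.arange(int(round(config.duration_s * fs))) / fs
        base = gain * _interp(np.maximum(tc - lag_s, 0.0), t, motion)
        bcg = config.bcg_amplitude * gain * np.sin(_interp(tc, t, psi))
        return base + bcg + noise.get(kind, 0.0) * rng.standard_normal(tc.size)

    ab = belt(ChannelKind.AB, config.belt_gain_ab, 0.0, config.fs_belt)
    th = belt(ChannelKind.TH, config.belt_gain_th, config.belt_phase_lag_s, config.fs_belt)

    t_flow = np.arange(int(round(config.duration_s * config.fs_flow))) / config.fs_flow
    flow_wave = np.cos(_interp(t_flow, t, phi)) + g_tex * _interp(t_flow, t, tex_d)
    npf_det = (
        config.flow_gain
        * _interp(t_flow, t, drive_amp)
        * 2.0 * math.pi * _interp(t_flow, t, f)
        * flow_wave
        * _interp(t_flow, t, flow_gate)
    )
    npf = npf_det + noise.get(ChannelKind.NPF, 0.0) * rng.standard_normal(t_flow.size)
    opf = (
        config.opf_fraction * npf_det
        + noise.get(ChannelKind.OPF, 0.0) * rng.standard_normal(t_flow.size)
    )

    # the Pes coupling gain wanders slowly and independently of the belts,
    # so the belt->Pes sensors face realistic, imperfect coupling
    pes_gain = config.pes_gain_cmH2O * np.exp(
        _ou_process(rng, n_lat, 1.0 / _LATENT_FS, 0.0,
                    config.pes_gain_wander_sd, config.pes_gain_wander_tau_s)
    )
    t_pes = np.arange(int(round(config.duration_s * config.fs_pes))) / config.fs_pes
    pes_raw = _interp(t_pes, t, pes_gain * motion)
    # soft saturation mimics the catheter's bounded excursions and keeps
    # ordinary breathing below the spike-cleaning threshold
    limit = config.pes_soft_limit_cmH2O
    pes = (
        -limit * np.tanh(pes_raw / limit)
        + config.pes_cardiac_cmH2O * np.sin(_interp(t_pes, t, psi))
        + noise.get(ChannelKind.PES, 0.0) * rng.standard_normal(t_pes.size)
    )

    n_sec = int(config.duration_s)
    per_sec = int(_LATENT_FS)
    pulse = hr[: n_sec * per_sec].reshape(n_sec, per_sec).mean(axis=1)
    pulse = pulse + noise.get(ChannelKind.PULSE, 0.0) * rng.standard_normal(n_sec)

    channel_arrays: dict[ChannelKind, tuple[np.ndarray, float]] = {
        ChannelKind.AB: (ab, config.fs_belt),
        ChannelKind.TH: (th, config.fs_belt),
        ChannelKind.NPF: (npf, config.fs_flow),
        ChannelKind.OPF: (opf, config.fs_flow),
        ChannelKind.PES: (pes, config.fs_pes),
        ChannelKind.PULSE: (pulse, 1.0),
    }

    for art in config.artifact_schedule:
        x, fs = channel_arrays[art.channel]
        i0 = int(round(art.start_s * fs))
        i1 = min(int(round((art.start_s + art.duration_s) * fs)), x.size)
        if art.type == ArtifactType.FLAT:
            x[i0:i1] = 0.0
        elif art.type == ArtifactType.SPIKE:
            # alternating half-second excursions beyond the spike threshold
            seg = np.arange(i0, i1)
            sign = np.where(((seg / fs) * 2).astype(int) % 2 == 0, 1.0, -1.0)
            x[i0:i1] = sign * config.spike_amplitude_cmH2O
        else:  # PULSE_JUMP
            x[i0:i1] = x[i0:i1] + config.pulse_step_bpm

    channels = {
        kind: ChannelSignal(kind=kind, samples=x, sampling_rate_hz=fs)
        for kind, (x, fs) in channel_arrays.items()
    }
    ahi = len(config.event_schedule) / (config.duration_s / 3600.0)
    recording = Recording(
        subject_id=subject_id,
        channels=channels,
        metadata={"ahi": ahi, "seed": config.seed},
    )
    truth = SyntheticGroundTruth(
        times_s=t,
        instantaneous_hr_bpm=hr,
        effort=r,
        breath_rate_hz=f,
        amplitude=drive_amp,
        event_intervals=config.event_schedule,
        corrupted_epoch_indices=_corrupted_epochs(config, cleaning),
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Exact-recovery harness
# ---------------------------------------------------------------------------

_DEFAULT_BETA_MEAN: dict[ModelKind, tuple[float, ...]] = {
    ModelKind.HR: (65.0, 3.0, 1.0, 5.0, -2.0, -0.8),
    ModelKind.NPF: (0.5, 1.2, 2.0),
    ModelKind.PES1: (0.5, 0.4, 0.9),
    ModelKind.PES2: (0.5, 1.0, 1.8),
}


def make_linear_cohort(
    n_subjects: int,
    kind: ModelKind,
    beta_mean: Sequence[float] | None = None,
    beta_sd: Sequence[float] | float = 0.0,
    noise_sd: float = 0.0,
    n_epochs: int = 400,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Draw per-subject feature tables whose targets follow known coefficients.

    Predictors are drawn to match the features' semantics — spectral
    magnitudes and RMS log-normal (positive), skewness Gaussian — and the
    target is the model equation applied with subject-specific coefficients
    plus i.i.d. Gaussian noise.  Returns the tables and the true coefficient
    matrix of shape ``(n_subjects, p+1)``.
    """
    kind = ModelKind(kind)
    if n_subjects < 1 or n_epochs < 1:
        raise ValidationError("n_subjects and n_epochs must be positive")
    predictors, target = MODEL_DESIGNS[kind]
    p_total = len(predictors) + 1
    if n_epochs <= p_total:
        raise ValidationError(f"n_epochs must exceed {p_total} for the {kind.value} model")
    mean = np.asarray(
        beta_mean if beta_mean is not None else _DEFAULT_BETA_MEAN[kind], dtype=np.float64
    )
    if mean.size != p_total:
        raise ValidationError(f"beta_mean must have {p_total} entries for {kind.value}")
    sd = np.broadcast_to(np.asarray(beta_sd, dtype=np.float64), (p_total,))

    rng = np.random.default_rng(seed)
    tables: list[pd.DataFrame] = []
    betas = np.empty((n_subjects, p_total))
    for s in range(n_subjects):
        beta = mean + sd * rng.standard_normal(p_total)
        betas[s] = beta
        cols: dict[str, np.ndarray] = {
            "subject_id": np.full(n_epochs, f"sim{s:03d}"),
            "epoch_index": np.arange(n_epochs),
        }
        X = np.ones((n_epochs, p_total))
        for j, name in enumerate(predictors, start=1):
            if name == "Skewness":
                v = rng.normal(0.0, 0.5, size=n_epochs)
            else:
                v = rng.lognormal(mean=0.0, sigma=0.5, size=n_epochs)
            cols[name] = v
            X[:, j] = v
        y = X @ beta + noise_sd * rng.standard_normal(n_epochs)
        cols[target] = y
        tables.append(pd.DataFrame(cols))
    return tables, betas


def write_cohort(
    recordings: Sequence[Recording],
    directory: str | Path,
) -> tuple[list[Path], Path]:
    """Write one EDF per subject plus a cohort metadata CSV.

    Returns the EDF paths and the metadata path.  The metadata table has one
    row per subject with its AHI (events/hour) and any further metadata keys.
    """
    if not recordings:
        raise ValidationError("empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    meta_rows = []
    for rec in recordings:
        path = directory / f"{rec.subject_id}.edf"
        write_edf(rec, path)
        paths.append(path)
        meta_rows.append({"subject_id": rec.subject_id, **rec.metadata})
    meta_path = directory / "cohort_metadata.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return paths, meta_path
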