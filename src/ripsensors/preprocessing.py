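"""Artifact handling and non-overlapping 60-s epoch segmentation.

Overnight recordings are cut into non-overlapping fixed-length epochs
(60 s by default, so 12,000 samples at 200 Hz and 15,000 at 250 Hz) and each
epoch is kept only if every required channel passes its artifact screen:

* pulse epochs with physiologically implausible rates (< 40 or > 180 bpm) or
  abrupt jumps (> 40 bpm between consecutive 1-s samples) are rejected;
* epochs dominated by near-zero samples (sensor disconnection) are rejected;
* esophageal pressure is cleaned before screening: samples beyond the spike
  threshold (±2 cmH2O) are replaced by linear interpolation between the
  nearest surviving neighbours and a running median is applied; epochs where
  too large a fraction of samples had to be replaced are rejected;
* epochs containing missing samples are rejected outright.

A recording enters model fitting only if its valid epochs amount to at least
``min_valid_hours`` (4 h by default, boundary inclusive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import ConfigurationError, PesCorruptError, ValidationError
from .signal_io import ChannelKind, ChannelSignal, Recording

__all__ = [
    "RejectionReason",
    "CleaningConfig",
    "Epoch",
    "segment_epochs",
    "flag_pulse_epoch",
    "flag_flat_epoch",
    "resolve_flat_eps",
    "clean_pes",
    "build_epoch_table",
    "recording_passes_inclusion",
    "epoch_table_frame",
    "InclusionSummary",
]


class RejectionReason(str, enum.Enum):
    IMPLAUSIBLE_PULSE = "IMPLAUSIBLE_PULSE"
    PULSE_JUMP = "PULSE_JUMP"
    FLAT_SIGNAL = "FLAT_SIGNAL"
    PES_CORRUPT = "PES_CORRUPT"
    MISSING_DATA = "MISSING_DATA"


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds for artifact screening.

    ``flat_eps=None`` resolves per channel to 1e-3 times the channel's robust
    amplitude (median absolute deviation about the median), which makes the
    near-zero test scale-free across belt gains.  All pulse comparisons are
    strict inequalities exactly as the plausibility rules are stated; the
    ``flat_fraction`` and 4-hour boundaries are inclusive.
    """

    epoch_seconds: float = 60.0
    pulse_min_bpm: float = 40.0
    pulse_max_bpm: float = 180.0
    pulse_jump_bpm: float = 40.0
    flat_eps: float | None = None
    flat_fraction: float = 0.9
    pes_spike_cmH2O: float = 2.0
    median_kernel_samples: int = 5
    pes_corrupt_fraction: float = 0.05
    min_valid_hours: float = 4.0

    def __post_init__(self) -> None:
        if not self.pulse_min_bpm < self.pulse_max_bpm:
            raise ValidationError("pulse_min_bpm must be below pulse_max_bpm")
        for name in ("epoch_seconds", "pulse_jump_bpm", "pes_spike_cmH2O"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.flat_fraction <= 1.0:
            raise ValidationError("flat_fraction must lie in [0, 1]")
        k = self.median_kernel_samples
        if k < 1 or k % 2 == 0:
            raise ValidationError("median_kernel_samples must be an odd positive integer")
        if self.min_valid_hours < 0:
            raise ValidationError("min_valid_hours must be non-negative")


@dataclass
class Epoch:
    """One fixed-length window across the required channels of a recording."""

    index: int
    start_time_s: float
    samples_per_channel: dict[ChannelKind, np.ndarray]
    rejection_reasons: set[RejectionReason] = field(default_factory=set)

    @property
    def valid(self) -> bool:
        return not self.rejection_reasons


def segment_epochs(signal: ChannelSignal, epoch_seconds: float) -> list[np.ndarray]:
    """Cut a channel into non-overlapping windows of ``epoch_seconds``.

    The trailing partial window is discarded.  ``epoch_seconds`` times the
    sampling rate must be a whole number of samples and at least 2.
    """
    n_per = epoch_seconds * signal.sampling_rate_hz
    n_int = int(round(n_per))
    if abs(n_per - n_int) > 1e-6:
        raise ValidationError(
            f"epoch of {epoch_seconds}s at {signal.sampling_rate_hz} Hz is not a whole "
            f"number of samples ({n_per})"
        )
    if n_int < 2:
        raise ValidationError("an epoch must contain at least 2 samples")
    n_epochs = signal.n_samples // n_int
    return [signal.samples[i * n_int : (i + 1) * n_int] for i in range(n_epochs)]


def flag_pulse_epoch(
    pulse_slice: Sequence[float] | np.ndarray, config: CleaningConfig
) -> set[RejectionReason]:
    """Screen a pulse epoch for implausible rates and abrupt jumps."""
    x = np.asarray(pulse_slice, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("empty pulse slice")
    reasons: set[RejectionReason] = set()
    if np.isnan(x).any():
        reasons.add(RejectionReason.MISSING_DATA)
    finite = x[~np.isnan(x)]
    if finite.size and ((finite < config.pulse_min_bpm) | (finite > config.pulse_max_bpm)).any():
        reasons.add(RejectionReason.IMPLAUSIBLE_PULSE)
    diffs = np.abs(np.diff(x))
    with np.errstate(invalid="ignore"):
        if np.any(diffs > config.pulse_jump_bpm):
            reasons.add(RejectionReason.PULSE_JUMP)
    return reasons


def resolve_flat_eps(signal_or_samples, config: CleaningConfig) -> float:
    """Resolve the near-zero threshold for one channel.

    Explicit ``config.flat_eps`` wins; otherwise 1e-3 times the median
    absolute deviation of the channel's finite samples.  For an identically
    zero channel this degenerates to 0, so exact zeros still count as flat.
    """
    if config.flat_eps is not None:
        return float(config.flat_eps)
    x = getattr(signal_or_samples, "samples", signal_or_samples)
    x = np.asarray(x, dtype=np.float64)
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return 0.0
    mad = float(np.median(np.abs(finite - np.median(finite))))
    return 1e-3 * mad


def flag_flat_epoch(
    sample_slice: Sequence[float] | np.ndarray,
    config: CleaningConfig,
    flat_eps: float | None = None,
) -> set[RejectionReason]:
    """Flag an epoch as flat when near-zero samples dominate it.

    The epoch is flat when the fraction of samples with ``|x| <= eps`` is at
    least ``flat_fraction`` (boundary inclusive).  Missing samples never count
    as flat.
    """
    x = np.asarray(sample_slice, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("empty slice")
    eps = flat_eps if flat_eps is not None else resolve_flat_eps(x, config)
    with np.errstate(invalid="ignore"):
        n_flat = int(np.count_nonzero(np.abs(x) <= eps))
    if n_flat / x.size >= config.flat_fraction:
        return {RejectionReason.FLAT_SIGNAL}
    return set()


def _spike_mask(x: np.ndarray, threshold: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.abs(x) > threshold


def clean_pes(signal: ChannelSignal, config: CleaningConfig) -> ChannelSignal:
    """Remove amplitude spikes from an esophageal pressure channel.

    Samples exceeding ``±pes_spike_cmH2O`` are replaced by linear
    interpolation between the nearest surviving neighbours (edge runs are
    extended from the nearest surviving value), then a running median of
    width ``median_kernel_samples`` (edge-replicated) is applied.  A signal
    with no spikes is returned unchanged, which makes the operation
    idempotent once its output is spike-free.  Missing (NaN) samples are left
    missing.
    """
    if signal.kind != ChannelKind.PES:
        raise ValidationError(f"clean_pes expects a PES channel, got {signal.kind.value}")
    x = signal.samples
    nan_mask = np.isnan(x)
    bad = _spike_mask(x, config.pes_spike_cmH2O)
    good = ~bad & ~nan_mask
    if not good.any():
        raise PesCorruptError(
            "every esophageal pressure sample exceeds the spike threshold; "
            "signal is unusable"
        )
    if not bad.any():
        return signal

    idx = np.arange(x.size)
    y = x.copy()
    y[bad | nan_mask] = np.interp(idx[bad | nan_mask], idx[good], x[good])
    if config.median_kernel_samples > 1:
        y = median_filter(y, size=config.median_kernel_samples, mode="nearest")
    y[nan_mask] = np.nan
    return replace(signal, samples=y)


def build_epoch_table(
    recording: Recording,
    required_kinds: Iterable[ChannelKind],
    config: CleaningConfig | None = None,
) -> list[Epoch]:
    """Segment a recording and screen each epoch across its required channels.

    Epoch ``i`` covers the half-open interval ``[i*T, (i+1)*T)`` seconds on
    every channel regardless of its sampling rate.  The esophageal pressure
    channel is spike-cleaned before screening; epochs where the replaced
    fraction exceeds ``pes_corrupt_fraction`` — or the whole channel is
    unusable — carry ``PES_CORRUPT``.  An epoch is valid iff no required
    channel raised a flag.
    """
    config = config or CleaningConfig()
    required = [ChannelKind(k) for k in required_kinds]
    for kind in required:
        if kind not in recording.channels:
            raise ConfigurationError(
                f"required channel {kind.value} absent from recording "
                f"{recording.subject_id!r}"
            )
    recording.check_span(config.epoch_seconds)

    slices: dict[ChannelKind, list[np.ndarray]] = {}
    spike_frac: dict[int, float] = {}
    pes_whole_corrupt = False
    flat_eps: dict[ChannelKind, float] = {}
    for kind in required:
        sig = recording.channels[kind]
        if kind == ChannelKind.PES:
            raw_slices = segment_epochs(sig, config.epoch_seconds)
            try:
                cleaned = clean_pes(sig, config)
            except PesCorruptError:
                pes_whole_corrupt = True
                cleaned = sig
            mask = _spike_mask(sig.samples, config.pes_spike_cmH2O)
            n_per = len(raw_slices[0]) if raw_slices else 0
            for i in range(len(raw_slices)):
                m = mask[i * n_per : (i + 1) * n_per]
                spike_frac[i] = float(np.count_nonzero(m)) / n_per if n_per else 0.0
            sig = cleaned
        slices[kind] = segment_epochs(sig, config.epoch_seconds)
        flat_eps[kind] = resolve_flat_eps(sig, config)

    n_epochs = min(len(s) for s in slices.values())
    epochs: list[Epoch] = []
    for i in range(n_epochs):
        reasons: set[RejectionReason] = set()
        per_channel: dict[ChannelKind, np.ndarray] = {}
        for kind in required:
            sl = slices[kind][i]
            per_channel[kind] = sl
            if np.isnan(sl).any():
                reasons.add(RejectionReason.MISSING_DATA)
            if kind == ChannelKind.PULSE:
                reasons |= flag_pulse_epoch(sl, config)
            else:
                reasons |= flag_flat_epoch(sl, config, flat_eps[kind])
            if kind == ChannelKind.PES:
                if pes_whole_corrupt or spike_frac.get(i, 0.0) > config.pes_corrupt_fraction:
                    reasons.add(RejectionReason.PES_CORRUPT)
        epochs.append(
            Epoch(
                index=i,
                start_time_s=i * config.epoch_seconds,
                samples_per_channel=per_channel,
                rejection_reasons=reasons,
            )
        )
    return epochs


@dataclass
class InclusionSummary:
    passes: bool
    n_epochs: int
    n_valid: int
    valid_hours: float
    rejections_by_reason: dict[str, int]


def recording_passes_inclusion(
    epochs: Sequence[Epoch], config: CleaningConfig | None = None
) -> tuple[bool, InclusionSummary]:
    """Apply the minimum-valid-duration inclusion rule (boundary inclusive)."""
    config = config or CleaningConfig()
    n_valid = sum(1 for e in epochs if e.valid)
    valid_hours = n_valid * config.epoch_seconds / 3600.0
    by_reason: dict[str, int] = {r.value: 0 for r in RejectionReason}
    for e in epochs:
        for r in e.rejection_reasons:
            by_reason[r.value] += 1
    passes = valid_hours >= config.min_valid_hours
    return passes, InclusionSummary(
        passes=passes,
        n_epochs=len(epochs),
        n_valid=n_valid,
        valid_hours=valid_hours,
        rejections_by_reason=by_reason,
    )


def epoch_table_frame(epochs: Sequence[Epoch], subject_id: str) -> pd.DataFrame:
    """Epoch validity table in the exportable CSV layout."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "epoch_index": [e.index for e in epochs],
            "start_time_s": [e.start_time_s for e in epochs],
            "valid": [e.valid for e in epochs],
            "reasons": [
                ";".join(sorted(r.value for r in e.rejection_reasons)) for e in epochs
            ],
        }
    )
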