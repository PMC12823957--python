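"""Per-epoch predictors and targets: DFT magnitudes, band means, RMS, skewness.

The core feature is the one-sided magnitude spectrum of the unnormalized
forward DFT, X_k = sum_n x_n exp(-j 2 pi k n / N), k = 0..floor(N/2).  No
detrending, windowing or zero padding is applied; the raw epoch slice is
transformed.  Two summaries of the spectrum are used:

* the mean magnitude inside a frequency band, with half-open membership
  [low, high) on bin-center frequencies (at 60-s epochs the bin width is
  1/60 Hz, so 0.3 Hz belongs to the 0.3-1.7 Hz band only); and
* the full-band mean magnitude over all non-DC bins.  The DC bin is excluded
  from every magnitude feature: belt signals carry arbitrary offsets, and
  dropping bin 0 makes the features offset-invariant.

The heart-rate model additionally uses the epoch RMS and the population
skewness of the abdominal slice, and its target is the epoch-average pulse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .errors import (
    ConfigurationError,
    EmptyBandError,
    UndefinedStatisticError,
    ValidationError,
)
from .preprocessing import Epoch
from .sensor_models import ModelKind
from .signal_io import ChannelKind

__all__ = [
    "FrequencyBand",
    "HR_BANDS",
    "MagnitudeSpectrum",
    "MODEL_CHANNELS",
    "FEATURE_COLUMNS",
    "dft_magnitude",
    "band_mean_magnitude",
    "mean_spectral_magnitude",
    "rms",
    "skewness",
    "mean_pulse",
    "extract_features",
    "feature_conventions",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A half-open frequency interval [low_hz, high_hz) in Hz."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_hz < self.high_hz):
            raise ValidationError(
                f"band must satisfy 0 <= low < high, got [{self.low_hz}, {self.high_hz})"
            )


#: HR-model bands: slow breathing dynamics, typical respiratory oscillations,
#: and subtle cardiac-related thoracoabdominal fluctuations.
HR_BANDS: tuple[FrequencyBand, FrequencyBand, FrequencyBand] = (
    FrequencyBand(0.07, 0.3),
    FrequencyBand(0.3, 1.7),
    FrequencyBand(1.7, 5.0),
)


@dataclass
class MagnitudeSpectrum:
    """One-sided DFT magnitudes |X_k|, k = 0..floor(N/2), with bin width fs/N."""

    magnitudes: np.ndarray
    bin_hz: float
    n_samples: int

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.magnitudes.size) * self.bin_hz

    @property
    def nyquist_hz(self) -> float:
        return self.bin_hz * self.n_samples / 2.0


#: channels each model kind requires from an epoch.
MODEL_CHANNELS: dict[ModelKind, tuple[ChannelKind, ...]] = {
    ModelKind.HR: (ChannelKind.AB, ChannelKind.PULSE),
    ModelKind.NPF: (ChannelKind.AB, ChannelKind.TH, ChannelKind.NPF),
    ModelKind.PES1: (ChannelKind.NPF, ChannelKind.OPF, ChannelKind.PES),
    ModelKind.PES2: (ChannelKind.AB, ChannelKind.TH, ChannelKind.PES),
}

#: full column vocabulary of the pooled feature table.
FEATURE_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "epoch_index",
    "Xband1",
    "Xband2",
    "Xband3",
    "RMS",
    "Skewness",
    "XAB",
    "XTH",
    "XNPF",
    "XOPF",
    "target_pulse",
    "target_npf_mag",
    "target_pes_mag",
)


def dft_magnitude(sample_slice: Sequence[float] | np.ndarray, fs: float) -> MagnitudeSpectrum:
    """One-sided magnitude spectrum of the unnormalized forward DFT."""
    x = np.asarray(sample_slice, dtype=np.float64)
    if x.size < 2:
        raise ValidationError("DFT requires at least 2 samples")
    if not fs > 0:
        raise ValidationError("sampling rate must be positive")
    mags = np.abs(np.fft.rfft(x))
    return MagnitudeSpectrum(magnitudes=mags, bin_hz=fs / x.size, n_samples=x.size)


def band_mean_magnitude(spectrum: MagnitudeSpectrum, band: FrequencyBand) -> float:
    """Mean |X_k| over bins whose center frequency lies in [low, high)."""
    if band.high_hz > spectrum.nyquist_hz + 1e-12:
        raise ValidationError(
            f"band upper edge {band.high_hz} Hz exceeds the Nyquist frequency "
            f"{spectrum.nyquist_hz:.6g} Hz"
        )
    freqs = spectrum.frequencies
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    if not mask.any():
        raise EmptyBandError(
            f"band [{band.low_hz}, {band.high_hz}) Hz contains no bins at "
            f"resolution {spectrum.bin_hz:.6g} Hz"
        )
    return float(spectrum.magnitudes[mask].mean())


def mean_spectral_magnitude(spectrum: MagnitudeSpectrum) -> float:
    """Mean |X_k| over all non-DC bins, k = 1..floor(N/2)."""
    return float(spectrum.magnitudes[1:].mean())


def rms(sample_slice: Sequence[float] | np.ndarray) -> float:
    """Root mean square of a slice."""
    x = np.asarray(sample_slice, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("empty slice")
    return float(np.sqrt(np.mean(x**2)))


def skewness(sample_slice: Sequence[float] | np.ndarray) -> float:
    """Population skewness m3 / m2^(3/2) (no small-sample correction)."""
    x = np.asarray(sample_slice, dtype=np.float64)
    if x.size < 3:
        raise ValidationError("skewness requires at least 3 samples")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("skewness is undefined for a constant slice")
    return float(_scipy_stats.skew(x, bias=True))


def mean_pulse(pulse_slice: Sequence[float] | np.ndarray) -> float:
    """Epoch-average pulse in bpm."""
    x = np.asarray(pulse_slice, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("empty pulse slice")
    return float(np.mean(x))


def _require_channels(epoch: Epoch, kinds: Iterable[ChannelKind], kind: ModelKind) -> None:
    for ch in kinds:
        if ch not in epoch.samples_per_channel:
            raise ConfigurationError(
                f"epoch {epoch.index} lacks channel {ch.value} required by the "
                f"{kind.value} model"
            )


def extract_features(
    epochs: Sequence[Epoch],
    model_kind: ModelKind,
    sampling_rates: dict[ChannelKind, float],
    subject_id: str = "",
    bands: tuple[FrequencyBand, ...] = HR_BANDS,
) -> pd.DataFrame:
    """Build the per-epoch feature table for one model kind.

    One row per *valid* epoch; invalid epochs contribute nothing.  Columns
    are exactly the predictors and target of the requested kind (plus
    ``subject_id`` and ``epoch_index``), named as in :data:`FEATURE_COLUMNS`.

    ``sampling_rates`` must give the rate of every channel the kind uses so
    spectra carry correct bin frequencies.
    """
    model_kind = ModelKind(model_kind)
    if model_kind == ModelKind.HR and len(bands) != 3:
        raise ConfigurationError("the HR model uses exactly three frequency bands")
    needed = MODEL_CHANNELS[model_kind]
    for ch in needed:
        if ch not in sampling_rates:
            raise ConfigurationError(f"sampling rate for channel {ch.value} not provided")

    rows: list[dict] = []
    for epoch in epochs:
        if not epoch.valid:
            continue
        _require_channels(epoch, needed, model_kind)
        row: dict = {"subject_id": subject_id, "epoch_index": epoch.index}
        get = epoch.samples_per_channel.__getitem__

        def msm(ch: ChannelKind) -> float:
            return mean_spectral_magnitude(dft_magnitude(get(ch), sampling_rates[ch]))

        if model_kind == ModelKind.HR:
            ab = get(ChannelKind.AB)
            spec = dft_magnitude(ab, sampling_rates[ChannelKind.AB])
            for i, band in enumerate(bands, start=1):
                row[f"Xband{i}"] = band_mean_magnitude(spec, band)
            row["RMS"] = rms(ab)
            row["Skewness"] = skewness(ab)
            row["target_pulse"] = mean_pulse(get(ChannelKind.PULSE))
        elif model_kind == ModelKind.NPF:
            row["XAB"] = msm(ChannelKind.AB)
            row["XTH"] = msm(ChannelKind.TH)
            row["target_npf_mag"] = msm(ChannelKind.NPF)
        elif model_kind == ModelKind.PES1:
            row["XNPF"] = msm(ChannelKind.NPF)
            row["XOPF"] = msm(ChannelKind.OPF)
            row["target_pes_mag"] = msm(ChannelKind.PES)
        else:  # PES2
            row["XAB"] = msm(ChannelKind.AB)
            row["XTH"] = msm(ChannelKind.TH)
            row["target_pes_mag"] = msm(ChannelKind.PES)
        rows.append(row)

    if not rows:
        columns = ["subject_id", "epoch_index"]
        if model_kind == ModelKind.HR:
            columns += ["Xband1", "Xband2", "Xband3", "RMS", "Skewness", "target_pulse"]
        else:
            preds, target = {
                ModelKind.NPF: (["XAB", "XTH"], "target_npf_mag"),
                ModelKind.PES1: (["XNPF", "XOPF"], "target_pes_mag"),
                ModelKind.PES2: (["XAB", "XTH"], "target_pes_mag"),
            }[model_kind]
            columns += preds + [target]
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)


def feature_conventions(
    epoch_seconds: float, bands: tuple[FrequencyBand, ...] = HR_BANDS
) -> dict:
    """The extraction conventions stored inside every saved model."""
    return {
        "epoch_seconds": float(epoch_seconds),
        "bands": [[b.low_hz, b.high_hz] for b in bands],
        "dc_excluded": True,
    }
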