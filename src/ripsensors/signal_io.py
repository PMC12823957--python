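"""Recording data model and readers/writers for EDF and delimited text.

The pipeline works on six channel kinds: the two respiratory inductance
plethysmography (RIP) belts (abdominal ``AB`` and thoracic ``TH``), nasal and
oral pneumoflow (``NPF``/``OPF``), esophageal pressure (``PES``, cmH2O) and a
1 Hz beats-per-minute pulse series (``PULSE``).  A :class:`Recording` bundles
one :class:`ChannelSignal` per kind together with subject metadata.

EDF (European Data Format) is the interchange format.  The reader and writer
here implement the plain EDF layout directly: a 256-byte fixed header, 256
bytes per signal of per-signal header fields, then sequential data records of
little-endian 16-bit integers mapped linearly between the declared physical
and digital ranges.  Only what the pipeline needs is supported: uniform
integer numbers of samples per one-second data record and ordinary signal
channels (annotation channels are skipped on read).

Missing samples are represented as NaN in memory and are never written to
EDF; they flow through the delimited-text path and invalidate epochs
downstream instead of being silently interpolated.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptyRecordingError,
    FormatError,
    ParseError,
    ValidationError,
)

__all__ = [
    "ChannelKind",
    "ChannelSignal",
    "Recording",
    "read_edf",
    "write_edf",
    "read_table",
    "write_table",
    "DEFAULT_UNITS",
]


class ChannelKind(str, enum.Enum):
    """The six channel kinds consumed by the four sensor models."""

    AB = "AB"
    TH = "TH"
    NPF = "NPF"
    OPF = "OPF"
    PES = "PES"
    PULSE = "PULSE"


DEFAULT_UNITS: dict[ChannelKind, str] = {
    ChannelKind.AB: "a.u.",
    ChannelKind.TH: "a.u.",
    ChannelKind.NPF: "a.u.",
    ChannelKind.OPF: "a.u.",
    ChannelKind.PES: "cmH2O",
    ChannelKind.PULSE: "bpm",
}


@dataclass
class ChannelSignal:
    """One uniformly sampled channel.

    Parameters
    ----------
    kind
        Channel kind.
    samples
        1-D float array; NaN marks an explicitly missing sample.  Infinite
        values are rejected.
    sampling_rate_hz
        Positive sampling rate.  Belts are typically 200 Hz, pneumoflow and
        esophageal pressure 250 Hz, pulse 1 Hz (1-s averaged bpm).
    units
        Free-text unit label; defaults to the conventional unit of the kind.
    """

    kind: ChannelKind
    samples: np.ndarray
    sampling_rate_hz: float
    units: str = ""

    def __post_init__(self) -> None:
        self.kind = ChannelKind(self.kind)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not self.sampling_rate_hz > 0:
            raise ValidationError(
                f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}"
            )
        if np.isinf(self.samples).any():
            raise ValidationError(
                "infinite sample values are not allowed; use NaN for missing data"
            )
        if not self.units:
            self.units = DEFAULT_UNITS[self.kind]

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Recording:
    """A subject's multichannel signal set.

    ``channels`` maps each :class:`ChannelKind` to at most one
    :class:`ChannelSignal`; all channels are assumed to start at the same
    instant.  ``metadata`` carries optional cohort fields (age, sex, BMI,
    AHI in events/hour).
    """

    subject_id: str
    channels: dict[ChannelKind, ChannelSignal]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed: dict[ChannelKind, ChannelSignal] = {}
        for kind, sig in self.channels.items():
            kind = ChannelKind(kind)
            if kind in fixed:
                raise ValidationError(f"duplicate channel kind {kind.value}")
            if sig.kind != kind:
                raise ValidationError(
                    f"channel stored under {kind.value} has kind {sig.kind.value}"
                )
            fixed[kind] = sig
        if not fixed:
            raise EmptyRecordingError("recording has no channels")
        self.channels = fixed

    @property
    def duration_s(self) -> float:
        return max(sig.duration_s for sig in self.channels.values())

    def check_span(self, epoch_seconds: float) -> None:
        """Raise unless every channel covers the same span within one epoch."""
        durations = [sig.duration_s for sig in self.channels.values()]
        if max(durations) - min(durations) > epoch_seconds:
            raise ValidationError(
                "channel durations differ by more than one epoch "
                f"({min(durations):.1f}-{max(durations):.1f} s)"
            )


# ---------------------------------------------------------------------------
# EDF layout
# ---------------------------------------------------------------------------

_EDF_HEADER = 256  # bytes, fixed part
_EDF_PER_SIGNAL = 256  # bytes of per-signal header fields
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def _fmt_num(value: float, width: int) -> bytes:
    for prec in range(width - 2, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return _pad(s, width)
    raise ValidationError(f"cannot format {value} in {width} EDF header bytes")


def write_edf(
    recording: Recording,
    path: str | Path,
    physical_range: Mapping[ChannelKind, tuple[float, float]] | None = None,
) -> Path:
    """Write a recording as a plain EDF file.

    Each channel becomes one EDF signal labelled by its kind name, with a
    one-second data record, so every sampling rate must be a positive integer
    and every channel must hold a whole number of seconds.  Samples are
    quantized linearly to 16-bit integers over the channel's physical range;
    the worst-case quantization error is (max-min)/2**16 per sample.

    Parameters
    ----------
    physical_range
        Optional per-kind (min, max).  Defaults to the observed data range
        padded by 1% (or a unit interval for constant channels).  A channel
        exceeding its declared range is a validation error rather than being
        clipped.
    """
    path = Path(path)
    kinds = list(recording.channels)
    if not kinds:
        raise EmptyRecordingError("recording has no channels")

    n_records: int | None = None
    specs = []
    for kind in kinds:
        sig = recording.channels[kind]
        x = sig.samples
        if np.isnan(x).any():
            raise ValidationError(
                f"channel {kind.value} contains missing samples; EDF cannot store NaN"
            )
        fs = sig.sampling_rate_hz
        spr = int(round(fs))
        if abs(fs - spr) > 1e-9 or spr < 1:
            raise ValidationError(
                f"channel {kind.value}: EDF writer requires an integer sampling rate, got {fs}"
            )
        if x.size % spr != 0:
            raise ValidationError(
                f"channel {kind.value}: {x.size} samples is not a whole number of "
                f"1-s records at {spr} Hz"
            )
        recs = x.size // spr
        if n_records is None:
            n_records = recs
        elif recs != n_records:
            raise ValidationError(
                "all channels must span the same whole number of seconds for EDF export"
            )
        if physical_range is not None and kind in physical_range:
            pmin, pmax = physical_range[kind]
            if not pmin < pmax:
                raise ValidationError(f"physical range for {kind.value} must have min < max")
            if x.min() < pmin or x.max() > pmax:
                raise ValidationError(
                    f"channel {kind.value} exceeds declared physical range "
                    f"[{pmin}, {pmax}]: data span [{x.min():.6g}, {x.max():.6g}]"
                )
        else:
            lo, hi = float(x.min()), float(x.max())
            span = hi - lo
            if span == 0.0:
                lo, hi = lo - 0.5, hi + 0.5
            else:
                lo, hi = lo - 0.01 * span, hi + 0.01 * span
            pmin, pmax = lo, hi
        specs.append((kind, sig, spr, float(pmin), float(pmax)))

    ns = len(specs)
    header_bytes = _EDF_HEADER + _EDF_PER_SIGNAL * ns
    out = bytearray()
    out += _pad("0", 8)
    out += _pad(recording.subject_id, 80)
    out += _pad("ripsensors", 80)
    out += _pad("01.01.00", 8)
    out += _pad("00.00.00", 8)
    out += _pad(str(header_bytes), 8)
    out += _pad("", 44)
    out += _pad(str(n_records), 8)
    out += _pad("1", 8)
    out += _pad(str(ns), 4)

    for kind, sig, _, _, _ in specs:
        out += _pad(kind.value, 16)
    for _ in specs:
        out += _pad("", 80)
    for kind, sig, _, _, _ in specs:
        out += _pad(sig.units, 8)
    for _, _, _, pmin, _ in specs:
        out += _fmt_num(pmin, 8)
    for _, _, _, _, pmax in specs:
        out += _fmt_num(pmax, 8)
    for _ in specs:
        out += _pad(str(_DIG_MIN), 8)
    for _ in specs:
        out += _pad(str(_DIG_MAX), 8)
    for _ in specs:
        out += _pad("", 80)
    for _, _, spr, _, _ in specs:
        out += _pad(str(spr), 8)
    for _ in specs:
        out += _pad("", 32)

    digital = []
    for _, sig, spr, pmin, pmax in specs:
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        d = np.rint((sig.samples - pmin) * gain + _DIG_MIN)
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))

    assert n_records is not None
    body = bytearray()
    for rec in range(n_records):
        for (_, _, spr, _, _), d in zip(specs, digital):
            body += d[rec * spr : (rec + 1) * spr].tobytes()

    path.write_bytes(bytes(out) + bytes(body))
    return path


def _header_field(raw: bytes, start: int, width: int) -> str:
    return raw[start : start + width].decode("ascii", errors="replace").strip()


def read_edf(
    path: str | Path,
    channel_name_map: Mapping[str, ChannelKind] | None = None,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    ``channel_name_map`` maps EDF signal labels to channel kinds; unmapped
    labels are ignored.  By default the map accepts the kind names themselves
    (as written by :func:`write_edf`).  Native sampling rates are preserved.
    """
    path = Path(path)
    if channel_name_map is None:
        channel_name_map = {k.value: k for k in ChannelKind}
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER:
        raise FormatError(f"{path}: too short to be an EDF file")
    version = _header_field(raw, 0, 8)
    if version != "0":
        raise FormatError(f"{path}: unsupported EDF version field {version!r}")
    subject_id = _header_field(raw, 8, 80) or path.stem
    try:
        header_bytes = int(_header_field(raw, 184, 8))
        n_records = int(_header_field(raw, 236, 8))
        record_dur = float(_header_field(raw, 244, 8))
        ns = int(_header_field(raw, 252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header ({exc})") from exc
    if ns < 1 or record_dur <= 0 or n_records < 0:
        raise FormatError(f"{path}: inconsistent EDF header")
    if header_bytes != _EDF_HEADER + _EDF_PER_SIGNAL * ns:
        raise FormatError(f"{path}: EDF header size does not match signal count")

    # per-signal blocks: label16 transducer80 dim8 pmin8 pmax8 dmin8 dmax8 prefilter80 spr8 reserved32
    offsets = [0, 16 * ns, 96 * ns, 104 * ns, 112 * ns, 120 * ns, 128 * ns, 136 * ns, 216 * ns]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8]

    def column(idx: int) -> list[str]:
        base = _EDF_HEADER + offsets[idx]
        w = widths[idx]
        return [
            raw[base + i * w : base + (i + 1) * w].decode("ascii", errors="replace").strip()
            for i in range(ns)
        ]

    labels = column(0)
    dims = column(2)
    try:
        pmins = [float(v) for v in column(3)]
        pmaxs = [float(v) for v in column(4)]
        dmins = [int(v) for v in column(5)]
        dmaxs = [int(v) for v in column(6)]
        sprs = [int(v) for v in column(8)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed per-signal EDF header ({exc})") from exc

    record_len = sum(sprs)
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    if n_records * record_len > data.size:
        raise FormatError(f"{path}: truncated EDF data section")
    data = data[: n_records * record_len].reshape(n_records, record_len)

    channels: dict[ChannelKind, ChannelSignal] = {}
    col = 0
    for i in range(ns):
        spr = sprs[i]
        block = data[:, col : col + spr]
        col += spr
        label = labels[i]
        if label.startswith("EDF Annotations"):
            continue
        kind = channel_name_map.get(label)
        if kind is None:
            continue
        kind = ChannelKind(kind)
        if dmaxs[i] == dmins[i] or pmaxs[i] == pmins[i]:
            raise FormatError(f"{path}: signal {label!r} has a degenerate scaling range")
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        x = (block.reshape(-1).astype(np.float64) - dmins[i]) * gain + pmins[i]
        channels[kind] = ChannelSignal(
            kind=kind,
            samples=x,
            sampling_rate_hz=spr / record_dur,
            units=dims[i] or DEFAULT_UNITS[kind],
        )

    if not channels:
        raise EmptyRecordingError(
            f"{path}: no EDF signal label matched the channel map "
            f"(labels present: {labels})"
        )
    return Recording(subject_id=subject_id, channels=channels)


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_table(path: str | Path, kind: ChannelKind, sampling_rate_hz: float) -> ChannelSignal:
    """Read a one-column delimited text file as a channel.

    One sample per row, '.' decimal separator, optional single header row.
    Empty cells and the literal ``nan`` mark missing samples.  A row that is
    neither numeric nor missing raises :class:`ParseError` naming the row.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ValidationError(f"{path}: empty file")
    start = 0
    if not _NUMBER_RE.match(lines[0]) and lines[0].lower() not in {"nan", ""}:
        start = 1  # header row
    if start == len(lines):
        raise ValidationError(f"{path}: header but no data rows")
    values = np.empty(len(lines) - start, dtype=np.float64)
    for i, ln in enumerate(lines[start:]):
        if ln.lower() == "nan":
            values[i] = np.nan
        elif _NUMBER_RE.match(ln):
            values[i] = float(ln)
        else:
            raise ParseError(f"{path}: non-numeric value {ln!r} at data row {i}")
    return ChannelSignal(kind=kind, samples=values, sampling_rate_hz=sampling_rate_hz)


def write_table(signal: ChannelSignal, path: str | Path, header: bool = True) -> Path:
    """Write a channel as a one-column text file (counterpart of :func:`read_table`)."""
    path = Path(path)
    col = pd.Series(signal.samples, name=signal.kind.value)
    col.to_csv(path, index=False, header=header, na_rep="nan")
    return path
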