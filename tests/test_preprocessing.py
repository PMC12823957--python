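"""Epoch segmentation, artifact flags, Pes spike cleaning, inclusion rule."""

import numpy as np
import pytest

from ripsensors import (
    ChannelKind,
    ChannelSignal,
    CleaningConfig,
    Recording,
    RejectionReason,
    build_epoch_table,
    clean_pes,
    flag_flat_epoch,
    flag_pulse_epoch,
    recording_passes_inclusion,
    segment_epochs,
)
from ripsensors.errors import ConfigurationError, PesCorruptError, ValidationError
from ripsensors.preprocessing import Epoch

from conftest import make_signal


class TestSegmentation:
    @pytest.mark.parametrize("fs,expected", [(200.0, 12000), (250.0, 15000)])
    def test_sixty_second_epoch_sample_counts(self, fs, expected):
        sig = make_signal(fs=fs, duration_s=120)
        slices = segment_epochs(sig, 60.0)
        assert len(slices) == 2
        assert all(len(s) == expected for s in slices)

    def test_trailing_partial_window_discarded(self):
        sig = make_signal(fs=200.0, duration_s=605)
        slices = segment_epochs(sig, 60.0)
        assert len(slices) == 10

    def test_slices_tile_the_signal(self):
        sig = make_signal(fs=200.0, duration_s=125)
        slices = segment_epochs(sig, 60.0)
        np.testing.assert_array_equal(np.concatenate(slices), sig.samples[: 2 * 12000])

    def test_degenerate_epochs_rejected(self):
        sig = ChannelSignal(ChannelKind.PULSE, [60.0, 61.0, 60.0], 1.0)
        with pytest.raises(ValidationError):
            segment_epochs(sig, 1.0)  # one sample per epoch
        with pytest.raises(ValidationError):
            segment_epochs(make_signal(fs=200.0), 60.0041)  # non-integer sample count


class TestPulseFlags:
    def test_constant_plausible_pulse_is_clean(self, cleaning):
        assert flag_pulse_epoch(np.full(60, 60.0), cleaning) == set()

    def test_low_rate_flagged(self, cleaning):
        x = np.full(60, 60.0)
        x[10] = 30.0
        assert RejectionReason.IMPLAUSIBLE_PULSE in flag_pulse_epoch(x, cleaning)

    def test_jump_flagged(self, cleaning):
        assert flag_pulse_epoch(np.array([100.0, 145.0]), cleaning) == {
            RejectionReason.PULSE_JUMP
        }

    def test_thresholds_are_strict(self, cleaning):
        # exactly 40/180 bpm and jumps of exactly 40 bpm are acceptable
        assert flag_pulse_epoch(np.array([40.0, 80.0, 120.0, 160.0]), cleaning) == set()
        assert flag_pulse_epoch(np.array([140.0, 180.0]), cleaning) == set()

    def test_missing_sample_flagged(self, cleaning):
        x = np.full(60, 60.0)
        x[0] = np.nan
        assert RejectionReason.MISSING_DATA in flag_pulse_epoch(x, cleaning)


class TestFlatFlags:
    def test_all_zero_slice_is_flat(self):
        cfg = CleaningConfig(flat_eps=1e-6)
        assert flag_flat_epoch(np.zeros(100), cfg) == {RejectionReason.FLAT_SIGNAL}

    def test_sinusoid_is_not_flat(self, cleaning):
        t = np.arange(12000) / 200.0
        assert flag_flat_epoch(np.sin(2 * np.pi * 0.25 * t), cleaning) == set()

    def test_fraction_boundary_is_inclusive(self):
        cfg = CleaningConfig(flat_eps=1e-6, flat_fraction=0.9)
        x = np.ones(10)
        x[:9] = 0.0
        assert flag_flat_epoch(x, cfg) == {RejectionReason.FLAT_SIGNAL}
        x[8] = 1.0  # 80% zeros: below the threshold
        assert flag_flat_epoch(x, cfg) == set()


def _brute_clean(x, threshold, kernel):
    """Loop-based reference: interpolation between survivors + sort median."""
    x = np.asarray(x, dtype=float)
    bad = np.abs(x) > threshold
    if not bad.any():
        return x.copy()
    good = np.flatnonzero(~bad)
    y = x.copy()
    for i in np.flatnonzero(bad):
        left = good[good < i]
        right = good[good > i]
        if left.size and right.size:
            l, r = left[-1], right[0]
            y[i] = x[l] + (x[r] - x[l]) * (i - l) / (r - l)
        elif left.size:
            y[i] = x[left[-1]]
        else:
            y[i] = x[right[0]]
    if kernel > 1:
        half = kernel // 2
        padded = np.concatenate([np.full(half, y[0]), y, np.full(half, y[-1])])
        y = np.array(
            [np.sort(padded[i : i + kernel])[half] for i in range(x.size)]
        )
    return y


class TestCleanPes:
    def _sig(self, values):
        return ChannelSignal(ChannelKind.PES, values, 250.0)

    def test_isolated_spike_midpoint_interpolated(self):
        cfg = CleaningConfig(median_kernel_samples=1)
        out = clean_pes(self._sig([0.1, 5.0, 0.3]), cfg)
        np.testing.assert_allclose(out.samples, [0.1, 0.2, 0.3])

    def test_spike_free_signal_unchanged(self, cleaning):
        x = 0.5 * np.sin(np.linspace(0, 20, 500))
        out = clean_pes(self._sig(x), cleaning)
        np.testing.assert_array_equal(out.samples, x)

    def test_matches_brute_force_reference(self, rng, cleaning):
        x = 1.2 * np.sin(np.linspace(0, 40, 800)) + 0.1 * rng.standard_normal(800)
        spikes = rng.choice(800, size=25, replace=False)
        x[spikes] = rng.choice([-1, 1], size=25) * 4.0
        out = clean_pes(self._sig(x), cleaning)
        expected = _brute_clean(x, cleaning.pes_spike_cmH2O, cleaning.median_kernel_samples)
        np.testing.assert_allclose(out.samples, expected)

    def test_idempotent_once_output_is_spike_free(self, rng, cleaning):
        x = np.sin(np.linspace(0, 40, 600))
        x[100:103] = 4.5
        once = clean_pes(self._sig(x), cleaning)
        assert np.all(np.abs(once.samples) <= cleaning.pes_spike_cmH2O)
        twice = clean_pes(once, cleaning)
        np.testing.assert_array_equal(twice.samples, once.samples)

    def test_totally_corrupt_signal_raises(self, cleaning):
        with pytest.raises(PesCorruptError):
            clean_pes(self._sig(np.full(100, 9.0)), cleaning)

    def test_wrong_kind_rejected(self, cleaning):
        with pytest.raises(ValidationError):
            clean_pes(make_signal(ChannelKind.AB), cleaning)


class TestEpochTable:
    def _recording(self, minutes=10):
        t = np.arange(int(minutes * 60 * 200)) / 200.0
        ab = np.sin(2 * np.pi * 0.25 * t)
        pulse = np.full(int(minutes * 60), 65.0)
        return Recording(
            "tab01",
            {
                ChannelKind.AB: ChannelSignal(ChannelKind.AB, ab, 200.0),
                ChannelKind.PULSE: ChannelSignal(ChannelKind.PULSE, pulse, 1.0),
            },
        )

    def test_clean_recording_all_valid(self, cleaning):
        epochs = build_epoch_table(
            self._recording(), [ChannelKind.AB, ChannelKind.PULSE], cleaning
        )
        assert len(epochs) == 10
        assert all(e.valid for e in epochs)

    def test_zeroed_belt_minutes_flagged_exactly(self, cleaning):
        rec = self._recording()
        rec.channels[ChannelKind.AB].samples[3 * 12000 : 5 * 12000] = 0.0
        epochs = build_epoch_table(rec, [ChannelKind.AB, ChannelKind.PULSE], cleaning)
        flagged = {e.index for e in epochs if not e.valid}
        assert flagged == {3, 4}
        for e in epochs:
            if not e.valid:
                assert e.rejection_reasons == {RejectionReason.FLAT_SIGNAL}

    def test_missing_required_channel_errors(self, cleaning):
        with pytest.raises(ConfigurationError, match="PULSE"):
            build_epoch_table(
                Recording("x", {ChannelKind.AB: make_signal()}),
                [ChannelKind.AB, ChannelKind.PULSE],
                cleaning,
            )

    def test_spiky_pes_epoch_flagged_corrupt(self, cleaning):
        n = 5 * 60 * 250
        pes = 0.8 * np.sin(2 * np.pi * 0.25 * np.arange(n) / 250.0)
        pes[2 * 15000 : 2 * 15000 + 3000] = 4.0  # 20% of epoch 2 above threshold
        rec = Recording(
            "pes01", {ChannelKind.PES: ChannelSignal(ChannelKind.PES, pes, 250.0)}
        )
        epochs = build_epoch_table(rec, [ChannelKind.PES], cleaning)
        assert [e.index for e in epochs if RejectionReason.PES_CORRUPT in e.rejection_reasons] == [2]


class TestInclusion:
    def _epochs(self, n_valid, n_invalid=0):
        out = []
        for i in range(n_valid + n_invalid):
            reasons = set() if i < n_valid else {RejectionReason.FLAT_SIGNAL}
            out.append(Epoch(i, i * 60.0, {}, reasons))
        return out

    @pytest.mark.parametrize(
        "n_valid,expected", [(300, True), (120, False), (240, True)]
    )
    def test_four_hour_rule_boundary_inclusive(self, n_valid, expected, cleaning):
        passes, summary = recording_passes_inclusion(self._epochs(n_valid), cleaning)
        assert passes is expected
        assert summary.n_valid == n_valid

    def test_summary_counts_rejections(self, cleaning):
        passes, summary = recording_passes_inclusion(self._epochs(250, 5), cleaning)
        assert passes
        assert summary.rejections_by_reason["FLAT_SIGNAL"] == 5
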