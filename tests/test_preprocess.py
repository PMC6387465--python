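"""Filtering, epoching arithmetic, and the artifact-rejection rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroproxy.preprocess import (FilterSpec, bandpass, drop_flagged,
                                   flag_amplitude, flag_trend, segment_epochs)
from neuroproxy.recordings_io import Block, ChannelInfo, Recording

FS = 250.0


def _recording(data, blocks=None, fs=FS):
    data = np.atleast_2d(data)
    chans = [ChannelInfo(f"Ch{i}", "EEG") for i in range(data.shape[0])]
    if blocks is None:
        blocks = [Block("OC", 1, 0.0, data.shape[1] / fs)]
    return Recording(sfreq=fs, channels=chans, data=data, blocks=blocks)


def _epochs_of(data, fs=FS):
    """Build an EpochSet directly from epochs x channels x samples data."""
    import pandas as pd
    from neuroproxy.preprocess import EpochSet
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, None, :]
    elif data.ndim == 2:  # channels x (n_epochs * 1000) concatenation
        data = np.stack(np.split(data, data.shape[1] // 1000, axis=1))
    meta = pd.DataFrame({"subject": 0, "condition": "OC", "repetition": 1,
                         "start_time": np.arange(data.shape[0]) * 4.0})
    chans = [ChannelInfo(f"Ch{i}", "EEG") for i in range(data.shape[1])]
    return EpochSet(sfreq=fs, channels=chans, data=data, meta=meta)


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(int(30 * FS)) / FS
        rec = _recording(np.sin(2 * np.pi * 10.0 * t))
        out = bandpass(rec, FilterSpec())
        mid = out.data[0, int(5 * FS):int(25 * FS)]
        assert abs(np.max(np.abs(mid)) - 1.0) < 0.05

    def test_stopband_tone_attenuated_48db(self):
        t = np.arange(int(30 * FS)) / FS
        rec = _recording(np.sin(2 * np.pi * 40.0 * t))
        out = bandpass(rec, FilterSpec())
        mid = out.data[0, int(5 * FS):int(25 * FS)]
        attenuation_db = -20 * np.log10(np.max(np.abs(mid)) + 1e-300)
        assert attenuation_db >= 48.0

    def test_dc_removed(self):
        rec = _recording(np.full(int(30 * FS), 7.5))
        out = bandpass(rec, FilterSpec())
        assert np.max(np.abs(out.data[0, int(5 * FS):int(25 * FS)])) < 0.05

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = _recording(np.zeros(1000))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, FilterSpec(high_cut=200.0))

    def test_epochs_cut_from_filtered_continuous_signal(self):
        # pipeline order: the filter runs on continuous data, epochs are
        # plain slices of it (no per-epoch re-filtering transients)
        rng = np.random.default_rng(0)
        rec = _recording(rng.standard_normal(int(12 * FS)))
        filt = bandpass(rec, FilterSpec())
        eps = segment_epochs(filt, 4.0, 2.0)
        i0 = int(2.0 * FS)
        assert np.array_equal(eps.data[1, 0], filt.data[0, i0:i0 + 1000])


class TestSegmentation:
    @pytest.mark.parametrize("block_s,expected", [
        (120.0, 1160),  # the standard 2-min block
        (4.1, 1),
        (4.0, 0),
    ])
    def test_epoch_counts(self, block_s, expected):
        n = int(round(block_s * FS))
        rec = _recording(np.zeros(n))
        if expected == 0:
            with pytest.warns(UserWarning, match="too short"):
                eps = segment_epochs(rec, 4.0, 0.1)
        else:
            eps = segment_epochs(rec, 4.0, 0.1)
        assert eps.n_epochs == expected

    def test_two_conditions_give_2320_epochs(self):
        n = int(240 * FS)
        blocks = [Block("OC", 1, 0.0, 120.0), Block("OA", 1, 120.0, 120.0)]
        rec = _recording(np.zeros(n), blocks=blocks)
        eps = segment_epochs(rec, 4.0, 0.1)
        assert eps.n_epochs == 2320
        assert (eps.meta["condition"] == "OC").sum() == 1160

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.5, max_value=40.0))
    def test_count_matches_closed_form(self, block_s):
        n = int(round(block_s * FS))
        rec = _recording(np.zeros(n))
        closed_form = max((n - 1000) // 25, 0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eps = segment_epochs(rec, 4.0, 0.1)
        assert eps.n_epochs == closed_form

    def test_labels_inherited_and_starts_inside_block(self):
        blocks = [Block("OA", 2, 0.0, 10.0), Block("OC", 3, 10.0, 10.0)]
        rec = _recording(np.zeros(int(20 * FS)), blocks=blocks)
        eps = segment_epochs(rec, 4.0, 1.0)
        oa = eps.meta[eps.meta.condition == "OA"]
        assert set(oa["repetition"]) == {2}
        assert oa["start_time"].max() + 4.0 <= 10.0 + 1e-9

    def test_bad_step_rejected(self):
        rec = _recording(np.zeros(2500))
        with pytest.raises(ValueError):
            segment_epochs(rec, 4.0, 0.0)


class TestArtifactRules:
    def test_amplitude_strictly_above_threshold(self):
        base = np.zeros(1000)
        over, boundary = base.copy(), base.copy()
        over[500] = 101.0
        boundary[500] = 100.0
        eps = _epochs_of(np.concatenate([over, boundary, base])[None, :])
        flagged = flag_amplitude(eps, 100.0)
        assert flagged.flags.tolist() == [True, False, False]
        assert flagged.reasons[0] == {"amplitude"}

    def test_negative_excursions_count(self):
        x = np.zeros(1000)
        x[10] = -120.0
        eps = _epochs_of(x)
        assert flag_amplitude(eps).flags[0]

    def test_trend_strictly_above_10uv_per_s(self):
        t = np.arange(1000) / FS
        ramp11 = 11.0 * t  # 44 uV over 4 s
        ramp10 = 10.0 * t
        flat = np.zeros(1000)
        eps = _epochs_of(np.concatenate([ramp11, ramp10, flat])[None, :])
        flagged = flag_trend(eps, 10.0)
        assert flagged.flags.tolist() == [True, False, False]
        assert flagged.reasons[0] == {"trend"}

    def test_negative_slope_flagged(self):
        t = np.arange(1000) / FS
        eps = _epochs_of(-12.0 * t)
        assert flag_trend(eps).flags[0]

    def test_flagging_joint_across_channels(self):
        # violation on one channel drops the epoch for all channels
        data = np.zeros((3, 1000))
        data[2, 5] = 150.0
        eps = _epochs_of(data)
        flagged = flag_amplitude(eps)
        clean = drop_flagged(flagged) if not flagged.flags.all() else None
        assert flagged.flags[0]
        assert clean is None

    def test_flags_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((1, 4000)) * 60
        data[0, 100] = 130.0
        eps = _epochs_of(data)
        ab = flag_trend(flag_amplitude(eps))
        ba = flag_amplitude(flag_trend(eps))
        twice = flag_amplitude(flag_amplitude(eps))
        assert np.array_equal(ab.flags, ba.flags)
        assert ab.reasons == ba.reasons
        assert np.array_equal(twice.flags, flag_amplitude(eps).flags)

    def test_drop_flagged_keeps_metadata(self):
        data = np.zeros((1, 3000))
        data[0, 1500] = 200.0  # second epoch only
        rec = _recording(data)
        eps = segment_epochs(rec, 4.0, 4.0)
        assert eps.n_epochs == 2
        clean = drop_flagged(flag_amplitude(eps))
        assert clean.n_epochs == 1
        assert clean.meta["start_time"].tolist() == [0.0]

    def test_all_flagged_raises(self):
        data = np.full((1, 3000), 200.0)
        eps = _epochs_of(data)
        with pytest.raises(ValueError, match="all epochs"):
            drop_flagged(flag_amplitude(eps))
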