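"""Generator contracts: determinism, condition structure, artifact injection."""

import numpy as np
import pytest

from neuroproxy.iafband import band_bins
from neuroproxy.preprocess import (flag_amplitude, flag_trend, segment_epochs)
from neuroproxy.spectral import condition_mean, epoch_psd
from neuroproxy.synthdata import (SimulationConfig, generate_cohort,
                                  generate_subject, inject_artifacts)

from conftest import quiet_sim


class TestConfigValidation:
    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            quiet_sim(alpha_amp_oc=-1.0).validate()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            quiet_sim(blink_rate=-0.1).validate()

    def test_coupling_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            quiet_sim(coupling={"Neck4": 1.5}).validate()

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            generate_cohort(quiet_sim(n_subjects=0))


class TestSubject:
    def test_eight_annotated_blocks_balanced(self, mini_recording):
        assert len(mini_recording.blocks) == 8
        conds = [b.condition for b in mini_recording.blocks]
        assert conds.count("OC") == 4 and conds.count("OA") == 4
        reps = sorted(b.repetition for b in mini_recording.blocks
                      if b.condition == "OC")
        assert reps == [1, 2, 3, 4]

    def test_seeded_determinism_bit_identical(self):
        cfg = quiet_sim(seed=9)
        a = generate_subject(cfg, 0)
        b = generate_subject(cfg, 0)
        assert np.array_equal(a.data, b.data)
        assert a.blocks == b.blocks and a.meta["true_iaf"] == b.meta["true_iaf"]

    def test_subjects_differ(self):
        cfg = quiet_sim(n_subjects=2, seed=9)
        a, b = generate_subject(cfg, 0), generate_subject(cfg, 1)
        assert not np.array_equal(a.data, b.data)

    def test_iaf_on_quarter_hz_grid(self):
        cfg = quiet_sim(n_subjects=6, seed=5)
        for rec in generate_cohort(cfg, with_artifacts=False):
            iaf = rec.meta["true_iaf"]
            assert 8.0 <= iaf <= 12.0
            assert (iaf / 0.25) == int(iaf / 0.25)

    def test_oc_alpha_power_exceeds_oa_at_coupled_channels(
            self, mini_recording):
        eps = segment_epochs(mini_recording, 4.0, 1.0)
        spec = epoch_psd(eps)
        oc = condition_mean(spec, "OC")
        oa = condition_mean(spec, "OA")
        iaf = mini_recording.meta["true_iaf"]
        bins = band_bins((iaf - 2, iaf + 2))
        sel = np.isin(spec.freqs, bins)
        for ch in ("Oz", "Pz", "Neck4", "WrL2"):
            i = oc.channel_index(ch)
            assert oc.values[i, sel].mean() > oa.values[i, sel].mean()

    def test_psd_peak_at_configured_iaf(self):
        rec = generate_subject(quiet_sim(subject_iaf=11.0,
                                         block_length=30.0), 0)
        spec = epoch_psd(segment_epochs(rec, 4.0, 1.0))
        oc = condition_mean(spec, "OC")
        window = (oc.freqs >= 7.5) & (oc.freqs <= 12.5)
        prof = oc.channel_profile("Oz")
        assert oc.freqs[window][np.argmax(prof[window])] == 11.0

    def test_uncoupled_channel_alpha_profile_uncorrelated(self):
        # a zero-coupling channel shares no alpha source with EEG: across
        # many subjects the profile correlations stay near zero
        from neuroproxy.crosscorr import alpha_profile_correlation
        from neuroproxy.iafband import AlphaSearchRange
        cfg = quiet_sim(n_subjects=10, block_length=16.0, seed=31,
                        coupling={"Neck4": 0.7})
        rs = []
        for rec in generate_cohort(cfg, with_artifacts=False):
            spec = epoch_psd(segment_epochs(rec, 4.0, 1.0))
            oc = condition_mean(spec, "OC")
            c = alpha_profile_correlation(
                oc.freqs, oc.channel_profile("Oz"),
                oc.channel_profile("Neck2"), AlphaSearchRange())
            rs.append(c.r)
        assert abs(np.mean(rs)) < 0.35  # ~0 on average, sd ~ 1/sqrt(19)

    def test_subject_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            generate_subject(quiet_sim(n_subjects=1), 1)


class TestCohort:
    def test_cohort_size_and_blocks(self):
        cfg = quiet_sim(n_subjects=12, block_length=6.0)
        recs = generate_cohort(cfg, with_artifacts=False)
        assert len(recs) == 12
        assert all(len(r.blocks) == 8 for r in recs)

    def test_single_subject_cohort(self):
        assert len(generate_cohort(quiet_sim(), with_artifacts=False)) == 1

    def test_master_seed_reproduces_cohort(self):
        cfg = quiet_sim(n_subjects=3, block_length=6.0, seed=17)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert [r.meta["true_iaf"] for r in a] == \
            [r.meta["true_iaf"] for r in b]
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))


class TestArtifacts:
    def test_zero_rates_identity(self, mini_recording):
        cfg = quiet_sim()
        out, events = inject_artifacts(mini_recording, cfg, seed=0)
        assert events == []
        assert np.array_equal(out.data, mini_recording.data)

    def test_blink_exceeds_amplitude_rule_downstream(self):
        cfg = quiet_sim(blink_rate=2.0, blink_amp=150.0, block_length=30.0,
                        montage="full")
        rec = generate_subject(cfg, 0)
        out, events = inject_artifacts(rec, cfg, seed=4)
        blinks = [e for e in events if e["kind"] == "blink"]
        assert blinks
        eps = flag_amplitude(segment_epochs(out, 4.0, 0.5))
        starts = eps.meta["start_time"].to_numpy()
        for e in blinks:
            overlap = (starts <= e["time"]) & (starts + 4.0 >= e["time"])
            if overlap.any():
                assert eps.flags[overlap].any()

    def test_flags_confined_to_event_windows(self):
        cfg = quiet_sim(emg_rate=1.0, emg_amp=150.0, block_length=30.0,
                        alpha_amp_oc=0.0, alpha_amp_oa=0.0, theta_amp_oc=0.0,
                        theta_amp_oa=0.0, delta_amp_oc=0.0, delta_amp_oa=0.0,
                        beta_amp_oc=0.0, beta_amp_oa=0.0,
                        background_scale=0.5, noeeg_background_scale=0.5)
        rec = generate_subject(cfg, 0)
        out, events = inject_artifacts(rec, cfg, seed=8)
        eps = flag_trend(flag_amplitude(segment_epochs(out, 4.0, 0.5)))
        starts = eps.meta["start_time"].to_numpy()
        flagged = starts[eps.flags]
        for t0 in flagged:
            near = any(e["time"] - 4.0 - 0.1 <= t0 <= e["time"]
                       + e["duration"] + 0.1 for e in events)
            assert near, f"epoch at {t0}s flagged with no nearby event"
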