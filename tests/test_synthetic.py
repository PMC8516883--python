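"""Synthetic cohort generator: determinism, spectral ground truth, group
effects, and the toy forward model."""

import numpy as np
import pytest

from roipower import (CohortSpec, generate_cohort, generate_subject,
                      generate_subject_roi, make_toy_forward_model,
                      pink_noise)
from roipower.spectral import BandScheme, compute_psd


class TestToyForwardModel:
    def test_identity_partition_one_source_per_roi(self):
        m = make_toy_forward_model(19, 68, 68, seed=1)
        assert m.lead_field.shape == (19, 68)
        assert m.n_rois == 68
        assert all(m.roi_labels.count(r) == 1 for r in m.rois)

    def test_even_partition(self):
        m = make_toy_forward_model(8, 20, 4, seed=7)
        assert [m.roi_labels.count(r) for r in m.rois] == [5, 5, 5, 5]

    def test_determinism_bitwise(self):
        a = make_toy_forward_model(8, 20, 4, seed=7)
        b = make_toy_forward_model(8, 20, 4, seed=7)
        assert np.array_equal(a.lead_field, b.lead_field)
        assert np.array_equal(a.source_positions, b.source_positions)
        assert a.roi_labels == b.roi_labels

    def test_rejects_more_rois_than_sources(self):
        with pytest.raises(ValueError):
            make_toy_forward_model(8, 4, 10, seed=0)

    def test_rejects_too_few_sensors(self):
        with pytest.raises(ValueError):
            make_toy_forward_model(2, 10, 2, seed=0)

    def test_atlas_labels_are_the_68_parcels(self):
        m = make_toy_forward_model(19, 68, 68, seed=1)
        assert len(set(m.roi_labels)) == 68
        assert "lh-precuneus" in m.rois and "rh-superiorfrontal" in m.rois

    def test_csv_round_trip(self, toy_model, tmp_path):
        from roipower.forward import read_forward_model, write_forward_model
        write_forward_model(toy_model, tmp_path / "gain.csv",
                            tmp_path / "src.csv")
        back = read_forward_model(tmp_path / "gain.csv", tmp_path / "src.csv")
        assert np.allclose(back.lead_field, toy_model.lead_field)
        assert back.roi_labels == toy_model.roi_labels


class TestGenerateSubject:
    def test_determinism(self, fast_spec, roi_model):
        a = generate_subject(fast_spec, "risk", roi_model, 42)
        b = generate_subject(fast_spec, "risk", roi_model, 42)
        assert np.array_equal(a.data, b.data)

    def test_unknown_group_rejected(self, fast_spec, roi_model):
        with pytest.raises(ValueError):
            generate_subject(fast_spec, "martian", roi_model, 1)

    def test_silence_when_everything_off(self, roi_model):
        spec = CohortSpec(band_amplitudes={}, noise_amplitude=0.0,
                          duration_s=5.0, fs_hz=200.0)
        rec = generate_subject(spec, "risk", roi_model, 3)
        assert np.allclose(rec.data, 0.0)

    def test_band_variance_fractions_match_amplitudes(self, roi_model):
        # noiseless two-band mixture: components are normalized to unit
        # RMS, so total variance must equal Σ amp² and the Welch in-band
        # fraction must track amp²/Σamp² (up to ~10 % band-edge smearing
        # of the 1 Hz bins)
        spec = CohortSpec(band_amplitudes={"delta": 1.0, "alpha": 2.0},
                          noise_amplitude=0.0, heterogeneity=0.0,
                          subject_sigma=0.0, duration_s=20.0, fs_hz=200.0)
        data = generate_subject_roi(spec, "protective", roi_model, 11)
        assert np.allclose(data.var(axis=1), 5.0, rtol=0.05)
        freqs, psd = compute_psd(data, 200.0)
        df = freqs[1] - freqs[0]
        scheme = BandScheme()
        masks = scheme.band_masks(freqs)
        power = np.array([psd[:, m].sum(axis=1) for m in masks]) * df
        frac_alpha = power[2] / power.sum(axis=0)
        assert np.allclose(frac_alpha, 4.0 / 5.0, atol=0.12)
        # and the two target bands dominate everything else
        assert power[[0, 2]].sum() > 0.85 * power.sum()

    def test_sensor_data_is_lead_field_times_sources(self, fast_spec,
                                                     toy_model):
        rec = generate_subject(fast_spec, "risk", toy_model, 5)
        assert rec.data.shape == (8, fast_spec.n_samples)
        assert rec.fs_hz == fast_spec.fs_hz


class TestEffectMultipliers:
    def test_beta_power_ratio_is_squared_multiplier(self, roi_model):
        # ground-truth subject amplitudes from the metadata: the risk /
        # protective ratio of mean squared β amplitude must be 0.8² = 0.64
        spec = CohortSpec(n_subjects_per_group=(150, 150),
                          effect_multipliers={"beta": 0.8},
                          duration_s=5.0, fs_hz=200.0)
        _, meta = generate_cohort(spec, roi_model, seed=21, bypass=True)
        by_group = meta.groupby("group")["amp_beta"].apply(
            lambda a: np.mean(np.square(a)))
        ratio = by_group["risk"] / by_group["protective"]
        assert ratio == pytest.approx(0.64, abs=0.05)

    def test_multiplier_only_touches_risk_group(self, roi_model, fast_spec):
        spec_eff = CohortSpec(effect_multipliers={"beta": 0.5},
                              duration_s=5.0, fs_hz=200.0)
        prot_a = generate_subject_roi(fast_spec, "protective", roi_model, 9)
        prot_b = generate_subject_roi(spec_eff, "protective", roi_model, 9)
        assert np.array_equal(prot_a, prot_b)


class TestGenerateCohort:
    def test_default_cohort_size_is_18_vs_35(self, roi_model):
        spec = CohortSpec(duration_s=5.0, fs_hz=200.0)
        sigs, meta = generate_cohort(spec, roi_model, seed=1, bypass=True)
        assert len(sigs) == 53
        assert meta["group"].value_counts().to_dict() == \
            {"risk": 18, "protective": 35}

    def test_empty_cohort(self, roi_model):
        spec = CohortSpec(n_subjects_per_group=(0, 0), duration_s=5.0,
                          fs_hz=200.0)
        sigs, meta = generate_cohort(spec, roi_model, seed=1)
        assert sigs == [] and len(meta) == 0

    def test_reproducible_given_master_seed(self, roi_model):
        spec = CohortSpec(n_subjects_per_group=(2, 2), duration_s=5.0,
                          fs_hz=200.0)
        s1, m1 = generate_cohort(spec, roi_model, seed=5, bypass=True)
        s2, m2 = generate_cohort(spec, roi_model, seed=5, bypass=True)
        assert all(np.array_equal(a, b) for a, b in zip(s1, s2))
        assert m1.equals(m2)

    def test_metadata_schema(self, roi_model):
        spec = CohortSpec(n_subjects_per_group=(2, 3), duration_s=5.0,
                          fs_hz=200.0)
        _, meta = generate_cohort(spec, roi_model, seed=5, bypass=True)
        for col in ("subject_id", "group", "seed", "sex", "severity", "age",
                    "mmse", "amp_delta", "amp_beta"):
            assert col in meta.columns
        assert set(meta["severity"]) <= {"MIL", "MOD", "SEV"}

    def test_bypass_matches_sensor_path_sources(self, fast_spec, roi_model):
        # same seed → bypass output is the ROI grouping of the same sources
        rec = generate_subject(fast_spec, "risk", roi_model, 77)
        roi = generate_subject_roi(fast_spec, "risk", roi_model, 77)
        # one source per ROI here, so sensor data = lead_field @ roi signals
        assert np.allclose(rec.data, roi_model.lead_field @ roi, atol=1e-9)


class TestSpecValidation:
    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            CohortSpec(fs_hz=120.0)

    def test_rejects_negative_amplitude(self):
        with pytest.raises(ValueError):
            CohortSpec(band_amplitudes={"alpha": -1.0})

    def test_rejects_unknown_band(self):
        with pytest.raises(KeyError):
            CohortSpec(band_amplitudes={"mu": 1.0})


class TestPinkNoise:
    def test_unit_rms_and_slope(self, rng):
        x = pink_noise((4, 200 * 60), 200.0, rng)
        assert np.allclose(x.std(axis=-1), 1.0, atol=1e-9)
        freqs, psd = compute_psd(x, 200.0)
        sel = (freqs >= 2) & (freqs <= 60)
        slope = np.polyfit(np.log(freqs[sel]),
                           np.log(psd[:, sel].mean(axis=0)), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_band_limited_support(self, rng):
        x = pink_noise((2, 200 * 30), 200.0, rng, f_lo=1.0, f_hi=70.0)
        freqs, psd = compute_psd(x, 200.0)
        out_of_band = psd[:, freqs >= 75].mean()
        in_band = psd[:, (freqs >= 2) & (freqs <= 60)].mean()
        assert out_of_band < 1e-3 * in_band
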