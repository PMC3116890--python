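import numpy as np
import pytest

import dataclasses

from levmodel.simulator import (LEVParams, frequency_response_curve,
                                generate_synthetic_dataset, integrate_lev,
                                mixture_component_scales)


@pytest.fixture(scope="module")
def sim(truth, protocol):
    return integrate_lev(truth, "in", 10.0, protocol)


@pytest.fixture(scope="module")
def dataset(truth, protocol):
    return generate_synthetic_dataset("in", truth, protocol, seed=5)


class TestIntegrateLev:

    def test_output_lengths(self, sim, protocol):
        # 30.6 s block: 100 Hz EEG, 10 Hz drive, one BOLD sample per TR
        assert len(sim.eeg) == 3060
        assert len(sim.drive) == 306
        assert len(sim.bold) == 10

    def test_bold_rises_during_stimulation(self, sim):
        evoked = sim.bold - sim.bold_rest
        assert evoked.max() > 0
        assert np.argmax(evoked) <= 6  # peak within/just after stimulation
        assert abs(evoked[-1]) < 0.5 * evoked.max()  # decays in rest

    def test_zero_gains_give_flat_response(self, truth, protocol):
        quiet = dataclasses.replace(
            truth, electrical=dataclasses.replace(
                truth.electrical, gain1=0.0, gain2=0.0, gain3=0.0))
        sim = integrate_lev(quiet, "in", 10.0, protocol)
        assert np.allclose(sim.eeg, 0.0, atol=1e-12)
        assert sim.peak_amplitude == pytest.approx(0.0, abs=1e-10)

    def test_unknown_model_rejected(self, truth, protocol):
        with pytest.raises(ValueError):
            integrate_lev(truth, "bogus", 10.0, protocol)

    def test_step_refinement_on_peak_bold(self, truth, protocol):
        peaks = {}
        for dt in (1e-3, 5e-4):
            sim = integrate_lev(truth, "in", 10.0, protocol, dt=dt)
            peaks[dt] = sim.peak_amplitude
        assert abs(peaks[1e-3] - peaks[5e-4]) / peaks[5e-4] < 0.01


class TestFrequencyResponse:
    def test_zero_gains_give_zero_curve(self, truth, small_protocol):
        quiet = dataclasses.replace(
            truth, electrical=dataclasses.replace(
                truth.electrical, gain1=0.0, gain2=0.0, gain3=0.0))
        curve = frequency_response_curve(quiet, "out",
                                         small_protocol.frequencies,
                                         small_protocol)
        assert all(abs(v) < 1e-10 for v in curve.values())

    def test_normalized_curve_peaks_at_one(self, truth, small_protocol):
        curve = frequency_response_curve(truth, "in",
                                         small_protocol.frequencies,
                                         small_protocol, normalize=True)
        assert max(curve.values()) == pytest.approx(1.0)

    def test_empty_grid_rejected(self, truth, small_protocol):
        with pytest.raises(ValueError):
            frequency_response_curve(truth, "in", [], small_protocol)


class TestMixture:
    def test_component_scales_positive(self, truth, small_protocol):
        s_no, s_fr = mixture_component_scales(truth, small_protocol)
        assert s_no > 0 and s_fr > 0

    def test_extreme_alpha_matches_single_mechanism_shape(self, truth,
                                                          small_protocol):
        # alpha = 1 reproduces the NO drive up to the unit-SD scaling
        pure_no = dataclasses.replace(
            truth, mixture=dataclasses.replace(truth.mixture, alpha_no=1.0))
        scales = mixture_component_scales(pure_no, small_protocol)
        sim_mix = integrate_lev(pure_no, "mix", 4.0, small_protocol,
                                mixture_scales=scales)
        sim_no = integrate_lev(pure_no, "in", 4.0, small_protocol)
        np.testing.assert_allclose(sim_mix.drive * scales[0], sim_no.drive,
                                   rtol=1e-9)


class TestSyntheticDataset:
    def test_one_entry_per_frequency(self, dataset, protocol):
        assert set(dataset.eeg) == set(protocol.frequencies)
        assert set(dataset.bold) == set(protocol.frequencies)

    def test_segment_and_epoch_lengths(self, dataset):
        for f in dataset.protocol.frequencies:
            assert len(dataset.eeg[f]) == 200  # 2 s at 100 Hz
            assert len(dataset.bold[f]) == 10  # 10 scans per epoch

    def test_determinism_given_seed(self, truth, protocol, dataset):
        again = generate_synthetic_dataset("in", truth, protocol, seed=5)
        for f in protocol.frequencies:
            np.testing.assert_array_equal(dataset.eeg[f], again.eeg[f])
            np.testing.assert_array_equal(dataset.bold[f], again.bold[f])

    def test_different_seed_changes_noise_only(self, truth, protocol,
                                               dataset):
        other = generate_synthetic_dataset("in", truth, protocol, seed=6)
        f = protocol.frequencies[0]
        np.testing.assert_array_equal(dataset.eeg_clean[f],
                                      other.eeg_clean[f])
        assert not np.array_equal(dataset.eeg[f], other.eeg[f])

    def test_clean_signals_are_standardized_globally(self, dataset, protocol):
        eeg = np.concatenate([dataset.eeg_clean[f]
                              for f in protocol.frequencies])
        assert abs(eeg.mean()) < 1e-9
        assert np.std(eeg, ddof=1) == pytest.approx(1.0)

    def test_eeg_noise_scale_matches_snr(self, dataset, protocol):
        resid = np.concatenate([dataset.eeg[f] - dataset.eeg_clean[f]
                                for f in protocol.frequencies])
        # SNR 1 on a unit-SD signal: noise SD 1.0 within 5%
        assert np.std(resid, ddof=1) == pytest.approx(1.0, rel=0.05)

    def test_bold_noise_scale_matches_snr(self, dataset, protocol):
        resid = np.concatenate([dataset.bold[f] - dataset.bold_clean[f]
                                for f in protocol.frequencies])
        # SNR 2: noise SD 0.5, 70 samples -> generous tolerance
        assert np.std(resid, ddof=1) == pytest.approx(0.5, rel=0.25)

    def test_invalid_snr_rejected(self, truth, protocol):
        with pytest.raises(ValueError):
            generate_synthetic_dataset("in", truth, protocol, snr_eeg=0.0)
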