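import numpy as np
import pandas as pd
import pytest

from neurophyskit.evoked import (
    EpochSet,
    RecruitmentSession,
    amplitude_at_multiple,
    extract_epochs,
    is_response,
    normalize_amplitude,
    peak_to_peak,
    peripheral_max,
    reject_trials,
    rmt_cortical,
    rmt_spinal,
    ssep_average,
)
from neurophyskit.io_formats import Recording, ValidationError

FS = 1000.0


def _events(indices, intensity=60.0):
    return pd.DataFrame({"sample_index": indices, "label": "stim",
                         "intensity": intensity})


def _recording(n=2000):
    return Recording(FS, ["emg"], np.arange(n, dtype=float))


class TestExtractEpochs:
    def test_half_open_window_arithmetic(self):
        es = extract_epochs(_recording(), "emg", _events([500]))
        assert es.n_samples == 200
        np.testing.assert_array_equal(es.epochs[0], np.arange(400.0, 600.0))
        assert es.event_index == 100

    def test_edge_events_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            es = extract_epochs(_recording(), "emg", _events([50, 500]))
        assert es.n_epochs == 1

    def test_event_order_preserved(self):
        es = extract_epochs(_recording(), "emg",
                            _events([300, 900, 1500], intensity=[40, 50, 60]))
        assert es.n_epochs == 3
        assert list(es.metadata["intensity"]) == [40, 50, 60]
        assert es.epochs[1][100] == 900.0

    def test_no_extractable_epochs_is_error(self):
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                extract_epochs(_recording(300), "emg", _events([10]))


class TestRejectTrials:
    def _epochs(self, rng, n=10):
        return rng.normal(0, 5.0, size=(n, 200))

    def test_homogeneous_epochs_all_kept(self, rng):
        es = EpochSet(self._epochs(rng), FS, (-0.1, 0.1))
        out = reject_trials(es)
        assert out.metadata["kept"].all()

    def test_prestim_burst_rejected(self, rng):
        eps = self._epochs(rng)
        eps[3, :100] *= 10.0  # 100x the pre-stimulus variance
        out = reject_trials(EpochSet(eps, FS, (-0.1, 0.1)))
        kept = out.metadata["kept"]
        assert not kept[3] and kept.drop(3).all()
        assert out.metadata.loc[3, "rejection_reason"] == "prestim_variance"

    def test_infinite_ratio_is_identity(self, rng):
        eps = self._epochs(rng)
        eps[0, :100] *= 100.0
        out = reject_trials(EpochSet(eps, FS, (-0.1, 0.1)), np.inf)
        assert out.metadata["kept"].all()


class TestPeakToPeak:
    def test_max_minus_min(self):
        epoch = np.zeros(200)
        epoch[130], epoch[150] = 40.0, -30.0
        assert peak_to_peak(epoch, FS, 100) == pytest.approx(70.0)

    def test_flat_epoch_zero(self):
        assert peak_to_peak(np.zeros(200), FS, 100) == 0.0

    def test_deflection_outside_window_excluded(self):
        epoch = np.zeros(200)
        epoch[105] = 500.0  # 5 ms post-stimulus: inside the artifact blank-out
        assert peak_to_peak(epoch, FS, 100) == 0.0


@pytest.mark.parametrize("p2p,expected", [(49.9, False), (50.0, True), (120.0, True)])
def test_is_response_inclusive_threshold(p2p, expected):
    assert is_response(p2p) is expected


def _session(rows, protocol="cortical"):
    return RecruitmentSession("BB", protocol, pd.DataFrame(rows))


def _trials(intensity, amps):
    return [{"intensity": intensity, "p2p": a, "kept": True} for a in amps]


class TestRmtCortical:
    def test_lowest_intensity_at_half_fraction(self):
        rows = (_trials(55, [60, 10, 10, 10, 10])      # 1/5
                + _trials(60, [60, 60, 60, 10, 10]))   # 3/5
        res = rmt_cortical(_session(rows))
        assert res.rmt == 60.0

    def test_absent_when_never_reached(self):
        rows = _trials(55, [10] * 5) + _trials(60, [60, 10, 10, 10, 10])
        assert rmt_cortical(_session(rows)).rmt is None

    def test_all_respond_returns_lowest_tested(self):
        rows = _trials(30, [80] * 5) + _trials(40, [90] * 5)
        assert rmt_cortical(_session(rows)).rmt == 30.0

    def test_monotone_in_added_low_intensity_responses(self, rng):
        """Adding responses at a lower intensity can never raise the RMT."""
        for _ in range(20):
            rows = []
            for inten in (40.0, 50.0, 60.0):
                rows += _trials(inten, rng.uniform(0, 120, size=5))
            before = rmt_cortical(_session(rows)).rmt
            rows += _trials(35.0, [100.0] * 5)
            after = rmt_cortical(_session(rows)).rmt
            if before is not None:
                assert after is not None and after <= before


class TestRmtSpinal:
    def test_five_of_ten_consecutive(self):
        amps = [80, 80, 80, 80, 80, 10, 10, 10, 10, 10]
        assert rmt_spinal(_session(_trials(40, amps), "spinal")).rmt == 40.0

    def test_four_of_ten_everywhere_absent(self):
        rows = []
        for inten in (40.0, 50.0):
            rows += _trials(inten, [80, 80, 80, 80] + [10] * 6)
        assert rmt_spinal(_session(rows, "spinal")).rmt is None

    def test_alternating_pattern_meets_windowed_rule(self):
        amps = [80, 10] * 5  # R,N,R,N,... -> 5 responses in the 10-window
        assert rmt_spinal(_session(_trials(40, amps), "spinal")).rmt == 40.0

    def test_sliding_window_across_longer_run(self):
        # 12 trials; only trials 3..7 respond -> some 10-window holds 5
        amps = [10, 10, 10, 80, 80, 80, 80, 80, 10, 10, 10, 10]
        assert rmt_spinal(_session(_trials(40, amps), "spinal")).rmt == 40.0

    def test_too_few_trials_everywhere_is_error(self):
        with pytest.raises(ValidationError):
            rmt_spinal(_session(_trials(40, [80] * 5), "spinal"))


class TestAmplitudeAtMultiple:
    def _grid_session(self):
        rows = []
        for inten in [50.0, 55.0, 60.0, 65.0, 70.0]:
            rows += _trials(inten, [100.0, 120.0, 140.0])
        return _session(rows)

    def test_on_grid_target_exact(self):
        raw, at = amplitude_at_multiple(self._grid_session(), 50.0)
        assert at == 55.0 and raw == pytest.approx(120.0)

    def test_snaps_to_nearest_grid_intensity(self):
        _, at = amplitude_at_multiple(self._grid_session(), 60.0)
        assert at == 65.0  # 66 -> 65 on the 5%-step grid

    def test_ties_snap_upward(self):
        rows = _trials(60.0, [100.0]) + _trials(70.0, [200.0])
        # target 65% sits exactly between the two tested intensities
        raw, at = amplitude_at_multiple(_session(rows), 65.0, multiple=1.0)
        assert at == 70.0 and raw == 200.0

    def test_absent_rmt_is_error(self):
        with pytest.raises(ValidationError):
            amplitude_at_multiple(self._grid_session(), None)


class TestNormalizeAmplitude:
    def test_ratio(self):
        assert normalize_amplitude(100.0, 2000.0).value == pytest.approx(0.05)

    def test_zero_raw_is_zero(self):
        assert normalize_amplitude(0.0, 123.0).value == 0.0

    def test_zero_reference_is_error(self):
        with pytest.raises(ValidationError):
            normalize_amplitude(100.0, 0.0)

    def test_homogeneous_in_common_scale(self):
        a = normalize_amplitude(100.0, 2000.0).value
        b = normalize_amplitude(100.0 * 7.3, 2000.0 * 7.3).value
        assert a == pytest.approx(b)


class TestPeripheralMax:
    def test_plateau_from_documented_tolerance(self):
        series = list(zip([10, 20, 30, 40, 50],
                          [1000.0, 1500.0, 1900.0, 1950.0, 1960.0]))
        res = peripheral_max(series)
        assert res.plateaued
        assert res.reference_uv == pytest.approx(np.mean([1950.0, 1960.0]))

    def test_strictly_rising_never_plateaus(self):
        series = [(10 * (i + 1), 1000.0 * 1.1 ** i) for i in range(6)]
        res = peripheral_max(series)
        assert not res.plateaued
        assert res.reference_uv == pytest.approx(1000.0 * 1.1 ** 5)

    def test_single_point_is_error(self):
        with pytest.raises(ValidationError):
            peripheral_max([(10, 1000.0)])


class TestSsepAverage:
    def test_identical_epochs_average_exactly(self, rng):
        epoch = rng.normal(size=960)
        es = EpochSet(np.tile(epoch, (50, 1)), 4800.0, (-0.1, 0.1))
        res = ssep_average(es)
        np.testing.assert_allclose(res.average, epoch, rtol=0, atol=1e-12)

    def test_single_epoch_average_is_the_epoch(self, rng):
        epoch = rng.normal(size=960)
        es = EpochSet(epoch[None, :], 4800.0, (-0.1, 0.1))
        np.testing.assert_array_equal(ssep_average(es).average, epoch)

    def test_embedded_deflection_detected(self, rng):
        n, fs = 960, 4800.0
        epochs = rng.normal(0, 20.0, size=(300, n))
        peak = int(0.12 * fs)  # 20 ms post-stimulus
        epochs[:, peak - 5:peak + 5] += 8.0
        res = ssep_average(EpochSet(epochs, fs, (-0.1, 0.1)))
        assert res.presence

    def test_no_kept_epochs_is_error(self, rng):
        meta = pd.DataFrame({"intensity": np.nan, "kept": [False] * 3,
                             "rejection_reason": ""})
        es = EpochSet(rng.normal(size=(3, 960)), 4800.0, (-0.1, 0.1), meta)
        with pytest.raises(ValidationError):
            ssep_average(es)
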