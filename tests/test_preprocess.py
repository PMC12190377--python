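"""Preprocessing chain: normalization, GSR, band-pass, FD and QC."""

import numpy as np
import pytest

import brainwin as bw
from brainwin.core import SubjectRecord, Volume4D
from brainwin.preprocess import FDSeries, MIN_TIMEPOINTS, qc_report


def _sine_volume(freq: float, tr: float = 2.0, t: int = 200,
                 shape=(4, 4, 4)) -> Volume4D:
    tt = np.arange(t) * tr
    series = np.sin(2 * np.pi * freq * tt)
    data = np.broadcast_to(series, (*shape, t)).copy()
    return Volume4D(data=data, tr=tr)


def _amplitude_at(vol: Volume4D, freq: float) -> float:
    series = vol.data[0, 0, 0]
    spec = np.abs(np.fft.rfft(series))
    freqs = np.fft.rfftfreq(series.size, d=vol.tr)
    return spec[np.argmin(np.abs(freqs - freq))]


@pytest.fixture()
def random_volume(toy_acq, toy_sig, default_noise):
    vol, _ = bw.generate_subject(toy_acq, toy_sig, default_noise, label=1, seed=13)
    return vol


class TestIntensityNormalize:
    def test_zero_mean_unit_sd_in_mask(self, random_volume):
        out = bw.intensity_normalize(random_volume)
        vals = out.data[out.effective_mask()]
        assert abs(vals.mean()) < 1e-6
        assert abs(vals.std() - 1.0) < 1e-6
        assert np.all(out.data[~out.effective_mask()] == 0)

    def test_affine_invariance(self, random_volume):
        shifted = random_volume.with_data(3.0 * random_volume.data + 10.0)
        a = bw.intensity_normalize(random_volume)
        b = bw.intensity_normalize(shifted)
        mask = random_volume.effective_mask()
        np.testing.assert_allclose(a.data[mask], b.data[mask], atol=1e-9)

    def test_constant_volume_rejected(self):
        vol = Volume4D(data=np.full((4, 4, 4, 30), 7.0), tr=2.0)
        with pytest.raises(ValueError, match="degenerate"):
            bw.intensity_normalize(vol)


class TestGlobalSignalRegress:
    def test_residuals_orthogonal_to_global(self, random_volume):
        out = bw.global_signal_regress(random_volume)
        mask = random_volume.effective_mask()
        g = random_volume.data[mask].mean(axis=0)
        gc = g - g.mean()
        resid = out.data[mask]
        rc = resid - resid.mean(axis=1, keepdims=True)
        corr = rc @ gc / (
            np.maximum(np.linalg.norm(rc, axis=1), 1e-30) * np.linalg.norm(gc)
        )
        assert np.abs(corr).max() < 1e-8

    def test_orthogonality_property_over_seeds(self):
        # random volumes with random masks, many seeds
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = rng.normal(size=(5, 4, 3, 40))
            vol = Volume4D(data=data, tr=2.0)
            out = bw.global_signal_regress(vol)
            g = data.reshape(-1, 40).mean(axis=0)
            gc = g - g.mean()
            resid = out.data.reshape(-1, 40)
            assert np.abs(resid @ gc).max() < 1e-8 * np.linalg.norm(gc) * 1e3

    def test_exact_fit_for_affine_voxel(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=40)
        data = np.broadcast_to(base, (3, 3, 3, 40)).copy()
        data[0, 0, 0] = 2.0 * data.reshape(-1, 40).mean(axis=0) + 5.0
        # every voxel is affine in the global signal -> residuals all ~0
        out = bw.global_signal_regress(Volume4D(data=data, tr=2.0))
        assert np.abs(out.data).max() < 1e-8

    def test_shape_preserved(self, random_volume):
        out = bw.global_signal_regress(random_volume)
        assert out.data.shape == random_volume.data.shape

    def test_constant_global_rejected(self):
        data = np.zeros((3, 3, 3, 40))
        data[0, 0, 0] = np.r_[np.ones(20), -np.ones(20)]
        data[1, 1, 1] = -data[0, 0, 0]  # global mean is exactly constant
        with pytest.raises(ValueError, match="constant global"):
            bw.global_signal_regress(Volume4D(data=data, tr=2.0))


class TestBandpass:
    @pytest.mark.parametrize("tr", [1.0, 2.0, 3.0])
    def test_passband_and_stopband(self, tr):
        cfg = bw.PreprocConfig()
        in_band = _sine_volume(0.05, tr=tr)
        out = bw.bandpass_filter(in_band, cfg)
        assert _amplitude_at(out, 0.05) / _amplitude_at(in_band, 0.05) >= 0.9
        if 0.2 < 0.5 / tr:
            stop = _sine_volume(0.2, tr=tr)
            out = bw.bandpass_filter(stop, cfg)
            assert _amplitude_at(out, 0.2) / _amplitude_at(stop, 0.2) <= 0.1

    def test_dc_removed(self):
        vol = Volume4D(data=np.full((4, 4, 4, 200), 5.0), tr=2.0)
        out = bw.bandpass_filter(vol, bw.PreprocConfig())
        assert np.abs(out.data).max() < 1e-6

    def test_band_above_nyquist_rejected(self):
        vol = _sine_volume(0.05, tr=2.0)
        cfg = bw.PreprocConfig(band_low=0.01, band_high=0.3)
        with pytest.raises(ValueError, match="Nyquist"):
            bw.bandpass_filter(vol, cfg)

    def test_short_series_rejected(self):
        vol = Volume4D(data=np.random.default_rng(0).normal(size=(3, 3, 3, MIN_TIMEPOINTS - 1)),
                       tr=2.0)
        with pytest.raises(ValueError, match="time points"):
            bw.bandpass_filter(vol, bw.PreprocConfig())


class TestFramewiseDisplacement:
    def test_zero_trace(self):
        fd = bw.framewise_displacement(np.zeros((50, 6)), bw.PreprocConfig())
        assert np.all(fd.values == 0) and fd.mean_fd == 0

    def test_single_translation_jump(self):
        trace = np.zeros((50, 6))
        trace[4:, 0] = 0.1  # 0.1 mm step between frames 3 and 4
        fd = bw.framewise_displacement(trace, bw.PreprocConfig())
        assert np.count_nonzero(fd.values) == 1
        assert fd.values[3] == pytest.approx(0.1)
        assert fd.mean_fd == pytest.approx(0.1 / 49)

    def test_rotation_jump(self):
        trace = np.zeros((10, 6))
        trace[5:, 3:] = 0.002  # 0.002 rad on each rotation axis
        fd = bw.framewise_displacement(trace, bw.PreprocConfig(head_radius=50.0))
        assert fd.values[4] == pytest.approx(3 * 0.002 * 50.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(size=(30, 6))
        offset = trace + np.array([1.0, -2.0, 0.5, 0.01, -0.02, 0.03])
        cfg = bw.PreprocConfig()
        np.testing.assert_allclose(
            bw.framewise_displacement(trace, cfg).values,
            bw.framewise_displacement(offset, cfg).values,
            atol=1e-12,
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bw.framewise_displacement(np.zeros((1, 6)), bw.PreprocConfig())


class TestQC:
    @staticmethod
    def _records_with_fd(mean_fds):
        records, fd_map = [], {}
        for i, m in enumerate(mean_fds):
            rec = SubjectRecord(subject_id=f"s{i}", site="A", label=i % 2)
            records.append(rec)
            fd_map[rec.subject_id] = FDSeries(values=np.full(10, m), mean_fd=m)
        return records, fd_map

    def test_threshold_rule(self):
        records, fd_map = self._records_with_fd([0.25, 0.0, 0.2])
        retained, excluded = bw.apply_qc(records, fd_map, bw.PreprocConfig())
        assert [r.subject_id for r in excluded] == ["s0"]  # 0.25 > 0.2
        assert [r.subject_id for r in retained] == ["s1", "s2"]  # 0.2 retained
        assert all(r.qc_pass for r in retained)
        assert not any(r.qc_pass for r in excluded)

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        records, fd_map = self._records_with_fd(rng.uniform(0, 0.5, 25))
        retained, excluded = bw.apply_qc(records, fd_map, bw.PreprocConfig())
        ids = {r.subject_id for r in records}
        r_ids = {r.subject_id for r in retained}
        e_ids = {r.subject_id for r in excluded}
        assert r_ids | e_ids == ids and not (r_ids & e_ids)

    def test_report_columns(self):
        records, fd_map = self._records_with_fd([0.1, 0.3])
        bw.apply_qc(records, fd_map, bw.PreprocConfig())
        rep = qc_report(records)
        assert list(rep.columns) == ["subject_id", "mean_fd", "qc_pass"]


class TestPreprocessSubject:
    def test_shape_finite_and_stage_order(self, random_volume):
        stages = []
        out, fd, qc = bw.preprocess_subject(
            random_volume, np.zeros((random_volume.t, 6)), bw.PreprocConfig(),
            stage_hook=lambda name, v: stages.append(name),
        )
        assert out.data.shape == random_volume.data.shape
        assert np.all(np.isfinite(out.data))
        assert stages == ["intensity_normalize", "global_signal_regress", "bandpass_filter"]
        assert qc

    def test_high_motion_fails_qc(self, random_volume):
        trace = np.zeros((random_volume.t, 6))
        trace[1::2, 0] = 0.6  # alternating 0.6 mm jumps -> mean FD ~ 0.6
        _, fd, qc = bw.preprocess_subject(random_volume, trace, bw.PreprocConfig())
        assert fd.mean_fd > 0.2
        assert not qc
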