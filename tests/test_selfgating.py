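"""Self-gating: SG projections, SOBI unmixing, source selection, triggers, states."""

import numpy as np
import pytest

import freecine as fc
from freecine.phantom import AnatomyConfig
from freecine.selfgating import (
    MotionSignals,
    SGSeries,
    _joint_diagonalize,
    detect_triggers,
    respiratory_states,
    select_physio_sources,
    sobi_unmix,
)

SG_DT = 0.07766  # seconds, the 22 x 3.53 ms cadence


def make_motion(cardiac, respiratory, timestamps, f_c, f_r):
    return MotionSignals(
        cardiac=cardiac, respiratory=respiratory, f_cardiac=f_c, f_respiratory=f_r,
        timestamps=timestamps, sg_interval=SG_DT * 1000.0, mixing_diagnostics={},
    )


@pytest.fixture(scope="module")
def breathing_kdata():
    """Breathing-only phantom (no contraction), 30 s acquisition."""
    anatomy = AnatomyConfig(contraction_fraction=0.0)
    ph = fc.DynamicPhantom(anatomy=anatomy, grid_shape=(24,) * 3)
    n_il = fc.interleaves_for_duration(30.0)
    traj = fc.phyllotaxis_trajectory(n_il, n_samples=24)
    physio = fc.generate_physio(
        fc.PhysioConfig(resp_rate=14.0, resp_amplitude=12.0, seed=4),
        traj.duration() + 1, traj.tr,
    )
    kdata = fc.simulate_kspace(ph, traj, physio, noise_sd=0.02, seed=4)
    return kdata, physio


class TestBuildSGSeries:
    def test_row_count_equals_interleaves(self, breathing_kdata):
        kdata, _ = breathing_kdata
        series = fc.build_sg_series(kdata)
        assert series.matrix.shape[0] == kdata.trajectory.n_interleaves
        assert series.sg_interval == pytest.approx(77.66)

    def test_static_phantom_rows_vanish_after_detrend(self):
        anatomy = AnatomyConfig(contraction_fraction=0.0)
        ph = fc.DynamicPhantom(anatomy=anatomy, grid_shape=(24,) * 3)
        traj = fc.phyllotaxis_trajectory(20, n_samples=24)
        physio = fc.generate_physio(fc.PhysioConfig(resp_amplitude=0.0, seed=0),
                                    traj.duration() + 1, traj.tr)
        kdata = fc.simulate_kspace(ph, traj, physio, noise_sd=0.0)
        series = fc.build_sg_series(kdata)
        assert np.abs(series.matrix).max() < 1e-4

    def test_first_principal_component_tracks_breathing(self, breathing_kdata):
        kdata, physio = breathing_kdata
        series = fc.build_sg_series(kdata)
        u, s, _ = np.linalg.svd(series.matrix, full_matrices=False)
        pc1 = u[:, 0]
        truth = physio.displacement_at(series.timestamps)
        r = np.corrcoef(pc1, truth)[0, 1]
        assert abs(r) >= 0.95

    def test_too_few_sg_readouts_rejected(self, breathing_kdata):
        kdata, _ = breathing_kdata
        import dataclasses

        small = dataclasses.replace(
            kdata,
            samples=kdata.samples[:44],
            trajectory=fc.phyllotaxis_trajectory(2, n_samples=24),
        )
        with pytest.raises(ValueError):
            fc.build_sg_series(small)


class TestSobi:
    def _mixed_series(self, rng, f1=1.2, f2=0.25, n=1000, noise=0.1, n_chan=6):
        t = np.arange(n) * SG_DT
        s1 = np.sin(2 * np.pi * f1 * t)
        s2 = np.sin(2 * np.pi * f2 * t + 0.4)
        mixing = rng.standard_normal((2, n_chan))
        x = np.stack([s1, s2]).T @ mixing + noise * rng.standard_normal((n, n_chan))
        return SGSeries(matrix=x, sg_interval=SG_DT * 1000.0, timestamps=t), (s1, s2)

    def test_recovers_known_two_source_mixing(self, rng):
        series, (s1, s2) = self._mixed_series(rng)
        res = sobi_unmix(series, n_components=4)
        corr = np.abs(np.corrcoef(res.sources.T, np.stack([s1, s2]))[:4, 4:])
        assert corr.max(axis=0)[0] >= 0.99
        assert corr.max(axis=0)[1] >= 0.99

    def test_orthogonal_sources_pass_through(self, rng):
        t = np.arange(800) * SG_DT
        s = np.stack([np.sin(2 * np.pi * 1.0 * t), np.sin(2 * np.pi * 0.2 * t)]).T
        series = SGSeries(matrix=s, sg_interval=SG_DT * 1000.0, timestamps=t)
        res = sobi_unmix(series, n_components=2)
        corr = np.abs(np.corrcoef(res.sources.T, s.T)[:2, 2:])
        # identity up to sign/permutation
        assert np.allclose(np.sort(corr.max(axis=0)), [1.0, 1.0], atol=1e-3)

    def test_white_noise_has_no_diagonalizable_structure(self, rng):
        x = rng.standard_normal((2000, 8))
        z = (x - x.mean(0)) / x.std(0)
        covs = []
        for lag in range(1, 26):
            c = z[:-lag].T @ z[lag:] / (2000 - lag)
            covs.append(0.5 * (c + c.T))
        covs = np.array(covs)
        _, rotated = _joint_diagonalize(covs)

        def offdiag_mass(mats):
            off = mats - np.eye(8)[None] * np.diagonal(mats, axis1=1, axis2=2)[:, :, None]
            ident = np.eye(8, dtype=bool)
            return sum(np.linalg.norm(m[~ident]) ** 2 for m in mats)

        before = sum(np.linalg.norm(c[~np.eye(8, dtype=bool)]) ** 2 for c in covs)
        after = sum(np.linalg.norm(c[~np.eye(8, dtype=bool)]) ** 2 for c in rotated)
        assert after > 0.5 * before

    def test_invariant_to_feature_scaling(self, rng):
        """Rescaling SG feature columns must not change the recovered sources.

        Exact invariance holds at full PCA rank; a truncated whitening keeps a
        (slightly) scaling-dependent subspace, so the physiological sources
        are then only required to survive at very high correlation.
        """
        series, _ = self._mixed_series(rng)
        n_chan = series.matrix.shape[1]
        scales = rng.uniform(0.2, 5.0, n_chan)
        scaled = SGSeries(matrix=series.matrix * scales,
                          sg_interval=series.sg_interval, timestamps=series.timestamps)
        a = sobi_unmix(series, n_components=n_chan).sources
        b = sobi_unmix(scaled, n_components=n_chan).sources
        corr = np.abs(np.corrcoef(a.T, b.T)[:n_chan, n_chan:])
        assert np.all(corr.max(axis=0) > 1.0 - 1e-6)

        a2 = sobi_unmix(series, n_components=2).sources
        b2 = sobi_unmix(scaled, n_components=2).sources
        corr2 = np.abs(np.corrcoef(a2.T, b2.T)[:2, 2:])
        assert np.all(corr2.max(axis=0) > 0.99)

    def test_rank_deficient_input_reduces_components(self, rng, caplog):
        t = np.arange(400) * SG_DT
        s = np.sin(2 * np.pi * 0.8 * t)
        x = np.outer(s, rng.standard_normal(6))  # rank 1
        series = SGSeries(matrix=x, sg_interval=SG_DT * 1000.0, timestamps=t)
        res = sobi_unmix(series, n_components=4)
        assert res.sources.shape[1] < 4


class TestSelectPhysioSources:
    def _sobi_like(self, sources):
        from freecine.selfgating import SobiResult

        return SobiResult(sources=sources, rotation=np.eye(sources.shape[1]),
                          whitener=None, explained_variance=None)

    def test_synthetic_frequencies_recovered(self):
        t = np.arange(800) * SG_DT
        s = np.stack([np.sin(2 * np.pi * 1.0 * t), np.sin(2 * np.pi * 0.2 * t)]).T
        motion = select_physio_sources(self._sobi_like(s), SG_DT * 1000.0, t)
        assert motion.f_cardiac == pytest.approx(1.0, abs=0.05)
        assert motion.f_respiratory == pytest.approx(0.2, abs=0.02)

    def test_cardiac_band_fits_under_sg_nyquist(self):
        # 77.66 ms cadence -> 6.44 Hz Nyquist, comfortably above the 3 Hz band edge
        assert 1000.0 / (2 * 77.66) > 3.0

    def test_white_noise_sources_rejected(self, rng):
        s = rng.standard_normal((800, 3))
        t = np.arange(800) * SG_DT
        with pytest.raises(ValueError, match="band"):
            select_physio_sources(self._sobi_like(s), SG_DT * 1000.0, t)

    def test_short_record_rejected(self):
        t = np.arange(50) * SG_DT
        s = np.stack([np.sin(2 * np.pi * t), np.sin(0.4 * np.pi * t)]).T
        with pytest.raises(ValueError, match="short"):
            select_physio_sources(self._sobi_like(s), SG_DT * 1000.0, t)


class TestDetectTriggers:
    def test_no_jitter_trigger_count_and_timing(self):
        physio = fc.generate_physio(
            fc.PhysioConfig(heart_rate_mean=60.0, rr_jitter_sd=0.0, seed=0), 60.0, 3.53
        )
        t = np.arange(0.0, 59.9, SG_DT)
        cardiac = np.cos(2 * np.pi * physio.phase_at(t))
        motion = make_motion(cardiac, np.zeros_like(t), t, 1.0, 0.2)
        triggers = detect_triggers(motion)
        assert abs(triggers.times.size - 60) <= 1
        # RMSE over matched triggers, after removing the constant fiducial offset
        det, true = triggers.times, physio.true_trigger_times
        d = det[:, None] - true[None, :]
        shift = np.median(d[np.arange(det.size), np.abs(d).argmin(axis=1)])
        err = np.abs((det - shift)[:, None] - true[None, :]).min(axis=0)
        matched = err <= 0.5  # within half a beat
        assert matched.mean() >= 0.95
        assert np.sqrt(np.mean(err[matched] ** 2)) <= SG_DT

    def test_jittered_rr_mean_within_3_percent(self):
        physio = fc.generate_physio(
            fc.PhysioConfig(heart_rate_mean=90.0, rr_jitter_sd=30.0, seed=1), 120.0, 3.53
        )
        t = np.arange(0.0, 119.9, SG_DT)
        cardiac = np.cos(2 * np.pi * physio.phase_at(t))
        motion = make_motion(cardiac, np.zeros_like(t), t, 1.5, 0.2)
        triggers = detect_triggers(motion)
        det_rr = np.diff(triggers.times).mean() * 1000.0
        true_rr = physio.rr_intervals.mean()
        assert abs(det_rr - true_rr) / true_rr < 0.03

    def test_constant_source_rejected(self):
        t = np.arange(0.0, 30.0, SG_DT)
        motion = make_motion(np.ones_like(t), np.zeros_like(t), t, 1.0, 0.2)
        with pytest.raises(ValueError):
            detect_triggers(motion)


class TestRespiratoryStates:
    def test_exact_equal_populations(self, rng):
        t = np.arange(1000) * SG_DT
        resp = np.sin(2 * np.pi * 0.23 * t) + 0.01 * rng.standard_normal(t.size)
        motion = make_motion(np.zeros_like(t), resp, t, 1.0, 0.23)
        states = respiratory_states(motion, t)
        assert sorted(np.bincount(states)) == [250, 250, 250, 250]

    def test_monotone_signal_gives_contiguous_blocks(self):
        t = np.arange(400) * SG_DT
        resp = np.linspace(-1, 1, t.size)
        motion = make_motion(np.zeros_like(t), resp, t, 1.0, 0.2)
        states = respiratory_states(motion, t)
        # four contiguous time blocks of 100 readouts each
        assert sorted(np.bincount(states)) == [100, 100, 100, 100]
        assert np.count_nonzero(np.diff(states)) == 3

    @pytest.mark.parametrize("polarity", [1.0, -1.0])
    def test_end_expiratory_state_has_smallest_displacement(self, polarity):
        """State 0 must track end-expiration for either blind-source polarity."""
        t = np.arange(0.0, 60.0, SG_DT)
        disp = np.sin(np.pi * t / 4.3) ** 4  # breathing with expiratory plateau
        motion = make_motion(np.zeros_like(t), polarity * disp, t, 1.0, 0.23)
        states = respiratory_states(motion, t)
        means = [disp[states == s].mean() for s in range(4)]
        assert np.argmin(means) == 0
        assert np.all(np.diff(means) > 0)
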