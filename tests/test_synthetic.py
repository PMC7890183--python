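"""Ground-truth recovery tests for the synthetic-data generators."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from balancenet.core import DataError, ParameterError
from balancenet.connectivity import wpli
from balancenet.posturography import (
    SampEnConfig,
    confidence_ellipse_area,
    mean_frequency,
    rms_sway,
    sample_entropy,
)
from balancenet.synthetic import (
    CopSpec,
    CouplingSpec,
    MixingModel,
    gen_cop,
    gen_coupled_eeg,
    gen_eog_artifacts,
    gen_null_pvalues,
)

CHI2_2_95 = 5.991464547107979


class TestCoupledEeg:
    def test_seed_determinism(self):
        spec = CouplingSpec(coupling_strength=0.7, snr_db=10.0)
        a = gen_coupled_eeg(spec, None, 4, 250.0, 8.0, seed=9)
        b = gen_coupled_eeg(spec, None, 4, 250.0, 8.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_perfect_lock_reaches_wpli_one(self):
        spec = CouplingSpec(node_pairs=((0, 1),), phase_lag=np.pi / 2,
                            coupling_strength=1.0, snr_db=np.inf)
        rec = gen_coupled_eeg(spec, None, 2, 250.0, 10.0, seed=0)
        assert wpli(rec.data[0], rec.data[1]) > 0.999

    def test_uncoupled_pair_wpli_vanishes_with_duration(self):
        vals = [
            wpli(*gen_coupled_eeg(
                CouplingSpec(coupling_strength=0.0, snr_db=20.0),
                None, 2, 250.0, 40.0, seed=s,
            ).data[:2])
            for s in range(50)
        ]
        assert np.mean(vals) < 0.1

    def test_zero_lag_common_source_suppressed_but_correlated(self):
        wv, cc = [], []
        for s in range(50):
            mm = MixingModel(mixing_matrix=np.array([[3.0], [3.0]]))
            rec = gen_coupled_eeg(
                CouplingSpec(node_pairs=(), snr_db=10.0),
                mm, 2, 250.0, 40.0, seed=s,
            )
            wv.append(wpli(rec.data[0], rec.data[1]))
            cc.append(np.corrcoef(rec.data[0], rec.data[1])[0, 1])
        assert abs(np.mean(wv)) < 0.1       # no spurious lagged coupling
        assert np.mean(cc) > 0.8            # but amplitudes strongly shared

    def test_wpli_monotone_in_coupling_strength(self):
        grid = np.linspace(0.0, 1.0, 6)
        means = []
        for c in grid:
            v = [
                wpli(*gen_coupled_eeg(
                    CouplingSpec(coupling_strength=float(c), snr_db=10.0),
                    None, 2, 250.0, 10.0, seed=s,
                ).data[:2])
                for s in range(10)
            ]
            means.append(np.mean(v))
        assert spearmanr(grid, means).statistic > 0.9

    def test_mismatched_mixing_matrix_rejected(self):
        mm = MixingModel(mixing_matrix=np.ones((5, 2)))
        with pytest.raises(DataError, match="mixing"):
            gen_coupled_eeg(CouplingSpec(), mm, 3, 250.0, 5.0, seed=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(node_pairs=((0, 0),)),
            dict(node_pairs=((0, 9),)),
            dict(coupling_strength=1.5),
            dict(band=(8.0, 200.0)),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            gen_coupled_eeg(CouplingSpec(**kwargs), None, 3, 250.0, 5.0)


class TestEogArtifacts:
    def _rec(self, seed=0):
        return gen_coupled_eeg(
            CouplingSpec(node_pairs=(), snr_db=10.0), None, 3, 250.0, 20.0,
            seed=seed,
        )

    def test_zero_propagation_leaves_scalp_untouched(self):
        rec = self._rec()
        art = gen_eog_artifacts(rec, propagation=np.zeros(3), seed=1)
        assert np.array_equal(art.contaminated.data, rec.data)

    def test_zero_amplitude_is_noop(self):
        rec = self._rec()
        art = gen_eog_artifacts(
            rec, blink_rate_hz=0.5, amplitude_uv=0.0,
            propagation=np.array([0.8, 0.4, 0.1]), seed=1,
            saccade_amplitude_uv=0.0,
        )
        assert np.allclose(art.contaminated.data, rec.data, atol=1e-12)

    def test_channels_receive_propagated_template(self):
        rec = self._rec()
        gains = np.array([0.8, 0.4, 0.1])
        art = gen_eog_artifacts(
            rec, blink_rate_hz=0.3, amplitude_uv=200.0,
            propagation=gains, seed=2, saccade_rate_hz=0.0,
        )
        added = art.contaminated.data - art.clean.data
        assert np.allclose(added, gains[:, None] * art.veog_true, atol=1e-12)

    def test_bipolar_derivations_recover_true_traces(self):
        from balancenet.preprocessing import derive_eog

        art = gen_eog_artifacts(
            self._rec(), blink_rate_hz=0.4, amplitude_uv=150.0,
            propagation=np.zeros(3), seed=3,
        )
        veog, heog = derive_eog(art.contaminated)
        assert np.allclose(veog, art.veog_true, atol=1e-12)
        assert np.allclose(heog, art.heog_true, atol=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            gen_eog_artifacts(self._rec(), blink_rate_hz=-1.0)

    def test_wrong_propagation_length_rejected(self):
        with pytest.raises(DataError):
            gen_eog_artifacts(self._rec(), propagation=np.ones(7))


class TestCopGenerator:
    def test_seed_determinism(self):
        spec = CopSpec(duration_s=10.0, fs=100.0)
        a, b = gen_cop(spec, seed=4), gen_cop(spec, seed=4)
        assert np.array_equal(a.ap, b.ap) and np.array_equal(a.ml, b.ml)

    def test_sample_covariance_matches_spec(self):
        target = np.array([[0.5, 0.12], [0.12, 0.3]])
        spec = CopSpec(duration_s=600.0, fs=100.0,
                       covariance=tuple(map(tuple, target)))
        cop = gen_cop(spec, seed=5)
        s = np.cov(np.vstack([cop.ap, cop.ml]))
        assert np.all(np.abs(s - target) <= 0.05 * np.abs(target).max())

    def test_unit_isotropic_recovers_analytic_ellipse(self):
        spec = CopSpec(duration_s=600.0, fs=100.0,
                       covariance=((1.0, 0.0), (0.0, 1.0)))
        cop = gen_cop(spec, seed=6)
        cea = confidence_ellipse_area(cop.ap, cop.ml)
        assert cea == pytest.approx(np.pi * CHI2_2_95, rel=0.05)

    def test_zero_covariance_gives_flat_trace(self):
        spec = CopSpec(duration_s=5.0, fs=100.0,
                       covariance=((0.0, 0.0), (0.0, 0.0)))
        cop = gen_cop(spec, seed=0)
        assert rms_sway(cop.ap) == 0.0 and rms_sway(cop.ml) == 0.0

    def test_spectral_centroid_recovered(self):
        vals = [
            mean_frequency(
                gen_cop(CopSpec(duration_s=60.0, fs=100.0,
                                covariance=((1, 0), (0, 1)),
                                spectral_centroid_hz=0.3), seed=s).ap,
                100.0,
            )
            for s in range(20)
        ]
        assert np.mean(vals) == pytest.approx(0.3, abs=0.05)

    def test_sampen_decreases_with_regularity(self):
        cfg = SampEnConfig(target_fs=100.0)
        means = []
        for reg in (0.0, 0.3, 0.6, 0.9):
            vals = [
                sample_entropy(
                    gen_cop(CopSpec(duration_s=60.0, fs=100.0,
                                    covariance=((1, 0), (0, 1)),
                                    regularity=reg), seed=s).ap,
                    cfg, fs=100.0,
                )
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ParameterError):
            CopSpec(covariance=((1.0, 2.0), (2.0, 1.0))).validate()

    def test_centroid_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            CopSpec(fs=0.5, spectral_centroid_hz=0.3).validate()


class TestNullPvalues:
    def test_seed_determinism_and_shape(self):
        a = gen_null_pvalues(3, 100, seed=7)
        b = gen_null_pvalues(3, 100, seed=7)
        assert a.shape == (100, 3)
        assert np.array_equal(a, b)

    def test_entries_uniform_on_unit_interval(self):
        p = gen_null_pvalues(4, 50000, seed=8)
        assert p.min() >= 0.0 and p.max() <= 1.0
        assert p.mean() == pytest.approx(0.5, abs=0.01)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ParameterError):
            gen_null_pvalues(0, 10)
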