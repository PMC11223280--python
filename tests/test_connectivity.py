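import numpy as np
import pytest

from eegfc.connectivity import (
    ConnectivityMatrix,
    aec,
    aec_c,
    aecc_matrix,
    group_average,
    mean_connectivity,
    orthogonalize,
    pli,
    pli_matrix,
)
from eegfc.errors import DataError, DegenerateInputError
from eegfc.signal_prep import BANDS, EpochedRecording, analytic, bandpass, Recording, epoch
from eegfc.synth import CouplingSpec, gen_coupled_pair

from oracles import pli_loop


def _epoched(data, band, fs=250.0, subject="s"):
    """Wrap a channels x samples array as a single-epoch recording."""
    labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EpochedRecording(
        epochs=data[None],
        fs=fs,
        epoch_length_s=data.shape[1] / fs,
        overlap_fraction=0.0,
        band=band,
        channel_labels=labels,
        subject_id=subject,
    )


class TestPli:
    def test_constant_half_pi_lag_is_one(self):
        phi = np.linspace(0, 40 * np.pi, 1000)
        assert pli(phi + np.pi / 2, phi) == 1.0

    def test_identical_signals_zero(self):
        phi = np.linspace(0, 40 * np.pi, 1000)
        assert pli(phi, phi) == 0.0

    def test_alternating_lags_cancel(self):
        phi = np.zeros(1000)
        delta = np.tile([np.pi / 2, -np.pi / 2], 500)
        assert pli(phi + delta, phi) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            pli(np.zeros(10), np.zeros(11))

    def test_matches_brute_force_loop(self, rng):
        """Short-series agreement with a direct loop over sign(sin dphi)."""
        for _ in range(25):
            n = int(rng.integers(2, 65))
            px = rng.uniform(-np.pi, np.pi, n)
            py = rng.uniform(-np.pi, np.pi, n)
            assert pli(px, py) == pytest.approx(pli_loop(px, py), abs=1e-12)

    def test_amplitude_rescaling_invariance(self, rng, theta):
        """PLI depends only on phases: rescaling either signal changes nothing."""
        cs = CouplingSpec((0, 1), "phase_lag", lag_radians=1.0)
        x, y = gen_coupled_pair(250, 8, cs, noise_sd=0.3, seed=5, band=theta)
        base = pli(analytic(x).phase, analytic(y).phase)
        scaled = pli(analytic(7.3 * x).phase, analytic(0.01 * y).phase)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_symmetry(self, rng):
        px, py = rng.uniform(-np.pi, np.pi, (2, 500))
        assert pli(px, py) == pli(py, px)


class TestPliMatrix:
    def test_planted_lag_entry_is_one(self, theta):
        cs = CouplingSpec((0, 1), "phase_lag", lag_radians=np.pi / 2)
        x, y = gen_coupled_pair(250, 13, cs, noise_sd=0.0, seed=0, band=theta)
        m = pli_matrix(_epoched(np.vstack([x, y]), theta))
        assert m.values[0, 1] == 1.0

    def test_single_epoch_equals_direct_pli(self, rng, theta):
        data = rng.standard_normal((3, 2000))
        m = pli_matrix(_epoched(data, theta), edge_trim=0.0)
        phases = [analytic(ch).phase for ch in data]
        for i in range(3):
            for j in range(i + 1, 3):
                assert m.values[i, j] == pytest.approx(pli(phases[i], phases[j]), abs=1e-12)

    def test_symmetric_zero_diagonal(self, rng, theta):
        m = pli_matrix(_epoched(rng.standard_normal((4, 1500)), theta))
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert np.all((m.values >= 0) & (m.values <= 1))


class TestOrthogonalize:
    def test_self_projection_gives_zero(self, rng):
        x = rng.standard_normal(500)
        assert np.allclose(orthogonalize(x, x), 0.0, atol=1e-10)

    def test_already_orthogonal_unchanged(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * t / 100)
        y = np.cos(2 * np.pi * t / 100)  # quadrature: zero correlation
        assert np.allclose(orthogonalize(x, y), x, atol=1e-10)

    def test_residual_uncorrelated_over_random_draws(self, rng):
        for _ in range(100):
            x, y = rng.standard_normal((2, 200))
            r = orthogonalize(x, y)
            assert abs(np.corrcoef(r, y)[0, 1]) < 1e-10

    def test_constant_regressor_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            orthogonalize(rng.standard_normal(100), np.full(100, 3.0))


class TestAec:
    def test_self_correlation_one(self, rng):
        env = np.abs(rng.standard_normal(500)) + 0.1
        assert aec(env, env) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        env = np.abs(rng.standard_normal(500)) + 0.1
        assert aec(env, 2.5 * env + 1.0) == pytest.approx(1.0)

    def test_constant_envelope_rejected(self):
        with pytest.raises(DegenerateInputError):
            aec(np.ones(100), np.linspace(0, 1, 100))

    def test_independent_envelopes_near_zero(self, rng):
        a, b = np.abs(rng.standard_normal((2, 50_000))) + 0.1
        assert abs(aec(a, b)) < 0.03


class TestAecC:
    def test_symmetric_exactly(self, rng, alpha):
        cs = CouplingSpec((0, 1), "envelope_share", envelope_corr=0.5)
        x, y = gen_coupled_pair(250, 20, cs, seed=3, band=alpha)
        assert aec_c(x, y) == aec_c(y, x)

    def test_zero_lag_mixing_suppressed(self, rng, alpha):
        """Leakage property: y = a*x + small noise fools AEC but not AEC-c."""
        cs = CouplingSpec((0, 1), "none")
        x, _ = gen_coupled_pair(250, 60, cs, seed=9, band=alpha)
        rng2 = np.random.default_rng(10)
        noise = bandpass(
            Recording(rng2.standard_normal((1, x.size)), 250.0, ("n",)), alpha
        ).data[0]
        y = 0.8 * x + 0.05 * noise
        raw = aec(analytic(x).envelope, analytic(y).envelope)
        corrected = aec_c(x, y)
        assert raw > 0.9
        assert corrected < 0.2

    def test_colinear_inputs_degenerate(self, rng, alpha):
        cs = CouplingSpec((0, 1), "none")
        x, _ = gen_coupled_pair(250, 10, cs, seed=4, band=alpha)
        with pytest.raises(DegenerateInputError):
            aec_c(x, 2.0 * x)

    def test_planted_share_detected(self, alpha):
        cs = CouplingSpec((0, 1), "envelope_share", envelope_corr=0.9)
        x, y = gen_coupled_pair(250, 60, cs, seed=6, band=alpha)
        assert aec_c(x, y) > 0.5


class TestAeccMatrix:
    def test_matches_pairwise_aec_c(self, rng, alpha):
        data = np.stack([
            gen_coupled_pair(250, 13, CouplingSpec((0, 1), "none"), seed=s, band=alpha)[0]
            for s in range(3)
        ])
        m = aecc_matrix(_epoched(data, alpha))
        for i in range(3):
            for j in range(i + 1, 3):
                assert m.values[i, j] == pytest.approx(aec_c(data[i], data[j]), abs=1e-10)

    def test_symmetric_zero_diagonal(self, rng, alpha):
        data = np.stack([
            gen_coupled_pair(250, 13, CouplingSpec((0, 1), "none"), seed=10 + s, band=alpha)[0]
            for s in range(4)
        ])
        m = aecc_matrix(_epoched(data, alpha))
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert np.all((m.values >= 0) & (m.values <= 1))


class TestMatrixHelpers:
    def _const_matrix(self, c, n=19, metric="PLI"):
        v = np.full((n, n), float(c))
        np.fill_diagonal(v, 0.0)
        labels = tuple(f"ch{i}" for i in range(n))
        return ConnectivityMatrix(v, metric, BANDS["theta"], labels, subject_id="s")

    def test_mean_connectivity_constant(self):
        assert mean_connectivity(self._const_matrix(0.42)) == pytest.approx(0.42)

    def test_mean_connectivity_single_pair(self):
        m = self._const_matrix(0.0)
        m.values[0, 1] = m.values[1, 0] = 1.0
        assert mean_connectivity(m) == pytest.approx(1 / 171)

    def test_mean_connectivity_reorder_invariant(self, rng):
        m = self._const_matrix(0.0, n=6)
        v = rng.random((6, 6))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        m.values = v
        perm = rng.permutation(6)
        m2 = self._const_matrix(0.0, n=6)
        m2.values = v[np.ix_(perm, perm)]
        assert mean_connectivity(m) == pytest.approx(mean_connectivity(m2))

    def test_group_average_identity_and_mean(self):
        a, b = self._const_matrix(0.2), self._const_matrix(0.4)
        assert np.allclose(group_average([a]).values, a.values)
        assert np.allclose(group_average([a, a]).values, a.values)
        avg = group_average([a, b])
        assert mean_connectivity(avg) == pytest.approx(0.3)
        assert avg.n_epochs_averaged == 2

    def test_group_average_mixed_inputs_rejected(self):
        a = self._const_matrix(0.2, metric="PLI")
        b = self._const_matrix(0.2, metric="AEC_c")
        with pytest.raises(DataError):
            group_average([a, b])
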