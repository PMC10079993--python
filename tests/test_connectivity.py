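"""PLI estimation against the brute-force sign-count oracle, plus
thresholding and difference matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plinet.connectivity import (ConnectivityMatrix, PhaseSeries,
                                 difference_matrix, group_mean_matrix,
                                 instantaneous_phase, pli_matrix, pli_pair,
                                 proportional_threshold, trial_pli_matrices)
from plinet.containers import EpochSet, ValidationError


def brute_force_pli(phi_x, phi_y):
    """Count positive/negative/zero wrapped phase differences explicitly."""
    pos = neg = 0
    for a, b in zip(phi_x, phi_y):
        d = a - b
        while d <= -np.pi:
            d += 2 * np.pi
        while d > np.pi:
            d -= 2 * np.pi
        if d > 0:
            pos += 1
        elif d < 0:
            neg += 1
    return abs(pos - neg) / len(phi_x)


def tone_epochs(freq=6.0, fs=250.0, n_trials=3, n_ch=3, phases=None):
    t = np.arange(250) / fs
    phases = phases if phases is not None else np.zeros(n_ch)
    data = np.stack([[np.cos(2 * np.pi * freq * t + p) for p in phases]
                     for _ in range(n_trials)])
    return EpochSet(data=data, channel_names=tuple(f"c{i}" for i in range(n_ch)),
                    sampling_rate=fs, band="theta")


class TestInstantaneousPhase:
    def test_tone_phase_slope(self):
        ph = instantaneous_phase(tone_epochs(freq=6.0))
        unwrapped = np.unwrap(ph.phase[0, 0])
        interior = slice(25, 225)  # Hilbert edge effects excluded
        slope = np.polyfit(np.arange(250)[interior] / 250.0,
                           unwrapped[interior], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 6, rel=0.01)

    def test_phase_range(self):
        ph = instantaneous_phase(tone_epochs())
        assert np.all(ph.phase > -np.pi - 1e-12)
        assert np.all(ph.phase <= np.pi + 1e-12)

    def test_quadrature_offset(self):
        fs, f = 250.0, 6.0
        t = np.arange(250) / fs
        data = np.stack([np.cos(2 * np.pi * f * t),
                         np.sin(2 * np.pi * f * t)])[None]
        ep = EpochSet(data=data, channel_names=("a", "b"), sampling_rate=fs)
        ph = instantaneous_phase(ep).phase[0]
        d = np.angle(np.exp(1j * (ph[0] - ph[1])))
        assert np.allclose(d[25:225], np.pi / 2, atol=0.02)

    def test_zero_channel_rejected(self):
        ep = tone_epochs()
        ep.data[:, 1, :] = 0.0
        with pytest.raises(ValidationError, match="c1"):
            instantaneous_phase(ep)


class TestPliPair:
    def test_identical_phases_give_zero(self):
        phi = np.random.default_rng(0).uniform(-np.pi, np.pi, 100)
        assert pli_pair(phi, phi) == 0.0

    def test_constant_lag_gives_one(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(-np.pi, np.pi, 300)  # includes branch-cut region
        lagged = np.angle(np.exp(1j * (phi - np.pi / 2)))
        assert pli_pair(phi, lagged) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_phases(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.uniform(-np.pi, np.pi, 250)
            b = rng.uniform(-np.pi, np.pi, 250)
            assert pli_pair(a, b) == pytest.approx(brute_force_pli(a, b),
                                                   abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pli_pair(np.zeros(10), np.zeros(11))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.floats(-3.0, 3.0))
    def test_invariant_to_common_offset(self, seed, offset):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-np.pi, np.pi, 64)
        b = rng.uniform(-np.pi, np.pi, 64)
        assert pli_pair(a + offset, b + offset) == pytest.approx(
            pli_pair(a, b), abs=1e-9)


class TestPliMatrix:
    def test_identical_channels_zero_offdiagonal(self):
        rng = np.random.default_rng(0)
        one = rng.uniform(-np.pi, np.pi, (4, 1, 50))
        phases = PhaseSeries(phase=np.repeat(one, 3, axis=1),
                             channel_names=("a", "b", "c"))
        m = pli_matrix(phases)
        assert np.allclose(m.values, 0.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        phases = PhaseSeries(phase=rng.uniform(-np.pi, np.pi, (5, 6, 80)),
                             channel_names=tuple("abcdef"))
        m = pli_matrix(phases)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert np.all((m.values >= 0) & (m.values <= 1))

    def test_subject_mean_equals_explicit_trial_loop(self):
        rng = np.random.default_rng(9)
        phase = rng.uniform(-np.pi, np.pi, (6, 4, 50))
        phases = PhaseSeries(phase=phase, channel_names=tuple("abcd"))
        m = pli_matrix(phases)
        expected = np.zeros((4, 4))
        for t in range(6):
            for i in range(4):
                for j in range(4):
                    if i != j:
                        expected[i, j] += brute_force_pli(phase[t, i],
                                                          phase[t, j])
        expected /= 6
        assert np.allclose(m.values, expected, atol=1e-12)

    def test_four_channel_fixture_matches_oracle_exactly(self):
        """The documented correctness fixture: 4 channels x 50 samples."""
        rng = np.random.default_rng(2024)
        phase = rng.uniform(-np.pi, np.pi, (1, 4, 50))
        trials = trial_pli_matrices(
            PhaseSeries(phase=phase, channel_names=tuple("wxyz")))
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert trials[0, i, j] == pytest.approx(
                        brute_force_pli(phase[0, i], phase[0, j]), abs=1e-13)

    def test_single_sample_trials_rejected(self):
        phases = PhaseSeries(phase=np.zeros((2, 3, 1)),
                             channel_names=("a", "b", "c"))
        with pytest.raises(ValidationError):
            pli_matrix(phases)

    def test_shuffled_surrogates_fall_below_coupled_value(self):
        """Phase-shuffling destroys lag consistency (permutation check)."""
        rng = np.random.default_rng(5)
        n = 250
        base = (2 * np.pi * 6 * np.arange(n) / 250.0
                + rng.normal(0, 0.1, n).cumsum())
        phi_x = np.angle(np.exp(1j * base))
        phi_y = np.angle(np.exp(1j * (base - 1.0)))
        coupled = pli_pair(phi_x, phi_y)
        surrogate = np.empty(100)
        for s in range(100):
            surrogate[s] = pli_pair(phi_x, rng.permutation(phi_y))
        assert np.quantile(surrogate, 0.95) < coupled


class TestThresholding:
    def make(self, seed=0, n=22):
        rng = np.random.default_rng(seed)
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        return ConnectivityMatrix(values=w,
                                  channel_names=tuple(f"c{i}" for i in range(n)))

    def test_density_030_keeps_69_edges(self):
        thr = proportional_threshold(self.make(), 0.30)
        assert np.count_nonzero(np.triu(thr.values, 1)) == 69

    def test_density_one_is_identity(self):
        C = self.make(3)
        thr = proportional_threshold(C, 1.0)
        assert np.allclose(thr.values, C.values)

    def test_all_equal_weights_tiebreak_deterministic(self):
        n = 22
        w = np.ones((n, n)) - np.eye(n)
        C = ConnectivityMatrix(values=w,
                               channel_names=tuple(f"c{i}" for i in range(n)))
        thr1 = proportional_threshold(C, 0.30)
        thr2 = proportional_threshold(C, 0.30)
        assert np.array_equal(thr1.values, thr2.values)
        # ties resolved by ascending (row, col): first 69 upper-tri slots
        iu, ju = np.triu_indices(n, k=1)
        expect = np.zeros((n, n))
        expect[iu[:69], ju[:69]] = 1.0
        expect = expect + expect.T
        assert np.array_equal(thr1.values, expect)

    def test_invalid_density(self):
        with pytest.raises(ValidationError):
            proportional_threshold(self.make(), 0.0)
        with pytest.raises(ValidationError):
            proportional_threshold(self.make(), 1.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6),
           st.floats(0.05, 1.0, exclude_min=False))
    def test_retained_count_formula(self, seed, density):
        thr = proportional_threshold(self.make(seed, n=12), density)
        kept = np.count_nonzero(np.triu(thr.values, 1))
        assert kept == int(np.floor(density * 66))


class TestDifferenceMatrix:
    def pair(self, seed=0):
        rng = np.random.default_rng(seed)
        names = tuple(f"c{i}" for i in range(22))
        mats = []
        for _ in range(2):
            w = rng.random((22, 22))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            mats.append(ConnectivityMatrix(values=w, channel_names=names))
        return mats

    def test_equal_groups_give_zero(self):
        Ca, _ = self.pair()
        assert np.allclose(difference_matrix(Ca, Ca), 0.0)

    def test_retained_count(self):
        Ca, Cb = self.pair(1)
        D = difference_matrix(Ca, Cb, 0.30)
        assert np.count_nonzero(np.triu(D, 1)) == 69

    def test_antisymmetry(self):
        Ca, Cb = self.pair(2)
        assert np.allclose(difference_matrix(Ca, Cb),
                           -difference_matrix(Cb, Ca))

    def test_montage_mismatch(self):
        Ca, Cb = self.pair(3)
        Cb.channel_names = tuple(reversed(Cb.channel_names))
        with pytest.raises(ValidationError):
            difference_matrix(Ca, Cb)


def test_group_mean_is_elementwise_mean():
    rng = np.random.default_rng(4)
    names = ("a", "b", "c")
    mats = []
    for k in range(5):
        w = rng.random((3, 3))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        mats.append(ConnectivityMatrix(values=w, channel_names=names,
                                       group_label="g"))
    gm = group_mean_matrix(mats, group_label="g")
    assert np.allclose(gm.values, np.mean([m.values for m in mats], axis=0))
    assert gm.level == "group"
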