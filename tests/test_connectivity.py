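"""Coherence estimator contracts, the FC state comparison, and dynamic features."""

from __future__ import annotations

import cmath
import math

import numpy as np
import pytest

from emofc.connectivity import (
    SpectralParams,
    coherence_matrix_from_array,
    coherence_pair,
    compare_states,
    dynamic_classification_curve,
    dynamic_fc_features,
    trial_fc_matrix,
)
from emofc.containers import HVA, LVA, CoherenceMatrix, TrialSegment


def brute_force_band_coherence(x, y, fs, seg_len_s=1.0, overlap=0.5, band=(1.0, 40.0)):
    """Independent oracle: per-segment DFTs via explicit complex arithmetic.

    Mirrors the estimator's definition — Hann-tapered demeaned segments,
    averaged cross-spectrum magnitude over root power product — but computes
    every DFT coefficient with explicit scalar sums.
    """
    nper = int(round(seg_len_s * fs))
    step = max(int(round(nper * (1.0 - overlap))), 1)
    n_segs = 1 + (len(x) - nper) // step
    window = [0.5 - 0.5 * math.cos(2 * math.pi * t / (nper - 1)) for t in range(nper)]
    n_freqs = nper // 2 + 1

    def seg_dft(sig, k):
        seg = sig[k * step : k * step + nper]
        mean = sum(seg) / nper
        tapered = [(v - mean) * w for v, w in zip(seg, window)]
        return [
            sum(tapered[t] * cmath.exp(-2j * math.pi * f * t / nper) for t in range(nper))
            for f in range(n_freqs)
        ]

    cross = [0j] * n_freqs
    px = [0.0] * n_freqs
    py = [0.0] * n_freqs
    for k in range(n_segs):
        X = seg_dft(list(map(float, x)), k)
        Y = seg_dft(list(map(float, y)), k)
        for f in range(n_freqs):
            cross[f] += X[f] * Y[f].conjugate()
            px[f] += abs(X[f]) ** 2
            py[f] += abs(Y[f]) ** 2
    vals = []
    for f in range(n_freqs):
        freq = f * fs / nper
        if band[0] <= freq <= band[1] and px[f] > 0 and py[f] > 0:
            vals.append(abs(cross[f] / n_segs) / math.sqrt(px[f] / n_segs * py[f] / n_segs))
    return sum(vals) / len(vals)


class TestCoherencePair:
    def test_matches_brute_force_dft_within_1e_10(self):
        """Estimator output equals the explicit-arithmetic oracle on 64-sample toys."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(64)
            y = 0.5 * x + rng.standard_normal(64)
            ours = coherence_pair(x, y, fs=32.0, seg_len_s=1.0, overlap=0.5, band=(1.0, 15.0))
            oracle = brute_force_band_coherence(x, y, fs=32.0, band=(1.0, 15.0))
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_self_coherence_is_one(self):
        x = np.random.default_rng(1).standard_normal(2000)
        assert coherence_pair(x, x, fs=100.0) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        base = coherence_pair(x, y, fs=100.0)
        scaled = coherence_pair(3.7 * x, -0.2 * y, fs=100.0)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_bounds_hold_on_random_inputs(self):
        """0 <= coherence <= 1 (Cauchy-Schwarz) over 1000 random signal pairs."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            x = rng.standard_normal(96)
            y = rng.standard_normal(96)
            c = coherence_pair(x, y, fs=32.0, band=(1.0, 15.0))
            assert 0.0 <= c <= 1.0

    def test_independent_white_noise_stays_near_the_bias_floor(self):
        """With K = 19 one-second segments the no-coherence bias floor is ~0.2."""
        rng = np.random.default_rng(4)
        vals = [
            coherence_pair(rng.standard_normal(1000), rng.standard_normal(1000), fs=100.0)
            for _ in range(20)
        ]
        assert max(vals) < 0.35

    def test_single_segment_rejected(self):
        x = np.zeros(100)
        with pytest.raises(ValueError):
            coherence_pair(x, x, fs=100.0, seg_len_s=1.0)


def _segment_from(data: np.ndarray, fs: float, labels, label=HVA, trial=0, subject=0):
    return TrialSegment(
        data=data, baseline=np.zeros((data.shape[0], 0)), label=label,
        subject_id=subject, trial_index=trial, fs=fs, labels=labels,
    )


class TestTrialFCMatrix:
    def test_eight_channels_give_28_unique_off_diagonals(self):
        rng = np.random.default_rng(5)
        labels = tuple(f"C{i}" for i in range(8))
        seg = _segment_from(rng.standard_normal((8, 600)), 100.0, labels)
        fc = trial_fc_matrix(seg, labels)
        assert fc.values.shape == (8, 8)
        assert np.allclose(fc.values, fc.values.T)
        assert np.allclose(np.diag(fc.values), 1.0)
        assert fc.upper_triangle().shape == (28,)

    def test_duplicated_channel_rows_have_unit_coherence(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(600)
        seg = _segment_from(np.vstack([x, x, rng.standard_normal(600)]), 100.0, ("a", "b", "c"))
        fc = trial_fc_matrix(seg, ("a", "b", "c"))
        assert fc.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_missing_channel_rejected(self):
        seg = _segment_from(np.zeros((2, 300)), 100.0, ("a", "b"))
        with pytest.raises(KeyError):
            trial_fc_matrix(seg, ("a", "zz"))


def _mat(values, label, trial, subject=0):
    n = values.shape[0]
    return CoherenceMatrix(
        values=values, channels=tuple(f"C{i}" for i in range(n)), band=(1.0, 40.0),
        trial_index=trial, subject_id=subject, label=label,
    )


def _const_fc(c, label, trial, subject=0, n=3):
    values = np.full((n, n), c)
    np.fill_diagonal(values, 1.0)
    return _mat(values, label, trial, subject)


class TestCompareStates:
    def test_identical_states_give_t_zero_p_one(self):
        mats = {
            s: {HVA: [_const_fc(0.3, HVA, 0, s)], LVA: [_const_fc(0.3, LVA, 0, s)]}
            for s in range(5)
        }
        stats = compare_states(mats)
        assert stats.t == 0.0 and stats.p == 1.0

    def test_fisher_z_of_half_is_0p5493(self):
        mats = {0: {HVA: [_const_fc(0.5, HVA, 0)], LVA: [_const_fc(0.5, LVA, 0)]}}
        stats = compare_states(mats)
        assert stats.subject_mean_z[HVA][0] == pytest.approx(0.5493, abs=1e-4)

    def test_unit_coherence_is_clipped_not_infinite(self):
        mats = {
            s: {HVA: [_const_fc(1.0, HVA, 0, s)], LVA: [_const_fc(0.5, LVA, 0, s)]}
            for s in range(3)
        }
        stats = compare_states(mats)
        assert np.isfinite(stats.subject_mean_z[HVA]).all()

    def test_missing_state_rejected(self):
        mats = {0: {HVA: [_const_fc(0.5, HVA, 0)], LVA: []}}
        with pytest.raises(ValueError):
            compare_states(mats)

    def test_planted_lva_excess_detected_across_subjects(self):
        """Estimator-level noise around distinct targets yields LVA > HVA, p < 0.05."""
        rng = np.random.default_rng(7)
        mats = {}
        for s in range(15):
            mats[s] = {HVA: [], LVA: []}
            for trial in range(6):
                for state, target in ((HVA, 0.25), (LVA, 0.30)):
                    noisy = np.clip(target + 0.02 * rng.standard_normal((3, 3)), 0, 0.99)
                    noisy = (noisy + noisy.T) / 2
                    np.fill_diagonal(noisy, 1.0)
                    mats[s][state].append(_mat(noisy, state, trial, s))
        stats = compare_states(mats)
        assert stats.mean_coherence[LVA] > stats.mean_coherence[HVA]
        assert stats.p < 0.05


class TestDynamicFeatures:
    def _mats_by_subject(self, n_subjects=3, n_trials=6, n_ch=3):
        rng = np.random.default_rng(8)
        out = {}
        for s in range(n_subjects):
            out[s] = {}
            for state in (HVA, LVA):
                mats = []
                for k in range(n_trials):
                    v = np.clip(rng.uniform(0.1, 0.9, (n_ch, n_ch)), 0, 1)
                    v = (v + v.T) / 2
                    np.fill_diagonal(v, 1.0)
                    mats.append(_mat(v, state, k, s))
                out[s][state] = mats
        return out

    def test_k1_feature_width_is_channel_count(self):
        feats = dynamic_fc_features(self._mats_by_subject(), k=1)
        assert all(f.Y.shape == (3, 3) for f in feats)
        assert len(feats) == 6

    def test_k6_with_8_channels_gives_8_by_48(self):
        feats = dynamic_fc_features(self._mats_by_subject(n_ch=8), k=6)
        assert all(f.Y.shape == (8, 48) for f in feats)

    def test_prefix_property_k1_ignores_later_trials(self):
        mats = self._mats_by_subject()
        base = dynamic_fc_features(mats, k=1)
        for s in mats:
            for state in mats[s]:
                head, tail = mats[s][state][0], mats[s][state][1:]
                mats[s][state] = [head] + tail[::-1]
        permuted = dynamic_fc_features(mats, k=1)
        for a, b in zip(base, permuted):
            np.testing.assert_array_equal(a.Y, b.Y)

    def test_subject_with_too_few_trials_skipped(self, caplog):
        mats = self._mats_by_subject(n_trials=2)
        feats = dynamic_fc_features(mats, k=4)
        assert feats == []


class TestDynamicClassificationCurve:
    def test_zero_contrast_features_classify_at_chance(self):
        """With no planted class difference, every k stays near 50%."""
        rng = np.random.default_rng(12)
        mats = {}
        for s in range(10):
            mats[s] = {}
            for state in (HVA, LVA):
                trials = []
                for t in range(6):
                    v = np.clip(0.25 + 0.05 * rng.standard_normal((4, 4)), 0, 1)
                    v = (v + v.T) / 2
                    np.fill_diagonal(v, 1.0)
                    trials.append(_mat(v, state, t, s))
                mats[s][state] = trials
        curve = dynamic_classification_curve(mats, ks=(1, 6), seed=0)
        for result in curve.values():
            assert 20.0 <= result.summary["accuracy"][0] <= 80.0

    def test_k_beyond_available_trials_surfaces_an_error(self):
        rng = np.random.default_rng(13)
        v = np.eye(3)
        mats = {0: {HVA: [_mat(v, HVA, 0)], LVA: [_mat(v, LVA, 0)]}}
        with pytest.raises(ValueError):
            dynamic_classification_curve(mats, ks=(4,), seed=0)
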