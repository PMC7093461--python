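"""Identification scoring: reverse dot-product, RT trapezoid, acceptance logic."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipidraft as lr
from lipidraft import errors
from lipidraft.features import Feature, Spectrum
from lipidraft.identify import (
    ScoringParams,
    identify,
    match_mass,
    rt_similarity,
    spectral_similarity,
)
from lipidraft.library import FragmentPeak


# ---------------------------------------------------------------------------
# independent oracle: a direct, loop-based evaluation of the weighted reverse
# dot-product, written from the formula and sharing no code with the package

def reverse_dot_product_oracle(ref_peaks, exp_peaks, m, n, tol):
    num = 0.0
    sum_d2 = 0.0
    sum_e2 = 0.0
    for mz_d, i_d in ref_peaks:
        matched = [(mz, i) for mz, i in exp_peaks if abs(mz - mz_d) <= tol]
        i_e = sum(i for _, i in matched)
        if i_e > 0:
            mz_e = sum(mz * i for mz, i in matched) / i_e
        else:
            mz_e = mz_d
        w_d = (i_d**n) * (mz_d**m)
        w_e = (i_e**n) * (mz_e**m)
        num += w_d * w_e
        sum_d2 += w_d * w_d
        sum_e2 += w_e * w_e
    if sum_e2 == 0.0 or sum_d2 == 0.0:
        return 0.0
    return num / math.sqrt(sum_d2 * sum_e2)


def _spec(peaks, mode="positive", precursor=700.0):
    return Spectrum(
        peaks=[FragmentPeak(mz, i) for mz, i in peaks], mode=mode,
        precursor_mz=precursor,
    )


class TestSpectralSimilarity:
    def test_self_match_scores_exactly_one(self):
        s = _spec([(100.0, 30.0), (200.0, 70.0), (300.0, 10.0)])
        assert spectral_similarity(s, s, ScoringParams()) == 1.0

    def test_disjoint_spectra_score_zero(self):
        a = _spec([(100.0, 1.0)])
        b = _spec([(200.0, 1.0)])
        assert spectral_similarity(a, b, ScoringParams()) == 0.0

    def test_half_matched_reference_frozen_value(self):
        # reference {(100,1),(200,1)}, experimental {(100,1)}, m=1, n=1:
        # weighted vectors (100,200) vs (100,0) -> cosine = 1/sqrt(5)
        params = ScoringParams(intensity_weight_n_pos=1.0)
        exp = _spec([(100.0, 1.0)])
        ref = _spec([(100.0, 1.0), (200.0, 1.0)])
        score = spectral_similarity(exp, ref, params)
        assert score == pytest.approx(0.4472135954999579, abs=1e-12)

    def test_negative_mode_uses_unit_intensity_weight(self):
        exp = _spec([(100.0, 4.0), (200.0, 1.0)], mode="negative")
        ref = _spec([(100.0, 1.0), (200.0, 1.0)], mode="negative")
        got = spectral_similarity(exp, ref, ScoringParams())
        want = reverse_dot_product_oracle(
            [(100.0, 1.0), (200.0, 1.0)], [(100.0, 4.0), (200.0, 1.0)],
            m=1.0, n=1.0, tol=0.02,
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_multiple_peaks_in_tolerance_are_summed(self):
        params = ScoringParams(fragment_tol_da=0.05)
        ref = _spec([(100.0, 1.0)])
        exp = _spec([(99.98, 3.0), (100.02, 1.0)])
        want = reverse_dot_product_oracle(
            [(100.0, 1.0)], [(99.98, 3.0), (100.02, 1.0)], 1.0, 0.6, 0.05
        )
        assert spectral_similarity(exp, ref, params) == pytest.approx(want, abs=1e-12)

    def test_empty_reference_is_validation_error(self):
        exp = _spec([(100.0, 1.0)])
        with pytest.raises(errors.ValidationError):
            Spectrum(peaks=[], mode="positive", precursor_mz=700.0)
        ref = _spec([(100.0, 1.0)])
        ref.peaks = []
        with pytest.raises(errors.ValidationError):
            spectral_similarity(exp, ref, ScoringParams())

    def test_mode_mismatch_rejected(self):
        a = _spec([(100.0, 1.0)], mode="positive")
        b = _spec([(100.0, 1.0)], mode="negative")
        with pytest.raises(errors.ValidationError):
            spectral_similarity(a, b, ScoringParams())

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_random_small_spectra(self, seed):
        rng = np.random.default_rng(seed)
        mode = "positive" if rng.random() < 0.5 else "negative"
        params = ScoringParams()
        n = params.intensity_weight(mode)

        def peaks(k):
            return [
                (float(rng.uniform(60, 900)), float(rng.uniform(0, 100)))
                for _ in range(k)
            ]

        ref = peaks(int(rng.integers(1, 7)))
        exp = peaks(int(rng.integers(1, 7)))
        got = spectral_similarity(
            _spec(exp, mode=mode), _spec(ref, mode=mode), params
        )
        want = reverse_dot_product_oracle(ref, exp, params.mz_weight_m, n,
                                          params.fragment_tol_da)
        assert got == pytest.approx(want, abs=1e-12)
        assert 0.0 <= got <= 1.0

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_intensity_scaling(self, scale):
        ref = _spec([(100.0, 10.0), (200.0, 40.0), (300.0, 5.0)])
        exp = _spec([(100.05, 20.0), (200.0, 30.0)])
        scaled = _spec([(100.05, 20.0 * scale), (200.0, 30.0 * scale)])
        params = ScoringParams()
        assert spectral_similarity(exp, ref, params) == pytest.approx(
            spectral_similarity(scaled, ref, params), rel=1e-9
        )

    def test_mean_score_degrades_monotonically_with_fragment_noise(self):
        # 200 seeded perturbations per noise level; mean similarity to the
        # clean reference must not increase with sigma
        rng = np.random.default_rng(123)
        ref_peaks = [(184.07, 100.0), (500.3, 40.0), (620.4, 25.0), (702.5, 10.0)]
        ref = _spec(ref_peaks)
        params = ScoringParams()
        means = []
        for sigma in (0.0, 0.2, 0.5, 1.0):
            scores = []
            for _ in range(200):
                noisy = [
                    (mz, i * math.exp(rng.normal(0, sigma)) if sigma else i)
                    for mz, i in ref_peaks
                ]
                scores.append(spectral_similarity(_spec(noisy), ref, params))
            means.append(np.mean(scores))
        assert all(a >= b for a, b in zip(means, means[1:]))
        assert means[0] == 1.0


class TestRtSimilarity:
    def test_zero_deviation_scores_one(self):
        assert rt_similarity(5.0, 5.0, ScoringParams()) == 1.0

    def test_plateau_scores_one(self):
        p = ScoringParams()
        assert rt_similarity(5.0, 5.0 + p.rt_plateau_a / 2, p) == 1.0
        assert rt_similarity(0.15, 0.0, p) == 1.0  # d == a exactly

    def test_beyond_zero_width_scores_zero(self):
        p = ScoringParams()
        assert rt_similarity(5.0, 5.0 + p.rt_zero_b, p) == 0.0
        assert rt_similarity(5.0, 12.0, p) == 0.0

    def test_flank_midpoint_scores_half(self):
        p = ScoringParams()
        d = (p.rt_plateau_a + p.rt_zero_b) / 2
        assert rt_similarity(5.0, 5.0 + d, p) == pytest.approx(0.5, abs=1e-12)

    @given(
        d1=st.floats(min_value=0.0, max_value=1.0),
        d2=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_non_increasing_in_deviation(self, d1, d2):
        p = ScoringParams()
        lo, hi = sorted([d1, d2])
        assert rt_similarity(5.0, 5.0 + lo, p) >= rt_similarity(5.0, 5.0 + hi, p)

    def test_continuity_at_breakpoints(self):
        p = ScoringParams()
        eps = 1e-9
        assert rt_similarity(0.0, p.rt_plateau_a + eps, p) == pytest.approx(1.0, abs=1e-6)
        assert rt_similarity(0.0, p.rt_zero_b - eps, p) == pytest.approx(0.0, abs=1e-6)

    def test_negative_rt_rejected(self):
        with pytest.raises(errors.ValidationError):
            rt_similarity(-1.0, 5.0, ScoringParams())


class TestMatchMass:
    def test_exact_match_is_first_with_zero_error(self, small_library):
        entry = small_library.entries[0]
        feature = Feature("F1", "S1", entry.precursor_mz, entry.predicted_rt, 10.0)
        hits = match_mass(feature, small_library, ScoringParams())
        assert hits[0].key == entry.key

    def test_far_feature_matches_nothing(self, small_library):
        entry = small_library.entries[0]
        feature = Feature(
            "F1", "S1", entry.precursor_mz * (1 + 100e-6), 5.0, 10.0
        )
        assert match_mass(feature, small_library, ScoringParams()) == []

    def test_agrees_with_brute_force_scan(self, noisy_experiment):
        _, library, features, _, _ = noisy_experiment
        params = ScoringParams()
        for feature in features[::17]:
            mode = feature.ms2.mode if feature.ms2 else None
            expected = sorted(
                (
                    e.key
                    for e in library.entries
                    if (mode is None or e.mode == mode)
                    and abs(e.precursor_mz - feature.mz) / e.precursor_mz * 1e6
                    <= params.precursor_tol_ppm
                ),
            )
            got = sorted(e.key for e in match_mass(feature, library, params))
            assert got == expected

    def test_nearer_candidate_sorts_first(self, small_library):
        # synthetic two-entry check: 5 ppm beats 8 ppm
        e = small_library.entries[0]
        mz5 = e.precursor_mz * (1 + 5e-6)
        feature = Feature("F1", "S1", mz5, 5.0, 10.0)
        hits = match_mass(feature, small_library, ScoringParams())
        errors_ppm = [
            abs(h.precursor_mz - feature.mz) / h.precursor_mz * 1e6 for h in hits
        ]
        assert errors_ppm == sorted(errors_ppm)


class TestIdentify:
    def test_noise_free_self_matches_accepted(self, noise_free_experiment):
        _, library, features, _, truth = noise_free_experiment
        ids = identify(features, library)
        accepted = {i.feature_id: i for i in ids if i.accepted}
        for fid, species in truth.feature_truth.items():
            assert accepted[fid].species_id == species
            assert accepted[fid].spectral_score == 1.0

    def test_high_spectral_low_rt_not_accepted(self, small_library):
        entry = small_library.entries[0]
        feature = Feature(
            "F1", "S1", entry.precursor_mz, entry.predicted_rt + 10.0, 10.0,
            ms2=Spectrum(peaks=list(entry.fragments), mode=entry.mode,
                         precursor_mz=entry.precursor_mz),
        )
        ids = identify([feature], small_library)
        (cand,) = [i for i in ids if i.library_key == entry.key]
        assert cand.spectral_score == 1.0
        assert cand.rt_score == 0.0
        assert not cand.accepted

    def test_features_without_ms2_yield_no_identification(self, small_library):
        feature = Feature("F1", "S1", small_library.entries[0].precursor_mz, 5.0, 1.0)
        assert identify([feature], small_library) == []

    def test_at_most_one_accepted_per_feature(self, noisy_experiment):
        _, library, features, _, _ = noisy_experiment
        ids = identify(features, library)
        counts = {}
        for i in ids:
            if i.accepted:
                counts[i.feature_id] = counts.get(i.feature_id, 0) + 1
        assert all(v == 1 for v in counts.values())

    def test_accepted_implies_both_thresholds(self, noisy_experiment):
        _, library, features, _, _ = noisy_experiment
        params = ScoringParams()
        for i in identify(features, library, params):
            if i.accepted:
                assert i.spectral_score > params.spectral_threshold
                assert i.rt_score > params.rt_threshold

    def test_audit_table_round_trip(self, noisy_experiment, tmp_path):
        _, library, features, _, _ = noisy_experiment
        ids = identify(features[:40], library)
        from lipidraft.identify import read_identifications, write_identifications

        write_identifications(ids, tmp_path / "id.tsv")
        assert read_identifications(tmp_path / "id.tsv") == ids
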