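"""Modified cosine, preprocessing and library matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strainscout import (
    LibraryEntry,
    SimilarityParams,
    Spectrum,
    library_match,
    modified_cosine,
    normalize,
    precursor_window_filter,
)

from conftest import FRAGMENT_TOL, exhaustive_modified_cosine, random_spectrum


def spec(peaks, precursor=500.0, fid=0):
    return Spectrum(feature_id=fid, precursor_mz=precursor, peaks=np.asarray(peaks, float))


class TestPrecursorWindowFilter:
    def test_removes_peaks_near_precursor(self):
        s = spec([[200.0, 1.0], [484.0, 1.0], [490.0, 1.0]], precursor=500.0)
        out = precursor_window_filter(s, 17.0)
        # 484 (delta 16) and 490 (delta 10) fall inside the window; 200 survives
        assert out.mz.tolist() == [200.0]

    def test_zero_window_removes_only_exact_precursor(self):
        s = spec([[499.99, 1.0], [500.0, 1.0], [500.01, 1.0]], precursor=500.0)
        out = precursor_window_filter(s, 0.0)
        assert out.mz.tolist() == [499.99, 500.01]

    @pytest.mark.parametrize("seed", range(5))
    def test_no_surviving_peak_inside_window(self, seed):
        rng = np.random.default_rng(seed)
        s = random_spectrum(rng, n_peaks=10, precursor=300.0, lo=50, hi=400)
        out = precursor_window_filter(s, 17.0)
        assert np.all(np.abs(out.mz - 300.0) > 17.0)

    def test_can_empty_a_spectrum(self):
        s = spec([[495.0, 1.0]], precursor=500.0)
        assert precursor_window_filter(s, 17.0).n_peaks == 0


class TestNormalize:
    def test_single_peak_gets_unit_weight(self):
        assert normalize(spec([[100.0, 123.4]]))[0] == pytest.approx(1.0)

    def test_two_equal_peaks(self):
        w = normalize(spec([[100.0, 4.0], [200.0, 4.0]]))
        np.testing.assert_allclose(w, [np.sqrt(2) / 2] * 2)

    def test_unit_euclidean_norm(self):
        rng = np.random.default_rng(1)
        s = random_spectrum(rng, n_peaks=12)
        assert np.sum(normalize(s) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_zero_intensities_rejected(self):
        with pytest.raises(ValueError):
            normalize(spec([[100.0, 0.0], [200.0, 0.0]]))


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = random_spectrum(rng, n_peaks=int(rng.integers(2, 10)))
            res = modified_cosine(s, s)
            assert res.score == pytest.approx(1.0, abs=1e-9)
            assert res.n_matched == s.n_peaks

    def test_disjoint_peaks_score_zero(self):
        a = spec([[100.0, 1.0], [200.0, 1.0]], precursor=500.0)
        b = spec([[150.0, 1.0], [250.0, 1.0]], precursor=500.0)
        res = modified_cosine(a, b)
        assert res.score == 0.0 and res.n_matched == 0

    def test_shifted_peaks_match_through_precursor_delta(self):
        # homolog pair: fragments offset by exactly the precursor difference
        a = spec([[100.0, 1.0], [150.0, 1.0], [220.0, 1.0]], precursor=400.0)
        b = spec([[114.0, 1.0], [164.0, 1.0], [234.0, 1.0]], precursor=414.0)
        res = modified_cosine(a, b)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.n_matched == 3

    def test_empty_spectrum_rejected(self):
        a = spec([[100.0, 1.0]])
        empty = Spectrum(feature_id=1, precursor_mz=500.0, peaks=np.empty((0, 2)))
        with pytest.raises(ValueError):
            modified_cosine(a, empty)

    @pytest.mark.parametrize("seed", range(50))
    def test_greedy_equals_exhaustive_on_spaced_spectra(self, seed):
        rng = np.random.default_rng(seed)
        a = random_spectrum(rng, n_peaks=4)
        b = random_spectrum(rng, n_peaks=4)
        # plant a few shared fragments so the matching is non-trivial
        shared = a.mz[: int(rng.integers(0, 4))]
        mz_b = np.sort(np.concatenate([shared, b.mz[len(shared):]]))
        if len(mz_b) < 2 or np.min(np.diff(mz_b)) >= FRAGMENT_TOL * 3:
            b = Spectrum(feature_id=1, precursor_mz=b.precursor_mz,
                         peaks=np.column_stack([mz_b, b.intensities]))
        res = modified_cosine(a, b)
        best_score, best_n = exhaustive_modified_cosine(a, b)
        assert res.score == pytest.approx(best_score, abs=1e-9)
        assert res.n_matched == best_n

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = random_spectrum(rng, n_peaks=int(rng.integers(2, 8)))
        b = random_spectrum(rng, n_peaks=int(rng.integers(2, 8)))
        ab, ba = modified_cosine(a, b), modified_cosine(b, a)
        assert ab.score == pytest.approx(ba.score, abs=1e-9)
        assert ab.n_matched == ba.n_matched
        assert 0.0 <= ab.score <= 1.0 + 1e-9
        assert ab.n_matched <= min(a.n_peaks, b.n_peaks)

    def test_jitter_within_tolerance_preserves_matches(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = random_spectrum(rng, n_peaks=6)
            jitter = rng.uniform(-FRAGMENT_TOL / 2, FRAGMENT_TOL / 2, size=6)
            b = Spectrum(
                feature_id=1,
                precursor_mz=a.precursor_mz,
                peaks=np.column_stack([a.mz + jitter, a.intensities]),
            )
            assert modified_cosine(a, b).n_matched == a.n_peaks

    def test_agrees_with_independent_reference_implementation(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(11)
        ref = ModifiedCosine(tolerance=FRAGMENT_TOL, intensity_power=0.5)
        for _ in range(20):
            a = random_spectrum(rng, n_peaks=int(rng.integers(3, 9)))
            b = random_spectrum(rng, n_peaks=int(rng.integers(3, 9)))
            shared = int(rng.integers(0, 3))
            if shared:
                mz_b = np.sort(np.concatenate([a.mz[:shared], b.mz[shared:]]))
                if np.min(np.diff(mz_b)) < FRAGMENT_TOL * 3:
                    continue
                b = Spectrum(1, b.precursor_mz, np.column_stack([mz_b, b.intensities]))
            ma = matchms.Spectrum(
                mz=a.mz, intensities=a.intensities, metadata={"precursor_mz": a.precursor_mz},
                metadata_harmonization=False,
            )
            mb = matchms.Spectrum(
                mz=b.mz, intensities=b.intensities, metadata={"precursor_mz": b.precursor_mz},
                metadata_harmonization=False,
            )
            expected = ref.pair(ma, mb)
            res = modified_cosine(a, b)
            assert res.score == pytest.approx(float(expected["score"]), abs=1e-6)
            assert res.n_matched == int(expected["matches"])


class TestLibraryMatch:
    def _library(self, rng, n=10):
        return [
            LibraryEntry(name=f"cmpd_{i}", spectrum=random_spectrum(rng, feature_id=i, n_peaks=8))
            for i in range(n)
        ]

    def test_identical_entry_is_top_hit_with_unit_score(self):
        rng = np.random.default_rng(21)
        lib = self._library(rng)
        query = lib[3].spectrum
        hits = library_match(query, lib)
        assert hits and hits[0][0].name == "cmpd_3"
        assert hits[0][1].score == pytest.approx(1.0, abs=1e-9)

    def test_subthreshold_score_excluded(self):
        # 3 of 6 equally weighted peaks shared -> cosine 0.5 < 0.6
        mz = np.arange(100.0, 700.0, 100.0)
        query = spec(np.column_stack([mz, np.ones(6)]), precursor=800.0)
        lib_mz = np.concatenate([mz[:3], mz[3:] + 7.0])
        entry = LibraryEntry(
            name="partial", spectrum=spec(np.column_stack([np.sort(lib_mz), np.ones(6)]), 800.0)
        )
        res = modified_cosine(query, entry.spectrum)
        assert res.score == pytest.approx(0.5) and res.n_matched == 3
        assert library_match(query, [entry], min_score=0.6, min_peaks=3) == []

    def test_precursor_gate_excludes_distant_entries(self):
        rng = np.random.default_rng(22)
        s = random_spectrum(rng, n_peaks=6, precursor=500.0)
        far = Spectrum(1, 503.0, s.peaks)
        assert library_match(s, [LibraryEntry("far", far)]) == []

    def test_noisy_copies_recovered_as_top_hits(self):
        rng = np.random.default_rng(23)
        lib = self._library(rng, n=20)
        p = SimilarityParams()
        recovered = 0
        for i, entry in enumerate(lib):
            s = entry.spectrum
            noisy = Spectrum(
                feature_id=i,
                precursor_mz=s.precursor_mz + float(rng.uniform(-0.01, 0.01)),
                peaks=np.column_stack(
                    [
                        s.mz + rng.uniform(-p.fragment_tol / 2, p.fragment_tol / 2, s.n_peaks),
                        s.intensities * rng.uniform(0.8, 1.2, s.n_peaks),
                    ]
                ),
            )
            hits = library_match(noisy, lib, p)
            if hits and hits[0][0].name == entry.name:
                recovered += 1
        assert recovered >= 18  # >= 90 % of 20
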