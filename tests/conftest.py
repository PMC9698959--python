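"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from strainscout import Spectrum, SyntheticConfig, generate, make_library
from strainscout.similarity import SimilarityParams, normalize

FRAGMENT_TOL = 0.02
MIN_SPACING = 3 * FRAGMENT_TOL


def spaced_mz(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Random fragment m/z with spacing >= 3 tolerances (unambiguous pairing)."""
    while True:
        mz = np.sort(rng.uniform(lo, hi, size=n))
        if n < 2 or np.min(np.diff(mz)) >= MIN_SPACING:
            return mz


def random_spectrum(
    rng: np.random.Generator,
    feature_id: int = 0,
    n_peaks: int = 4,
    precursor: float | None = None,
    lo: float = 50.0,
    hi: float = 400.0,
) -> Spectrum:
    mz = spaced_mz(rng, n_peaks, lo, hi)
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=precursor if precursor is not None else float(rng.uniform(450, 900)),
        peaks=np.column_stack([mz, rng.uniform(0.1, 1.0, size=n_peaks)]),
    )


def exhaustive_modified_cosine(
    a: Spectrum, b: Spectrum, p: SimilarityParams | None = None
) -> tuple[float, int]:
    """Maximum-weight one-to-one peak assignment by brute-force enumeration.

    Independent oracle: enumerates every injective assignment of a-peaks to
    b-peaks over the allowed (direct or precursor-shifted) pairs and returns
    the best achievable score with its matched-pair count. Feasible for
    spectra of a few peaks only.
    """
    p = p or SimilarityParams()
    wa, wb = normalize(a, p.intensity_power), normalize(b, p.intensity_power)
    shift = a.precursor_mz - b.precursor_mz
    allowed = [
        [
            j
            for j in range(b.n_peaks)
            if abs(a.mz[i] - b.mz[j]) <= p.fragment_tol
            or abs(a.mz[i] - b.mz[j] - shift) <= p.fragment_tol
        ]
        for i in range(a.n_peaks)
    ]
    best = (0.0, 0)
    n = a.n_peaks

    def rec(i: int, used: set[int], score: float, count: int) -> None:
        nonlocal best
        if i == n:
            if (score, count) > best:
                best = (score, count)
            return
        rec(i + 1, used, score, count)  # leave peak i unmatched
        for j in allowed[i]:
            if j not in used:
                rec(i + 1, used | {j}, score + wa[i] * wb[j], count + 1)

    rec(0, set(), 0.0, 0)
    return best


def bruteforce_venn(matrix: np.ndarray, labels: list[str]) -> dict[frozenset, int]:
    """Region counts by scanning every feature row independently."""
    counts: dict[frozenset, int] = {}
    for row in matrix:
        region = frozenset(l for l, p in zip(labels, row) if p)
        if region:
            counts[region] = counts.get(region, 0) + 1
    return counts


def bruteforce_strain_specific(matrix: np.ndarray, samples: list[str]) -> dict[str, int]:
    counts = {s: 0 for s in samples}
    for row in matrix:
        present = [s for s, p in zip(samples, row) if p]
        if len(present) == 1:
            counts[present[0]] += 1
    return counts


NOISELESS = SyntheticConfig(
    mz_jitter_sd=0.0, intensity_noise_cv=0.0, dropout_prob=0.0, seed=42
)


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default-condition synthetic cohort (shared across tests)."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate(NOISELESS)


@pytest.fixture(scope="session")
def annotation_inputs(noiseless_cohort):
    _, spectra, _, truth = noiseless_cohort
    return make_library(truth, spectra)
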