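"""Spectrum preprocessing and the modified-cosine similarity score.

The modified cosine allows a fragment of one spectrum to match a fragment of
the other either directly (|mz_a - mz_b| <= fragment tolerance) or shifted by
the precursor mass difference (|mz_a - mz_b - (prec_a - prec_b)| <= fragment
tolerance), so that homologous fragments of structurally related compounds
still pair up. Intensities are square-root weighted and L2-normalized; the
score is the sum of weight products over a one-to-one peak assignment chosen
greedily by descending product, and therefore lies in [0, 1] with
self-similarity exactly 1 for well-separated peaks.

Before networking, fragment ions within +/-17 Da of the precursor are
removed (they are dominated by residual precursor and neutral-loss signals
that inflate similarity between unrelated compounds).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import Spectrum

__all__ = [
    "SimilarityParams",
    "SimilarityResult",
    "LibraryEntry",
    "precursor_window_filter",
    "normalize",
    "modified_cosine",
    "library_match",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Tolerances and weighting for spectral comparison.

    fragment_tol, precursor_tol : Da (both default 0.02)
    precursor_window : Da half-width of the precursor exclusion window (17.0)
    intensity_power : exponent applied to intensities before L2 norm (0.5)
    """

    fragment_tol: float = 0.02
    precursor_tol: float = 0.02
    precursor_window: float = 17.0
    intensity_power: float = 0.5

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.precursor_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.intensity_power < 0:
            raise ValueError("intensity_power must be >= 0")


@dataclass(frozen=True)
class SimilarityResult:
    """Cosine score in [0, 1] and the number of matched peak pairs."""

    score: float
    n_matched: int


@dataclass(frozen=True)
class LibraryEntry:
    """An annotated reference spectrum (library compound)."""

    name: str
    spectrum: Spectrum
    rt: float | None = None
    class_label: str | None = None


def precursor_window_filter(s: Spectrum, window: float) -> Spectrum:
    """Drop fragment peaks within ``window`` Da of the precursor m/z.

    Peaks with |fragment m/z - precursor m/z| <= window are removed; the
    result may be empty, in which case the spectrum is excluded from
    networking by the caller.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    keep = np.abs(s.mz - s.precursor_mz) > window
    return replace(s, peaks=s.peaks[keep])


def normalize(s: Spectrum, intensity_power: float = 0.5) -> np.ndarray:
    """Intensity weights: intensities**power scaled to unit Euclidean norm."""
    if s.n_peaks == 0:
        raise ValueError("cannot normalize an empty spectrum")
    w = s.intensities.astype(float) ** intensity_power
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("all-zero intensities cannot be normalized")
    return w / norm


def modified_cosine(
    a: Spectrum, b: Spectrum, p: SimilarityParams | None = None
) -> SimilarityResult:
    """Modified-cosine similarity with matched-peak counting.

    Candidate pairs are peaks matching directly or shifted by the signed
    precursor difference (prec_a - prec_b); a one-to-one assignment is built
    greedily by descending weight product, ties broken by smaller m/z in
    ``a`` then in ``b`` so results are reproducible. A peak is consumed once,
    whether it matched directly or shifted.
    """
    p = p or SimilarityParams()
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified_cosine requires non-empty spectra")
    wa = normalize(a, p.intensity_power)
    wb = normalize(b, p.intensity_power)
    dmz = a.mz[:, None] - b.mz[None, :]
    shift = a.precursor_mz - b.precursor_mz
    cand = np.abs(dmz) <= p.fragment_tol
    if abs(shift) > 1e-12:
        cand |= np.abs(dmz - shift) <= p.fragment_tol
    ii, jj = np.nonzero(cand)
    if ii.size == 0:
        return SimilarityResult(score=0.0, n_matched=0)
    products = wa[ii] * wb[jj]
    order = np.lexsort((b.mz[jj], a.mz[ii], -products))
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    score = 0.0
    n_matched = 0
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        score += products[k]
        n_matched += 1
    return SimilarityResult(score=float(min(score, 1.0 + 1e-9)), n_matched=n_matched)


def library_match(
    query: Spectrum,
    library: list[LibraryEntry],
    p: SimilarityParams | None = None,
    min_score: float = 0.6,
    min_peaks: int = 3,
) -> list[tuple[LibraryEntry, SimilarityResult]]:
    """Rank library spectra against a query.

    Candidates are restricted to entries whose precursor m/z lies within the
    precursor tolerance of the query; hits must reach ``min_score`` cosine
    AND ``min_peaks`` matched peaks. Returned sorted by score descending
    (ties by entry name) — an empty list is a valid outcome.
    """
    p = p or SimilarityParams()
    hits: list[tuple[LibraryEntry, SimilarityResult]] = []
    for entry in library:
        if abs(entry.spectrum.precursor_mz - query.precursor_mz) > p.precursor_tol:
            continue
        if entry.spectrum.n_peaks == 0:
            continue
        res = modified_cosine(query, entry.spectrum, p)
        if res.score >= min_score and res.n_matched >= min_peaks:
            hits.append((entry, res))
    hits.sort(key=lambda h: (-h[1].score, h[0].name))
    return hits
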