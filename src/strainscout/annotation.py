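"""Three-level dereplication cascade and family-level class propagation.

Confidence levels follow the community convention for metabolite
identification:

* level 1 — identified: precursor m/z, retention time AND MS/MS spectrum all
  match a pure reference standard from the in-house library;
* level 2 — putatively identified: MS/MS spectrum consistent with an
  externally acquired library spectrum (no retention-time evidence);
* level 3 — tentatively assigned: best in-silico structure candidate passes
  the score filter (CSI:FingerID score < -150 and Zodiac score > 60%);
* unknown — none of the above.

Levels are assigned consecutively with precedence 1 > 2 > 3; a feature
annotated at one level is never re-annotated lower. Chemical classes are
propagated to molecular families by simple majority among annotated members,
with ties and fully unannotated families left unclassified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .data_io import Feature, Spectrum
from .network import MolecularNetwork
from .similarity import LibraryEntry, SimilarityParams, library_match, modified_cosine

__all__ = [
    "AnnotationParams",
    "Annotation",
    "InHouseEntry",
    "InSilicoCandidate",
    "UNCLASSIFIED",
    "level1_match",
    "level2_match",
    "level3_filter",
    "cascade",
    "annotation_summary",
    "propagate_classes",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class AnnotationParams:
    """Thresholds of the dereplication cascade.

    lib_min_score / lib_min_peaks : spectral-library gates (0.6, 3).
    csi_max_score : accept in-silico candidates with CSI:FingerID score
        strictly below this value (-150; the sign convention is
        configurable because it varies between software versions).
    zodiac_min : accept only candidates whose Zodiac formula score is
        strictly above this fraction (0.60).
    rt_tol : retention-time gate for level 1, minutes (0.2 — typical UPLC
        run-to-run reproducibility).
    precursor_tol : Da (0.02).
    """

    lib_min_score: float = 0.6
    lib_min_peaks: int = 3
    csi_max_score: float = -150.0
    zodiac_min: float = 0.60
    rt_tol: float = 0.2
    precursor_tol: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.lib_min_score <= 1:
            raise ValueError("lib_min_score must be in [0, 1]")
        if not 0 < self.zodiac_min <= 1:
            raise ValueError("zodiac_min must be in (0, 1]")
        if self.rt_tol <= 0:
            raise ValueError("rt_tol must be > 0")

    def similarity_params(self) -> SimilarityParams:
        return SimilarityParams(precursor_tol=self.precursor_tol)


@dataclass(frozen=True)
class InHouseEntry:
    """A reference standard: precursor m/z, retention time and spectrum."""

    name: str
    precursor_mz: float
    rt: float
    spectrum: Spectrum
    class_label: str | None = None


@dataclass(frozen=True)
class InSilicoCandidate:
    """A structure proposal from in-silico annotation of one feature."""

    feature_id: int
    formula: str
    structure: str
    csi_score: float
    zodiac_score: float
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.zodiac_score <= 1:
            raise ValueError("zodiac_score must be in [0, 1]")


@dataclass(frozen=True)
class Annotation:
    """Per-feature dereplication record.

    ``level`` is 1, 2 or 3, or None for unknown features (which carry an
    empty name and source "none").
    """

    feature_id: int
    level: int | None
    name: str = ""
    source: str = "none"
    class_label: str | None = None
    score: float | None = None
    n_matched: int | None = None
    csi_score: float | None = None
    zodiac_score: float | None = None

    def __post_init__(self) -> None:
        if self.level == 1 and self.source != "inhouse":
            raise ValueError("level 1 requires an in-house source")
        if self.level is None and self.name:
            raise ValueError("unknown features carry no compound name")

    @property
    def is_annotated(self) -> bool:
        return self.level is not None


def level1_match(
    feature: Feature,
    spectrum: Spectrum,
    inhouse: Sequence[InHouseEntry],
    p: AnnotationParams | None = None,
) -> Annotation | None:
    """Match against pure reference standards (precursor + RT + MS/MS).

    A hit requires |delta precursor| <= precursor_tol, |delta RT| <= rt_tol
    and a spectral match passing the library gates; the best hit by score
    wins (ties by entry name).
    """
    p = p or AnnotationParams()
    sp = p.similarity_params()
    best: tuple[float, str, InHouseEntry, int] | None = None
    for entry in inhouse:
        if abs(entry.precursor_mz - feature.mz) > p.precursor_tol:
            continue
        if abs(entry.rt - feature.rt) > p.rt_tol:
            continue
        if entry.spectrum.n_peaks == 0 or spectrum.n_peaks == 0:
            continue
        res = modified_cosine(spectrum, entry.spectrum, sp)
        if res.score >= p.lib_min_score and res.n_matched >= p.lib_min_peaks:
            key = (-res.score, entry.name, entry, res.n_matched)
            if best is None or key[:2] < best[:2]:
                best = key
    if best is None:
        return None
    _, _, entry, n_matched = best
    return Annotation(
        feature_id=feature.feature_id,
        level=1,
        name=entry.name,
        source="inhouse",
        class_label=entry.class_label,
        score=-best[0],
        n_matched=n_matched,
    )


def level2_match(
    spectrum: Spectrum,
    external_library: Sequence[LibraryEntry],
    p: AnnotationParams | None = None,
) -> Annotation | None:
    """Match against external spectral libraries (no retention-time gate)."""
    p = p or AnnotationParams()
    hits = library_match(
        spectrum,
        list(external_library),
        p.similarity_params(),
        min_score=p.lib_min_score,
        min_peaks=p.lib_min_peaks,
    )
    if not hits:
        return None
    entry, res = hits[0]
    return Annotation(
        feature_id=spectrum.feature_id,
        level=2,
        name=entry.name,
        source="spectral_library",
        class_label=entry.class_label,
        score=res.score,
        n_matched=res.n_matched,
    )


def level3_filter(
    candidates: Sequence[InSilicoCandidate],
    p: AnnotationParams | None = None,
) -> Annotation | None:
    """Accept the best in-silico candidate passing the score filter.

    A candidate passes iff csi_score < csi_max_score AND
    zodiac_score > zodiac_min (both strict); among passing candidates the
    one with the highest Zodiac score wins (ties by csi score then
    structure id).
    """
    p = p or AnnotationParams()
    passing = [
        c
        for c in candidates
        if c.csi_score < p.csi_max_score and c.zodiac_score > p.zodiac_min
    ]
    if not passing:
        return None
    best = min(passing, key=lambda c: (-c.zodiac_score, c.csi_score, c.structure))
    return Annotation(
        feature_id=best.feature_id,
        level=3,
        name=best.structure,
        source="insilico",
        class_label=best.class_label,
        csi_score=best.csi_score,
        zodiac_score=best.zodiac_score,
    )


def cascade(
    features: Sequence[Feature],
    spectra: Mapping[int, Spectrum],
    inhouse: Sequence[InHouseEntry] = (),
    external: Sequence[LibraryEntry] = (),
    insilico: Mapping[int, Sequence[InSilicoCandidate]] | None = None,
    p: AnnotationParams | None = None,
) -> list[Annotation]:
    """Run the consecutive dereplication cascade over all features.

    Precedence is level 1 > 2 > 3; remaining features are marked unknown.
    Output order follows feature id, and the result is independent of the
    order features are supplied in.
    """
    p = p or AnnotationParams()
    insilico = insilico or {}
    out: list[Annotation] = []
    for feature in sorted(features, key=lambda f: f.feature_id):
        fid = feature.feature_id
        spectrum = spectra.get(fid)
        ann: Annotation | None = None
        if spectrum is not None and spectrum.n_peaks > 0:
            ann = level1_match(feature, spectrum, inhouse, p)
            if ann is None:
                ann = level2_match(spectrum, external, p)
        if ann is None:
            ann = level3_filter(list(insilico.get(fid, ())), p)
        if ann is None:
            ann = Annotation(feature_id=fid, level=None)
        out.append(ann)
    return out


def annotation_summary(annotations: Iterable[Annotation]) -> dict[str, float]:
    """Counts and percentage shares per confidence level.

    The four shares partition the feature set:
    n1 + n2 + n3 + n_unknown = total.
    """
    anns = list(annotations)
    total = len(anns)
    counts = Counter(a.level for a in anns)
    out: dict[str, float] = {"total": total}
    for lvl, key in ((1, "level1"), (2, "level2"), (3, "level3"), (None, "unknown")):
        n = counts.get(lvl, 0)
        out[f"n_{key}"] = n
        out[f"pct_{key}"] = 100.0 * n / total if total else 0.0
    return out


def propagate_classes(
    network: MolecularNetwork, annotations: Iterable[Annotation]
) -> dict[int, str]:
    """Assign each molecular family the majority class of its members.

    The family class is the most frequent class label among annotated
    members; families with no annotated member, and families whose top
    classes tie, are left unclassified. Keys are family indices in the
    order of ``network.families``.
    """
    class_of = {
        a.feature_id: a.class_label
        for a in annotations
        if a.is_annotated and a.class_label
    }
    out: dict[int, str] = {}
    for k, family in enumerate(network.families):
        votes = Counter(class_of[n] for n in family if n in class_of)
        if not votes:
            out[k] = UNCLASSIFIED
            continue
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out[k] = UNCLASSIFIED
        else:
            out[k] = ranked[0][0]
    return out
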