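"""Per-strain "talent" reports combining occurrence, annotation and network
evidence.

A talented producer strain is one worth scaling up for compound isolation:
it shows many strain-specific features (signals seen in no other extract), a
high fraction of unannotated (hence potentially novel) features, molecular
families exclusive to it, and — as supporting context — taxonomic novelty
(16S similarity below the species/genus demarcation thresholds of 98.7% and
95%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import Annotation
from .data_io import SampleMeta
from .network import MolecularNetwork, family_exclusivity
from .occurrence import PresenceMatrix, strain_specific_counts

__all__ = ["StrainReport", "PriorityParams", "build_reports", "rank_strains"]


@dataclass(frozen=True)
class PriorityParams:
    """Thresholds driving the report flags.

    specific_threshold : strain-specific feature count regarded as high (80,
        the cut drawn through the per-extract bar plot of the cohort).
    unknown_threshold_pct : percentage of unannotated features regarded as
        high (80).
    species_similarity_cutoff / genus_similarity_cutoff : 16S identity
        demarcations for new species (98.7%) and new genus (95%).
    """

    specific_threshold: int = 80
    unknown_threshold_pct: float = 80.0
    species_similarity_cutoff: float = 98.7
    genus_similarity_cutoff: float = 95.0

    def __post_init__(self) -> None:
        if min(
            self.specific_threshold,
            self.unknown_threshold_pct,
            self.species_similarity_cutoff,
            self.genus_similarity_cutoff,
        ) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class StrainReport:
    """Prioritization summary for one extract."""

    extract_id: str
    total_features: int
    specific_features: int
    pct_unknown: float
    exclusive_families: tuple[int, ...]
    taxonomy_similarity: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.specific_features <= self.total_features:
            raise ValueError("specific_features must be within [0, total_features]")
        if not 0 <= self.pct_unknown <= 100:
            raise ValueError("pct_unknown must be within [0, 100]")


def build_reports(
    pm: PresenceMatrix,
    annotations: Iterable[Annotation],
    network: MolecularNetwork | None,
    meta: Iterable[SampleMeta],
    params: PriorityParams | None = None,
) -> list[StrainReport]:
    """One report per non-blank extract of the presence matrix.

    ``pct_unknown`` is the percentage of an extract's detected features that
    lack any annotation (0 for extracts without features).
    ``exclusive_families`` lists the indices of molecular families whose
    nodes are all exclusive to the extract (fraction 1.0).
    """
    params = params or PriorityParams()
    by_id = {m.extract_id: m for m in meta}
    missing = [s for s in pm.sample_ids if s not in by_id]
    if missing:
        raise KeyError(f"extracts without metadata: {missing}")

    ann_by_fid = {a.feature_id: a for a in annotations}
    specific = strain_specific_counts(pm)
    exclusive_fams: dict[str, list[int]] = {}
    if network is not None:
        for k, (extract, frac) in family_exclusivity(network, pm).items():
            if extract is not None and frac == 1.0:
                exclusive_fams.setdefault(extract, []).append(k)

    reports = []
    for j, extract in enumerate(pm.sample_ids):
        col = pm.matrix[:, j]
        present_fids = [f for f, p in zip(pm.feature_ids, col) if p]
        total = len(present_fids)
        unknown = sum(
            1
            for f in present_fids
            if f not in ann_by_fid or not ann_by_fid[f].is_annotated
        )
        pct_unknown = 100.0 * unknown / total if total else 0.0
        sim = by_id[extract].similarity_pct
        flags = {
            "specific_ge_threshold": specific[extract] >= params.specific_threshold,
            "unknown_ge_threshold": pct_unknown >= params.unknown_threshold_pct,
            "novel_taxon": sim < params.species_similarity_cutoff,
            "novel_genus": sim < params.genus_similarity_cutoff,
        }
        reports.append(
            StrainReport(
                extract_id=extract,
                total_features=total,
                specific_features=specific[extract],
                pct_unknown=pct_unknown,
                exclusive_families=tuple(sorted(exclusive_fams.get(extract, []))),
                taxonomy_similarity=sim,
                flags=flags,
            )
        )
    return reports


def rank_strains(
    reports: Sequence[StrainReport],
    weights: Mapping[str, float] | None = None,
) -> list[StrainReport]:
    """Order strains by follow-up priority (most promising first).

    By default the ranking is lexicographic on (specific_features desc,
    pct_unknown desc, number of exclusive families desc), with ties broken
    deterministically by extract id. Passing ``weights`` (keys
    ``specific``, ``unknown``, ``families``) switches to a weighted-sum
    score over the same three criteria.
    """
    if not reports:
        raise ValueError("no reports to rank")
    if weights is None:
        key = lambda r: (
            -r.specific_features,
            -r.pct_unknown,
            -len(r.exclusive_families),
            r.extract_id,
        )
    else:
        w_s = weights.get("specific", 0.0)
        w_u = weights.get("unknown", 0.0)
        w_f = weights.get("families", 0.0)
        key = lambda r: (
            -(
                w_s * r.specific_features
                + w_u * r.pct_unknown
                + w_f * len(r.exclusive_families)
            ),
            r.extract_id,
        )
    return sorted(reports, key=key)
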