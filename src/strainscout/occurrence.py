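"""Presence/absence calls and set-algebra analytics over the feature table.

A feature is called *present* in a sample when its peak area exceeds a
threshold (default 0: any non-zero area counts, the convention of gap-filled
peak-picking exports). On top of the boolean presence matrix the module
computes the Venn partition of features over phyla ("detected in a phylum"
means present in at least one member strain), per-extract strain-specific
feature counts (features seen in exactly one extract), and the Pearson
correlation between per-group uniqueness and group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .data_io import FeatureTable, SampleMeta, read_quant_table

__all__ = [
    "PresenceMatrix",
    "VennPartition",
    "MetadataError",
    "presence_matrix",
    "venn_partition",
    "group_specific_counts",
    "strain_specific_counts",
    "uniqueness_isolate_correlation",
    "mass_filter_count",
    "reproduce_deposited_summary",
]


class MetadataError(KeyError):
    """A sample in the table has no metadata record."""


@dataclass
class PresenceMatrix:
    """Boolean features x samples detection matrix.

    ``matrix[i, j]`` is True iff feature ``feature_ids[i]`` has peak area
    strictly greater than ``threshold`` in sample ``sample_ids[j]``. Blank/QC
    samples are excluded at construction.
    """

    matrix: np.ndarray
    feature_ids: list[int]
    sample_ids: list[str]
    threshold: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("presence matrix shape inconsistent with ids")

    def presence_set(self, feature_id: int) -> frozenset[str]:
        """Samples in which the feature is present."""
        i = self.feature_ids.index(feature_id)
        return frozenset(
            s for s, p in zip(self.sample_ids, self.matrix[i]) if p
        )


@dataclass
class VennPartition:
    """Counts of features per non-empty subset of groups.

    ``region_counts`` maps each populated subset S of group labels to the
    number of features whose set of detecting groups equals S exactly.
    Regions are disjoint by construction and their counts sum to the number
    of features present in at least one retained sample. ``groups`` is the
    full group universe (so empty singleton regions report 0 downstream).
    """

    region_counts: dict[frozenset[str], int]
    groups: frozenset[str]

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())


def presence_matrix(
    table: FeatureTable,
    meta: Iterable[SampleMeta],
    threshold: float = 0.0,
) -> PresenceMatrix:
    """Binarize a feature table into presence calls (area > threshold).

    Blank samples (``is_blank``) are dropped before the call, so all
    downstream occurrence analytics ignore them. Samples in the table
    without a metadata record raise :class:`MetadataError`.
    """
    by_id = {m.extract_id: m for m in meta}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise MetadataError(f"samples without metadata: {missing}")
    keep = [s for s in table.sample_ids if not by_id[s].is_blank]
    cols = [table.sample_ids.index(s) for s in keep]
    areas = table.area_matrix()[:, cols]
    return PresenceMatrix(
        matrix=areas > threshold,
        feature_ids=table.feature_ids,
        sample_ids=keep,
        threshold=threshold,
    )


def venn_partition(
    pm: PresenceMatrix, grouping: Mapping[str, str]
) -> VennPartition:
    """Partition features by the exact set of groups that detect them.

    A group (e.g. a phylum) detects a feature when at least one of its member
    samples is a presence. Features absent from every retained sample are
    excluded from all regions.
    """
    if not grouping:
        raise ValueError("empty grouping")
    missing = [s for s in pm.sample_ids if s not in grouping]
    if missing:
        raise MetadataError(f"samples without group label: {missing}")
    labels = np.array([grouping[s] for s in pm.sample_ids])
    groups = frozenset(grouping[s] for s in pm.sample_ids)
    region_counts: dict[frozenset[str], int] = {}
    for row in pm.matrix:
        region = frozenset(labels[row])
        if not region:
            continue
        region_counts[region] = region_counts.get(region, 0) + 1
    return VennPartition(region_counts=region_counts, groups=groups)


def group_specific_counts(vp: VennPartition) -> dict[str, int]:
    """Per-group counts of features detected only in that group.

    Returns the singleton-region count for every group in the partition's
    universe (0 when the region is empty); the values sum to the total
    number of single-group features.
    """
    return {
        g: vp.region_counts.get(frozenset({g}), 0) for g in sorted(vp.groups)
    }


def strain_specific_counts(pm: PresenceMatrix) -> dict[str, int]:
    """Per-sample counts of features present in exactly that one sample."""
    rowsums = pm.matrix.sum(axis=1)
    exclusive = pm.matrix & (rowsums == 1)[:, None]
    counts = exclusive.sum(axis=0)
    return {s: int(c) for s, c in zip(pm.sample_ids, counts)}


def uniqueness_isolate_correlation(
    specific_per_group: Mapping[str, float],
    isolates_per_group: Mapping[str, float],
) -> float:
    """Pearson correlation between per-group uniqueness and group size.

    Both mappings must share the same keys and contain at least three
    groups; zero variance in either vector makes the correlation undefined.
    """
    if set(specific_per_group) != set(isolates_per_group):
        raise ValueError("group key sets differ")
    keys = sorted(specific_per_group)
    if len(keys) < 3:
        raise ValueError("need at least 3 groups for a correlation")
    x = np.array([specific_per_group[k] for k in keys], dtype=float)
    y = np.array([isolates_per_group[k] for k in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def mass_filter_count(
    table: FeatureTable, feature_ids: Iterable[int], max_mz: float
) -> int:
    """Count listed features with precursor m/z strictly below ``max_mz``.

    The tabulated feature m/z stands in for the neutral mass, as is
    customary for singly protonated small molecules.
    """
    ids = set(feature_ids)
    known = set(table.feature_ids)
    unknown = ids - known
    if unknown:
        raise KeyError(f"unknown feature ids: {sorted(unknown)}")
    return sum(1 for f in table.features if f.feature_id in ids and f.mz < max_mz)


def reproduce_deposited_summary(
    quant_table_path,
    meta: Iterable[SampleMeta] | None = None,
    threshold: float = 0.0,
) -> dict[str, object]:
    """Recompute the cohort-level occurrence summary from a deposited table.

    Given the study's deposited quantification table (features x 60 extracts)
    and the packaged metadata, returns the deterministic set-algebra summary:
    total feature count, the all-phyla-shared count, the per-phylum and total
    single-phylum counts, per-extract strain-specific counts, and the number
    of all-phyla-shared features with precursor m/z < 300 Da.
    """
    from .data_io import load_study_metadata

    meta = list(meta) if meta is not None else load_study_metadata()
    table = read_quant_table(quant_table_path)
    pm = presence_matrix(table, meta, threshold=threshold)
    phylum_of = {m.extract_id: m.phylum for m in meta}
    vp = venn_partition(pm, phylum_of)
    per_phylum = group_specific_counts(vp)
    shared_ids = [
        fid
        for fid, row in zip(pm.feature_ids, pm.matrix)
        if frozenset(np.array([phylum_of[s] for s in pm.sample_ids])[row])
        == vp.groups
    ]
    return {
        "total_features": len(table),
        "all_phyla_shared": vp.region_counts.get(vp.groups, 0),
        "one_phylum_specific_total": sum(per_phylum.values()),
        "one_phylum_specific": per_phylum,
        "strain_specific": strain_specific_counts(pm),
        "shared_below_300": mass_filter_count(table, shared_ids, 300.0),
    }
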