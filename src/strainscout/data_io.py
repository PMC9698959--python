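"""Readers and writers for the formats the pipeline touches.

Units are Da for m/z and minutes for retention time throughout the package.

Supported formats:

* MZmine-style quantification tables (CSV with ``row ID``, ``row m/z``,
  ``row retention time`` and per-sample ``<name> Peak area`` columns), plus a
  plain dialect (``feature_id``, ``mz``, ``rt`` followed by sample columns).
* Mascot generic format (MGF) for feature MS/MS spectra, read through
  pyteomics and written by an in-package serializer.
* GraphML / TSV edge lists for molecular networks (Cytoscape-compatible).
* The packaged study-metadata table of the 60 bacterial isolates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Feature",
    "FeatureTable",
    "Spectrum",
    "SampleMeta",
    "FormatError",
    "IntegrityError",
    "read_quant_table",
    "write_quant_table",
    "read_mgf",
    "write_mgf",
    "load_study_metadata",
    "write_network",
    "read_network_graphml",
]


class FormatError(ValueError):
    """A file does not follow the expected dialect (e.g. missing column)."""


class IntegrityError(ValueError):
    """A file violates a uniqueness or consistency contract."""


@dataclass(frozen=True)
class Feature:
    """One LC-MS feature: a unique (m/z, retention time) pair with areas.

    Parameters
    ----------
    feature_id
        Integer key, unique within a table.
    mz
        Precursor mass-to-charge ratio in Da (> 0).
    rt
        Retention time in minutes (>= 0).
    areas
        Mapping sample id -> non-negative peak area. A missing sample means
        area 0 (the gap-filled MZmine convention).
    """

    feature_id: int
    mz: float
    rt: float
    areas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        if any(a < 0 for a in self.areas.values()):
            raise ValueError(f"feature {self.feature_id}: negative peak area")

    def area(self, sample_id: str) -> float:
        return float(self.areas.get(sample_id, 0.0))


@dataclass
class FeatureTable:
    """An ordered collection of features over an ordered list of samples."""

    features: list[Feature]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample ids in feature table")
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate feature ids in feature table")
        known = set(self.sample_ids)
        for f in self.features:
            extra = set(f.areas) - known
            if extra:
                raise IntegrityError(
                    f"feature {f.feature_id} has areas for unknown samples {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[int]:
        return [f.feature_id for f in self.features]

    def feature(self, feature_id: int) -> Feature:
        try:
            return self._index[feature_id]
        except AttributeError:
            self._index = {f.feature_id: f for f in self.features}
            return self._index[feature_id]

    def area_matrix(self) -> np.ndarray:
        """Dense features x samples peak-area matrix (row order = features)."""
        m = np.zeros((len(self.features), len(self.sample_ids)))
        col = {s: j for j, s in enumerate(self.sample_ids)}
        for i, f in enumerate(self.features):
            for s, a in f.areas.items():
                m[i, col[s]] = a
        return m


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum keyed by its feature id.

    ``peaks`` is an (n, 2) float array of (fragment m/z in Da, intensity),
    sorted by m/z ascending with non-negative intensities.
    """

    feature_id: int
    precursor_mz: float
    peaks: np.ndarray

    def __post_init__(self) -> None:
        pk = np.asarray(self.peaks, dtype=float)
        if pk.ndim != 2 or pk.shape[1] != 2:
            raise ValueError("peaks must be an (n, 2) array")
        if np.any(pk[:, 1] < 0):
            raise ValueError("negative peak intensity")
        if np.any(np.diff(pk[:, 0]) < 0):
            pk = pk[np.argsort(pk[:, 0], kind="stable")]
        object.__setattr__(self, "peaks", pk)

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.shape[0])

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one extract (sample) of the strain cohort."""

    extract_id: str
    strain_id: str
    phylum: str
    genus: str
    similarity_pct: float
    is_blank: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.similarity_pct <= 100:
            raise ValueError(
                f"extract {self.extract_id}: similarity_pct must be in (0, 100]"
            )


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------

_MZMINE_COLS = {"id": "row ID", "mz": "row m/z", "rt": "row retention time"}
_PLAIN_COLS = {"id": "feature_id", "mz": "mz", "rt": "rt"}
_AREA_SUFFIX = " Peak area"


def read_quant_table(path: str | Path, dialect: str = "mzmine") -> FeatureTable:
    """Read a feature quantification table exported from peak picking.

    Parameters
    ----------
    path
        CSV file. In the ``mzmine`` dialect the header must contain
        ``row ID``, ``row m/z``, ``row retention time`` and one or more
        ``<sample> Peak area`` columns; in the ``plain`` dialect
        ``feature_id``, ``mz``, ``rt`` followed by per-sample columns.
        Extra columns (e.g. blanks/controls or MZmine bookkeeping columns)
        are tolerated: only recognized columns are consumed.
    dialect
        ``"mzmine"`` (default) or ``"plain"``.

    Empty or missing area cells are read as 0.0 (gap-filled exports use 0
    for absence; the occurrence analytics rely on this convention).
    """
    if dialect not in ("mzmine", "plain"):
        raise ValueError(f"unknown quant-table dialect {dialect!r}")
    # round-trip float parsing so write -> read -> write is byte-stable
    df = pd.read_csv(path, float_precision="round_trip")
    cols = _MZMINE_COLS if dialect == "mzmine" else _PLAIN_COLS
    for key, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"quantification table is missing column {name!r}")
    if dialect == "mzmine":
        sample_cols = [c for c in df.columns if c.endswith(_AREA_SUFFIX)]
        sample_ids = [c[: -len(_AREA_SUFFIX)] for c in sample_cols]
    else:
        sample_cols = [c for c in df.columns if c not in cols.values()]
        sample_ids = list(sample_cols)
    if not sample_cols:
        raise FormatError("quantification table has no per-sample area column")

    ids = df[cols["id"]].astype(int)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise IntegrityError(f"duplicate feature ids in quantification table: {dupes}")

    areas = df[sample_cols].apply(pd.to_numeric, errors="coerce").fillna(0.0)
    features = []
    for i in range(len(df)):
        row_areas = {
            s: float(areas.iat[i, j])
            for j, s in enumerate(sample_ids)
            if areas.iat[i, j] != 0.0
        }
        features.append(
            Feature(
                feature_id=int(ids.iat[i]),
                mz=float(df[cols["mz"]].iat[i]),
                rt=float(df[cols["rt"]].iat[i]),
                areas=row_areas,
            )
        )
    return FeatureTable(features=features, sample_ids=sample_ids)


def write_quant_table(
    table: FeatureTable, path: str | Path, dialect: str = "mzmine"
) -> None:
    """Write a feature table in the dialect ``read_quant_table`` consumes."""
    if dialect not in ("mzmine", "plain"):
        raise ValueError(f"unknown quant-table dialect {dialect!r}")
    cols = _MZMINE_COLS if dialect == "mzmine" else _PLAIN_COLS
    suffix = _AREA_SUFFIX if dialect == "mzmine" else ""
    data = {
        cols["id"]: [f.feature_id for f in table.features],
        cols["mz"]: [f.mz for f in table.features],
        cols["rt"]: [f.rt for f in table.features],
    }
    for s in table.sample_ids:
        data[f"{s}{suffix}"] = [f.area(s) for f in table.features]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MGF spectra
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> dict[int, Spectrum]:
    """Read an MGF file into a map feature id -> :class:`Spectrum`.

    The feature key is taken from the ``FEATURE_ID`` header field, falling
    back to ``SCANS`` (both dialects occur in MZmine/GNPS exports); the
    precursor m/z comes from ``PEPMASS``. Blocks without a precursor or
    without any fragment peak are skipped with a warning; duplicate keys
    raise :class:`IntegrityError`.
    """
    spectra: dict[int, Spectrum] = {}
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for block in reader:
            params = block.get("params", {})
            key = params.get("feature_id", params.get("scans"))
            if key is None:
                warnings.warn("MGF block without FEATURE_ID/SCANS skipped")
                continue
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                warnings.warn(f"MGF block {key} without PEPMASS skipped")
                continue
            fid = int(key)
            mz = np.asarray(block["m/z array"], dtype=float)
            inten = np.asarray(block["intensity array"], dtype=float)
            if mz.size == 0:
                warnings.warn(f"MGF block {fid} without peaks skipped")
                continue
            if fid in spectra:
                raise IntegrityError(f"duplicate feature id {fid} in MGF file")
            spectra[fid] = Spectrum(
                feature_id=fid,
                precursor_mz=float(pepmass[0]),
                peaks=np.column_stack([mz, inten]),
            )
    return spectra


def write_mgf(spectra: Mapping[int, Spectrum] | Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with FEATURE_ID/PEPMASS headers.

    Peak m/z and intensities are printed with six decimals, which round-trips
    through :func:`read_mgf` to that precision.
    """
    if isinstance(spectra, Mapping):
        items = [spectra[k] for k in sorted(spectra)]
    else:
        items = sorted(spectra, key=lambda s: s.feature_id)
    with open(path, "w") as fh:
        for s in items:
            fh.write("BEGIN IONS\n")
            fh.write(f"FEATURE_ID={s.feature_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write("CHARGE=1+\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# Study metadata fixture
# ---------------------------------------------------------------------------


def load_study_metadata() -> list[SampleMeta]:
    """Load the packaged cohort table of the 60 bacterial isolates.

    One record per extract, with strain id, phylum, genus and 16S similarity
    (percent identity to the closest described relative).
    """
    ref = resources.files("strainscout").joinpath("data/study_isolates.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"extract_id": str})
    return [
        SampleMeta(
            extract_id=row.extract_id,
            strain_id=row.strain_id,
            phylum=row.phylum,
            genus=row.genus,
            similarity_pct=float(row.similarity_pct),
            is_blank=bool(row.is_blank),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------


def write_network(network, path: str | Path, format: str = "graphml") -> None:
    """Write a molecular network for Cytoscape (GraphML) or as a TSV edge list.

    Node attributes carried over: mz, rt, annotation level, class and
    provenance extracts; edge attributes: cosine score and matched-peak count.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    if format == "graphml":
        g = nx.Graph()
        for n, attrs in graph.nodes(data=True):
            clean = {
                k: (";".join(sorted(v)) if isinstance(v, (set, frozenset, list)) else v)
                for k, v in attrs.items()
                if v is not None
            }
            g.add_node(n, **clean)
        for a, b, attrs in graph.edges(data=True):
            g.add_edge(a, b, **{k: v for k, v in attrs.items() if v is not None})
        nx.write_graphml(g, str(path))
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tscore\tmatched_peaks\n")
            rows = sorted(graph.edges(data=True))
            for a, b, attrs in rows:
                fh.write(
                    f"{a}\t{b}\t{attrs.get('score', float('nan')):.6f}"
                    f"\t{attrs.get('matched_peaks', 0)}\n"
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Re-import a GraphML network with integer node ids."""
    g = nx.read_graphml(str(path))
    return nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
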