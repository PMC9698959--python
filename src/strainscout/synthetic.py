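"""Synthetic cohort generator with planted ground truth.

Emulates the data a peak-picking export produces for a multi-strain
bacterial cohort — a quantification table plus an MGF of feature MS/MS
spectra — with three planted occurrence strata mirroring the structure seen
in real cross-phylum metabolome surveys:

* core features, detected in at least one strain of every phylum;
* phylum-specific features, detected only within one phylum (in at least
  two of its strains, so they never masquerade as strain-specific — except
  in a single-strain phylum, where phylum-specific and strain-specific
  coincide by definition);
* strain-specific features, detected in exactly one extract.

Spectra come in planted spectral families: members of a family share a
fragment template (with m/z jitter and intensity noise), so molecular
networking should recover the family as one connected component. Remaining
features get independent random spectra and should stay singletons.
Fragment templates keep a minimum inter-peak spacing of three fragment
tolerances so that peak assignments are unambiguous.

Defaults are a ~1/5-scale rendition of a 60-strain, four-phylum cohort:
14 strains split 7/4/2/1 across phyla, with core/phylum/strain strata sized
at roughly 1/20 of the cohort-level feature counts. All randomness flows
from one seeded generator, so identical configurations yield byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import InHouseEntry, InSilicoCandidate
from .data_io import (
    Feature,
    FeatureTable,
    SampleMeta,
    Spectrum,
    write_mgf,
    write_quant_table,
)
from .similarity import LibraryEntry

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ConfigError",
    "generate",
    "make_library",
    "write_synthetic_dataset",
]

_PHYLA = ("Proteobacteria", "Bacteroidetes", "Actinobacteria", "Firmicutes")
_CLASSES = (
    "Carboxylic acids and derivatives",
    "Fatty acyls",
    "Indoles and derivatives",
    "Benzene and substituted derivatives",
    "Organooxygen compounds",
)


class ConfigError(ValueError):
    """The synthetic configuration is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of the synthetic cohort.

    Counts are per stratum; ``n_phylum_specific`` may be one int (same for
    every phylum) or a per-phylum sequence, ``n_strain_specific`` is per
    strain. ``mz_jitter_sd`` (Da) should stay at or below the fragment
    tolerance used downstream, ``intensity_noise_cv`` is the coefficient of
    variation of multiplicative intensity noise, and ``dropout_prob`` is the
    per-cell probability that a planted presence is lost (never applied to
    strain-specific features, and floored so core features keep one strain
    per phylum and phylum-specific features keep two strains).
    ``level_fractions`` are the planted shares of annotation levels 1/2/3.
    """

    n_phyla: int = 4
    strains_per_phylum: tuple[int, ...] = (7, 4, 2, 1)
    n_core_features: int = 38
    n_phylum_specific: tuple[int, ...] | int = (74, 43, 23, 4)
    n_strain_specific: int = 8
    n_spectral_families: int = 20
    family_size_range: tuple[int, int] = (3, 10)
    peak_count_range: tuple[int, int] = (6, 14)
    mz_range: tuple[float, float] = (150.0, 1000.0)
    rt_range: tuple[float, float] = (0.5, 14.0)
    mz_jitter_sd: float = 0.005
    intensity_noise_cv: float = 0.1
    dropout_prob: float = 0.1
    level_fractions: tuple[float, float, float] = (0.006, 0.066, 0.092)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phyla < 1 or self.n_phyla > len(_PHYLA):
            raise ConfigError(f"n_phyla must be in [1, {len(_PHYLA)}]")
        if len(self.strains_per_phylum) != self.n_phyla:
            raise ConfigError("strains_per_phylum length must equal n_phyla")
        if any(s < 1 for s in self.strains_per_phylum):
            raise ConfigError("each phylum needs at least one strain")
        if min(self.n_core_features, self.n_strain_specific, self.n_spectral_families) < 0:
            raise ConfigError("feature counts must be >= 0")
        if self.mz_jitter_sd < 0:
            raise ConfigError("mz_jitter_sd must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if self.family_size_range[0] < 2 or self.family_size_range[0] > self.family_size_range[1]:
            raise ConfigError("family_size_range must be an ordered pair with min >= 2")
        if self.peak_count_range[0] < 1 or self.peak_count_range[0] > self.peak_count_range[1]:
            raise ConfigError("peak_count_range must be an ordered pair with min >= 1")
        if sum(self.level_fractions) > 1:
            raise ConfigError("level_fractions must sum to at most 1")
        n = self.total_features
        if self.n_spectral_families * self.family_size_range[0] > n:
            raise ConfigError("spectral family sizes exceed the feature count")

    @property
    def phylum_specific_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_phylum_specific, int):
            return (self.n_phylum_specific,) * self.n_phyla
        if len(self.n_phylum_specific) != self.n_phyla:
            raise ConfigError("n_phylum_specific length must equal n_phyla")
        return tuple(self.n_phylum_specific)

    @property
    def total_strains(self) -> int:
        return sum(self.strains_per_phylum)

    @property
    def total_features(self) -> int:
        return (
            self.n_core_features
            + sum(self.phylum_specific_counts)
            + self.n_strain_specific * self.total_strains
        )


@dataclass
class GroundTruth:
    """Planted design of a generated cohort.

    stratum : feature id -> "core" | "phylum:<name>" | "strain:<extract>"
    family_of : feature id -> spectral family id, or None for singletons
    level_of : feature id -> planted annotation level (1/2/3) or None
    presence : realized boolean detection design (features x samples)
    feature_rt : feature id -> retention time (minutes)
    seed : the generator seed the cohort was drawn with
    """

    stratum: dict[int, str]
    family_of: dict[int, int | None]
    level_of: dict[int, int | None]
    presence: pd.DataFrame
    feature_rt: dict[int, float]
    seed: int

    def expected_strain_specific_counts(self) -> dict[str, int]:
        """Per-extract counts of features planted in exactly that extract."""
        rowsums = self.presence.to_numpy().sum(axis=1)
        excl = self.presence.to_numpy() & (rowsums == 1)[:, None]
        return {
            s: int(c) for s, c in zip(self.presence.columns, excl.sum(axis=0))
        }

    def expected_region(self, phylum_of: Mapping[str, str]) -> dict[int, frozenset[str]]:
        """Feature id -> set of phyla the feature was planted in."""
        labels = np.array([phylum_of[s] for s in self.presence.columns])
        return {
            fid: frozenset(labels[row])
            for fid, row in zip(self.presence.index, self.presence.to_numpy())
        }

    def family_labels(self) -> dict[int, str]:
        """Cluster labels for family-recovery scoring (singletons unique)."""
        return {
            fid: (f"family:{fam}" if fam is not None else f"singleton:{fid}")
            for fid, fam in self.family_of.items()
        }

    def expected_level_counts(self) -> dict[int | None, int]:
        counts: dict[int | None, int] = {1: 0, 2: 0, 3: 0, None: 0}
        for lvl in self.level_of.values():
            counts[lvl] += 1
        return counts


def _spaced_fragments(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_spacing: float
) -> np.ndarray:
    """Draw n fragment m/z values in [lo, hi] with a minimum spacing."""
    if hi - lo < (n - 1) * min_spacing:
        raise ConfigError("m/z range too narrow for the requested peak count")
    for _ in range(1000):
        mz = np.sort(rng.uniform(lo, hi, size=n))
        if n < 2 or np.min(np.diff(mz)) >= min_spacing:
            return mz
    raise RuntimeError("could not place fragments with the requested spacing")


def _dropout_with_floor(
    rng: np.random.Generator,
    row: np.ndarray,
    prob: float,
    floor_groups: Sequence[np.ndarray],
    min_keep: int,
) -> np.ndarray:
    """Apply i.i.d. dropout but keep >= min_keep presences per floor group."""
    out = row.copy()
    if prob > 0:
        drop = rng.random(row.size) < prob
        out &= ~drop
    for group in floor_groups:
        kept = out[group].sum()
        if kept < min_keep:
            planted = [g for g in group if row[g]]
            need = min(min_keep, len(planted)) - kept
            candidates = [g for g in planted if not out[g]]
            if need > 0 and candidates:
                revive = rng.choice(len(candidates), size=int(need), replace=False)
                for r in revive:
                    out[candidates[int(r)]] = True
    return out


def generate(
    config: SyntheticConfig | None = None,
) -> tuple[FeatureTable, dict[int, Spectrum], list[SampleMeta], GroundTruth]:
    """Generate the cohort: quant table, spectra, metadata and ground truth."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    fragment_tol = 0.02  # matches the default similarity tolerance downstream
    min_spacing = 3 * fragment_tol

    # --- samples -----------------------------------------------------------
    phyla = _PHYLA[: cfg.n_phyla]
    meta: list[SampleMeta] = []
    sample_phylum: list[str] = []
    for p_idx, (phylum, n_strains) in enumerate(zip(phyla, cfg.strains_per_phylum)):
        for s_idx in range(n_strains):
            extract = f"E{len(meta) + 1:02d}"
            meta.append(
                SampleMeta(
                    extract_id=extract,
                    strain_id=f"SYN{p_idx + 1}_{s_idx + 1}",
                    phylum=phylum,
                    genus=f"Synthomonas{p_idx + 1}",
                    similarity_pct=float(np.round(rng.uniform(92.0, 100.0), 2)),
                )
            )
            sample_phylum.append(phylum)
    sample_ids = [m.extract_id for m in meta]
    n_samples = len(sample_ids)
    phylum_cols = {
        p: np.array([j for j, q in enumerate(sample_phylum) if q == p])
        for p in phyla
    }

    # --- feature strata and presence design --------------------------------
    n_features = cfg.total_features
    feature_ids = list(range(1, n_features + 1))
    mz = rng.uniform(*cfg.mz_range, size=n_features)
    rt = rng.uniform(*cfg.rt_range, size=n_features)

    stratum: dict[int, str] = {}
    presence = np.zeros((n_features, n_samples), dtype=bool)
    phylum_floors = [phylum_cols[p] for p in phyla]
    i = 0
    for _ in range(cfg.n_core_features):
        fid = feature_ids[i]
        stratum[fid] = "core"
        row = np.ones(n_samples, dtype=bool)
        presence[i] = _dropout_with_floor(
            rng, row, cfg.dropout_prob, phylum_floors, min_keep=1
        )
        i += 1
    for phylum, n_spec in zip(phyla, cfg.phylum_specific_counts):
        cols = phylum_cols[phylum]
        for _ in range(n_spec):
            fid = feature_ids[i]
            stratum[fid] = f"phylum:{phylum}"
            row = np.zeros(n_samples, dtype=bool)
            if len(cols) == 1:
                # sole strain of its phylum: coincides with strain-specific
                row[cols[0]] = True
                presence[i] = row
            else:
                k = int(rng.integers(2, len(cols) + 1))
                chosen = rng.choice(cols, size=k, replace=False)
                row[chosen] = True
                presence[i] = _dropout_with_floor(
                    rng, row, cfg.dropout_prob, [cols], min_keep=2
                )
            i += 1
    for j, m in enumerate(meta):
        for _ in range(cfg.n_strain_specific):
            fid = feature_ids[i]
            stratum[fid] = f"strain:{m.extract_id}"
            presence[i, j] = True  # dropout never applied to specific features
            i += 1

    # --- peak areas ---------------------------------------------------------
    base_area = 10.0 ** rng.uniform(4.3, 5.85, size=n_features)
    noise = rng.normal(1.0, cfg.intensity_noise_cv, size=(n_features, n_samples))
    areas = presence * base_area[:, None] * np.maximum(noise, 0.1)

    # --- spectral families and spectra --------------------------------------
    family_of: dict[int, int | None] = {fid: None for fid in feature_ids}
    pool = rng.permutation(n_features)
    pos = 0
    members_of: dict[int, list[int]] = {}
    for fam in range(cfg.n_spectral_families):
        size = int(rng.integers(cfg.family_size_range[0], cfg.family_size_range[1] + 1))
        size = min(size, n_features - pos)
        if size < 2:
            break
        members = [int(pool[pos + k]) for k in range(size)]
        pos += size
        members_of[fam] = members
        for m_idx in members:
            family_of[feature_ids[m_idx]] = fam

    spectra: dict[int, Spectrum] = {}
    for fam, members in members_of.items():
        lo = 50.0
        hi = min(mz[m] for m in members) - 20.0
        n_peaks = int(rng.integers(cfg.peak_count_range[0], cfg.peak_count_range[1] + 1))
        template_mz = _spaced_fragments(rng, n_peaks, lo, hi, min_spacing)
        template_int = rng.uniform(0.1, 1.0, size=n_peaks)
        for m_idx in members:
            fid = feature_ids[m_idx]
            frag_mz = template_mz + rng.normal(0.0, cfg.mz_jitter_sd, size=n_peaks)
            frag_int = template_int * np.maximum(
                rng.normal(1.0, cfg.intensity_noise_cv, size=n_peaks), 0.05
            )
            spectra[fid] = Spectrum(
                feature_id=fid,
                precursor_mz=float(mz[m_idx]),
                peaks=np.column_stack([frag_mz, frag_int]),
            )
    for m_idx in range(n_features):
        fid = feature_ids[m_idx]
        if fid in spectra:
            continue
        n_peaks = int(rng.integers(cfg.peak_count_range[0], cfg.peak_count_range[1] + 1))
        frag_mz = _spaced_fragments(rng, n_peaks, 50.0, mz[m_idx] - 20.0, min_spacing)
        frag_int = rng.uniform(0.1, 1.0, size=n_peaks)
        spectra[fid] = Spectrum(
            feature_id=fid,
            precursor_mz=float(mz[m_idx]),
            peaks=np.column_stack([frag_mz, frag_int]),
        )

    # --- planted annotation levels ------------------------------------------
    level_of: dict[int, int | None] = {fid: None for fid in feature_ids}
    n1, n2, n3 = (int(round(f * n_features)) for f in cfg.level_fractions)
    shuffled = rng.permutation(n_features)
    for k in range(n1):
        level_of[feature_ids[int(shuffled[k])]] = 1
    for k in range(n1, n1 + n2):
        level_of[feature_ids[int(shuffled[k])]] = 2
    for k in range(n1 + n2, n1 + n2 + n3):
        level_of[feature_ids[int(shuffled[k])]] = 3

    # --- assemble ------------------------------------------------------------
    features = []
    for m_idx, fid in enumerate(feature_ids):
        row_areas = {
            sample_ids[j]: float(areas[m_idx, j])
            for j in range(n_samples)
            if presence[m_idx, j]
        }
        features.append(
            Feature(feature_id=fid, mz=float(mz[m_idx]), rt=float(rt[m_idx]), areas=row_areas)
        )
    table = FeatureTable(features=features, sample_ids=list(sample_ids))
    truth = GroundTruth(
        stratum=stratum,
        family_of=family_of,
        level_of=level_of,
        presence=pd.DataFrame(presence, index=feature_ids, columns=sample_ids),
        feature_rt={fid: float(rt[m]) for m, fid in enumerate(feature_ids)},
        seed=cfg.seed,
    )
    return table, spectra, meta, truth


def make_library(
    truth: GroundTruth,
    spectra: Mapping[int, Spectrum],
    seed: int | None = None,
) -> tuple[list[InHouseEntry], list[LibraryEntry], dict[int, list[InSilicoCandidate]]]:
    """Build annotation inputs matching the planted levels.

    Features planted at level 1 get in-house standards (precursor + RT +
    spectrum); level 2 get external-library entries; level 3 get in-silico
    candidates drawn to pass the score filter (CSI < -150, Zodiac > 0.60),
    alongside a failing decoy candidate. Half of the unknown features get
    failing candidates only, the rest nothing.
    """
    rng = np.random.default_rng(truth.seed + 10_007 if seed is None else seed)
    inhouse: list[InHouseEntry] = []
    external: list[LibraryEntry] = []
    insilico: dict[int, list[InSilicoCandidate]] = {}

    def _passing(fid: int) -> InSilicoCandidate:
        return InSilicoCandidate(
            feature_id=fid,
            formula=f"C{rng.integers(5, 40)}H{rng.integers(8, 60)}NO{rng.integers(1, 9)}",
            structure=f"struct_{fid}",
            csi_score=float(rng.uniform(-300.0, -155.0)),
            zodiac_score=float(rng.uniform(0.65, 0.99)),
            class_label=str(rng.choice(_CLASSES)),
        )

    def _failing(fid: int, tag: str) -> InSilicoCandidate:
        if rng.random() < 0.5:
            csi, zodiac = float(rng.uniform(-140.0, -50.0)), float(rng.uniform(0.65, 0.99))
        else:
            csi, zodiac = float(rng.uniform(-300.0, -155.0)), float(rng.uniform(0.0, 0.55))
        return InSilicoCandidate(
            feature_id=fid,
            formula=f"C{rng.integers(5, 40)}H{rng.integers(8, 60)}O{rng.integers(1, 9)}",
            structure=f"decoy_{tag}_{fid}",
            csi_score=csi,
            zodiac_score=zodiac,
            class_label=str(rng.choice(_CLASSES)),
        )

    for fid in sorted(truth.level_of):
        lvl = truth.level_of[fid]
        s = spectra[fid]
        if lvl == 1:
            inhouse.append(
                InHouseEntry(
                    name=f"standard_{fid}",
                    precursor_mz=s.precursor_mz,
                    rt=truth.feature_rt[fid],
                    spectrum=s,
                    class_label=str(rng.choice(_CLASSES)),
                )
            )
        elif lvl == 2:
            external.append(
                LibraryEntry(
                    name=f"library_{fid}",
                    spectrum=s,
                    class_label=str(rng.choice(_CLASSES)),
                )
            )
        elif lvl == 3:
            insilico[fid] = [_passing(fid), _failing(fid, "alt")]
        else:
            if rng.random() < 0.5:
                insilico[fid] = [_failing(fid, "unk")]
    return inhouse, external, insilico


def write_synthetic_dataset(
    outdir: str | Path, config: SyntheticConfig | None = None
) -> dict[str, Path]:
    """Generate a cohort and write it in the dialects the readers consume.

    Writes ``quant_table.csv`` (MZmine dialect), ``spectra.mgf``,
    ``metadata.tsv`` and ``ground_truth.json``; returns the paths.
    """
    cfg = config or SyntheticConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, spectra, meta, truth = generate(cfg)
    paths = {
        "quant_table": outdir / "quant_table.csv",
        "mgf": outdir / "spectra.mgf",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_quant_table(table, paths["quant_table"])
    write_mgf(spectra, paths["mgf"])
    pd.DataFrame(
        [
            {
                "extract_id": m.extract_id,
                "strain_id": m.strain_id,
                "phylum": m.phylum,
                "genus": m.genus,
                "similarity_pct": m.similarity_pct,
                "is_blank": int(m.is_blank),
            }
            for m in meta
        ]
    ).to_csv(paths["metadata"], sep="\t", index=False)
    truth_json = {
        "seed": truth.seed,
        "config": asdict(cfg),
        "stratum": {str(k): v for k, v in truth.stratum.items()},
        "family_of": {str(k): v for k, v in truth.family_of.items()},
        "level_of": {str(k): v for k, v in truth.level_of.items()},
    }
    paths["ground_truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return paths
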