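"""Dereplication cascade: level gates, precedence, class propagation."""

import numpy as np
import pytest

from strainscout import (
    Annotation,
    AnnotationParams,
    InHouseEntry,
    InSilicoCandidate,
    LibraryEntry,
    Spectrum,
    annotation_summary,
    cascade,
    level1_match,
    level2_match,
    level3_filter,
    propagate_classes,
)
from strainscout.annotation import UNCLASSIFIED
from strainscout.data_io import Feature
from strainscout.network import Edge, MolecularNetwork, NetworkParams

import networkx as nx

from conftest import random_spectrum


def _feature(fid, mz, rt):
    return Feature(feature_id=fid, mz=mz, rt=rt, areas={"S1": 1.0})


def _standard(s, rt, name="std"):
    return InHouseEntry(name=name, precursor_mz=s.precursor_mz, rt=rt, spectrum=s)


class TestLevel1:
    def test_exact_standard_replica_is_level1(self):
        rng = np.random.default_rng(0)
        s = random_spectrum(rng, feature_id=1, n_peaks=6, precursor=400.0)
        ann = level1_match(_feature(1, 400.0, 5.0), s, [_standard(s, rt=5.0)])
        assert ann is not None and ann.level == 1 and ann.source == "inhouse"

    def test_retention_time_gate(self):
        rng = np.random.default_rng(1)
        s = random_spectrum(rng, feature_id=1, n_peaks=6, precursor=400.0)
        ann = level1_match(_feature(1, 400.0, 6.0), s, [_standard(s, rt=5.0)])
        assert ann is None  # delta RT 1.0 min > 0.2 min tolerance

    def test_precursor_gate(self):
        rng = np.random.default_rng(2)
        s = random_spectrum(rng, feature_id=1, n_peaks=6, precursor=400.0)
        std = InHouseEntry("std", 400.5, 5.0, s)
        assert level1_match(_feature(1, 400.0, 5.0), s, [std]) is None

    def test_jittered_standards_recovered_within_tolerances(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(20):
            s = random_spectrum(rng, feature_id=i, n_peaks=8, precursor=500.0 + i)
            jittered = Spectrum(
                i,
                s.precursor_mz + float(rng.uniform(-0.008, 0.008)),
                np.column_stack(
                    [s.mz + rng.uniform(-0.008, 0.008, s.n_peaks),
                     s.intensities * rng.uniform(0.9, 1.1, s.n_peaks)]
                ),
            )
            std = _standard(s, rt=5.0)
            ann = level1_match(
                _feature(i, jittered.precursor_mz, 5.0 + float(rng.uniform(-0.1, 0.1))),
                jittered,
                [std],
            )
            hits += ann is not None
        assert hits == 20


class TestLevel2:
    def test_library_replica_without_rt_is_level2(self):
        rng = np.random.default_rng(4)
        s = random_spectrum(rng, feature_id=1, n_peaks=6)
        ann = level2_match(s, [LibraryEntry("cmpd", s)])
        assert ann is not None and ann.level == 2 and ann.source == "spectral_library"

    def test_two_matched_peaks_rejected(self):
        # perfect score on 2 shared peaks still fails the 3-peak gate
        a = Spectrum(1, 500.0, np.array([[100.0, 1.0], [200.0, 1.0]]))
        ann = level2_match(a, [LibraryEntry("cmpd", a)])
        assert ann is None

    def test_decoy_library_hit_rate_low(self):
        rng = np.random.default_rng(5)
        queries = [random_spectrum(rng, feature_id=i, n_peaks=8) for i in range(40)]
        # decoys share the precursor (pass the gate) but carry shuffled peaks
        decoys = [
            LibraryEntry(
                f"decoy_{i}",
                Spectrum(
                    1000 + i,
                    q.precursor_mz,
                    np.column_stack(
                        [np.sort(rng.uniform(50, 400, q.n_peaks)),
                         rng.permutation(q.intensities)]
                    ),
                ),
            )
            for i, q in enumerate(queries)
        ]
        hits = sum(level2_match(q, decoys) is not None for q in queries)
        assert hits <= 2  # <= 5 % of 40


class TestLevel3:
    def _cand(self, csi, zodiac, fid=1, structure="s1"):
        return InSilicoCandidate(
            feature_id=fid, formula="C6H12O6", structure=structure,
            csi_score=csi, zodiac_score=zodiac,
        )

    @pytest.mark.parametrize(
        "csi,zodiac,accepted",
        [(-160.0, 0.70, True), (-140.0, 0.90, False), (-160.0, 0.60, False)],
    )
    def test_score_filter_boundaries(self, csi, zodiac, accepted):
        ann = level3_filter([self._cand(csi, zodiac)])
        assert (ann is not None) == accepted
        if accepted:
            assert ann.level == 3 and ann.source == "insilico"

    def test_best_passing_candidate_selected(self):
        cands = [
            self._cand(-200.0, 0.70, structure="weak"),
            self._cand(-180.0, 0.95, structure="strong"),
            self._cand(-120.0, 0.99, structure="failing"),
        ]
        ann = level3_filter(cands)
        assert ann.name == "strong"


class TestCascade:
    def test_inhouse_takes_precedence_over_external(self):
        rng = np.random.default_rng(6)
        s = random_spectrum(rng, feature_id=1, n_peaks=6, precursor=400.0)
        anns = cascade(
            [_feature(1, 400.0, 5.0)],
            {1: s},
            inhouse=[_standard(s, rt=5.0)],
            external=[LibraryEntry("ext", s)],
        )
        assert anns[0].level == 1

    def test_no_inputs_means_all_unknown(self):
        rng = np.random.default_rng(7)
        features = [_feature(i, 300.0 + i, 2.0) for i in range(1, 6)]
        spectra = {i: random_spectrum(rng, feature_id=i) for i in range(1, 6)}
        anns = cascade(features, spectra)
        assert all(a.level is None for a in anns)
        assert annotation_summary(anns)["pct_unknown"] == 100.0

    def test_levels_partition_feature_set(self, noiseless_cohort, annotation_inputs):
        table, spectra, _, _ = noiseless_cohort
        inhouse, external, insilico = annotation_inputs
        anns = cascade(table.features, spectra, inhouse, external, insilico)
        s = annotation_summary(anns)
        assert s["n_level1"] + s["n_level2"] + s["n_level3"] + s["n_unknown"] == len(table)

    def test_output_invariant_to_feature_order(self, noiseless_cohort, annotation_inputs):
        table, spectra, _, _ = noiseless_cohort
        inhouse, external, insilico = annotation_inputs
        fwd = cascade(table.features, spectra, inhouse, external, insilico)
        rev = cascade(list(reversed(table.features)), spectra, inhouse, external, insilico)
        assert fwd == rev

    def test_tightening_thresholds_never_adds_annotations(
        self, noiseless_cohort, annotation_inputs
    ):
        table, spectra, _, _ = noiseless_cohort
        inhouse, external, insilico = annotation_inputs
        loose = annotation_summary(
            cascade(table.features, spectra, inhouse, external, insilico)
        )
        tight = annotation_summary(
            cascade(
                table.features, spectra, inhouse, external, insilico,
                p=AnnotationParams(lib_min_score=0.9, zodiac_min=0.9, rt_tol=0.05),
            )
        )
        for key in ("n_level1", "n_level2", "n_level3"):
            assert tight[key] <= loose[key]


class TestPropagateClasses:
    def _net(self, *families):
        g = nx.Graph()
        nets = MolecularNetwork(graph=g, params=NetworkParams())
        for fam in families:
            members = sorted(fam)
            for a, b in zip(members, members[1:]):
                g.add_edge(a, b, score=0.9, matched_peaks=5)
        nets.refresh_components()
        return nets

    def _ann(self, fid, cls):
        return Annotation(feature_id=fid, level=2, name=f"c{fid}",
                          source="spectral_library", class_label=cls)

    def test_majority_class_wins(self):
        net = self._net({1, 2, 3, 4})
        anns = [self._ann(i, "Indoles and derivatives") for i in (1, 2, 3)]
        assert propagate_classes(net, anns) == {0: "Indoles and derivatives"}

    def test_tie_resolves_to_unclassified(self):
        net = self._net({1, 2, 3})
        anns = [self._ann(1, "A"), self._ann(2, "B")]
        assert propagate_classes(net, anns) == {0: UNCLASSIFIED}

    def test_unannotated_family_is_unclassified(self):
        net = self._net({1, 2, 3})
        assert propagate_classes(net, []) == {0: UNCLASSIFIED}
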