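# strainscout

Prioritizing "talented" bacterial producer strains from untargeted
LC-MS/MS metabolomics.

## The scientific problem

Microbial natural-product discovery screens dozens of bacterial isolates at
once, but only a few strains are worth scaling up for compound isolation.
Untargeted LC-MS/MS metabolomics turns each strain extract into a list of
*features* — unique (m/z, retention time) pairs with per-sample peak areas —
and the question becomes: **which strains produce chemistry that no other
strain in the cohort produces, and how much of it is unknown to the
libraries?**

`strainscout` implements the downstream half of that workflow:

1. **Occurrence analysis** — presence/absence calls from the quantification
   table, Venn partitions of feature detections across phyla,
   strain-specific feature counts (features present in exactly one
   extract), and the correlation between per-phylum chemical uniqueness
   and isolate counts.
2. **Spectral similarity** — a from-scratch modified-cosine score: fragment
   peaks may match directly or offset by the precursor mass difference,
   over a one-to-one peak assignment with square-root intensity weighting.
3. **Molecular networking** — feature-based molecular networking (FBMN):
   edges above a cosine/matched-peak threshold, mutual top-K pruning, and a
   family-size cap; connected components with ≥ 2 nodes are *molecular
   families*, the rest are *singletons*.
4. **Annotation** — a three-level dereplication cascade: level 1 via
   in-house standards (precursor + retention time + MS/MS), level 2 via an
   external spectral library, level 3 via in-silico candidate filtering
   (CSI score < −150 and Zodiac score > 0.60), with chemical-class
   propagation across families.
5. **Prioritization** — per-strain reports combining strain-specific
   counts, unknown fraction, strain-exclusive families and 16S taxonomy
   flags, ranked into a follow-up shortlist.
6. **Synthetic cohort generator** — a seeded generator with planted ground
   truth (occurrence strata, spectral families, annotation levels) used to
   validate every stage end to end.

The package ships the metadata of a real 60-isolate, four-phylum marine
bacterial cohort as its reference strain table.

## Running the tests

```bash
python -m pytest -q tests/
```

One acceptance test (`test_deposited_cohort_set_algebra_reproduced`)
requires the deposited full-cohort quantification table at
`data/MSV000088967/quant_table.csv`; it fails with a clear message when
that file is absent (it is too large to ship and cannot be downloaded in
an offline environment). All other tests are self-contained.

## Worked example

Generate a synthetic 14-strain cohort (294 features across four phyla) and
run the full pipeline:

```bash
strainscout synth --out demo/data --seed 7
strainscout all \
    --quant demo/data/quant_table.csv \
    --mgf demo/data/spectra.mgf \
    --meta demo/data/metadata.tsv \
    --out demo/out
```

The `all` command prints the run summary:

```json
{
 "annotation": {
  "n_level1": 0, "n_level2": 0, "n_level3": 0, "n_unknown": 294,
  "pct_unknown": 100.0, "total": 294
 },
 "network": {
  "edges": 332, "families": 20, "nodes": 294,
  "singleton_fraction": 0.5952380952380952, "singletons": 175
 }
}
```

(no annotation libraries were supplied, so every feature is unknown), and
writes `venn_regions.tsv`, `strain_specific.tsv`, `annotations.tsv`,
`network.graphml`, `families.tsv`, `reports.tsv`, `ranked.tsv` and a
`manifest.json` recording all parameters and input hashes. The ranking
puts the sole Firmicutes strain first — it owns the most strain-specific
features:

```
extract_id  total_features  specific_features  pct_unknown
E14         50              12                 100.0
E01         78              8                  100.0
E02         89              8                  100.0
```

and the Venn partition recovers the planted occurrence design exactly
(38 core features shared by all four phyla; 130/75/39/12 detected in a
single phylum):

```
region                                                   count
Actinobacteria                                           39
Bacteroidetes                                            75
Firmicutes                                               12
Proteobacteria                                           130
Actinobacteria&Bacteroidetes&Firmicutes&Proteobacteria   38
```

From Python, the modified cosine recognizes a homolog pair whose fragments
are offset by the 14 Da precursor difference:

```python
>>> import numpy as np
>>> from strainscout import Spectrum, modified_cosine
>>> a = Spectrum(1, 400.0, np.array([[100.0, 1.0], [150.0, 0.6], [220.0, 0.3]]))
>>> b = Spectrum(2, 414.0, np.array([[114.0, 1.0], [164.0, 0.6], [234.0, 0.3]]))
>>> modified_cosine(a, b)
SimilarityResult(score=0.9999999999999997, n_matched=3)
```

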