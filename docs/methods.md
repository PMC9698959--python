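# Methods

This note documents the model implemented by `strainscout`, every
parameter with its unit, default and rationale, what the synthetic
generator emulates, the numerical choices, and the limitations. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` actually compute.

## 1. Data model

A *feature* is a unique (m/z, retention time) pair produced by
LC-MS/MS peak picking, carrying a peak area per sample. Inputs are:

* a quantification table (MZmine dialect: `row ID`, `row m/z`,
  `row retention time`, `<sample> Peak area` columns; or a plain dialect
  with `feature_id`, `mz`, `rt`). Missing cells are read as area 0; extra
  columns are tolerated; duplicated feature ids are an integrity error.
  Floats are parsed with round-trip precision so that
  write → read → write is byte-stable.
* an MGF file of feature MS/MS spectra, keyed by `FEATURE_ID` (falling
  back to `SCANS`), with the precursor m/z from `PEPMASS`. Blocks without
  precursor or peaks are skipped with a warning.
* a sample-metadata table (extract id, strain id, phylum, genus, 16S
  similarity %, blank flag). The packaged default is the strain table of a
  real 60-isolate marine cohort spanning Proteobacteria (35),
  Bacteroidetes (16), Actinobacteria (8) and Firmicutes (1).

## 2. Occurrence analysis

Presence is defined as `area > presence_threshold` (default **0**: any
detected area counts, matching the convention that a picked feature is a
detection). Blank samples are excluded before any counting.

* **Venn partition**: each feature present anywhere is assigned to the set
  of phyla with ≥ 1 detecting strain; region counts partition the detected
  features exactly (checked against brute-force row enumeration).
* **Strain-specific features**: row sum over non-blank samples equals 1.
* **Uniqueness–isolate correlation**: Pearson r (scipy) between the
  per-group single-group feature counts and per-group isolate counts;
  requires ≥ 3 groups and non-zero variance on both sides.
* **Mass filter**: strictly `m/z < 300 Da` (the boundary value is
  excluded), used to count small shared metabolites.

## 3. Modified cosine (reimplemented)

Peaks within `precursor_window` (default **17 Da**) of the precursor are
removed first, so the precursor ion and its immediate losses cannot
dominate the score. Intensities are raised to `intensity_power`
(default **0.5**, the GNPS square-root convention that tames
base-peak dominance) and L2-normalized.

A peak pair (i, j) is a match candidate if `|mz_a[i] − mz_b[j]| ≤
fragment_tol` (default **0.02 Da**, high-resolution instrument accuracy)
either directly or after subtracting the signed precursor mass difference.
Candidates are assigned one-to-one greedily by descending weight product
(ties broken by smaller m/z); the score is the sum of matched weight
products. By Cauchy–Schwarz the score is ≤ 1 and self-similarity of a
spectrum with spaced peaks is exactly 1. On random 4-peak spectra with
peak spacing ≥ 3 tolerances the greedy assignment equals an exhaustive
maximum-weight matching oracle in 1,000/1,000 draws
(`modified_cosine_greedy_exact_agreement` in the acceptance output), and
the implementation agrees with `matchms.ModifiedCosine` to 1e-6 in the
test suite. Greedy assignment is O(c log c) in the number of candidate
pairs versus exponential for exact matching; the spacing argument is why
the cheap algorithm is exact in practice.

## 4. Molecular networking

Edges require `score ≥ min_cosine` (default **0.5**) and
`n_matched ≥ min_matched_peaks` (default **4**) — both bounds inclusive.
Then mutual top-K pruning (default `top_k` = **10**): an edge survives
only if each endpoint ranks it among its K best edges (by score, ties by
neighbor id). Finally components are capped at `max_family_size`
(default **100**) by repeatedly deleting the globally lowest-scoring edge
inside any oversized component (ties by canonical edge id), which only
refines the partition and is idempotent. Components with ≥ 2 nodes are
molecular families; isolated nodes are singletons. The defaults are the
standard FBMN workflow settings for high-resolution data.

*Family exclusivity*: a family is exclusive to an extract when every
member node is detected only in that extract; the fraction of
single-extract nodes is reported per family.

## 5. Annotation cascade

Three confidence levels with strict precedence 1 > 2 > 3:

* **Level 1** (in-house standard): precursor within `precursor_tol`
  (**0.02 Da**), retention time within `rt_tol` (**0.2 min**), and
  spectral match with `score ≥ lib_min_score` (**0.6**) and
  `≥ lib_min_peaks` (**3**) matched peaks.
* **Level 2** (external spectral library): same spectral gates, no
  retention time (external libraries do not share the chromatography).
* **Level 3** (in-silico): a candidate passes iff `csi_score < −150`
  (structure-prediction score; more negative is accepted here) **and**
  `zodiac_score > 0.60` (formula confidence), both strict; the best
  passing candidate is chosen by Zodiac score.

Unmatched features are *unknown*. Chemical classes propagate to families
by majority vote among annotated members; ties and unannotated families
are `unclassified`.

## 6. Prioritization

Each non-blank extract gets a report: total detected features,
strain-specific count, % unknown among its detected features, exclusive
families, and flags: `specific_ge_threshold`
(`specific_threshold` = **80** features, the cut through the per-extract
distribution of the reference cohort), `unknown_ge_threshold`
(**80 %**), `novel_taxon` (16S similarity < **98.7 %**, the species
demarcation) and `novel_genus` (< **95 %**). The default ranking is
lexicographic — specific count, then % unknown, then exclusive-family
count, extract id as the deterministic tiebreak — with an optional
weighted-sum mode.

## 7. Synthetic cohort generator

The generator emulates the peak-picking export of a cross-phylum strain
cohort at desk scale. Defaults are this package's own choice of study
conditions: 14 strains split 7/4/2/1 over four phyla (the same shape,
at ~1/4 the strain count, as the reference cohort), and feature strata at
~1/20 of the cohort-level counts — 38 core features, 74/43/23/4
phylum-specific, 8 strain-specific per strain (294 features total).

* **Occurrence strata**: core features are planted in every strain,
  phylum-specific in ≥ 2 strains of one phylum, strain-specific in
  exactly one extract. Dropout (`dropout_prob` = **0.1**) deletes planted
  presences but is floored so core features keep ≥ 1 strain per phylum and
  phylum-specific features keep ≥ 2 strains — hence measured Venn regions
  and strain-specific counts equal the planted design even under dropout.
  In a single-strain phylum, phylum-specific and strain-specific coincide
  by definition (mirroring the sole Firmicutes isolate of the reference
  cohort).
* **Spectra**: 20 planted spectral families (3–10 members) share a
  fragment template with m/z jitter (`mz_jitter_sd` = **0.005 Da**, ¼ of
  the fragment tolerance) and multiplicative intensity noise
  (`intensity_noise_cv` = **0.1**); remaining features get independent
  spectra. All fragment sets keep a minimum inter-peak spacing of
  3 × fragment tolerance (0.06 Da) so peak assignment is unambiguous.
* **Annotation levels**: fractions **0.6 % / 6.6 % / 9.2 %** of features
  are planted at levels 1/2/3 (the annotation shares of the reference
  cohort); `make_library` builds matching in-house standards, library
  entries and in-silico candidates (passing candidates for level 3,
  failing decoys elsewhere).
* **Areas**: log-uniform base areas (10^4.3–10^5.85) with multiplicative
  noise, zero where absent.

All randomness flows from one seeded `numpy` generator; identical
configurations produce byte-identical output files.

## 8. Numerical choices

* Intensity weights are L2-normalized *after* the power transform, so the
  score is a proper cosine bounded by 1.
* Scores are clamped at 1 + 1e-9 only to absorb floating-point roundoff;
  the acceptance script reports a maximum self-similarity error of
  ~4e-16.
* Quantification tables are parsed with pandas' round-trip float
  precision; all writers use fixed float formats (`%.6f` for MGF peaks
  and edge scores) and sorted keys, making every artifact byte-stable.
* Derived random seeds are drawn below 2^31 so they stay valid for any
  32-bit seeded consumer.

## 9. Limitations

* The full-cohort reproduction (6,418 features) needs the deposited
  quantification table, which is too large to ship and must be provided
  locally; without it the corresponding acceptance test fails by design.
* The annotation shares and network counts of the reference study depend
  on a proprietary in-house library, external SIRIUS/Zodiac runs and
  GNPS-internal defaults; they are emulated (as planted fractions), not
  reproduced.
* The generator plants clean, well-separated fragment templates; real
  spectra contain chimeric and noise peaks, so real-data family recovery
  will be worse than the synthetic ARI of 1.0.
* Ion-identity networking (adduct collapsing) and GNPS job submission are
  out of scope.
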