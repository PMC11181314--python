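# Methods

## Profiling model

A Cell Painting screen produces, per microscope site, on the order of 1700
numeric image features. The analysis model here is:

1. **Aggregation.** Site values are collapsed to wells by the per-feature
   median (9 sites → 1 well by default), and replicate plates are collapsed
   the same way per (compound, concentration). Missing values are excluded
   pairwise from every median; a group with no values at all yields a
   missing output and a log entry. Medians of an even count use the mean of
   the two central values.

2. **Robust feature selection.** For two repeats of one reference plate,
   each feature's "profile" is its value vector across wells in fixed
   row-major order (A01…P24). A feature is kept when the biosimilarity of
   the two vectors is ≥ 80 % (the ≥ 0.8 correlation rule), inclusive.
   Zero-variance features have undefined correlation and are dropped with a
   warning, never silently. This mirrors the published procedure that
   reduced 1716 features to 579 robust ones; the well order only matters
   through pairing, so any fixed convention is equivalent.

3. **Z-scoring.** Controls are matched to test wells by plate *and* DMSO
   load (`dmso_percent`); pooling across plates or loads is never done
   silently — absence of matching controls is an error. The score is
   `z = (x − median(controls)) / MAD(controls)` with the *raw* MAD
   (no 1.4826 factor; `mad_scale="normal"` switches conventions). At least
   3 matching control wells are required. A feature whose control MAD is
   zero gets the scale floored at `max(1e−6, 1e−6·|median|)` and is counted
   in a diagnostics report — infinities are never emitted. Profiles missing
   more than 5 % of the robust features are rejected with a diagnostic.

4. **Induction and activity.** Induction is the percentage of features with
   `|z| ≥ c`. The cutoff default is `c = 3/Φ⁻¹(0.75) ≈ 4.4478` raw-MAD
   units, i.e. three Gaussian standard deviations expressed on the raw-MAD
   scale. Rationale: raw-MAD z-scores of Gaussian noise have standard
   deviation 1.4826, so a cutoff of 3 raw-MAD units would flag 4.3 % of
   null features and push inactive compounds right against the 5 % activity
   threshold; the chosen default keeps the per-feature false-positive rate
   at the conventional two-sided 0.27 % (null induction ≈ 0.3–0.4 % in
   practice, the excess coming from finite-control MAD estimation). The
   cutoff is a plain parameter everywhere. Activity is induction ≥ 5 %,
   boundary inclusive; retest selection uses ≥ 10 % and confirmation in the
   retest uses the activity threshold again — all three are separate config
   keys.

5. **Biosimilarity.** `max(0, 1 − CD) × 100` with CD the correlation
   distance; equivalently the positive part of the Pearson correlation in
   percent. Constant vectors raise a dedicated error and the caller decides
   (feature selection drops the feature; concordance records a missing
   value). Full-profile similarity threshold: 75 %.

6. **Cluster subprofiles.** Given defining profiles of a bioactivity
   cluster, a feature is retained iff `max(n⁺, n⁻)/n ≥ 0.85` where n⁺/n⁻
   count strictly positive/negative values; zeros count in the denominator
   but toward neither sign (conservative reading of "same sign"). The
   comparison is inclusive — 17 of 20 defining profiles is exactly 0.85 and
   is kept. The subprofile value is the per-feature median over all
   defining profiles. Assignment threshold: subprofile biosimilarity
   ≥ 80 % (higher than the 75 % full-profile threshold because subprofiles
   are shorter). Residual structure is explored by hierarchical clustering
   of profiles restricted to the complement of a cluster's features, with
   correlation distance and average linkage — a conventional choice, since
   no linkage was dictated by the analysis being reproduced.

7. **Curation funnel.** Standardization keeps the largest fragment (ties:
   heavy-atom count, then exact mass, then canonical SMILES) and computes
   standard InChIKeys; a failed key is recorded, never dropped. Stages in
   order: availability ≥ 2 mg (missing amounts fail and are counted
   separately) → heavy atoms ≥ 25 (inclusive: 25 is kept) → removal of
   records whose full InChIKey occurs in a reference key set (exact,
   case-sensitive string match). Diversity selection is MaxMin
   (lazy farthest-point) on Morgan fingerprints, radius 2, 2048 bits,
   mandatory seed — the community-default parametrization. PAINS flags come
   from RDKit's published PAINS SMARTS catalog; the lysosomotropism call is
   `logP > 2 and 6.5 ≤ pKa ≤ 11` with externally supplied (predicted) pKa —
   predictions are consumed, never computed here.

## The synthetic-data generator

The generator emulates the *data model* of the screen, not its biology:

* per-feature baseline medians (`10^U(1,3)`) and dispersion scales
  (`10^U(−1,1)`) drawn log-uniformly, so features are scale-heterogeneous;
* 384-well plates with a `control_fraction` (default 12.5 %) of evenly
  interspersed DMSO wells, all at one DMSO load;
* cluster effect templates: sign patterns in {−1, 0, +1} over a
  `template_support` fraction (default 15 %) of features; an active
  compound's well is shifted by `effect_size` (default 4) dispersion units
  per affected feature;
* i.i.d. Gaussian well noise of `noise_sd` (default 1) dispersion units,
  with a heavy-tailed option (Student t, df = 3), plus site-level jitter
  (default 0.5) around each well mean;
* replicate pairs share layout, templates, and truth; `replicate_correlation`
  mixes in a shared noise component; a `precipitation_rate` fraction of the
  active compounds has its effect zeroed in run 2 only, emulating compounds
  that fall out of solution after a freeze–thaw cycle;
* a toy SDF with salts, exact duplicates, and sub-25-heavy-atom records,
  each carrying an `available` amount field.

Because z-scoring divides by the raw control MAD, an effect of `e`
dispersion units lands at `1.4826·e/noise_sd` z-units and pure noise has
z-standard-deviation 1.4826; the analytic null induction rate is
`2(1 − Φ(0.6745·c))`. These identities are what the generator-based tests
check against.

What the generator does **not** emulate — and therefore what passing tests
do not show about real screens: spatial plate effects and edge artifacts,
dose–response structure, correlated feature blocks (real CellProfiler
features are heavily collinear), batch drift between runs, and any real
relationship between chemistry and phenotype. Synthetic recovery rates are
upper bounds on real-data performance.

## Numerical choices

* Correlations are computed from centered dot products in float64; values
  are clipped at 0 from below but not forced to exactly 100 at the top, so
  self-similarity is 100 only up to ~1e−14 — tests compare with tolerance,
  and threshold semantics are tested at the exactly-computed value rather
  than at a rounded constant.
* MAD = 0 handling (epsilon floor) and the ≥ 3 matching-controls rule are
  hard requirements, not warnings, to keep degenerate plates from passing
  silently.
* `nan` policy: medians are nan-aware; correlation inputs are not — a
  profile with missing values is either rejected (> 5 % missing) or the
  missing features excluded upstream.
* All stochastic components take explicit integer seeds
  (`numpy.random.default_rng`); MaxMin picking takes its seed through
  RDKit. Pipeline runs re-derive child seeds from the one config seed and
  record them in the run manifest.

## Problem sizes used in the shipped benchmarks

Oracle checks run on 1000 random vector pairs; cluster-label recovery uses
10 seeds × 52 compounds at the full 579-feature scale with 8 defining
profiles per cluster; precipitation concordance uses 200 active compounds;
the null-induction check uses 192 effect-free compounds against 192 control
wells. These sizes put binomial error comfortably inside the asserted
tolerances while keeping the whole suite and the acceptance script in the
seconds range.

## Known limitations

* The deposited retest tables of the original screen are an optional input;
  the shipped checks run on synthetic stand-ins in the same schema, clearly
  labeled as such.
* Subprofile feature sets on synthetic data contain a predictable fraction
  of sign-consistent noise features (≈ 7 % of off-template features at 8
  defining profiles and 85 % consistency); with few defining profiles the
  subprofile is noticeably diluted, exactly as with real reference sets.
* The curation funnel reproduces the *procedure*, not the original selected
  set, which would require the vendor's proprietary SD file.
* pKa and logP for the lysosomotropism rule are inputs; no prediction
  method is bundled.
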