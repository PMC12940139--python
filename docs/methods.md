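# Methods

This note records the models and procedures `bloodsig` implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions, so that results can be
interpreted and the design revisited with its reasoning intact.

## Data model

The central object is a samples × genera matrix of non-negative integer
counts (`FeatureTable`), with sample metadata carrying study membership
and a binary group label (`Ct` control / `NCt` case). All statistics
operate at genus level; collapsing amplicon sequence variants to genus is
assumed to have happened upstream. Merging studies takes the union of
genus namespaces and fills absences with explicit zeros — a genus a study
never observed is "not detected", which the prevalence semantics below
rely on, not "missing".

Phylogenies are rooted trees with branch lengths on every edge (a missing
length is an error, never silently defaulted), tips labelled by genus.

## Quality control

Three conventions, each encoded exactly once in `PipelineConfig`:

- Samples with **fewer than 100 reads** are removed; the comparison is
  strict, so a 100-read sample survives.
- Contaminant genera (study-specific lists, e.g. from an upstream de-novo
  contaminant caller) are zeroed within their study by default. The
  alternative of dropping the genus table-wide is exposed (`mode="global"`)
  because published pipelines are ambiguous on this point; per-study
  zeroing is the default since reagent contamination is a property of a
  study's kit, not of the genus.
- Relative abundance divides each sample by its total; zero-total samples
  must be filtered first.

Every filtering step appends to a `QCAccounting` ledger with the
invariant `reads_in = reads_removed + reads_retained`, chained across
stages. Upstream steps that this package does not compute (human-read
removal, denoising) can be entered as user-supplied ledger rows so the
full retention curve can be reported; they are never computed here.

## Origin attribution

Evidence is a table of (genus, raw sample type, number of experiments
reporting the genus in that sample type), in the style of a Disbiome
export. Raw sample types are grouped: feces, anal swab and rectal swab →
gut; buccal, dental plaque, mouthwash, oral plaque, oral swab, oral wash,
oropharynx swab, saliva, subgingival plaque, supragingival plaque and
tongue scrape → oral; skin and foot swabs → skin. The vocabulary is open
(vaginal is included by default) because blood data does surface
gut+vaginal combinations. Types that cannot be matched to a body site are
dropped and logged, never guessed.

A site is *valid* evidence for a genus when strictly **more than five
experiments** report it there (`min_experiments = 6`). A genus with
exactly 5 experiments at a site is therefore unsupported — the boundary
case is genuinely ambiguous in the source conventions, and the strict
reading was chosen; it is a single config value if a user disagrees.
One valid site → single origin; **two or more** valid sites →
multi-origin (`multi_min_sites = 2`; the published figures treat two-site
combinations as multi-origin even though prose elsewhere says "more than
two", and the figure reading is followed); no valid site, including no
records at all → unidentified. With `multi_min_sites > 2`, a genus with
fewer valid sites than the cut-off is labelled by its dominant valid site
(largest count, ties broken alphabetically).

Thresholds are absolute experiment counts. The percentage equivalences
sometimes quoted for such thresholds (≈0.1% of gut, 0.5% of oral, 1% of
skin experiments) depend on the composition of the evidence database at
export time and are therefore stored as documentation only, never used in
classification.

## Diversity

Counts are rarefied **once** to 2000 reads per sample (multivariate
hypergeometric subsampling, seeded; samples below the depth are excluded
from diversity analyses). One draw rather than an average over repeated
rarefactions keeps the procedure simple and exactly reproducible; the
seed is part of the run manifest.

- **Observed richness**: genera with count > 0.
- **Faith's PD**: total branch length of the minimal subtree connecting
  the present tips *and the root* (rooted-PD convention, matching the
  common implementations; the convention matters for a single-tip
  sample, whose PD is its root path, not 0).
- **Unweighted UniFrac**: fraction of branch length unique to one of two
  presence sets among branch length present in either; computed on the
  rarefied presence/absence (one rarefaction depth serves both alpha and
  beta diversity; computing UniFrac on unrarefied presence is available
  to callers by passing the unrarefied table).
- **PCoA**: Gower double-centering −½·J·D²·J and eigendecomposition;
  coordinates are eigenvector·√eigenvalue on positive axes; negative
  eigenvalues (UniFrac matrices are generally non-Euclidean) are reported
  unmodified, not corrected.

Faith's PD, UniFrac and PCoA are delegated to scikit-bio; the test suite
verifies them against independent brute-force oracles (root-path edge
union; hand-worked double-centering).

Group comparison uses the **Kruskal–Wallis** test (midranks, tie
correction) even for two groups, where it is the square of the
standardized rank-sum statistic — chosen for consistency with the
per-study multi-group use. Per-study relative diversity divides each
sample's value by the mean of its study's Ct samples; a study with no
controls is skipped with a warning rather than normalized to an
undefined baseline.

## Differential abundance

An ALDEx2-style CLR Dirichlet Monte-Carlo procedure, authored here:

1. For each of `mc_instances = 128` instances, draw per-sample
   proportions from Dirichlet(counts + 0.5) (gamma-variate construction)
   and transform to CLR: log p_i − mean_j log p_j. Prior 0.5 and 128
   instances follow the published defaults of the method family; both
   are configurable.
2. Per instance, a two-sided Wilcoxon rank-sum test per genus between Ct
   and NCt. Exact null enumeration when both groups have ≤ 8 samples and
   values are tie-free; otherwise a vectorized normal approximation with
   midranks, tie correction and continuity correction (CLR values from
   continuous Dirichlet draws are tie-free almost surely, so the
   approximation path is the one exercised at scale). Genera constant
   across both groups get p = 1.
3. Benjamini–Hochberg correction **within each instance**, then q =
   mean of adjusted p over instances (the expected-q convention); the
   alternative — BH once on expected p — is available via
   `aggregate_mc`. Significance is q < 0.05.
4. Effect size per genus: per instance,
   (median CLR in NCt − median CLR in Ct) / max(IQR_Ct, IQR_NCt, 1e-12),
   reported as the median over instances. The formula is a design choice
   (the method family's "effect size" has several variants); it is
   antisymmetric under label swap, zero for identical groups, and
   monotone in a location shift, which is what the downstream volcano
   and direction calls require. Positive = higher in NCt.

All studies are pooled into one two-group comparison by default (the
balanced within-study design means study effects do not confound the
group contrast); per-study stratified runs are a caller-side loop, and no
meta-combination rule across studies is invented.

## Signatures

Detection is strictly positive abundance after QC — no detection floor
beyond the QC chain itself, so prevalence depends only on the zero
pattern and is invariant to the relative-abundance transform. Study
prevalence counts a study as positive when at least one of its samples
detects the genus. Common-signature selection uses strict `>` thresholds
(a genus at exactly 20% or 50% prevalence is *not* selected). Per-sample
origin proportions partition abundance mass by origin category;
multi-origin is its own category and is never redistributed to its
constituent sites. The "top genera" ranking uses mean relative abundance
(prevalence-based ranking is a one-line variant via the prevalence
table).

## Synthetic generator

The generator emulates the *structure* of a multi-cohort blood 16S
meta-analysis, with ground truth for every recovery test:

- **Design**: 8 studies × 20 Ct + 20 NCt, 300 genera — the scale of a
  mid-sized meta-analysis, sized so the full pipeline runs in seconds.
- **Baseline**: a global log-abundance profile (standard normal), with a
  30-genus core set boosted by `core_boost = 3` log-units so it is
  prevalent everywhere.
- **Batch effects**: per-(study, genus) normal offsets with SD
  `batch_scale = 1.0` log-unit added to the profile; expected
  proportions are the softmax. This reproduces the study-wise clustering
  real cohorts show in UniFrac ordinations (asserted as a property:
  between-study distances exceed within-study distances).
- **Disease amplification**: 12 genera drawn from the gut/oral-origin,
  non-core pool, given a rare baseline (≈ −2.5 log-units) and multiplied
  8-fold in NCt samples before renormalization. Amplifying *rare* genera
  raises both their abundance and their detectability, so case samples
  are also richer — the two case-group findings (enrichment and higher
  diversity) emerge from a single mechanism, which is the translocation
  reading of the real data.
- **Depths**: log-normal (median 15k) clipped to [5000, 50000];
  counts multinomial at the drawn depth. Plain multinomial rather than
  Dirichlet-multinomial is the default (an overdispersed biological
  replicate model is not needed for the recovery properties tested);
  batch offsets already provide between-sample variation.
- **Contaminants**: 2 per study, in a dedicated namespace block with zero
  baseline; spiking adds ≈2% of each sample's depth in every sample of
  the study (both groups, as reagent contamination behaves), so
  per-study removal with the truth list restores the pre-spike table
  exactly.
- **Evidence**: each true origin site gets ≥ 6 experiments split over
  that site's raw sample-type names; noise adds sub-threshold (≤ 4)
  records at wrong sites and unmappable sample types. Sub-threshold
  records never stack above the validity threshold at a single site, so
  at zero noise the classifier output *equals* the truth, and under
  noise unidentified-truth genera remain unidentified.

What it does **not** emulate: read-level error (no FASTQ, chimeras or
denoising artifacts), human-read admixture, compositional interactions
between genera, overdispersed biological replicates, unbalanced or
confounded designs, or longitudinal structure. Passing recovery tests
therefore demonstrates the pipeline's correctness and calibration under
a clean multi-study model — not robustness to every pathology of real
amplicon data.

## Numerical conventions

- Strict inequalities at every threshold boundary (reads, prevalence,
  evidence counts), stated per-parameter above.
- Rank ties: midranks with tie correction in both Kruskal–Wallis and the
  rank-sum approximation.
- CLR rows sum to zero within 1e-9; relative-abundance rows and origin
  proportions sum to one within 1e-9 (asserted, not assumed).
- Effect-size dispersion guard ε = 1e-12.
- All randomness flows through `numpy.random.Generator` seeded from a
  single integer; sub-streams are spawned via `SeedSequence`, so full
  runs are bit-for-bit reproducible.

## Known limitations

- The evidence classifier inherits the evidence database's composition
  bias: genera from under-catalogued habitats will be "unidentified"
  regardless of their true source, and the absolute thresholds do not
  adapt if a site's database coverage changes.
- Pooling studies assumes balanced group composition within studies;
  with strongly unbalanced cohorts, batch effects leak into the group
  contrast and a stratified analysis should be preferred.
- Single-draw rarefaction adds sampling noise to diversity values;
  at the 2000-read depth this is small relative to group effects, but
  borderline per-study comparisons should not be over-interpreted.
- The acceptance-style recovery rates (sensitivity, FDR, null
  calibration) are measured on the synthetic model above and carry the
  caveats of its simplifications.
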