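# Methods

## Scope and data model

The package analyses longitudinal serum N-glycome and N-glycoproteome data
from a two-outcome ICU cohort. Its in-memory containers are deliberately
plain: cohort tables and glycome profiles are pandas DataFrames (profiles:
samples × structures, percent, rows summing to 100), spectra are m/z-sorted
peak arrays, glycoPSM tables are DataFrames in a canonical TSV schema.
Search-engine outputs (glycopeptide identification, FDR control, fucose-type
classification) are treated as upstream: the package consumes their tables
and never re-implements identification.

## Glycan model

Compositions are HexNAc/Hex/Fuc/NeuAc counts parsed from strings such as
`HexNAc4Hex5Fuc1NeuAc2` (any token order, optional parenthesised
multiplicities, repeats accumulate). Broad N-glycan type is a total function
of composition using standard conventions: paucimannose (HexNAc2, Hex ≤ 4),
oligomannose (HexNAc2, Fuc0, NeuAc0, Hex 5–9), hybrid (HexNAc3), complex
otherwise. Everything composition cannot resolve — core vs antennary (Lewis)
fucose placement, α2,3 vs α2,6 sialyl linkage, antennarity, bisecting
GlcNAc — lives in the structure catalog as annotations, because in practice
those assignments come from manual CID-MS/MS and PGC-retention
interpretation, not from composition.

Feature aggregates weight by structure abundance: a structure with at least
one Lewis fucose contributes its full relative abundance to
`pct_lewis_fuc`, and analogously for the other flags. This matches how
"% Lewis fucosylation"-style aggregates are conventionally reported and
makes the feature map linear in the profile; per-residue weighting is a
deliberate non-feature.

Day-to-day glycome change between consecutive samples of one patient is the
total-variation distance ½·Σ|a_d − a_{d+1}| (percent, bounded 0–100,
symmetric, a metric). The underlying heat-map statistic in comparable
studies is typically undefined in print; total variation was chosen for
boundedness and interpretability and is isolated behind one function so it
can be swapped.

## Diagnostic-ion scanning

Two parameterisations of the same scan:

* **manual**: a target ion hits if some peak lies within an *inclusive*
  ±0.01 Th window (±0.20 Th for the CID glycomics ions) and its intensity is
  *strictly* greater than 1% of the base peak. The asymmetric conventions
  (inclusive window, strict intensity) are kept exactly as stated by the
  scanning rule this mode mirrors.
* **glycounter**: 10 ppm window, absolute intensity ≥ 1000, peak among the
  50 most intense, and a signal-to-noise gate approximated as intensity ≥
  3 × the median peak intensity of the spectrum (the reference tool's exact
  noise estimator is not public; the approximation is documented and
  switchable). No minimum co-occurring oxonium count is required. An
  optional per-spectrum gate discards hits when the summed matched intensity
  falls below a configurable fraction of the total ion current; it is off in
  manual mode.

Among multiple qualifying peaks the most intense is reported, ties broken
toward lower m/z. A spectrum counts once per target regardless of how many
peaks qualify, so `diagnostic_fraction` is the fraction of MS/MS spectra
featuring the ion. The narrow glycoPSM filter applies the same scan at
±0.02 Th to the m/z 512.20 Lewis ion and keeps only rows whose spectrum
hits.

## Spectral counting

The Lewis glycoform level of a sample is `#Lewis glycoPSMs / #glycoPSMs`.
Rows with fucose type `ambiguous` (e.g. Byonic-like tables, which report no
core/antennary call) stay in the denominator and are excluded from the
numerator by default — conservative toward the Lewis estimate — with an
`include_ambiguous` switch. Per-protein levels divide by the same
denominator, so levels partition exactly: Σ over proteins = global level.
Carrier shares are computed over Lewis-typed rows only and sum to 1.

## Statistical conventions

* **Mann-Whitney U** (unpaired groups): mid-rank ties; exact null when the
  pooled sample has ≤ 12 observations without ties, otherwise the normal
  approximation with tie and continuity corrections (via scipy). The
  statistic reported is U of the first sample.
* **Wilcoxon signed-rank** (paired data): zero differences dropped; exact
  null for ≤ 20 nonzero differences without ties, else the corrected normal
  approximation.
* **ROC**: the raw feature is the score (univariate; no model). AUC by
  mid-rank pair counting, which equals U/(n⁺·n⁻) exactly, ties included;
  the curve is the standard threshold sweep (via scikit-learn).
* **Clustering**: Euclidean average linkage (UPGMA) on log2-transformed
  profiles, log2(a + floor) with floor defaulting to half the smallest
  nonzero value. The agglomeration is implemented directly (Lance-Williams
  update) because the tie-break is part of the contract: among
  minimal-distance pairs the smallest (i, j) cluster-index pair merges
  first, making trees reproducible; scipy's implementation serves as an
  independent oracle in the tests on tie-free inputs.
* **Multiplicity**: no correction by default (p < 0.05 per comparison, as
  in the discovery analyses this mirrors); Benjamini-Hochberg is available
  but off. Tail choice is always explicit in the caller: two-sided for
  discovery, one-sided (nonsurvivor > survivor) for the targeted day-1
  Lewis hypotheses.

## Survivorship classifier

A random forest (default 500 trees, unlimited depth, √p features per split,
no class weighting, mandatory seed) on untransformed per-structure relative
abundances. The longitudinal design: all samples from ICU day ≥ 2 form the
training set, each labelled with its patient's outcome; the single day-1
sample per patient forms the test set; prediction is the majority of tree
votes with ties going to the positive (nonsurvivor) class, and the score is
the fraction of trees voting nonsurvivor.

This design evaluates on day-1 samples of the same patients whose later
samples were trained on. Because serum N-glycome profiles are strongly
patient-stable, the forest can recognise patients as well as outcomes, so
day-1 "test" performance is an optimistic, admission-time *recognition*
estimate rather than a generalisation estimate. The design is reproduced
deliberately (it is the clinically posed question: predict at admission
from data the model will later accumulate), and `patient_disjoint_cv`
provides the honest alternative: grouped folds in which held-out patients
contribute nothing to training.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions.

**Cohort**: 29 survivors (2–6 samples each) and 8 nonsurvivors (3–7),
sampled daily from day 1 (contiguous schedules), sample counts uniform on
the group interval.

**Glycome profiles** are built per sample from four components:

1. *Group/day Lewis mean*: survivors 3.2% on days 1–2, nonsurvivors 5.4%
   throughout (the midpoints of the reported day-1/2 bands 3.09–3.32% and
   5.25–5.52%); survivors rise linearly from day 2 and meet the nonsurvivor
   level at day 4 (`convergence_day`), modelling a gradual increase rather
   than a step.
2. *Lewis-feature noise*: the per-sample Lewis total is the group/day mean
   plus a patient-stable offset plus day noise, with total cross-sectional
   SD `within_group_sd` = 0.65% of which 75% of the variance
   (`patient_effect_fraction`) is the stable patient offset. The SD makes
   the day-1 effect unambiguous (Cohen's d ≈ 3), the regime in which the
   parameter-recovery properties below hold reliably; real cohorts are
   noisier (see Limitations).
3. *Lewis split*: the elevation above the survivor baseline loads only onto
   glycans 22a (55%) and 23a (45%) (`effect_share_by_structure`); glycan 36
   keeps its small baseline in both groups, mirroring an
   elevated-but-not-discriminating isomer. Within the Lewis block,
   proportions get mild logistic-normal jitter (σ 0.03 patient / 0.03 day).
4. *Non-Lewis composition*: the remaining (100 − Lewis) mass follows the
   baseline serum composition perturbed logistic-normally with a persistent
   patient fingerprint and day noise (σ 0.25 / 0.09 on the log scale).
   The fingerprint is **low-rank**: each patient's offset is a
   loading-weighted mix of 2 latent axes (`patient_axes`), reflecting that
   interpersonal serum-glycome variation is governed by a few physiological
   axes rather than independent per-structure differences. Axis scores and
   Lewis-split offsets are centred within each outcome group, so the
   fingerprint carries no survivorship information by construction and the
   configured Lewis effect is the only group difference; the Lewis-total
   patient offsets stay i.i.d. so rank tests on the Lewis feature keep
   their nominal null behaviour (verified at 3.5% empirical type-I over
   1000 null cohorts).

Every row is nonnegative and sums to 100 within 1e-6. The patient
fingerprint is what makes the longitudinal split behave as in real data:
day-1 samples resemble the same patient's later samples, so the forest
attains high day-1 specificity and substantial sensitivity, while the
importance ranking is led by 22a/23a because the fingerprint is
class-orthogonal.

The default catalog is an illustrative 26-structure serum set spanning
oligomannose, hybrid, complex bi-/tri-/tetra-antennary, bisected,
core-fucosylated and the three Lewis-fucosylated structures (22a: Lewis on
the 3′ arm with an α2,6-sialyl-LacNAc 6′ arm; 23a: its sialyl-Lewis
counterpart; 36: triantennary sialyl-Lewis), with baseline abundances
placing the feature aggregates in realistic serum ranges (oligomannose ~5%,
core fucosylation ~27%, α2,6-sialylation ~88%, biantennary ~85%, Lewis
~3.2%). It stands in for the full supplementary structure catalog of a real
study and does not claim to reproduce deposited structures.

**Spectra**: engineered MGF files place each target ion in exactly
`round(fraction × n)` spectra, within ±`mz_jitter` (default 0.005 Th) of the
target at a configurable fraction of the base peak (default 5%), and keep
all decoy peaks at least 0.5 Th away from every target, so any scan at a
tolerance up to that halfwidth recovers the engineered fraction exactly.
Chromatography, isotope envelopes and realistic fragmentation are out of
scope — only diagnostic-ion content is controlled.

**GlycoPSM tables**: per sample, exactly `round(fraction × n)` rows are
Lewis-typed; Lewis rows are assigned to carrier proteins multinomially with
shares defaulting to AGP-1 75.3%, haptoglobin 7.7%, SERPINA1 3.6%,
hemopexin 1.7%, ANKRD36 1.5%, remainder pooled. Default Lewis-PSM fractions
are 3.2% (survivors, days < 3) and 5.4% (nonsurvivors and converged days),
i.e. the glycomics effect restated at the PSM level.

All generators are deterministic given their seed (byte-identical files)
and write JSON manifests recording their construction ground truth so tests
assert against construction, not re-estimation.

## What passing tests do and do not show

On synthetic cohorts at the defaults, the day-1 one-tailed Mann-Whitney on
the Lewis feature rejects in essentially every seed, glycans 22a/23a lead
the forest importances in ≥ 90% of seeds, and mean day-1
sensitivity/specificity (~0.5 / ~1.0) clearly beat the always-survivor
baseline. This demonstrates that the pipeline recovers parameters it was
configured with — an internal-consistency property. It does not demonstrate
clinical performance: real cohorts have smaller effect sizes, batch and
treatment confounders, non-compositional noise, and no guarantee that
patient fingerprints are outcome-orthogonal.

## Numerical choices and degenerate inputs

Profiles are renormalised to exactly 100 after noise; the Lewis total is
clipped to [0.05, 80]%. Empty spectra, all-zero profiles, single-class
labels, empty groups, and all-zero paired differences raise errors rather
than returning silent defaults; a metric with a zero denominator is NaN and
flagged, never 0. MGF parsing is delegated to pyteomics after a structural
pre-scan that reports the first malformed block by index. Performance
metrics are reported both as fractions and percentages.

## Known limitations

* The effect-size regime is deliberately strong (d ≈ 3); power and
  importance-recovery results do not transfer to weaker real-world effects.
* The generator's compositional noise is logistic-normal; real XIC-derived
  abundances have intensity-dependent, occasionally non-compositional error.
* Byonic-like tables carry no core/antennary call, so their rows are
  `ambiguous` and excluded from Lewis numerators by default; quantitative
  comparisons across dialects therefore differ by construction.
* The longitudinal split's leakage-by-patient is intrinsic to the design it
  reproduces; use `patient_disjoint_cv` for generalisation estimates.
* Only univariate rank-based ROC is provided; multivariate (e.g. SVM-based)
  ROC is out of scope, as are glycan structure elucidation, O-glycans and
  search-engine internals.
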