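# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `galswitch`. It is written for a
reader who wants to know exactly what the code computes and what passing
its tests does and does not demonstrate about real data.

## Cytometry processing

**Gating.** Events are gated in FSC-A × SSC-A in two stages. Stage 1 keeps
the central `rect_quantile` of observations *per axis* (default 0.95, i.e.
2.5% trimmed from each tail of FSC and of SSC independently; a joint-box
reading of "a rectangle including 95%" would be equally defensible — the
marginal rule was chosen because it is deterministic and
parameter-free). Stage 2 standardizes both axes, finds the mode of a 64×64
2-D histogram, and keeps the `1 − centroid_exclusion` fraction of stage-1
survivors nearest that centroid (default exclusion 0.40, the midpoint of a
typical 30–50% outlier-exclusion practice). Ties at the distance threshold
are kept, so a degenerate all-identical cloud passes unchanged. Samples
retaining fewer than `min_gated_events` (default 100) are flagged censored,
never silently dropped.

**Saturation correction.** FITC-A values at or above the detector ceiling
(default 2^18 − 1 A.U., a typical digital cytometer maximum) are replaced by
the prediction of an ordinary least-squares fit of log FITC-A on log PE-A
over the sample's non-saturated, positive-signal events (PE is a spectrally
adjacent channel strongly correlated with FITC). The fit is per sample; it
requires ≥ 30 usable events and nonzero PE variance, otherwise the sample is
flagged and ceiling values are left in place.

**Pseudo-log scale.** All expression statistics use
x = log10(raw + 1000) − 3, defined down to raw = −999 A.U. (cytometers emit
negative values for dim cells; the +1000 offset exists for exactly this).
raw 0 maps to 0 and raw 99,000 to 2. The 60-bin histogram grid spans
pseudo-log [−0.5, 3.5] (raw ≈ −684 to ~3×10^6 A.U.); the bin count is part
of the feature definition and the range is config-exposed and recorded in
outputs. Out-of-range values are clipped into the edge bins so the
normalization `sum × binwidth = 1` is exact.

**ON/OFF cutoff.** The ON cutoff is the 99.9th percentile of pooled
autofluorescent-control signal on the pseudo-log scale (default three
control samples). With the default OFF component this lands near 0.42,
well below any ON component.

**Density and growth.** Cell density is the OLS slope of cumulative event
count against acquisition time (events/ms), times 1000, divided by the
sampling rate (µl/s). The slope is taken over all events of the sample
passed in; the pipeline uses the pre-gate table for the rate so the density
refers to the aspirated culture. Growth: the galactose culture is
inoculated at 9/150 of the saturated glucose culture, so
µ = ln(D_gal/(D_glu·9/150))/12 h and generations = log2 of the same ratio.
Nonpositive densities mark µ undefined and flag the genotype.

## Expression-class assignment

Profiles are per-genotype replicate means of the paired glucose+galactose
bin densities (120 values). Each value is transformed
V = log10(round(v, 3) + 0.001) — the rounding uses round-half-to-even
(numpy's rule; v = 0.0005 rounds to 0, v = 0.0025 to 0.002), so densities
below 0.0005 collapse to V = −3 — then each bin is z-scaled across
genotypes (numerically constant bins are set to 0).

Clustering is HDBSCAN* (scikit-learn's implementation) run once per minPts
in a grid (default {5, 10, 15, 25}). Each labeling is scored by the
fraction of total phenotypic variance it explains: the five per-genotype
phenotypes (fraction ON and mean signal in both conditions, µ) are each
z-scaled, stacked long, and fit with the saturated model
`value ~ cluster × phenotype`; for a full categorical interaction model the
least-squares fit is the per-cell mean, so the score is computed exactly as
1 − SSR/SST from group means. Noise points enter as singleton clusters so
the score is defined for every labeling. The chosen labeling maximizes the
score with a parsimony tie-break: candidates within 0.005 go to the fewest
clusters, then to the smallest minPts.

Clusters are named by their centroid's nearest class archetype in feature
space (correlation distance, acceptance ceiling 0.75). Archetypes are the
expected 120-bin profiles of the five classes at their central mixture
parameters — the same information a deletion panel (Inducible /
Constitutive / Uninducible) plus curated Leaky and Weak-expression
exemplars provides. Per-genotype curation rules then fix boundary calls
using the induction ratio, defined as 10^(mean pseudo-log galactose signal −
mean pseudo-log glucose signal), i.e. a ratio of raw-scale geometric means:

* Constitutive call with ratio ≥ 3 → Leaky if the glucose ON fraction is
  detectable (≥ 0.05), else Inducible;
* Inducible or Leaky call with ratio ≤ 1.5 → Constitutive if broadly ON in
  glucose (fraction ≥ 0.40), else Uninducible;
* Uninducible call with galactose ON fraction > 0.40 and a galactose modal
  bin above pseudo-log 1.0 → Inducible.

All three thresholds are config values; the class definitions bound them
only loosely, so they are declared conventions rather than estimated
quantities. Unassigned genotypes (HDBSCAN noise, or clusters beyond the
archetype ceiling) are rescued: first re-clustered together with the
Weak-expression/Leaky anchors, then with the three broad archetypes — a
cluster containing an anchor adopts its class, but only for members within
the archetype distance ceiling (tiny re-clustering runs would otherwise
glue unrelated profiles to an anchor) — and any residue takes its nearest
anchor class outright. Rescued calls then pass through the same curation
rules. Rescue guarantees total assignment; provenance
(primary_cluster/curated/rescued) is preserved in the output. The broad
3-class label is a deterministic coarsening: Leaky → Inducible;
Weak-expression goes to the broad class its summary statistics support.

## Epistasis models

Growth rates are background-subtracted before the multiplicative
combination µ_MUT = µ_mut1·µ_mut2/µ_WT and the background re-added for
reporting. The background is the mean growth of broad-Uninducible
genotypes — the measurable proxy for growth in the absence of functional
GAL regulation (in the synthetic truth this equals the intercept of the
growth model). Standard errors propagate in two selectable modes:
`corrected` (default) is the first-order delta method for a
product/quotient, |µ_MUT|·sqrt((se1/µ1)² + (se2/µ2)² + (seW/µW)²), which a
10^5-draw Monte-Carlo check confirms to within a few percent at small
relative errors; `as_printed` reproduces verbatim an alternative published
reading, |µ_MUT|·|(N−1)(seW/µW) + se1/µ1 + se2/µ1|, whose (N−1) weighting
and repeated µ1 denominator do not follow from standard propagation — it is
shipped for comparability only and the mode is recorded in outputs.

Class-mean models key each double mutant either by the per-locus class
triple in which the unmutated locus carries Inducible (locus-aware) or by
the unordered class pair (locus-blinded). The locus-aware keying is what
makes the combinatorial accounting close: with 2 admissible GAL3 classes
and 4 each for GAL80 and GAL4, 4·4·2 = 32 triples are possible, the 9 with
an Uninducible GAL3 and non-Inducible classes at both other loci would
require triple mutants, leaving 23 realizable in a pairwise design (18 − 4
= 14 for the 3-class scheme). Parameters are group means of observed
growth; combinations unseen in training fall back to the grand mean and
are flagged. Variance explained is 1 − SSR/SST about the grand mean,
computed on within-genotype mean growth (an all-replicates variant is a
config switch). Downsampled cross-validation draws k alleles per
(locus, class) group, trains on doubles whose two alleles were both drawn,
scores the held-out remainder, and reports the median and IQR over
iterations (1000 by default; tests and the acceptance script use 200,
which stabilizes the median to well under a percentage point).

## Sensor-dependency analysis

Arms are contrasted with Welch (unequal-variance) two-sample t-tests, one
Benjamini–Hochberg family per contrast type (the ∆GAL3 family, the GAL1::GALK
family, the above-null family), with significance requiring q < 0.05 *and*
|effect| ≥ 0.03 µ/h — the effect filter applied after FDR control. Arms
with fewer than two replicates are excluded and logged.

The leakiness null is the 3-parameter logistic
µ = Asym/(1 + exp((xmid − x)/scal)) fit to per-pair means of the
double-sensorless arm, with x the pair's mean pseudo-log glucose
expression, separately per heterologous galactokinase (E. coli vs
C. albicans orthologs grow at different maximal rates). Initialization is
self-starting (scaled-logit linearization), with a coarse grid of restarts
on failure; a fit that cannot beat a constant mean is flagged. Growth above
the null is tested one-sided per pair×arm against the prediction at the
pair's leakiness, BH-adjusted.

Per-sensor verdicts: *essential* — the removal arm grows below background +
0.02/h while the intact arm grows (≥ 0.15/h); *contributing* — removal
significantly reduces growth without abolishing it; *deleterious* — removal
significantly increases growth, or restores glucose repression (glucose
signal drop ≥ 0.5 pseudo-log units with the arm's class flipping to
Inducible/Leaky); *dispensable* otherwise. All thresholds are config
values; the "non-growing" margin encodes a judgment the source analyses
made visually. The harmonious flag requires both single mutants
non-Inducible, the intact double Inducible or Leaky, and galactose growth
at ≥ 75% of the WT rate.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment.

**Design.** 46/39/43 alleles of GAL3/GAL80/GAL4 (per-locus class
composition: GAL3 28 Inducible + 18 Uninducible; GAL80 17 I + 8
Constitutive + 7 Uninducible + 7 Leaky; GAL4 22 I + 8 C + 10 U + 3
Weak-expression — the split within each locus is not dictated by the class
definitions, so it was chosen once to give every class enough members for
clustering and to keep the rare Weak class rare, and is config-exposed).
The design is WT + all singles + all 5,449 cross-locus pairs, with a 2%
dropout default mirroring realistic construction coverage; replicate count
defaults to 2.

**Class logic.** A double mutant's class follows a deterministic cascade
encoding the switch's regulatory logic: dead activator masks everything;
dead repressor → Constitutive; constitutively active GAL4 → Constitutive
(here the super-repressor GAL80 × constitutive GAL4 combination is planted
as Constitutive, the majority outcome; the generator does not model the
minority harmonious-inducible outcome of that pairing in the pairwise
library); super-repressor GAL80 → Uninducible; weak repressor → Leaky
(with or without a functional sensor — leaky expression bootstraps
induction); no sensor in an otherwise WT-like switch → Uninducible; a
weak-output GAL4 caps any expressing outcome at Weak-expression (including
with a dead repressor, where real weak alleles would look
"weak-constitutive"; the generator uses a single Weak profile — a known
simplification).

**Truth draws.** Single mutants carry their allele's drawn values; doubles
draw fraction-ON and ON-location from class-conditional distributions
(uniform supports: e.g. Inducible glucose 0–0.02 / galactose 0.95–1;
Leaky glucose 0.06–0.30 at a low ON location ~1.15; Weak galactose
0.70–0.92 at ~1.15). Growth is linear in the ON fractions,
µ = 0.02 + 0.28·fracON_gal − 0.02·fracON_glu + N(0, 0.008), clipped at 0 —
coefficients chosen once so WT grows at ~0.30/h, Uninducible genotypes at
the 0.02/h background, and expression predicts growth, the qualitative
relationship the analysis assumes. Every random draw is keyed by
(master seed, CRC32 of the genotype/sample identifier), so adding
genotypes never perturbs existing ones.

**Events.** Fluorescence is a two-component mixture sampled as Gaussians on
the pseudo-log scale (equivalently log-normal in raw + 1000 A.U. — a plain
log-normal cannot put its mode at raw ≈ 0, which is where autofluorescence
sits): OFF ~ N(0.05, 0.12), ON ~ N(class location, 0.15), with a 2% bright
ON subfraction at N(2.6, 0.08) that exceeds the detector ceiling and is
clipped, PE-A carrying the uncensored correlated signal
(0.5·(raw+1000)·lognoise). Scatter is a correlated bivariate normal with
3% uniform outliers. Timestamps are a Poisson stream at
density × sampling rate, with the sampling rate switched 0.5/2.0 µl/s by
density as an operator would; per-culture lognormal density jitter
(sd 0.04) makes replicate growth rates genuinely vary.

**Sensor panel.** 24 GAL4×GAL80 pair archetypes (WT-like, leaky-GAL80,
mid-leakiness, constitutive-GAL4, constitutive-GAL80, super-repressor, and
super-repressor × constitutive-GAL4) × 4 arms × 2 galactokinase orthologs ×
8 replicates, at the record level (means + replicate noise; the event-level
machinery is not re-run here because the panel's statistics operate on
growth/expression summaries). Sensorless-arm growth lies exactly on the
per-ortholog logistic (E. coli Asym 0.26, C. albicans 0.30; xmid 0.9,
scal 0.25) — including constitutive pairs, which sit at its saturated end —
and the four canonical rewiring patterns are planted: WT-like pairs need
GAL3 and ignore GAL1; leaky-GAL80 pairs accept either sensor;
constitutive-GAL4 pairs revert to Leaky when GAL1 sensing is removed
(intact-arm glucose signal 2.0 vs intrinsic leakiness 0.9–1.6, so the
repression-restoration rule fires); super-repressor × constitutive-GAL4
pairs depend on GAL1 instead of GAL3.

**What the generator does not emulate.** Mutation biology (alleles are
abstract class-parameterized objects); plate/batch effects, carryover, or
day structure; spectral spillover beyond the single FITC–PE relation;
debris/doublets beyond scatter outliers; within-class covariance between
expression and growth beyond the linear model; the minority outcomes of
the most variable class combinations. Passing tests therefore demonstrates
the pipeline's correctness and statistical behavior under the declared
generative model, not robustness to instrument drift or to real biological
heterogeneity.

## Problem sizes and runtimes

The study-scale synthetic run (46/39/43 alleles → ~5,480 genotypes,
~21,900 samples at 5,000 events each) completes in about 2 minutes on one
CPU; the shared reduced fixture used by most statistical tests (31 alleles,
~350 genotypes, 2,000 events/sample) runs in seconds. Downsampled CV uses
200 iterations in tests and the acceptance script. These sizes were chosen
so the full validation cycle stays interactive while every class and model
key remains well populated.

## Known limitations

* The archetype-matching distance operates in the z-scaled feature space,
  whose geometry depends on the library's class composition; the
  summary-statistic curation rules exist precisely to make final calls
  robust to that geometry.
* The narrow (many-cluster) labeling is emitted as raw cluster labels only;
  no curated naming is attempted for it.
* The as-printed SE mode is reproduced verbatim but cannot be reconciled
  with first-order propagation; neither mode is endorsed as "the" published
  number.
* Dependency verdicts mix significance-based and threshold-based criteria;
  only the direction/class logic is scale-equivariant, and the growth
  floors must be rescaled along with any unit change.
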