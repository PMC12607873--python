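# Methods

## Data model

The canonical container is a taxa × samples matrix of **percent relative
abundance** (columns sum to 100 after renormalization), at species or genus
rank. Percent — not proportion — is the internal unit throughout; only
Bray-Curtis, which is scale-invariant after renormalization, is indifferent
to the choice. Sample metadata carry host species (human/mouse), donor id,
timepoint (T0 = pre-treatment, T2 = post-treatment), study id, exposure
route, and a replicate group identifying mice seeded from one stool. A
pairing map links each donor sample to the recipient group(s) derived from
it; a recipient group whose timepoint has no matching human sample is
paired with the donor's T0 sample (the stool that actually seeded it), and
groups with no donor at all are excluded with a warning.

Merged-profiler input (first column `clade_name`, rank-prefixed taxonomy
strings) keeps only rows terminating at the requested rank; rows at other
ranks are silently dropped and unclassified rows are dropped and logged —
whether to retain unclassified mass before renormalization is genuinely
open, and dropping it keeps the taxon set interpretable.

## Pseudo-replication control

Cage mates gavaged from a single stool share one colonization event, so
they are technical replicates, not independent animals. Every
between-group statistic therefore operates on replicate-averaged profiles:
one arithmetic-mean column per replicate group, renormalized (a no-op guard
— means of normalized columns already sum to 100). Averaging is arithmetic
because abundances are compositional fractions of a common total; the
geometric alternative would not preserve column sums. A flag disables
averaging for sensitivity analyses.

## Abundance filter and display transform

The low-abundance filter removes taxa whose *maximum* RA over samples is
below 0.1 % (a taxon at exactly 0.1 % is kept — the cutoff removes what is
*less than* the threshold). The filter deliberately does not renormalize:
it feeds association and correlation stages where rescaling survivors
would manufacture signal. For display, log₁₀ of percent RA is used with
zeros floored at −3 (below any observable abundance at realistic
sequencing depth).

## Beta diversity

* **Bray-Curtis** `d(x,y) = Σ|x−y| / Σ(x+y)` over the shared taxon index.
* **PCoA**: double-center `−d²/2`, eigendecompose; coordinates are
  eigenvectors scaled by √λ for eigenvalues above 1e−12, zero otherwise;
  `proportion_explained` is each positive eigenvalue over the
  positive-eigenvalue sum. Bray-Curtis is semi-metric, so negative
  eigenvalues occur; dispersion analysis embeds them as imaginary axes.
* **PERMANOVA** (one-way): `SS_total = Σ_{i<j} d²_ij / n`, `SS_within`
  analogously per group, `F = (SS_between/(a−1)) / (SS_within/(n−a))`,
  `R² = SS_between/SS_total`. Labels are permuted (vectorized over
  permutations); `p = (1+b)/(1+m)`, never zero, so `p ≥ 1/(m+1)`.
* **PERMDISP**: distances from each sample to its group centroid in the
  corrected PCoA embedding — squared distance = real-axis contribution
  minus imaginary-axis contribution, floored at zero (identical to vegan's
  `betadisper(type="centroid")`, against which the statistic is verified
  exactly). The test statistic is the one-way ANOVA F on those distances.
  Under permutation the centroids and distances are **recomputed for every
  permuted labeling**: permuting labels over fixed distances (the common
  shortcut) breaks exchangeability and measurably inflates type-I error at
  these sample sizes, whereas full recomputation keeps the rejection rate
  at the nominal 5 % (verified over 2,000 null simulations). Centroids, not
  spatial medians, define dispersion here.
* **Group-wise extraction** partitions every off-diagonal pair of the
  replicate-averaged matrix into donor–donor, mouse–mouse, donor–paired
  recipient, donor–other recipient; "mice" are averaged recipient groups,
  consistent with the pseudo-replication rule. Categories are compared by
  Kruskal-Wallis (midranks, tie-corrected) with Dunn's pairwise z-tests
  under Bonferroni (the adjustment is configurable in principle;
  Bonferroni is the conservative default), or by one-way ANOVA with Tukey
  HSD where the values are approximately normal (Fisher-z coefficients).

## Engraftment statistics

Presence is RA strictly above a detection threshold (default 0: any
positive abundance counts; profiler floors differ, so the threshold is
exposed). Percent engraftment divides pairs-with-taxon-in-both by
donors-carrying; each pair contributes once, and a recipient group carries
a taxon when any cage mate does — an OR that replicate averaging preserves,
since means of non-negative values keep any positive entry positive. Taxa
no donor carries have an undefined (0/0) statistic and are excluded.
Counting pairs rather than individual mice keeps the statistic invariant
to cage size.

Stratification averages percent engraftment across studies where the taxon
is defined: high > 80, low < 60, medium the closed interval [60, 80] — the
only assignment that partitions the line given three labels. The plotting
filter keeps taxa with ≥ 5 engrafted pairs ("more than 4").

The per-donor engrafted fraction is `100 · |donor ∩ recipient| / |donor|`
over present taxa, per pair. Engraftment–abundance association is Pearson
r between per-taxon percent engraftment and mean recipient RA.

## Concordance

ΔRA per entity (donor, or recipient group keyed by donor) is
`RA(T2) − RA(T0)` taxon-wise on the percent scale; absent = 0, so loss to
extinction is a negative delta. Donor and recipient deltas are correlated
(Pearson, t-test p) over taxa observed in both hosts; taxa with a zero
delta on either axis sit on an axis of the scatter and are excluded from
the quadrant denominators but retained in the correlation.

Cross-sample correlation matrices union taxa across tables with zero fill,
then correlate each sample pair over the pair's **union support** (taxa
present in at least one of the two). A taxon absent from both samples
carries no information about their agreement; including such zeros would
let every unrelated study's taxon list inflate r through shared absences,
and excluding them also makes the matrix invariant to padding the tables
with never-observed taxa. Coefficients with |r| = 1 are clamped to
1 − 1e−15 before `z = atanh(r)` rather than dropped, preserving pair
counts. Group testing (human–human / human–mouse / mouse–mouse) runs on z,
whose sampling distribution is approximately normal; category means are
reported on untransformed r.

## Synthetic cohorts

The generator emulates the statistical structure of an HMA experiment, not
its biology:

* **Donors**: per taxon, occupancy ~ Bernoulli(prevalence) with prevalence
  a logistic function of the log-abundance location μ (abundant taxa are
  prevalent ones; an explicit override exists for scenario design), and
  abundance `exp(N(μ, σ))` for occupied taxa, renormalized.
* **Host filter**: each donor-carried taxon engrafts into that donor's
  lineage with probability `engraftment_prob[t]`, drawn **once per
  donor-taxon** and shared by cage mates — engraftment is a colonization
  event, so replicate mice are true technical replicates. Engrafted
  abundance per mouse is donor RA × `mouse_fitness[t]` ×
  `exp(N(0, noise_sd))`, renormalized. Log-scale noise precedes
  renormalization.
* **Consortium spike**: the community is scaled to `100 − dose` and the
  dose is split over consortium taxa in fixed proportions, so the
  consortium occupies the dose percentage (plus scaled-down prior
  abundance) and columns still sum to 100.
* **Designs**: HTR seeds separate mouse lineages from the T0 stool and the
  spiked (T2) stool; MTR seeds mice from T0 stool and spikes the mice
  directly.

Defaults mirror a small therapeutic-consortium trial: 6 donors, 3 mice per
donor, paired T0/T2, a 5 % spike dose, and a 100-taxon pool containing a
20-taxon host-adapted core (engraftment probability 0.9), an 11-genus
consortium of mixed engraftment ability, and variable flora crossing the
filter at probability 0.05.

**Strong-filter scenario.** The qualitative signatures of deterministic
host filtering — recipient communities more alike to each other than to
their own donors, and correlation agreement ordered mouse–mouse >
human–mouse > human–human — are properties of a *mega-analysis across
human populations*: human–human pairs mostly span populations with
different variable flora, while every population's mice pass through the
same murine gut. The scenario therefore fixes a host-adapted core (20
taxa, log-location N(2.2, 1.2), within-population scale 0.5, engraftment
probability 0.95, common fitness reshaping with log-sd 0.35 — the filter
is strong in *selection*, mild in rank reshuffling, because the taxa mice
favor are also dominant and stable in humans) and draws each study's
variable flora independently (log-location spread 1.2 between studies,
scale 1.8 within, engraftment probability 0.02). Four studies of six
donors emulate the mega-analysis design. Under these conditions both
orderings hold in ≥ 95 % of seeded replicates.

What the synthetic cohorts do **not** carry over from real data:
ecological interactions (competition, cross-feeding), donor-specific
filtering, strain-level variation, compositional count noise from finite
sequencing depth, and temporal drift beyond the spike. Passing tests
establish that the estimators recover the generative parameters and
reproduce the qualitative orderings under the stated mechanism — not that
the mechanism is the one operating in any particular mouse colony.

## Numerical and reproducibility choices

* Every stochastic operation takes an explicit seed; there is no global
  RNG state. Pipeline runs with the same config are byte-identical.
* Permutation tests compare with `F_perm ≥ F_obs − 1e−12` to keep ties
  deterministic across platforms.
* Eigenvalues within 1e−12 of zero are treated as zero axes.
* All-zero sample columns are errors at renormalization (upstream of every
  dissimilarity); all-zero donor columns are errors in the engraftment
  fraction.
* Kruskal-Wallis on completely tied data returns statistic 0 and p = 1
  with a warning rather than failing.
* Problem sizes in the test-suite simulations (e.g. 2,000 null replicates
  for test calibration, 500 for the binomial recovery oracle, 200 for the
  ordering checks, 10-sample designs for enumeration oracles) were chosen
  so each check's Monte-Carlo error is small relative to the property being
  asserted.

## Known limitations

* PERMANOVA is one-way only; no stratified or multi-factor designs.
* PERMDISP recomputes centroids per permutation, which is O(permutations ×
  n × axes); fine for cohort-scale n, not for thousands of samples.
* The engraftment statistic treats the replicate-averaged group as the
  recipient unit; per-mouse counting would need raw (unaveraged) presence
  and a different inclusion-filter interpretation.
* Correlation matrices are dense; the pairwise union-support loop is
  quadratic in samples.
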