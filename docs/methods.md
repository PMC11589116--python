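# Methods

This note documents the models, rules and numerical choices implemented in
`tripcheck`, the parameters that matter, what the synthetic-data generator
emulates (and does not), and the limitations a user should know about.

## Allele-dosage inference (MAC-PR)

A microsatellite locus observed by capillary fragment analysis yields 1–3
allele peaks. Peak height is approximately proportional to template copy
number, so for a two-peak profile the ratio
r = height(smaller-size allele) / height(larger-size allele) concentrates
near 1, 2 or 0.5 for the AB (1+1), AAB (2+1) and ABB (1+2) configurations.
Classification maps r through calibrated open bands:

| band | interval (default) | call |
|---|---|---|
| 1 : 2 | (0.38, 0.63) | ABB, somy 3 |
| balanced | (0.75, 1.40) | AB, somy 2 |
| 2 : 1 | (1.60, 2.60) | AAB, somy 3 |

The bands centre on the theoretical ratios and leave guard gaps; a ratio
in a gap — or exactly on a boundary — is `unresolved` and flagged, never
guessed. Three distinct peaks force ABC (somy 3) without any ratio test.
A single peak is a homozygous profile whose copy number, and therefore
somy, fragment analysis cannot determine; it is scored but carries no
ploidy information.

Pre-processing: peaks below `min_peak_height_rfu` (default 100 RFU) are
ignored; a peak exactly one repeat motif below a retained peak and below
`max_stutter_fraction` (default 0.15) of its height is removed as PCR
stutter, iterated to a fixpoint. When two true alleles sit one motif
apart, the upper allele's stutter bleeds into the lower allele's peak;
`stutter_correction` (default 0.08, a typical observed stutter ratio)
subtracts the expected bleed-through before the ratio is formed. An
optional multiplicative size-bias correction for differential
amplification of shorter fragments exists and is off by default.

Markers are screened for dosage informativeness per cohort: a marker is
excluded from somy aggregation when its two-peak calls land in the guard
gaps too often (`max_unresolved_fraction`, default 0.25), when stutter
filtering repeatedly interferes with the call, or when it shows no
heterozygous calls at all. Screened-out markers still contribute to family
assignment and aberration typing through allele presence only — their
inferred copy numbers are deliberately discarded there, because a
high-noise marker's 2:1 band calls are unreliable and would plant false
mismatches.

## Ploidy classification

Per individual, over the screened-informative markers with a resolved
heterozygous call, the trisomic proportion p = n_trisomic / n_resolved_het
gives: diploid (p = 0), triploid (p = 1), aneuploid (0 < p < 1),
undetermined (no resolved heterozygous marker). Individuals scoring fewer
than 50% of the informative panel are excluded beforehand; the boundary is
read strictly ("< 50%" excluded, exactly 50% retained) and is
configurable. Individuals classifiable from a single informative locus are
flagged low-confidence rather than suppressed. Aneuploids are graded:
`single_locus_deviation` when exactly one locus deviates from an otherwise
uniform state (trisomic-at-1 or disomic-at-1), `intermediate` otherwise.
Because a trisomy is only visible at loci where dosage resolves and the
individual is heterozygous, all aneuploidy estimates are minimum
estimates; this is inherent to the marker class, not to the
implementation.

## Family assignment (exclusion)

Each offspring is tested against every candidate (dam, shared sire) pair.
A locus is compatible when some standard gamete combination reproduces the
observed call — diploid: one dam allele + one sire allele; triploid: two
dam alleles (any pair, including the same allele twice, because
second-polar-body retention can duplicate either chromatid) + one sire
allele, with copy numbers respected when resolved; unknown/aneuploid
context falls back to allele presence. Mismatch counts are accumulated
per family; a locus whose incompatibility disappears after sliding one
*novel* observed allele (absent from both parents) by ±1–2 repeat motifs
is excused as probable slippage, up to the mismatch tolerance (default 1
locus), and reported. An offspring is assigned only when exactly one
family lies within tolerance; two or more candidates give `ambiguous_tie`
(never resolved arbitrarily), none gives `unassigned`. An assignment
supported by no dam-specific allele anywhere is flagged
`questionable_no_maternal_evidence`, the pattern expected when maternal
DNA is absent altogether.

## Aberration typing

Per-locus findings come from gamete enumeration against the assigned
parents. A locus with resolved somy is judged by its own somy — a
trisomic locus inside an otherwise diploid individual must still satisfy
a trisomic gamete explanation; with somy unknown, any standard diploid or
triploid combination counts (conservative). The decision order is:

1. a normal explanation exists → `ok`, unless the profile is also
   formable from one parent alone (shared alleles) → `ambiguous`;
2. resolved trisomy formable only as one dam + two sire copies →
   `double_paternal`;
3. a novel allele within 1–2 motifs of an explanation → `bp_shift_candidate`
   (slippage is common and benign, so it pre-empts a missing-parent call;
   requiring the mutant copy to be a *novel* allele prevents profiles made
   entirely of one parent's alleles from being explained away);
4. profile formable from the sire alone → `maternal_allele_missing`,
   from the dam alone → `paternal_allele_missing`, from either →
   `ambiguous`;
5. otherwise `incompatible`.

Per individual, maternal-missing findings at more than 3 loci collapse to
one multi-locus event (the uniparental-disomy pattern); at 1–3 loci they
stay a few-loci event. When additionally no scored locus shows a
dam-specific allele, the event is flagged `total_maternal_absence` — the
signature of androgenetic haploidy or whole-genome maternal loss, which
microsatellites cannot distinguish further, so the flag is never resolved
into a ploidy claim. The parental origin of a trisomic extra copy is
resolved by enumerating decompositions; disagreement between
decompositions, or an extra allele carried by both parents, yields
`ambiguous`.

## Incidence models

Both responses (triploid yes/no, aneuploid yes/no) are Bernoulli with
logit link; pressure treatment, family and developmental stage enter as
unordered factors (reference levels: no-pressure treatment, family 1).
The un-nested design uses a plain binomial GLM (statsmodels IRLS). The
replicate-nested design uses a random-intercept logistic regression

  logit P(y_ij = 1) = x_ij' β + u_j,  u_j ~ N(0, σ²),

whose marginal likelihood is integrated per group by adaptive
Gauss–Hermite quadrature: an inner Newton step finds the posterior mode
and curvature of u_j, the nodes are recentred and rescaled there, and the
log integral is accumulated by log-sum-exp. Default 15 nodes; 1 node is
the Laplace approximation; node counts 7 vs 31 agree to < 10⁻³ in
log-likelihood on cohort-sized data. σ is estimated jointly with β under
an L-BFGS-B bound σ ≥ 0; at σ = 0 the likelihood is evaluated in closed
form and the fit equals the plain GLM (the `fix_re_sd=0` option exposes
this limit exactly). Standard errors come from the numerical Hessian at
the optimum. The implementation reproduces lme4's `glmer` (nAGQ = 15) to
~10⁻³ on shared data; that cross-check lives in the test suite, not in
the code path.

Model selection follows single-term deletions compared on
AIC = 2k − 2ℓ, where k counts all estimated parameters including σ; the
random intercept is never a deletion candidate. Quasi-complete separation
is detected as any factor level whose response cells are constant (all 0
or all 1); the flagged fit keeps its estimates but marks its standard
errors unreliable, and the remedy — refitting without the offending
level's observations — is provided side by side. Mortality rates are
pooled-count rates per stage interval; aggregation sums counts before
dividing, never averages rates.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with full latent truth retained:

* **Design.** Twelve dams × one shared sire. The five-treatment design
  uses families 1–3 × pressures {0, 6500, 7500, 8500, 9500} PSI × two
  replicates, with 15 eggs sampled and 100 reared per unit (450 / 3000
  total); the two-treatment design uses all 12 families × {0, 9500} PSI,
  20 eggs sampled and 100 reared per unit (480 / 2400).
* **Markers.** 30 unlinked microsatellites (motifs 2–4 bp, 4–8 alleles
  drawn from Dirichlet frequencies). Twenty markers carry the default peak
  noise (lognormal, σ = 0.05 per allele peak — a 5% height CV typical of
  well-behaved capillary runs, at which the 2:1 band recovers the
  generating configuration in ≥ 99% of draws); ten carry high noise
  (σ = 0.35) and are expected to fail the informativeness screen, giving
  the ~20-informative-of-30 panel the analysis assumes.
* **Retention.** P(second-polar-body retention) is logistic in PSI with
  midpoint 7500 and scale 400 — an illustrative calibration reproducing
  the qualitative success gradient (a few percent at 6500, ~50% at 7500,
  > 90% at and above 8500), not a fitted curve. The retained polar-body
  copy equals the egg copy or the dam's other allele with probability 0.5
  each (recombination between centromere and locus).
* **Treatment disruption.** With probability 0.35 · 4r(1 − r) (maximal at
  intermediate doses, vanishing at 0 PSI and nearly so at full dose) the
  shock mis-segregates: per locus at rate 0.15 a retained individual
  loses the extra maternal copy or a non-retained individual gains one
  (partial polar-body retention → aneuploidy), and with probability 0.10
  a disrupted individual loses the maternal contribution entirely at
  1 + Poisson(1.5) loci (maternal-missing).
* **Spontaneous nondisjunction.** Family-specific per-locus rates
  (defaults 0.010 / 0.008 / 0.003 for families 1–3, so family 3 shows the
  fewest aneuploids; 0.002–0.015 across the twelve). In a diploid
  template the extra copy is maternal or paternal with equal probability;
  a paternal extra requires no retention event, which confines
  double-paternal trisomies to low doses. In a triploid template
  nondisjunction drops the retained polar-body copy.
* **Rare events.** Uniparental-disomy blocks of 5–9 loci at rate 0.004
  per individual; androgenesis (whole-genome maternal loss) at 0.002;
  repeat slippage of ±1–2 motifs in one inherited allele copy at 0.025
  per individual (the 2–3% range typical of microsatellite panels).
* **Peaks.** Height = 1500 RFU × copy number × lognormal noise; identical
  alleles merge copies into one peak; stutter appears one motif below
  each allele at fraction 0.08, merging into a real peak when they
  coincide.
* **Viability.** Survival through the three stage intervals
  (fertilization → eyed egg → start-feed → parr) depends on the latent
  category: baseline (0.975, 0.965, 0.96); single-locus deviants
  (0.95, 0.70, 0.85); intermediate aneuploids (0.80, 0.25, 0.55);
  maternal-DNA loss (0.70, 0.10, 0.50). Penalties concentrate in the
  eyed-egg → start-feed interval, which puts the mortality peak where
  the study design expects it and purges aberrant individuals before the
  parr stage.

One global seed spawns per-stage substreams (parents, offspring, peaks,
viability), so runs are bit-reproducible and stages can be regenerated
independently.

**What passing recovery tests shows — and what it does not.** The
generator shares the classifier's height-proportionality assumption, so
round-trip recovery validates the inference logic and thresholds, not the
biology of real electropherograms (size-dependent amplification bias,
plus-A artifacts, allelic dropout, DNA-quality gradients and mosaicism are
not modelled). Markers are unlinked, whereas a real panel has fewer
chromosomes than loci; per-locus aberration counts in real data are
correlated within chromosomes. The viability model's shape is a free
assumption — the data the design produces cannot distinguish purging by
degree from purging by type of aneuploidy — and the printed survival
values are chosen for realism, not fitted.

## Problem sizes used by the test and acceptance runs

Dosage round-trips use 10⁴ loci per configuration. Pipeline-recovery
properties sweep 200 seeds of the full five-treatment study (~3,450
individuals each) for the egg → parr purge and 50 seeds for the
family-effect rank; mixed-model recovery uses 200 replicates of 10 groups
× 200 observations (the acceptance script reports 50-seed and
30-replicate versions of the same quantities). These sizes give binomial
standard errors well under the margins being asserted.

## Known limitations

* Homozygous profiles carry no somy information, so whole-genome
  homozygotes (androgenesis candidates) have undetermined ploidy — they
  are flagged, never resolved.
* Somy calling is limited to 2 vs 3; tetraploid or mosaic states are out
  of scope.
* Exclusion parentage has no likelihood model; severely aberrant
  offspring are intentionally left unassigned or flagged rather than
  forced into a family.
* The separation remedy (dropping the offending level) changes the
  estimand; both fits are reported so the user can see what was dropped.
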