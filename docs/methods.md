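# Methods

This note documents the statistical procedures, the synthetic-study
generator and the design decisions behind `tmapro`.

## Challenge-test phenotyping

A challenge curve is the timed TMAO (and carnitine) concentration series of
one subject in one fluid, starting at the fasting baseline (t = 0) with
samples at 24 and 48 h. Two productivity statistics summarise it:

- **TMAO_MAX** — the maximum over all timepoints, baseline included;
- **TMAO_AUC** — the trapezoid over the observed timepoints, with *no*
  baseline subtraction. Reported challenge AUCs are single raw values whose
  magnitudes (hundreds to ~1200 μM·h over 48 h) match the raw trapezoid, so a
  constant curve at c integrates to 48·c.

Classification is deliberately asymmetric at the boundary: plasma uses the
strict rule (high ⟺ TMAO_MAX **>** 10 μM; 10.0 is *low*), the urine rule is
inclusive (high ⟺ uTMAO_MAX **≥** 162.79 mmol/mol creatinine), matching how
each cutoff is stated clinically. Both comparators are configurable.

The urine cutoff is not a free parameter: it is the image of the plasma
cutoff under an ordinary-least-squares fit of per-subject
(plasma TMAO_MAX, urine TMAO_MAX) pairs, exact (zero residual) on colinear
data. Urine TMAO is expressed in mmol TMAO per mol creatinine throughout;
the equivalent form "nmol/mmol Cr" seen in some tables is numerically
identical.

Curves missing a required timepoint are rejected by default; an
`allow_partial` option accepts any curve with a baseline and ≥ 2 points,
with a warning, since no imputation scheme is defined for these designs.
Reported cohort proportions use round-half-up integer percentages
(25/56 → 45%).

## Renal handling and bioavailability

Fractional excretion borrows the clinical FeNa formula on paired spot
samples: FeX = (uX·pCr)/(pX·uCr)·100, invariant to common rescaling of the
analyte pair and of the creatinine pair separately. Urine analytes are
creatinine-normalised as uX/uCr scaled to mmol/mol. The cohort medians
(FeTMAO near 94%, FeCarnitine well under 2%) express the physiology the
generator emulates: kidneys dump TMAO and conserve carnitine.

Pre/post supplementation changes are tested with a Wilcoxon signed-rank
test using the **Pratt** convention: zero differences enter the ranking of
|d| but are excluded from signing. The null distribution is enumerated
exactly (a convolution over doubled midranks, so ties are handled without
approximation) for n ≤ 25; larger samples use the normal approximation with
the Pratt zero correction, tie correction and a 0.5 continuity correction.
scipy's implementation cannot combine exact enumeration with Pratt zeros,
which is why the test lives in-package; it is cross-checked against
brute-force sign enumeration (n ≤ 12) and against scipy on zero-free data.
All paired differences equal to zero returns p = 1 with a warning.

## Community statistics

Counts enter pre-binned as a samples × OTUs integer matrix with taxonomy
lineages. Single rarefaction draws each sample down to exactly 61,600 reads
without replacement (multivariate hypergeometric, one recorded seed);
samples below depth are dropped, never scaled. The pipeline rarefies first
and then applies the low-count filter (default: drop OTUs with total < 2),
treating the filter as cleanup of the final table; fixtures generated at
exactly the rarefaction depth therefore pass through rarefaction unchanged.

Alpha diversity: Shannon uses natural log over nonzero proportions;
Chao1 is S + F1²/(2·F2), switching to the bias-corrected
S + F1(F1−1)/(2(F2+1)) when no doubletons exist (this also makes Chao1
equal observed richness when there are no singletons). Beta diversity is
Bray-Curtis, ordinated by classical PCoA (negative eigenvalues reported,
coordinates restricted to positive axes, via scikit-bio).

PERMANOVA is the one-way decomposition of squared distances:
SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within summed per group, pseudo-F =
(SS_between/(a−1))/(SS_within/(n−a)), R² = SS_between/SS_total, and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) over label permutations. R²
depends only on the observed labelling; the implementation is cross-checked
against scikit-bio's pseudo-F and its type-I error is verified by
simulation at α = 0.05.

Differential abundance compares per-OTU relative abundances between two
groups by two-sided Mann-Whitney U — exact when both groups have ≤ 20
observations and the pooled values are tie-free, otherwise the
tie-corrected normal approximation — with Benjamini-Hochberg control and
constant OTUs assigned p = 1. Presence of a taxon is count ≥ 1 (post
rarefaction) by default.

## The phenotype classifier

Feature selection ranks OTUs by |Pearson r| between log10(relative
abundance + pseudocount) and log10 urine TMAO_MAX; the pseudocount is half
the smallest nonzero relative abundance, which keeps absent taxa below
every observed value without disturbing rank order. The default k = 39
mirrors the top ~2.5% of a 1637-OTU universe; k is explicit because 2.5%
of 1637 rounds to 41, and the printed 39 is taken as authoritative. Ties
break by OTU id, so selection is deterministic and idempotent.

The classifier is a bagged ensemble of CART trees (sqrt(m) features per
split, bootstrap samples of size n) written as an explicit loop over
sklearn decision trees so bootstrap/out-of-bag indices stay first-class.
Scores are hard-vote fractions. Accuracy is estimated by leave-one-out
cross-validation, pooling the n out-of-fold scores into a *single* ROC
(per-fold ROCs are undefined at LOOCV); AUROC is the trapezoid, equal by
construction to the rank-based U/(n₊·n₋) identity, and the optimal cutoff
maximises Youden's J. Optional AUROC confidence intervals come from a
stratified bootstrap of the pooled scores (2000 replicates by default,
opt-in). Feature importance is Breiman's mean decrease accuracy: per-tree
out-of-bag accuracy drop under within-feature permutation, averaged over
trees. External validation scores a fixed model on a new matrix, aligning
columns by feature id and imputing missing taxa as absent; labels are
never refitted. Cross-validation is sample-wise by default (subject-wise
leave-out would halve the fold count on paired samples and is left to the
caller via the features index). Every stochastic operation takes a seed.

## hGM taxon discovery

A mouse is a d9-producer iff any post-gavage d9-TMA or d9-TMAO value
exceeds the limit of detection (default: the smallest positive value in
the input, configurable; d9-γBB never triggers a call). A group's core is
the intersection of its mice's presence sets. Candidate key taxa are

    (core of the producer group) ∩ (producer donor inventory)
        −  ∪ {OTUs observed in any mouse of any non-producer group}.

Subtracting the *observed* union (not just the other groups' cores) is the
conservative reading of the exclusion Venn — it minimises false
candidates; the core-based variant is available behind a flag
(`exclude="core"`). Producer-enriched taxa aggregate counts to genus,
test producer vs non-producer mice (Mann-Whitney + BH), and by default
require presence in every producer mouse.

Presence/absence diagnostics report confusion counts with percentages
rounded to one decimal; PPV/NPV are reported as not-applicable when their
denominators are empty. The combination search enumerates every non-empty
OR-of-presence subset of ≤ 20 candidates, reports all metrics per rule and
ranks by a chosen criterion (default accuracy; Youden, PPV, sensitivity
and specificity are also computed since the optimality criterion behind
"best combination" claims is rarely stated), breaking ties by higher
specificity, then smaller rule.

## The synthetic-study generator

The generator's defaults are the study conditions, not tuning knobs:

- **Cohort** — 56 subjects (33 omnivores / 23 vegetarians), 45% high
  producers pre-supplementation (25/31), 6 of the high producers
  vegetarian (~26% of vegetarians). Productivity (the plasma peak) is
  uniform on (11, 32) μM for high and (1.5, 9) μM for low producers;
  fasting baselines are uniform on (1, 4) μM capped below the peak.
- **Supplementation** — low producers are multiplied by one common factor,
  calibrated so exactly 7 cross the 10 μM cutoff (passing an explicit
  factor disables calibration; factor 1 shifts nobody). Six high producers
  regress below the cutoff, which is what makes the 112 subject-phase
  samples split 51 high / 61 low as the sample-level analyses assume; with
  no regressions the margins would be 57/55. High producers are otherwise
  unchanged.
- **Challenge curves** — plasma TMAO rises from baseline to the
  productivity peak at 24 h (p = 0.7) or 48 h, with the off-peak point at
  55% of the excursion. Urine TMAO is slope·plasma + N(0, 4) truncated at
  zero, slope 16.279, so the noise-free regression maps 10 μM to exactly
  162.79 mmol/mol creatinine. Plasma creatinine is drawn near 57.7 μM,
  which makes the implied FeTMAO median ≈ 94%; fasting urine carnitine
  means follow the per-phenotype pre/post values (4.79 → ×3.49 in low,
  17.18 → ×0.65 in high producers, log-normal noise).
- **OTU table** — 1637 OTUs over 112 samples. Background OTUs are
  independent log-normals (per-OTU mean sd 1.0, per-sample noise 0.35 in
  log10); a 37-OTU block scales log-linearly with the standardised
  productivity response (slopes 0.25–0.6 log10 units per SD). The two key
  taxa are planted at 8×10⁻⁵ relative abundance (5 reads at depth) in 13
  and 12 high-status samples (overlap 3) plus 2 low-status carriers for
  the second taxon, giving the 22/2 OR-rule confusion counts. Carriers are
  drawn among high-status samples with productivity-weighted (softmax)
  probability so the planted taxa correlate with the response, as rare
  producers do in real cohorts; with uniform carriers a 13/112 binary
  feature would not reliably out-correlate ~1600 null OTUs and
  "planted taxon recovered in the top k" would not be a property of the
  signal. Counts are multinomial at exactly the rarefaction depth (key
  taxa placed deterministically so presence counts are exact);
  `depth_factor > 1` samples deeper to exercise rarefaction nontrivially.
- **hGM fixture** — four groups of 11 mice. The producer donor holds 353
  OTUs; the producer core is exactly 78 (3 candidate OTUs unique to
  producer mice, 16 OTUs in 8 marker genera, 59 commons; donor extras are
  pruned if they ever reach all 11 mice). Non-producer donors share the
  75 non-candidate core OTUs and part of the extras; their mice sample
  inventories at presence 0.95 (core) / 0.7 (other), with any uncovered
  non-candidate core OTU force-assigned so the exclusion leaves exactly
  the 3 candidates. Marker genera are abundant in every producer mouse
  (~800 vs ~10 reads), giving exactly 8 producer-enriched genera; the
  candidates' genera are dominated by OTUs common to all groups so the
  5-read candidates cannot create spurious enrichment. Producer mice get
  d9-TMA/TMAO excursions of 2–6 μM (rise-fall over 24 h) and rising-then-
  falling d9-γBB; non-producers get zero TMA/TMAO and monotone γBB.

All draws descend from one `numpy` SeedSequence; equal seeds give equal
studies. What the generator does **not** emulate: compositional covariance
between taxa, sequencing error, batch effects, subject-level confounders,
or any mechanistic link between the microbiome and the kinetic curves
beyond the planted monotone block. Passing tests therefore demonstrate
correctness of the *analysis* under the planted statistical structure, not
biological validity on real cohorts; in particular the classifier's
near-perfect LOOCV AUROC on synthetic data reflects the planted signal
strength, not expected real-world accuracy.

## Numerical choices and scale

- Permutation p-values use the add-one convention, (1 + hits)/(1 + n_perm).
- The exact Wilcoxon convolution doubles midranks to stay in integer
  arithmetic; two-sided p is 2·min(P(W ≤ w), P(W ≥ w)) capped at 1.
- Degenerate inputs fail loudly: zero-variance regression designs,
  single-class labels, empty samples, zero creatinine, unknown OTU ids.
- Problem sizes in the test suite and acceptance script are desk-scale by
  design: replicate studies of the classifier use 50-tree forests (30 for
  the all-feature reference, 25 for permutation nulls) because the planted
  signal saturates well below the 500-tree default; PERMANOVA calibration
  uses 200 null datasets × 199 permutations; the full pipeline default
  keeps 500 trees and 999 permutations.

## Known limitations

- PERMANOVA is one-way only (no strata/covariates), matching its use here.
- Genus aggregation relies on `g__` tokens in the lineage strings; OTUs
  without one are pooled as unclassified.
- The Mann-Whitney exact path is skipped whenever ties are present, which
  for sparse count data means the asymptotic path is the norm.
- The urine/plasma mapping assumes a single linear relation across
  subjects; no subject-level calibration is attempted.
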