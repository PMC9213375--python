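# Methods

This note records the statistical model behind each component, the
defaults and why they were chosen, and what the synthetic cohorts can and
cannot say about real patients.

## The score ladder

`LesionFeatures` carries six binary MRI findings plus the tumor–capsule
interface length in mm. Two flags are derived: `interface_gt10`
(strictly > 10.0 mm — a contact of exactly 10 mm is negative, mirroring
the "greater than 1.0 cm" criterion) and `measurable_disease`
(recto-prostatic-angle obliteration **or** capsular breach; the two signs
are near-perfectly specific and frequently co-occur, so they are graded as
one finding). Capsular abutment is an independent observation: it is not
inferred from a positive interface length, because a reader can record a
short contact without calling abutment.

Rules are evaluated as an ordered ladder in which the *highest* satisfied
level wins; abutment (level 2) therefore only determines the score when no
level-3+ rule fires. All 2⁶ feature patterns × both interface regimes map
to exactly one score in 1–5, the mapping is monotone (adding a finding or
lengthening the interface never lowers the score), and measurable disease
dominates everything (score 5). These are tested exhaustively.

Rule sets are declarative `(level, condition)` tables serialisable to
YAML, so the three comparator systems ship as data, not code:

* **ESUR-score** — a qualitative 1–5 ladder without the interface-length
  criterion (abutment 2, margin/contour signs 3, NVB asymmetry 4,
  measurable disease 5), positive > 3;
* **mEPE-grade** — 0–3 with a **15-mm** contact criterion and contour
  signs, omitting abutment and NVB asymmetry (one criterion = 1, both = 2,
  frank extension = 3), positive > 1;
* **early-and-late-EPE** — 1 none / 2 "early" capsule-contact signs /
  3 "late" measurable disease, positive > 1.

All three are **provisional reconstructions** from secondary summaries of
those systems, flagged `provisional=True` and overridable via
`--config`/`load_rulesets_config`; conclusions about the comparators
should be read as "a system of this shape", not as faithful replicas.

## Accuracy statistics

Every statistic is a binomial proportion of a 2×2 table: Se = tp/(tp+fn),
Sp = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn),
accuracy = (tp+tn)/n, and the *detection rate* (the fraction of
feature-positive patients with pathologic EPE) which coincides with PPV.
Confidence intervals default to the Wald form p̂ ± z·√(p̂(1−p̂)/m), clipped
to [0,1]: this is the interval that reproduces the reference tables
(e.g. Se 23/45 = 0.51, CI 0.365–0.66 at m = 45). Wald is known to
under-cover for small m or extreme p̂; Wilson and Clopper–Pearson are one
keyword away and recommended for new analyses. A zero denominator marks
the statistic undefined rather than zero.

The odds ratio is the cross-product (tp·tn)/(fp·fn) with the log-scale
Wald interval exp(ln OR ± z·√(Σ1/cell)) — identical to the univariate
logistic MLE for a binary predictor, which `univariate_blr` verifies
through an actual statsmodels `Logit` fit. Any zero cell yields
"not determined" (interval 0–∞), matching how separated features should be
reported; a Haldane–Anscombe +0.5 correction exists behind a flag but is
not the default. OR p-values are Wald z-tests of the logistic slope,
falling back to Fisher's exact test when a zero cell makes the Wald test
meaningless.

Mann-Whitney uses scipy's exact null distribution for combined n ≤ 12
without ties, a full permutation enumeration (two-sided p = 2·min(tail
probabilities), capped at 1) for small tied samples, and the tie-corrected
normal approximation otherwise.

## ROC analysis and threshold choice

Operating points are the achievable cutoffs of the ordinal score under the
strict convention "positive ⇔ score > t" — no interpolation between
attainable points, because a 1–5 scale has only five usable thresholds.
The AUC is computed as the mean DeLong placement value, which equals both
the trapezoidal area over the empirical polyline and the concordance
probability P(score₊ > score₋) + ½P(tie); the equality is asserted against
independent pair-counting and geometric oracles, and against
scikit-learn's `roc_auc_score`. CIs and the paired test use DeLong's
placement-value (co)variance; Hanley–McNeil is available by keyword.
Unpaired curves are compared with a z-test on the two DeLong standard
errors.

The operating threshold is selected by the triple criterion — maximum
harmonic mean of Se and Sp, maximum Youden J, minimum Euclidean distance
to (Se, Sp) = (1, 1). When the three disagree, all three candidates are
reported, `agreed=False`, and the Youden maximizer is selected: Youden is
the only criterion with an unambiguous formula in the source convention.
Ties within a criterion resolve to the lower threshold, favouring
sensitivity.

## Cohen's kappa

κ = (p_o − p_e)/(1 − p_e) with chance agreement from the marginal
products, computed through `statsmodels.stats.inter_rater.cohens_kappa`,
whose Fleiss-type asymptotic variance feeds a normal CI clipped to
[−1, 1]. Multi-category score agreement is unweighted by default (no
weighting scheme is specified for the reference analysis); linear weights
are available and coincide with unweighted κ when only two categories
occur. The degenerate case of two identical constant raters (p_e = 1) is
defined as κ = 1 with a `degenerate` flag. Labels follow Landis–Koch:
< 0 poor, 0–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80
substantial, 0.81–1.00 almost perfect.

## The synthetic cohort generator

Defaults encode the derivation cohort: prevalence 0.45 (45/100
pEPE-positive) and per-feature conditional rates from the printed counts,
P(feature | pEPE) = detections/45 and P(feature | no pEPE) =
(positives − detections)/55 — e.g. abutment (1.0, 52/55), interface > 10 mm
(23/45, 8/55), irregular margin (33/45, 20/55), bulging (31/45, 6/55),
NVB asymmetry (11/45, 2/55), measurable disease (9/45, 0).

Only the marginals are published; the joint distribution is not. Features
are therefore coupled through one latent standard-normal severity z per
patient: feature i is positive when ρz + √(1−ρ²)ε_i exceeds the normal
quantile of its conditional rate. This Gaussian-copula threshold model was
chosen over shifting logistic intercepts by z because it preserves every
calibrated conditional marginal *exactly* (the parameter-recovery tests
demand agreement within 3 binomial SEs at n = 10⁵), while still making
feature co-occurrence increase with severity. The loading defaults to
ρ = 0.5 — a moderate pairwise latent correlation of 0.25 — as a
middle ground between independence (which would overstate the score's AUC)
and near-redundant features; it is a config knob, and cohort-level AUC
outcomes should be read as approximate consequences of this choice, never
as calibrated targets.

Interface lengths are log-normal with median 8 mm and σ = 0.58 (the mean
of the two σ values implied by the slightly asymmetric printed quartiles
5 and 11), truncated to [0, 50] mm and drawn by inverse CDF on the side of
10 mm dictated by the `interface_gt10` flag, so flag and length never
disagree. Measurable disease splits into angle obliteration vs. breach at
the printed 4 : 9 ratio. ISUP grade is categorical
(1/2/3/4/5 → 0.01/0.38/0.37/0.15/0.09, reconciling the partially
inconsistent printed counts to P(ISUP ≥ 3) ≈ 0.6) and independent of pEPE,
consistent with the reported absence of a subgroup AUC difference. The
second reader re-reads each of the six assessed findings with per-feature
flip probabilities defaulting to (abutment 0.20, interface 0.15, margin
0.12, bulging 0.12, NVB 0.10, measurable 0.03) — chosen once to reproduce
the reported *ordering* of inter-reader agreement (abutment worst,
measurable disease almost perfect), not its exact κ values.

`make_fixture_cohort` is different in kind: a deterministic 100-patient
table built by count allocation (severity-ordered patients, each feature
marking a prefix of its class, measurable disease nested inside
interface > 10) whose per-feature 2×2 tables equal the reconstructed
derivation tables cell for cell. It exists for bit-exact regression tests,
not as a sample from the generative model.

What the generator does **not** emulate: site effects, reader-specific
bias (flips are symmetric), correlation between ISUP and severity, lesion
geometry, and any feature dependence beyond the single-factor copula.
Passing tests on synthetic cohorts demonstrate internal consistency of the
machinery and plausibility of the study-scale behaviour — not clinical
performance on real patients.

## Pipeline and determinism

`DerivationStudy` / `ValidationStudy` / `ReaderStudy` orchestrate the
modules and never compute statistics themselves; tests spot-check that
every reported number equals the underlying operation called directly.
Reports carry a provenance block (SHA-256 digest of the input table, seed,
package version); all randomness flows through one seeded
`numpy.random.Generator`, and `reproduce-paper` output and seeded
simulations are byte-identical across runs. Raw p-values are reported
without multiplicity adjustment, matching the reference analysis style.

Problem sizes used by the test suite — 10⁴ patients for
threshold-selection checks, 10⁵ for parameter recovery, 200 replicates for
null-calibration and oracle sweeps — keep every stochastic check
comfortably inside 3-SE bands while the whole suite runs in seconds.

## Known limitations

* The comparator rule sets are reconstructions (see above).
* Wald intervals are kept as the default only for fidelity to the
  reference tables.
* Several printed values in the reference tables are internally
  inconsistent with their own counts (specificity and NPV of capsular
  abutment, a few CI endpoints, and odds-ratio points sitting 2–3% above
  the cross-products); the package documents these in
  `reproduce-paper`'s `discrepancies.csv` and reproduces only the
  consistent values.
* Agreement handles exactly two raters; no Fleiss κ / Krippendorff α.
* No multivariable models or clinical nomograms: the score is purely
  imaging-based by design.
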