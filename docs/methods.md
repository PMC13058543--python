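# Methods

## Scores

Both scores are sums of independent integer components over structured chest
X-ray findings; no interaction or combination rules exist, so a patient with
mixed contusion patterns must be pre-abstracted to a single ordinal grade by
the data supplier.

| component | C-CTS | SA-CTS |
|---|---|---|
| age (<45 / 45–65 / >65) | 1 / 2 / 3 | — |
| rib fractures (0 / 1–2 / 3–5 / >5) | see below / 1 / 2 / 3 | 0 / 1 / 2 / 3 |
| bilateral rib fractures | 2 | 2 |
| contusion (none → bilateral major) | 0–4 | 0–4 |
| pneumothorax | — | 1 |
| haemothorax | — | 1 |

Band edges are inclusive where ambiguous: age 45 and 65 fall in the middle
band, rib counts 3 and 5 in the "3–5" band. These choices are fixed, not
configurable.

**Zero-rib convention.** The published C-CTS component table assigns the
"< 3 fractures" category one point, which read literally gives an uninjured
patient a rib score of 1 and a score floor of 2. Published worked examples
are split: one is only consistent with the literal reading, two others with
an uninjured chest scoring 0. Both conventions are implemented behind
`ZeroRibRule`; the literal table is the default because it is what the
component table states and what produces the documented 2–12 range. The
SA-CTS resolves the ambiguity by definition (0 fractures → 0). The bilateral
component is scored independently of the count band: two fractures, one per
side, score rib 1 + bilateral 2 under the SA-CTS.

A missing field is a validation error, never an implicit zero.

## Exact inference

All margins of an observed table are treated as fixed. For a 2×2 table the
conditioned cell follows Fisher's noncentral hypergeometric distribution
P(X = x | ψ) ∝ C(m, x) C(n, k − x) ψˣ over support
max(0, k−n) ≤ x ≤ min(k, m).

* **p-values** use probability-mass ordering at ψ = 1: p is the sum of
  P(t) over tables with P(t) ≤ P(obs) · (1 + 10⁻⁷). The relative slack
  absorbs floating-point ties and matches R's `fisher.test`, whose estimates
  these routines reproduce; tail-doubling definitions are deliberately not
  offered. A table with a zero margin yields p = 1 (logged).
* **Odds ratio** is the conditional MLE: the ψ with E_ψ[X] = x_obs. The
  expectation is strictly increasing in ψ, so the root is unique; it is
  found by Brent's method on log ψ over [−50, 50] (machine-precision
  tolerances, far tighter than the 10⁻⁹ relative accuracy quoted in the
  API). Observed cells at the support minimum/maximum map to 0 / ∞.
* **Confidence intervals** invert the exact tails: the lower bound solves
  P_ψ(X ≥ x_obs) = α/2, the upper P_ψ(X ≤ x_obs) = α/2, with the same
  boundary conventions. Shrinking the confidence level provably shrinks the
  interval; tests check nesting and that the CMLE always lies inside.
* **r×c tables** are tested by complete enumeration of all tables with the
  observed margins (recursive row fill), summing multivariate
  hypergeometric probabilities under the same mass ordering. The enumerator
  refuses workloads above a configurable cap (default 10⁷ tables) rather
  than silently approximating; all per-variable tables arising from a
  ~300-patient cohort with ≤ 5 levels are far below it. All-zero rows or
  columns are dropped before testing (they carry no information), not
  treated as degeneracy.

All probability computations run in log space via `gammaln`, stable for
totals to ~10⁴. Exact integer/rational arithmetic appears only in the test
oracles, which re-derive every p-value definition independently
(exhaustively for all 2×2 tables with total ≤ 30). `scipy`'s
`fisher_exact`/`odds_ratio` serve as a second, independent cross-check in
tests; the implementation does not call them.

## Cutpoint analysis

The per-score outcome curve reports exact critical/non-critical counts at
every score value, padding unattained values in the scheme's theoretical
range with zeros. Dichotomization at cutoff c forms rows (score < c,
score ≥ c) against (non-critical, critical).

Threshold selection in the source analyses was visual ("the critical
fraction rises sharply at …"). The implemented surrogate is reproducible:
among feasible candidates (both groups non-empty), select the cutoff
minimizing the two-sided exact p, breaking ties toward the smaller cutoff.
The full sweep — per-candidate table, p, OR, CI, sensitivity, specificity —
is always returned so users can overrule the rule. Sensitivity/specificity
are descriptive companions; no ROC/AUC machinery is included. Note that
min-p selection over many candidates inflates the type-I error well above
the nominal 5% (measured at roughly 10–25% across 200 null replicates in the
test suite); the selected cutoff's p-value should not be read as a
single-test p-value.

## Synthetic cohort generator

The generator emulates a 301-patient adult ED cohort. Demographics and
findings are sampled independently from fixed marginals: male 0.708; age
bands (0.761, 0.183, 0.056); mechanisms (0.601, 0.299, 0.070, 0.020, 0.010);
rib bands (0.631, 0.230, 0.136, 0.003) with the count uniform within its
band (">5" realized as 6–8 — any count ≥ 6 scores identically);
contusion grades (0.359, 0.256, 0.123, 0.176, 0.086); pneumothorax 0.086;
haemothorax 0.375. Bilaterality is sampled only when the count is ≥ 2, with
conditional probability 0.183 chosen so the implied marginal bilateral rate
is the observed 4.7%.

**Outcome coupling.** Outcome depends on findings only through the SA-CTS
(a deliberate simplification that makes threshold recovery well-posed). Two
logistic links are available:

* `step` (default): P(critical) = expit(α + β·1[SA-CTS ≥ 4]) — a genuine
  risk jump at the threshold, the direct generative analogue of a
  dichotomized risk table, and the coupling under which the min-p sweep
  recovers the generating threshold in ≥ 95% of 301-patient replicates;
* `linear`: P(critical) = expit(α + β·SA-CTS) — a smooth dose-response
  alternative. Under it the minimum-p cutoff wanders over adjacent values
  (recovery ~30% at n = 301), which is why it is not the default for
  recovery experiments.

Because the SA-CTS distribution implied by the marginals has a closed form
(a small convolution, including the rib/bilaterality cases and the optional
pleural dependence), both links are calibrated by exact nested root-finding,
not simulation: the intercept matches the population critical fraction
(target 0.328, to 10⁻³) and the slope matches the population odds ratio of
score ≥ 4 (target 4.17, well within 5%).

Disposition is then drawn within the outcome class (critical →
ICU/death/T-piece at 86:11:2; non-critical → ward/discharged at 200:2), and
ventilation conditionally on outcome (29/99 vs 3/202). Ventilation is a
consequence label only; no causal claim is modelled.

**What the generator does not emulate:** correlations among findings (only
marginals are known; an optional multiplier for pleural injury given ≥ 3
fractures exists, default off), referral-pattern selection, polytrauma
outliers (low-score critical patients with extra-thoracic injuries), and the
age–outcome confounding seen in real cohorts. Passing recovery tests
therefore show the *pipeline* is correct and well-powered under the stated
coupling, not that the SA-CTS threshold would replicate in new clinical
data.

All randomness flows from one `numpy` generator seeded per cohort, with
fields drawn in a fixed documented order, so cohorts are bit-reproducible
across platforms.

## Reporting

The full-analysis driver re-derives the outcome label from disposition
(any outcome column in an input file is ignored), runs the per-variable
association battery (2×2 variables get p + conditional-MLE OR + exact CI;
≥ 3-level variables get the r×2 exact p only), the curves, the sweeps and
the dichotomized analysis, and renders everything as CSVs plus a checksum
manifest. No multiple-testing correction is applied: each variable is tested
at α = 0.05 and flagged, and raw p-values are printed (3 dp, or scientific
with 3 significant digits below 0.001); readers combining many tests should
adjust externally. The rendering layer formats numbers already computed by
the analysis modules; it recomputes nothing.

## Problem sizes used in the checks

The oracle-equivalence checks enumerate all 46 376 2×2 tables with total
≤ 30 and 40 random 3×2 tables with total ≤ 15; recovery and null
experiments use 200 replicates of 301-patient cohorts; marginal-convergence
checks use single 50 000-patient cohorts (tolerance 0.01). These sizes give
stable verdicts while keeping the full suite fast.

## Known limitations

* The r×c enumerator is exact but exponential; it is meant for the small
  tables of cohort analyses, not for large sparse tables (no Monte Carlo or
  network-algorithm fallback is provided).
* No asymptotic (chi-square/Wald) methods, no Mantel–Haenszel
  stratification, no regression adjustment — the analysis is deliberately
  the exact univariable battery.
* The scores themselves are implemented exactly as tabulated; no
  re-weighting or validation against external scoring systems (TTSS, Rib
  Score, etc.) is attempted.
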