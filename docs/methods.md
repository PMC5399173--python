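# Methods

This note records the models, parameter choices and numerical conventions
behind `reosig`, and what the synthetic experiments do and do not establish.

## The REO model

A relative expression ordering (REO) rule is the boolean indicator
I(G\_a > G\_b) evaluated within one sample.  Because the comparison never
leaves the sample, a rule's value is invariant under any strictly monotone
transform of that sample's measurements (rank transforms, positive affine
maps, exponentiation, ...) and under any per-sample global shift.  Gene-wise
additive batch shifts shared across samples *can* flip an ordering when the
two genes' values are closer than the shift, which is why the builder
prefers pairs with large within-sample rank gaps and why
`rank_difference_diagnostic` reports the mean rank gap per rule (together
with the size of the rank universe, since the gap scales with it).

A signature is an ordered list of rules, each tagged with the sign of its
Cox coefficient: β > 0 means the ordering G\_a > G\_b is a risk factor.  A
sample is called high risk when at least half of its non-abstaining rules
vote high; the tie goes to high by the literal "at least a half" reading, so
with six rules ≥ 3 risky orderings ⇒ high.  A rule abstains when either gene
is missing; a sample abstaining on more than half of the rules is reported
unclassifiable rather than guessed.

## Statistical kernel

* **Spearman correlation** with the t-approximation for the p-value; an
  exact permutation p is available for n ≤ 10.  Two-sided throughout (the
  screens' sidedness is not otherwise constrained, and two-sided is the
  conservative choice).
* **Wilcoxon rank-sum**: exact enumeration when both groups have ≤ 12
  observations and no ties; otherwise the normal approximation with tie and
  continuity corrections.
* **Fisher's exact test**, two-sided by summing tables with probability ≤
  the observed table (the R convention).
* **Hypergeometric enrichment** as the upper tail P(X ≥ observed overlap).
* **Concordance scores** s/k with significance from the upper-tail binomial
  at p\_e = 0.5.  Note that k sign-concordances bound the attainable p-value
  below by 2^−k; a 30-gene screen can therefore reach 9.3e-10 but not
  smaller, and the package reports the exact tail rather than a generic
  floor such as 1.1e-16.
* **Cox proportional hazards** is implemented directly: Newton–Raphson on
  the partial likelihood with Efron tie handling (Breslow selectable),
  step-halving, convergence at relative log-likelihood change < 1e-9 within
  50 iterations.  Monotone-likelihood separation is flagged as
  non-converged when |β| > 15 or SE > 50 — a pure |β| bound misses
  plateaued likelihoods whose gradient vanishes at moderate β.  The
  implementation is cross-checked against an independent survival package
  in the test suite to ~1e-5 agreement on tied and untied data.
* **Harrell's C-index** uses an explicit permissible-pair rule: a pair is
  usable iff the member with the shorter time has an event; with equal
  times, one event makes the pair usable with the event as the earlier
  member, two events exclude the pair.  Concordant pairs score 1, score
  ties 0.5.  One consequence worth stating: a *binary* risk score cannot
  reach C = 1 even under perfect separation, because within-group
  permissible pairs are score ties (2-vs-2 perfect separation gives
  C = 5/6, not 1).
* **Benjamini–Hochberg** step-up adjustment.  BH-adjusted values are *not*
  a fixed point of the procedure (the valid output (0.2, 0.6) re-adjusts to
  (0.4, 0.6)), so the tests assert the real guarantees — bounds, order
  preservation and equivalence of the rejection set with the classic
  step-up rule — rather than idempotence.

## Signature construction

Pairs are enumerated once per unordered pair in lexicographic orientation:
testing both orientations would duplicate each test with a mirrored β and
double the multiple-testing burden for no information.  Expression ties make
the indicator false (strict inequality).  Each surviving rule's solo C-index
uses its own binary vote as the risk score.  Set2 sorts by descending solo
C-index with ties broken by smaller p-value, then lexicographic pair id, so
the ordering is a deterministic function of the rule set.

**Forward selection scores the graded vote count, not the collapsed
label.**  The natural-looking alternative — recompute the majority-vote
*label* after each tentative addition and demand its C-index increase — is
degenerate, and the package deliberately departs from it.  With the
tie-goes-high rule, any even-sized rule set labels roughly 75% of samples
high (one high vote out of two suffices), and the C-index of that lopsided
partition essentially never exceeds the preceding odd-sized step: across
both independent and shared-latent-factor vote models, in population
(n = 200,000) and at n = 300, the label-based greedy terminates after a
single rule.  A one-rule signature contradicts the very possibility of
multi-pair signatures built this way.  Scoring the candidate set by the
C-index of the *number of high votes* — the quantity the majority vote
thresholds — makes each genuinely informative rule raise the score and
reproduces the expected behavior (five to seven rules accepted, the planted
rules first).  Classification itself still uses the majority-vote label;
only the selection criterion is graded.  The label-based criterion remains
available (`forward_select(..., score="binary")`) for anyone who wants to
observe the degeneracy.  The default stopping policy is stop-at-first-
failure; skip-and-continue is available behind a flag.

No internal cross-validation is performed: selection optimizes the training
C-index, and hold-out performance is reported only when an explicit
validation cohort is supplied (the synthetic experiments always generate
one).

## Synthetic data: what it emulates

`SimConfig` defaults define the reference study conditions used by the test
suite and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_genes` / `n_samples` | 412 / 300 | 6 planted pairs (12 genes) + 400 noise genes |
| `pair_effect` | ln 3 | log-hazard added per risky ordering |
| `baseline_hazard` | 0.001 /month | relapse hazard at zero risky orderings |
| `censor_rate` | 0.025 /month | independent exponential censoring |
| `reversal_prevalence` | 0.30–0.70 | per-pair firing rates, evenly spread |
| `pair_state_noise` | 0.8 | sd of per-pair deviation from the latent risk |
| margins | U(2.5, 4) log2 | ordering margin within a pair (noise sd 0.3) |
| `n_cell_lines` / `gi50_coupled_genes` | 58 / 30 | cell panel with latent resistance score |
| `group_sizes` | 90 / 90 | omics contrast groups |
| `cna_region_freqs` | e.g. (0.956, 0.435) | per-region (high, low) alteration rates |
| `msi_high_freqs` | (0.12, 0.28) | MSI-High rate in (high, low) group |

Design rationale:

* **Shared latent risk.**  Each sample carries a latent risk factor; pair
  *p* reverses when risk + deviation exceeds a pair-specific threshold.
  Real signature rules track a common biology but trigger at different
  points of the risk continuum; statistically, this is also the regime in
  which combining several binary rules outperforms any single one.  With
  fully independent pair states, no greedy selection over votes can help
  even in population terms.
* **Within-pair shared baseline.**  The two genes of a pair share a
  per-sample baseline (sd 3) that cancels inside the pair comparison but
  dominates comparisons with other genes.  The planted information
  therefore lives in the pair *ordering*, not in single-gene levels —
  the premise of the REO approach — and cross-pair gene combinations carry
  little signal.
* **Hazard model.**  Relapse times are exponential with hazard
  baseline · exp(pair\_effect · #risky orderings) and independent
  exponential censoring; the defaults give ≈ 45–55% observed relapses over
  a median ~28-month follow-up, a deliberately event-rich but not absurd
  adjuvant-cohort profile.  A Cox fit on the true risky-ordering count
  recovers `pair_effect` within ±10% at n = 5000 (asserted in the tests).
* **Margins.**  Ordering margins of 2.5–4 log2 units against within-pair
  noise of sd 0.3 make the observed ordering equal the latent state
  essentially always, and give the planted pairs large within-sample rank
  gaps — the robustness property the rank-gap diagnostic measures.
* **Omics layers.**  Region-level copy-number calls, gene-level mutations
  and MSI-High labels are Bernoulli draws with per-group frequencies
  (defaults mirror a strong amplification block ~0.96 vs ~0.43, a deletion
  block ~0.88 vs ~0.39, mutation excess in the low-risk group, and null
  features); methylation betas are inverse-logit of −(coupling) ·
  (expression − 8) plus noise, planting the negative
  methylation–expression correlation.

What the generator does **not** emulate: realistic gene–gene correlation
networks, platform-specific noise, informative censoring, missingness
patterns, or probe-level artifacts.  Passing tests therefore demonstrate
the pipeline's correctness and calibration under its stated model — not
clinical performance on real cohorts, which depends on data the package
does not ship.

Determinism: one integer seed; every component derives its own substream
via `numpy.random.SeedSequence(seed, spawn_key=(component,))`, so outputs
are bit-identical across runs and machines with the same numpy.

## Degenerate inputs and numerical conventions

Constant genes are skipped with a warning in every screen (an undefined
correlation is an error at the single-call level).  Pairs with constant
indicators (including identical expression rows) are excluded before
testing.  Non-converged Cox fits are excluded and logged.  The multivariate
Cox design must be full rank after dropping incomplete rows; constant and
collinear columns are rejected by name.  Fisher/hypergeometric inputs are
validated as consistent nonnegative counts.  All screens apply BH within
the set of features actually tested.

## Problem sizes in the test suite

The suite exercises the pipeline at the reference conditions above: 50-seed
end-to-end recovery, 10-seed × 4-transform invariance, 100-seed
copy-number power, 20-seed Cox recovery at n = 2000, and ≥ 50 random
instances per enumeration oracle.  These sizes were chosen to make each
binomial pass/fail bound comfortably away from its expected value under
correct behavior.

## Known limitations

* The pair screen is quadratic in the candidate gene count; it is intended
  for post-screen lists (tens of genes), not transcriptome-wide pair
  enumeration.
* The forward selection is greedy and ordering-dependent by design; it
  reproduces the published procedure's structure rather than searching for
  a global optimum.
* Survival machinery assumes right-censoring with non-informative censoring
  times; no competing risks, time-varying covariates or stratified models.
* The bundled six-pair signature is provided as published values; this
  package cannot re-derive it without the original cohorts.
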