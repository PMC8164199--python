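# Methods

## Model and assumptions

The package treats multi-receptor acute toxicity as a profile-similarity
problem. Each compound contributes one comparison sequence per receptor:
its EC50/LC50 concentration in mg/L. The reference sequence is the
constant classification boundary (1.0 mg/L — the conventional cutoff
below which a substance is classed as acutely "very toxic" to aquatic
life). Because all sequences share the same units and scale, no
dimensionless pre-normalization is applied — deliberately; the pipeline
provides no hook for one, since rescaling would silently change the
difference extremes and hence every coefficient.

For compound $k$ and receptor sequence $i$, the absolute difference from
the reference is $\Delta_i(k) = |x_0 - x_i(k)|$, and the grey
interconnect coefficient is

$$\xi_i(k) = \frac{\Delta_{\min} + \rho \Delta_{\max}}
                  {\Delta_i(k) + \rho \Delta_{\max}}.$$

The per-compound grey interconnect degree is the weighted horizontal
mean of the coefficients across receptors. Interpretation: a compound
whose toxicity values sit near the 1 mg/L boundary in every receptor
has small differences, coefficients near 1, and a degree near 1 —
meaning *low* comprehensive toxicity. The statistic is a ranking device,
not a dose–response model: it assumes the panel is complete and
positive, and it is sensitive to panel composition by construction
(extremes are taken over the compounds present).

### The two extreme conventions

The textbook coefficient uses double extremes,
$\min_i \min_k \Delta_i(k)$ and $\max_i \max_k \Delta_i(k)$ (mode
`global`). In practice, grey-relational software frequently computes
each comparison sequence's own $\min_k, \max_k$ (mode `per_sequence`).
The two disagree whenever the columns have different difference ranges.
On the reference phthalate panel the per-sequence form is the one that
reproduces the published coefficient table cell-for-cell (e.g. DEHP's
fish coefficient is 0.7268 under fish-column extremes but 0.6027 under
the global extremes, which happen to coincide with the daphnid column's).
We default to `per_sequence` to match the reference results, keep
`global` as an explicit mode, and treat the discrepancy as a fact about
conventions to be surfaced, not resolved: which one any given historical
analysis "intended" is generally unknowable, so the choice is a named
parameter rather than a heuristic.

### Degenerate inputs, ties, numerics

- A panel whose values all equal the reference has $\Delta \equiv 0$ and
  an undefined coefficient (0/0); this raises `DegeneratePanelError`
  rather than producing NaN. In per-sequence mode the error triggers
  per column.
- $\xi = 1$ exactly iff $\Delta$ equals the governing minimum; a
  single-compound panel therefore has all coefficients 1.
- No rounding happens mid-pipeline. Published tables print 6 decimals
  for differences and 4 for coefficients/degrees, so comparisons against
  them use absolute tolerances of one rounding ulp (6e-7) and 1e-3
  respectively. CSV writers apply 6/4-decimal display formatting only.
- The coefficient is invariant to scaling the whole difference matrix
  (extremes included) by any $c > 0$; tests exploit this algebraic
  cancellation as a cheap correctness check.

## Screening rules

All comparisons reduce to the change rate $(new-old)/old \times 100$,
computed unrounded; two-decimal display is separate.

- **Stage 1 (activity increase).** A derivative passes when its
  estimated comprehensive characterization value exceeds the parent's by
  strictly more than the threshold (default 10%). Strict, because the
  rule is "more than"; a tie at exactly the threshold fails.
- **Stage 2 (all-receptor reduction).** Computed on negative-log values
  (pEC50/pLC50), where a *negative* rate means the concentration rose,
  i.e. toxicity fell. A derivative passes only when every receptor's
  rate is strictly negative.
- **Proportionality.** "Close to 1:1:…:1" is quantified as
  max|rate|/min|rate| across receptors, defined only when all rates are
  nonzero and share a sign. The default advisory bound is 2.5, chosen so
  that derivative sets historically described as near-proportional
  (ratio ≈ 2.35) fall inside it; the raw ratio is always reported next
  to the flag because the bound is a judgment call, not a published
  criterion.

## Property evaluation

- **Stability.** The rule operates on the change rate of the total
  electronic energy as tabulated (hartree, negative values). A
  non-positive rate passes outright; a positive rate passes while
  strictly below the limit (default 5%). Note that on an all-negative
  energy axis the rate's sign is inverted relative to the physical
  energy direction; the evaluator follows the tabulated-rate convention
  so its verdicts agree with the published assessments, and documents
  this rather than silently "fixing" it.
- **Insulation.** The HOMO–LUMO gap change is reported with no
  threshold — no conventional cutoff exists.
- **Existence.** Lowest vibrational frequency > 0 (a true minimum on the
  potential-energy surface).
- **POPs.** Change rates for log Kow, log Koa and air half-life;
  persistence flag = half-life > 48 h (the two-day criterion). The
  log-descriptor rates are percent changes *of the logarithm*, which is
  unconventional but matches how such tables are published; every
  verdict carries a note saying so.
- **Docking.** Per-protein score change; `all_weaker` requires strictly
  negative change everywhere (identical scores are not "weaker").
- **Metabolism.** $\Delta E = E_{TS} - \sum E_{reactant}$ in whatever
  units the caller supplies; no hartree↔kJ/mol conversion is performed,
  because published barrier tables are already in kJ/mol and unit
  bookkeeping belongs to the data provider.

## Pharmacophore-model validation

The signed error ratio is $+est/act$ when the model over- (or exactly)
estimates and $-act/est$ otherwise: the fold-error with a direction,
magnitude always ≥ 1. This formula is a reconstruction — hypothesis-
generation software prints the value without defining it — validated
against all 14 published fit rows: the sign is recovered for every
compound and the magnitude to within 0.015, which is exactly the
uncertainty propagated from the printed inputs (estimates printed to 2–3
decimals carry ±0.005 rounding; a ratio near 1.07 of a 0.74 estimate
inherits ≈ ±0.013). Five published rows differ from the printed-input
recomputation by 0.01 in the second decimal, consistent with the
original values having been computed from unrounded internal estimates;
the package reports the ratio of the inputs it is given and does not
attempt to reverse-engineer hidden precision.

Model acceptance: configuration cost ≤ 17 (non-strict, "should not be
greater than"), correlation > 0.7 (strict), every |error| < 2. The
total-minus-fixed cost gap is reported without a threshold. The verdict
is monotone: improving any single diagnostic can never flip a pass to a
fail.

## Synthetic data

The generator emulates the numeric regime the pipeline assumes — it is a
stress-tester for the arithmetic, not a toxicity model:

- concentrations $10^{p_k + s_i + \varepsilon}$ with compound potency
  $p_k \sim U(-5, -0.2)$ in log10 mg/L (the published panel spans
  ~1.4e-6 to 0.6 mg/L), receptor offsets $s_i$ defaulting to
  (green algae −0.35, daphnid +0.33, mysid −0.55, fish +0.28) to mirror
  the reference sensitivity ordering with mysid consistently most
  sensitive, and log-normal noise with $\sigma = 0.15$;
- values are clipped strictly below the 1 mg/L reference (margin 1e-6 in
  the exponent) so the monotone-remission property is well-posed; a
  `clip=False` flag allows boundary-crossing panels for robustness
  testing;
- derivatives shift a parent profile by a uniform log10 amount
  (optionally jittered per receptor), so a positive shift is a provably
  less-toxic derivative, giving closed-form expectations for the
  screens;
- property cases realize requested change rates exactly on both sides of
  every decision boundary (±5% energy, frequency sign, 48 h half-life);
- one seeded `numpy.random.Generator` per run; no global state; same
  seed ⇒ bit-identical output.

What passing on synthetic data does *not* show: anything about chemistry.
No structure–activity relationship is simulated, receptor correlations
are purely additive offsets, and noise is homoscedastic in log space —
real QSAR-predicted panels violate all three. Synthetic results certify
the arithmetic and its invariants (bounds, scale invariance, permutation
equivariance, monotone remission, oracle agreement), while the shipped
reference tables certify agreement with the published worked example.

## Problem sizes and test design

All computations are closed-form on small matrices; the full suite and
the acceptance script each run in seconds. Property-based tests use 5×3
to 14×4 panels with seeded/derandomized generation — the statistic's
behaviour does not change with scale (it is row/column-extreme
arithmetic), so small panels exercise every code path, including tie and
degenerate cases. The independent oracle used in tests is a deliberately
naive loop-based recomputation sharing no code with the vectorized
implementation.

## Known limitations

- Degrees depend on panel composition: adding or removing a compound
  changes the extremes and hence every coefficient. This is intrinsic to
  the statistic, not a defect, but it means degrees from different
  panels are not comparable.
- The comprehensive characterization value weighs all receptors equally
  by default; ecological importance weighting is the caller's decision
  via `weights`.
- The screening thresholds (10%, 5%, 48 h, 2.5) are conventions carried
  from the validated workflow, exposed as parameters, and not themselves
  statistically derived.
- The package evaluates supplied numbers; it performs no toxicity
  prediction, conformer generation, docking or quantum chemistry.
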