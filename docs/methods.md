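# Methods

## Model

Each mRNA's expression is modelled as a linear combination of the
expression of all miRNAs on the panel: for mRNA *i* and sample *k*,
`Y[i,k] = Σ_j a_ij X[j,k]`, or `Y = A X` with `A` an n × m coefficient
matrix.  A negative `a_ij` reads as inhibition of mRNA *i* by miRNA *j*,
the biologically expected direction for miRNA regulation; the model itself
does not constrain the sign.  The model is condition-specific: one `A` is
fitted per condition (normal, cancer) from that condition's paired panels.

Assumptions worth stating plainly: linearity of the miRNA→mRNA map,
instantaneous (steady-state) relations with no dynamics, no interaction
terms among miRNAs, and no unmodelled regulators — mRNA variance not
attributable to the panel's miRNAs is absorbed into the residual.  miRNA
expression is treated as an exogenous covariate (measured, not modelled).

Both panels must share sample IDs; `align_panels` restricts them to the
intersection.  Whether miRNA and mRNA profiles come from physically matched
samples is an interpretation the caller must make — the package requires
shared IDs and leaves the pairing semantics to the data.

No expression normalization is applied by default.  An optional
`log2(x+1)` pre-transform is exposed (off by default) for callers whose
panels span decades of intensity.

## Estimation

`A` is estimated by minimizing an error norm of the residual `A X − Y`:

* **L1**: `Σ_ik |(A X − Y)[i,k]|`
* **L2**: `Σ_ik (A X − Y)[i,k]²`

with either **BFGS** (quasi-Newton, analytic gradients) or **Powell**
(direction-set, derivative-free), always from a **zero initial guess**.
BFGS pairs well with L1 and Powell with L2; Powell with L1 is exposed but
carries no convergence guarantee (it is known to behave poorly on this
objective, and its outcome is recorded rather than asserted).

Both norms are sums over mRNA rows, so the n·m-parameter joint problem is
the direct sum of n independent m-parameter row problems with the same
optimum.  `fit_rowwise` (the pipeline default) exploits this; the joint
solver `fit_interactions` exists for small problems and for verifying the
equivalence, which the test suite asserts on consistent systems.

### Numerical choices

* **L1 smoothing.** The L1 norm is non-smooth at zero residual, which is
  incompatible with a curvature-based line-search method.  The optimizer
  is handed the hyperbolic smoothing `Σ sqrt(r² + ε²)` with
  `ε = l1_smoothing_eps` (default 1e-9, configurable; the exact norm is
  recovered as ε → 0).  All *reported* errors (`final_error`,
  `per_row_error`) are the exact unsmoothed norm.
* **Stopping.** Three criteria, first met wins: exact objective ≤ `gtol`
  (default 1e-14, checked each accepted iteration and implemented as a
  graceful optimizer halt); gradient infinity-norm ≤ 1e-12 (BFGS) or the
  optimizer's own xtol/ftol termination (Powell); `max_iter` (default
  10000 per subproblem).  The secondary criteria exist so inconsistent
  (noisy) systems terminate; hitting `max_iter` sets `converged=False` and
  is never an exception.
* **Convergence labelling.** A fit is labelled converged when every row met
  the objective rule or a gradient-based stop.  Because an absolute
  tolerance of 1e-14 sits below floating-point resolution once a row's
  targets are large (machine epsilon times the data magnitude exceeds it),
  the converged judgement — not the stopping rule — floors the threshold at
  `16 · eps_machine · ‖y_row‖`.  Noisy fits, whose residuals are orders of
  magnitude above that floor, are still honestly labelled unconverged when
  they stall above `gtol`.
* **Zero initialization** is mandatory.  In the underdetermined regime it
  acts as an implicit bias toward small-magnitude solutions (BFGS and
  Powell search within the span of gradients/directions explored from the
  origin), which is what makes truly-zero coefficients come out numerically
  tiny rather than arbitrary.
* **Monotone descent.** Per-row objective traces (recorded at accepted
  iterations) are exposed on `FitResult.traces`; both optimizers enforce
  descent via their line searches, and the suite asserts the traces never
  increase.
* **Determinism.** No randomness anywhere in estimation; identical inputs
  and options give bit-identical fits.

### The underdetermined ("malpositioning") regime

With fewer samples than miRNAs per row (K < m) — the package's target
regime, e.g. 26 miRNAs against 4–7 samples — infinitely many matrices
reproduce the data exactly.  The fit drives the residual to numerical zero
while individual coefficients remain partially unidentified; two different
exact solutions can differ substantially in their nonzero pattern.  The
pipeline diagnostics flag this regime (`underdetermined: true` per
condition) rather than pretending the coefficients are well determined.
Downstream, the comparison step partially compensates: coefficients that
are spurious in the same way in both condition fits cancel in the CV.

## Comparison and selection

`CV[i,j] = (P_normal[i,j] − P_cancer[i,j]) / max(|P_normal[i,j]|, eps)`
with `eps = 1e-12` guarding division by zero.  Entries with
`|P_normal| ≤ eps` but differing coefficients are flagged *unstable* and
excluded from selection (a relative change from a zero baseline is
undefined; passing such entries through would surface as arbitrarily huge
scores).  The zero-initialized solver returns truly-zero coefficients at
~1e-15, safely under this threshold.

CV is used **signed**: the canonical signature of interest — a weak
inhibitory coefficient in normal tissue becoming strongly negative in
cancer — gives a large positive CV (e.g. −0.1 → −5.83 scores 57.3).  An
absolute-value mode exists behind a flag for sensitivity analysis.

Two cutoffs are exposed because both appear in practice: an **inclusion**
threshold of 0.5 (the screening rule applied to every pair) and a
**reporting** threshold of 5.0 (the score used for headline tables and
frequency figures).  Selection additionally requires `a_cancer < 0` by
default (the inhibitory reading of a candidate relation in the tumor fit);
this is toggleable since "negative relationship" admits more than one
formalization.  Tables are sorted by descending CV with lexicographic
(mRNA, miRNA) tie-breaks for deterministic output.

## Sequence filtering

Prediction resources are consumed as pair lists (TSV: miRNA, mRNA,
optional source) — no sequence scanning is performed here, and the
resources carry no condition information.  Matching is case-insensitive
with an optional alias map, because miRNA naming is inconsistent across
resources ("miR-98" vs "miR-98a").  Default mode is `any` (support from a
single resource suffices); `all` demands unanimous support and always
selects a subset of `any`.  Filtering is annotation-only — it never alters
CVs or row counts — unless `drop=true`.

## Synthetic data

The generator emulates small paired tumor-profiling panels: defaults are
26 miRNAs × 26 mRNAs, 4 normal and 7 cancer samples — the shape where the
method is meant to operate and the per-row systems are underdetermined.

* Interaction matrix: `edge_density` (default 0.15) of the n·m entries
  nonzero, values uniform on [−2, −0.2] (inhibitory-only, matching the
  biology; a mixed-sign mode exists for stress testing).  Default density
  is a choice — sparse enough that a gene has a few regulators, dense
  enough that a 26 × 26 panel carries ~100 edges.
* Condition change: a seeded `change_fraction` (default 0.25) of the
  nonzero edges is scaled by `effect_multiplier` (default 3) in cancer, or
  zeroed; `changed_edges` is defined by actual matrix inequality.
* miRNA expression: positive lognormal (log-mean 0, log-sd 1), a standard
  stand-in for intensity-scale expression.
* mRNA expression: the forward model plus optional Gaussian noise on Y
  only (X is a measured covariate) — the minimal noise model consistent
  with the linear formulation.
* Fully reproducible from the seed, bit for bit.

What the generator does **not** emulate: probe/batch effects, heavy-tailed
or multiplicative measurement noise, unmodelled regulators, nonlinearity,
and miRNA–miRNA correlation structure.  Passing tests on synthetic data
therefore demonstrate correctness of the machinery and the identifiability
behavior of the model — not that real tumor panels satisfy the linear
model's assumptions.

## Problem sizes used in the checks

The bundled checks run at: 50 random 4 × 4 systems with K = 8 for
solver-vs-oracle agreement; an 8 × 8 panel with K = 16 per condition for
exact changed-edge recovery (well-determined, noiseless, effect
multiplier 3); the 26 × 26, K = 4/7 shape for the underdetermined regime
(676 coefficients); and a 4 × 4 benchmark for the optimizer/norm matrix.
These sizes keep the whole suite under a minute while covering both
identifiability regimes.

## Known limitations

* Coefficients from underdetermined fits are start-dependent estimates,
  not identified parameters; only their condition-difference signal is
  interpreted, and even that can miss changes that the zero-start solution
  manifold absorbs.
* The CV denominator makes scores scale-free but explodes as
  `|P_normal| → 0`; the unstable-entry exclusion handles the numerical
  zero case but a genuinely tiny (not zero) normal coefficient still
  yields a large, hard-to-interpret score.
* No uncertainty quantification or multiple-testing control — selection is
  by fixed cutoffs, as the procedure defines.
* Powell + L1 is exposed for completeness but not guaranteed to converge.
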