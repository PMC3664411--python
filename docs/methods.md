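# Methods

## Model

The package analyses models built from a **single** stage-classified
matrix pair `(U, F)`: individuals age, but their vital rates depend
only on their current stage. This is the "age-from-stage" setting — the
age dimension is pure bookkeeping over a stage-driven life cycle, which
is exactly what makes the resulting age patterns interpretable as
emergent consequences of stage dynamics rather than of age-specific
rate estimates. Genuinely age-and-stage-estimated rates (different
`U_i`, `F_i` per age class) are accepted by `build_projection` — the
finite-difference oracle depends on that — but no analysis in the
package exercises them beyond single-cell perturbations.

Conventions, fixed throughout:

- Matrix orientation: column = source stage, row = destination.
- The projection interval is one year (every worked matrix is annual);
  age class `i` is reported as "age `i` years", 1-based in all output,
  0-based in the Python API.
- The state vector groups stages within age classes
  (`n[j + i*s]` = stage `j`, age class `i`); the vec-permutation matrix
  `K` switches to ages-within-stages where ageing operators are block
  diagonal.
- The final age class is open (ages `>= omega`): the age-advance matrix
  `D_U` has a 1 in its lower-right corner. The open class is retained in
  the model and all arrays, flagged in output, and excluded from
  critical-age searches — its gradient aggregates all ages beyond
  `omega` and would otherwise masquerade as a late peak.

## Parameterization of the perturbations

- Mortality. `U = G diag(sigma)` with `sigma_j` the column sum of `U`
  and `G` the transitions conditional on survival. The trait is the
  force of mortality `mu = -log sigma`, perturbed additively in one
  (stage, age) cell; equivalently column `j` of `U` at age `i` scales by
  `exp(-h)`. Stages with `sigma_j = 0` carry `mu = +inf` and an exactly
  zero gradient row: with no survival there is nothing mortality can
  reduce. `G`'s columns for such stages are zero and flagged.
- Fertility. The trait `phi_j` adds, per capita of stage `j`, one
  offspring of *every* offspring type: the perturbation matrix is
  `Phi = z phi'` where `z_i = 1` iff row `i` of `F` is positive
  (configurable override). All gradients are evaluated at `phi = 0`,
  the observed life history.
- Fitness metric: `r = log lambda` by default; `lambda` optionally. The
  two gradient arrays differ by the constant factor `1/lambda`, so
  critical ages are identical under either choice (tested).

## Key tunable parameters

| parameter | default | meaning |
|---|---|---|
| `omega` | `"auto"` | age classes; `"auto"` = smallest omega with >= `coverage` of the stable age-stage mass below the open class |
| `coverage` | 0.99 | coverage for the omega rule |
| `metric` | `"r"` | fitness metric for gradients |
| `max_excess` | 0.1 | largest tolerated column-sum overshoot of `U` before rescaling is refused |
| `fnss_index` | first non-seed stage | stage whose life expectancy `eta` scales critical ages |
| oracle `h` | 1e-6 | finite-difference step (years of mortality hazard / offspring per capita) |

The `omega` coverage criterion is evaluated on the omega-truncated model
itself (the object actually analysed), via the closed-form stable
structure below; the search doubles then bisects, capped at 5000 by
default. When within-stage survival persists at the growth rate
(`rho(U) -> lambda`) the open class never empties and the rule has no
solution; the search reports that instead of returning the cap.

Survival rescaling (for published matrices whose column sums slightly
exceed 1 through rounding or sampling) scales the offending columns of
`U` to sum exactly 1 (`sigma = 1`, `mu = 0`); overshoots beyond
`max_excess` are treated as misplaced fertility and refused. Exact-1 is
a convention; nothing downstream depends on the residual epsilon.

## Numerical choices

- **Eigensystems.** Dense LAPACK for dimension `s*omega <= 2000`;
  above that, for single-matrix models, the closed form: `lambda` and
  the stable stage distribution `w_A` come from the `s x s` matrix `A`,
  age class 1 of the stable structure is `F w_A / lambda`, each next
  class applies `U / lambda`, and the open class applies
  `(lambda I - U)^{-1} U`. Reproductive value is age-independent
  (`v = 1 ⊗ v_A`), because an individual's future depends only on its
  stage. Both closed forms agree with the numeric eigenvectors to
  ~1e-13 (tested) and sidestep the badly conditioned large sparse
  eigenproblems that arise for near-critical life cycles. ARPACK
  remains the fallback for large non-uniform matrices.
- **Normalizations.** `w` sums to 1, `v'w = 1`. All gradient formulas
  are ratios, hence invariant to these choices (tested).
- **Imprimitivity.** A life cycle whose dominant eigenvalue ties in
  modulus with a complex pair (e.g. strict semelparity) still has a
  real Perron root; the analysis proceeds with a spectral-gap warning.
  Only when no real positive dominant root exists is an error raised.
- **Degenerate inputs.** `sigma_j = 0` stages (flagged, zero gradient
  row); all-zero `F` (fertility gradients zero, with a warning);
  `rho(U) >= 1` (life expectancy undefined — error); `omega < 3`
  (no interior to search for critical ages — error).
- **Ties.** Critical-age argmax ties break to the earliest age —
  conservative against overstating contra-senescence. Gradient rows
  with maximum magnitude below 1e-14 are reported "undefined" rather
  than assigned age 1.

## The finite-difference oracle

The analytic gradients implement the chain rule through the two-term
structure of the projection matrix. Their verification contract is a
*central finite difference* over the age-expanded model: rebuild with
the single `(stage, age)` cell perturbed by `±h` and difference the
fitness. Two evaluation modes:

- `direct`: literal rebuild + full eigensolve + subtraction. Its
  absolute accuracy saturates near `eps/(2h)` because two nearly equal
  eigenvalues are subtracted — fine for leading entries, hopeless for
  entries many orders of magnitude down (deep age classes of growing
  populations decay geometrically).
- `compensated` (default): the same central difference, but the
  eigenvalue *shift* `d = lambda(perturbed) - lambda` is the computed
  object. The perturbation matrix `E` is assembled exactly (the
  construction is linear in the per-age blocks, so only one column
  propagates), and `d` is found by Newton iteration on the bordered
  system `[(Atilde - lambda I), -w; v', 0]` in increment form, the base
  residual evaluated once in extended precision. No large quantities
  are ever subtracted, so the difference retains full relative accuracy
  — measured ~1e-7 relative even for entries near 1e-13. The two modes
  are cross-checked against each other in the tests.

Oracle agreement is enforced at relative 1e-5 on every entry with
magnitude above 1e-12, across 50 random life cycles with `s` in 2..8
and `omega` in 3..40 (entries below the floor must also be below 1e-9
in the oracle). A step-halving diagnostic warns when the difference
fails to contract at second order (step too large, or below the noise
floor of the direct mode).

## Life expectancy

`eta_j` is the column sum of the fundamental matrix `(I - U)^{-1}`,
**including** the starting census (`eta_j >= 1`; a stage with no
survival has `eta = 1`). Conventions that exclude the first census
differ by exactly 1; the inclusive convention applies everywhere `eta`
scales an axis or a critical age. The scaling stage (FNSS, first
non-seed stage) is configuration with a sensible default, because
seed-bank residence times are usually the least trusted part of a plant
matrix; the package does not try to detect seed stages itself.

## The synthetic generators, and what passing tests do not show

`random_lefkovitch` draws per-column survival in (0.2, 0.98) split into
stasis / growth / retrogression (shrinkage included — the feature that
produces strong contra-senescent phases), with fertility from the last
third of the stages, screened to growth rates in (0.3, 3) and a
spectral gap above 1e-3. `leslie_fixture` produces strictly
age-classified schedules with finite lifespan (no terminal self-loop),
for which the classical closed-form gradients are exact and the
age-stage arrays must concentrate on stage = age. Generation is
deterministic per seed (PCG64).

These generators emulate the *structure* of published plant matrices,
not their estimation: no sampling noise, no near-reducible life cycles,
no seasonal or environmental variation, and survival never exceeds 1.
Tests passing on them certify the algebra and numerics of the method —
they say nothing about any real species until a transcribed published
matrix is supplied through the CSV interface. Problem sizes in the test
and acceptance sweeps (up to `s = 8`, `omega = 40` for oracle
comparisons; `omega` in the hundreds only through the closed-form
path) were chosen as the smallest families that exercise every code
path with comfortable margins.

## Known limitations

- Only additive perturbations of `mu` and `phi`; proportional
  perturbations need a different parameterization and are out of scope.
- One projection matrix per species: no density dependence,
  environmental stochasticity, or second-order (history-dependent)
  transitions.
- The single-matrix construction makes within-stage mortality and
  fertility gradients proportional across age; conclusions about their
  *relative* age profiles within a stage are constrained by design.
- Critical ages are reported in age-class units; sub-annual resolution
  would require a shorter projection interval, not interpolation.
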