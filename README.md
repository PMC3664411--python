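# agestage

Age-by-stage matrix population models for the demography of senescence
in stage-structured organisms (plants in particular), with selection
gradients on age- and stage-dependent mortality and fertility.

## The problem

In purely age-classified demography the selection gradients on additive
mortality and fertility perturbations are non-increasing with age: a
trait that harms old individuals costs less fitness than one harming
young individuals, which makes senescence evolutionarily inevitable
whenever early and late performance trade off. Plant demography,
however, is driven by stage (usually size), not age. A stage-classified
projection matrix `A = U + F` — `U` holding survival/transition
probabilities, `F` per-capita offspring production — says nothing about
age on its own. This package expands a single stage-classified matrix
into a joint **age-by-stage** model and asks: within a given stage, how
does the strength of selection on mortality and fertility change with
age?

The answer, for many stage-structured life cycles, is that it first
*increases* (a contra-senescent phase) before declining (pro-senescent).
The age-class at which the gradient within a stage peaks is the
**critical age**; rescaled by the life expectancy `eta` of the first
non-seed stage it is comparable across species.

## The model

With `s` stages and `omega` age classes, the population state is an
`s x omega` matrix `N`; its vectorization `n = vec N` is projected by

```
Atilde = K' (I_s ⊗ D_U) K (I_omega ⊗ U) + K' (I_s ⊗ D_F) K (I_omega ⊗ F)
```

where `K = K_{s,omega}` is the vec-permutation matrix
(`K vec N = vec N'`), `D_U` advances extant individuals one age class
(the last class is open: ages `>= omega`), and `D_F` sends new recruits
to age class 1. The growth rate `lambda` (fitness `r = log lambda`),
stable age-stage structure `w` and reproductive values `v` come from
the dominant eigensystem of `Atilde`.

Writing `U = G diag(sigma)` with `sigma = exp(-mu)` (so `mu` is the
force of mortality per stage) and perturbing fertility through
`Phi = z phi'` (indicator `z` marking offspring types), the selection
gradients on mortality and fertility of stage `j` in age class `i` are

```
d r / d mu_{j,i}  = - (v' M_U)_[i] U[:,j] * w_{j,i} / (lambda v'w)   <= 0
d r / d phi_{j,i} =   (v' M_F)_[i] z      * w_{j,i} / (lambda v'w)   >= 0
```

with `M_U`, `M_F` the two ageing operators above. Summing over stages
gives the gradient on purely age-dependent traits (which is
non-increasing, as in age-classified theory); summing over ages
reproduces exactly the stage-classified gradients. Every analytic entry
is verifiable against a central finite-difference oracle built on the
age-expanded model.

## Worked example

The two-stage life cycle `U = [[0, 0], [0.5, 0.8]]`,
`F = [[0, 2], [0, 0]]` (juveniles mature with probability 0.5, adults
survive with probability 0.8 and produce 2 juveniles each):

```python
import agestage as ag

m = ag.fixtures.toy_two_stage()
omega = ag.select_omega(m)            # 99% coverage rule -> 9
model = ag.build_projection(m, omega)
eig = ag.eigen_analysis(model)
print(omega, eig.lam)                 # 9 1.4770329614269042
field = ag.compute_gradients(model, eig)
print(field.grad_mu[1, :3])           # [-0.         -0.17023569 -0.09220414]
print(ag.fundamental_matrix(m).eta)   # [3.5 5. ]
```

The growth rate equals the dominant root of
`lambda^2 - 0.8 lambda - 1 = 0`, i.e. `(0.8 + sqrt(4.64))/2`. The
adult-mortality gradient row is zero in age class 1 (recruits are
juveniles, so no adult can be that young), peaks at age class 2 — the
first age at which adults exist — and declines thereafter. Richer
life cycles (retrogression, multiple adult classes) produce genuine
interior peaks; `critical_ages` locates them per stage. Life
expectancies are 3.5 years for a juvenile and 5 for an adult.

The same analyses run from the shell on CSV matrices:

```
agestage build --u U.csv --f F.csv --config cfg.json --out summary.csv
agestage gradients --u U.csv --f F.csv --config cfg.json --fd-check --out gradients.csv
agestage critical-ages --u U.csv --f F.csv --config cfg.json --out critical.csv
agestage pool --glob 'results/*.csv' --out pooled.csv
```

`cfg.json` declares the offspring stages, seed stages, the first
non-seed stage, `omega` (or `"auto"`), and the fitness metric (`r` or
`lambda`); stage indices in configuration and output are 1-based.

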