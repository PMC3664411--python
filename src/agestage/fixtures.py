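"""Synthetic stage-classified matrices and closed-form oracles.

Three generators cover the model space:

* :func:`leslie_fixture` — purely age-classified (Leslie) life cycles
  in which stage and age class coincide. These admit the classical
  closed-form selection gradients (:func:`hamilton_gradient_oracle`):
  on additive age-specific mortality the gradient is the negative
  discounted reproduction remaining beyond that age, non-increasing
  with age; on fertility it is the discounted survivorship, decreasing
  whenever the population is not declining.
* :func:`random_lefkovitch` — random stage-structured (size-classified)
  life cycles with stasis, growth and retrogression (shrinkage), the
  structure typical of plant matrices.
* :func:`toy_two_stage` — a tiny two-stage worked example with
  hand-checkable eigenvalue ``(0.8 + sqrt(4.64)) / 2``.

Generation is deterministic given the seed; the RNG is
``numpy.random.default_rng`` (PCG64), part of the fixture contract.
"""

from __future__ import annotations

import numpy as np

from .stage_io import AnalysisConfig, StageMatrixSet, build_stage_set

__all__ = [
    "leslie_fixture",
    "hamilton_gradient_oracle",
    "random_lefkovitch",
    "toy_two_stage",
]


def toy_two_stage() -> StageMatrixSet:
    """Two-stage worked example: U = [[0,0],[0.5,0.8]], F = [[0,2],[0,0]]."""
    U = np.array([[0.0, 0.0], [0.5, 0.8]])
    F = np.array([[0.0, 2.0], [0.0, 0.0]])
    return build_stage_set(U, F)


def leslie_fixture(p: np.ndarray, f: np.ndarray) -> StageMatrixSet:
    """Leslie (age-classified) life cycle as a stage set with stage == age.

    Parameters
    ----------
    p : array, length a-1
        Survival probabilities from age class x to x+1, in [0, 1). No
        self-loop is placed on the last class, so lifespan is finite and
        the classical finite-lifespan gradient formulas apply exactly.
    f : array, length a
        Per-capita fertilities by age class (recruits into class 1);
        at least one must be positive.
    """
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    a = f.size
    if p.size != a - 1:
        raise ValueError(f"need {a - 1} survival probabilities for {a} age classes")
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("survival probabilities must lie in [0, 1)")
    if np.any(f < 0) or not np.any(f > 0):
        raise ValueError("fertilities must be nonnegative with at least one positive")
    U = np.zeros((a, a))
    U[np.arange(1, a), np.arange(a - 1)] = p
    F = np.zeros((a, a))
    F[0, :] = f
    return build_stage_set(U, F)


def hamilton_gradient_oracle(leslie: StageMatrixSet) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form age-classified selection gradients of ``r``.

    For a Leslie life cycle with survivorship ``l_x`` (probability of
    being alive at age class ``x``; ``l_1 = 1``), fertility ``m_x``,
    growth rate ``lambda`` and generation time
    ``T = sum_x x lam^-x l_x m_x``:

    * mortality: ``d r / d mu_x = -(sum_{y > x} lam^-y l_y m_y) / T``
    * fertility: ``d r / d m_x = lam^-x l_x / T``

    Returns ``(mortality, fertility)`` gradients, length ``a`` each.
    """
    U, F = leslie.U, leslie.F
    a = leslie.s
    sub = U[np.arange(1, a), np.arange(a - 1)]
    if np.any(U - np.diag(sub, k=-1) != 0) or np.any(F[1:] != 0):
        raise ValueError("hamilton_gradient_oracle requires a Leslie structure")
    lam = np.max(np.real(np.linalg.eigvals(leslie.A)))
    m = F[0]
    l = np.concatenate([[1.0], np.cumprod(sub)])  # survivorship to class x
    x = np.arange(1, a + 1)
    disc = lam ** (-x.astype(float)) * l * m  # lam^-x l_x m_x
    T = float((x * disc).sum())
    # tail sums over ages strictly beyond x
    tail = np.concatenate([np.cumsum(disc[::-1])[::-1][1:], [0.0]])
    grad_mu = -tail / T
    grad_phi = lam ** (-x.astype(float)) * l / T
    return grad_mu, grad_phi


def random_lefkovitch(
    s: int,
    seed: int,
    retrogression_prob: float = 0.5,
    max_tries: int = 200,
) -> StageMatrixSet:
    """Random stage-classified (size-based) life cycle.

    Column ``j`` of ``U`` splits a survival probability drawn uniformly
    from (0.2, 0.98) into stasis, growth to stage ``j+1`` and (with
    probability ``retrogression_prob`` per column) retrogression to
    stage ``j-1`` — plants can shrink. Fertility flows from the last
    ``ceil(s/3)`` stages into stage 1, scaled so the life cycle is
    neither collapsing nor exploding. Candidates are screened to have a
    growth rate in (0.3, 3) and a positive spectral gap; the first
    passing candidate of the seeded stream is returned, so output is
    deterministic per ``(s, seed)``.
    """
    if s < 2:
        raise ValueError("need at least 2 stages")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        U = np.zeros((s, s))
        for j in range(s):
            sigma = rng.uniform(0.2, 0.98)
            use_retro = j > 0 and rng.random() < retrogression_prob
            parts = rng.dirichlet(np.ones(3 if use_retro else 2))
            U[j, j] += sigma * parts[0]
            U[min(j + 1, s - 1), j] += sigma * parts[1]
            if use_retro:
                U[j - 1, j] += sigma * parts[2]
        F = np.zeros((s, s))
        n_fertile = -(-s // 3)  # ceil(s/3)
        fertile = np.arange(s - n_fertile, s)
        F[0, fertile] = rng.uniform(0.5, 4.0, size=n_fertile)
        m = build_stage_set(U, F)
        ev = np.linalg.eigvals(m.A)
        mods = np.sort(np.abs(ev))[::-1]
        lam = float(np.max(np.real(ev)))
        gap_ok = mods.size < 2 or (mods[0] - mods[1]) / mods[0] > 1e-3
        if 0.3 < lam < 3.0 and abs(lam - mods[0]) < 1e-9 * mods[0] and gap_ok:
            return m
    raise RuntimeError(f"no acceptable random life cycle after {max_tries} draws (seed {seed})")
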