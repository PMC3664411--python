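"""Age-from-stage life-course statistics.

The transition matrix ``U`` defines an absorbing Markov chain (death is
the absorbing state). Its fundamental matrix ``N = (I - U)^{-1}`` gives
the expected number of time steps spent in each stage before death; the
column sums are the life expectancies ``eta_j`` of an individual
starting in stage ``j``. The census year is counted (``eta_j >= 1``):
``eta_j = 1' (I-U)^{-1} e_j`` includes the starting census, so a stage
with no survival has ``eta = 1`` exactly. Conventions that exclude the
starting census differ by a constant 1.

The life expectancy of the first non-seed stage (FNSS) is the scaling
factor used to compare critical ages across species, avoiding the
poorly known residence times of seed banks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stage_io import StageMatrixSet

__all__ = ["FundamentalMatrix", "fundamental_matrix", "simulate_lifetimes"]


@dataclass(frozen=True)
class FundamentalMatrix:
    """Fundamental matrix of the mortality chain and derived life expectancies."""

    N_fund: np.ndarray  # (s, s): expected visits to row stage from column stage
    eta: np.ndarray  # (s,): life expectancy by starting stage
    fnss_index: int

    @property
    def eta_fnss(self) -> float:
        return float(self.eta[self.fnss_index])


def fundamental_matrix(m: StageMatrixSet) -> FundamentalMatrix:
    """Solve ``(I - U) N = I``; life expectancy is the column sum.

    Requires the spectral radius of ``U`` to be strictly below 1 (some
    mortality reachable from every stage); otherwise expected lifetimes
    diverge.
    """
    s = m.s
    rho = np.max(np.abs(np.linalg.eigvals(m.U))) if s > 1 else float(m.U[0, 0])
    if rho >= 1.0 - 1e-10:
        raise ValueError(
            f"spectral radius of U is {rho:.10g}: immortal life cycle; "
            "life expectancy undefined"
        )
    N = np.linalg.solve(np.eye(s) - m.U, np.eye(s))
    eta = N.sum(axis=0)
    return FundamentalMatrix(N_fund=N, eta=eta, fnss_index=m.fnss_index)


def simulate_lifetimes(
    m: StageMatrixSet,
    start_stage: int,
    n_paths: int,
    rng: np.random.Generator,
    max_steps: int = 10**6,
) -> np.ndarray:
    """Monte-Carlo lifetimes (number of censuses alive) under ``U``.

    Each path starts in ``start_stage`` at its first census (counted, so
    every lifetime is >= 1) and at each step either moves by the
    conditional-transition law or dies with probability ``1 - sigma``.
    Returns the array of ``n_paths`` lifetimes; its mean estimates
    ``eta[start_stage]``.
    """
    s = m.s
    if not (0 <= start_stage < s):
        raise ValueError(f"start_stage {start_stage} out of range 0..{s - 1}")
    # cumulative destination probabilities per source column; mass beyond
    # sigma_j is death
    cum = np.cumsum(m.U, axis=0)
    lifetimes = np.ones(n_paths, dtype=np.int64)
    state = np.full(n_paths, start_stage, dtype=np.intp)
    alive = np.ones(n_paths, dtype=bool)
    for _ in range(max_steps):
        if not alive.any():
            return lifetimes
        u = rng.random(alive.sum())
        col = cum[:, state[alive]]  # (s, n_alive)
        dest = (u[None, :] < col).argmax(axis=0)
        died = u >= col[-1]
        idx = np.flatnonzero(alive)
        state[idx[~died]] = dest[~died]
        alive[idx[died]] = False
        lifetimes[idx[~died]] += 1
    raise RuntimeError("lifetime simulation exceeded max_steps; U nearly immortal?")
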