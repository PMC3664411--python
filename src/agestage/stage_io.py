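"""Stage-classified demography: reading, validation and parameterization.

A stage-classified projection matrix ``A`` is supplied decomposed into a
transition matrix ``U`` (survival and movement of extant individuals) and
a fertility matrix ``F`` (per-capita production of new individuals,
sexual plus asexual). Which entries of ``A`` are reproductive is
biological knowledge, so the decomposition is required as input rather
than guessed.

The mortality parameterization writes ``U = G @ diag(sigma)`` where
``sigma_j`` is the survival probability of stage ``j`` (the column sum of
``U``), ``G`` holds transition probabilities conditional on survival, and
the force of mortality is ``mu = -log(sigma)`` entry-wise. Fertility
perturbations are additive: a unit of the perturbation parameter
``phi_j`` adds one offspring of every offspring type (the stages flagged
by the indicator ``z``) to the output of stage ``j``, i.e. the
perturbation matrix is ``Phi = outer(z, phi)``. All gradients downstream
are evaluated at ``phi = 0``.

Matrix orientation follows the population-projection convention:
column ``j`` is the source stage, row ``i`` the destination.
Python indices are 0-based throughout the API; file and CSV output use
1-based stage numbering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StageMatrixSet",
    "StageMatrixError",
    "AnalysisConfig",
    "read_stage_matrices",
    "read_matrix_csv",
    "write_stage_matrices",
    "build_stage_set",
    "rescale_excess_survival",
    "offspring_indicator",
]

#: Tolerance below which a column sum of U may exceed 1 without comment.
SURVIVAL_TOL = 1e-9


class StageMatrixError(ValueError):
    """Structural or validation failure of a stage-classified matrix."""


@dataclass(frozen=True)
class AnalysisConfig:
    """User-facing analysis configuration.

    Stage indices in configuration files are 1-based (matching published
    matrix tables); they are converted to 0-based on load.
    """

    offspring_stages: Sequence[int] | str = "auto"  # 0-based after load
    seed_stages: Sequence[int] = ()  # 0-based after load
    fnss_index: int | str = "first_non_seed"  # 0-based after load
    rescale_survival: bool = False
    max_excess: float = 0.1
    omega: int | str = "auto"
    coverage: float = 0.99
    metric: str = "r"

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        kwargs: dict = {}
        off = raw.get("offspring_stages", "auto")
        kwargs["offspring_stages"] = (
            "auto" if off == "auto" else tuple(int(i) - 1 for i in off)
        )
        kwargs["seed_stages"] = tuple(int(i) - 1 for i in raw.get("seed_stages", ()))
        fnss = raw.get("fnss_index", "first_non_seed")
        kwargs["fnss_index"] = fnss if fnss == "first_non_seed" else int(fnss) - 1
        for key in ("rescale_survival", "max_excess", "omega", "coverage", "metric"):
            if key in raw:
                kwargs[key] = raw[key]
        cfg = cls(**kwargs)
        if cfg.metric not in ("r", "lambda"):
            raise StageMatrixError(f"metric must be 'r' or 'lambda', got {cfg.metric!r}")
        if not (0.0 < cfg.coverage < 1.0):
            raise StageMatrixError(f"coverage must be in (0, 1), got {cfg.coverage}")
        return cfg


@dataclass(frozen=True)
class StageMatrixSet:
    """A validated stage-classified demography ``A = U + F``.

    Attributes
    ----------
    U, F : ndarray, shape (s, s)
        Transition and fertility matrices; nonnegative.
    G : ndarray, shape (s, s)
        Transitions conditional on survival; column ``j`` sums to 1 when
        ``sigma[j] > 0`` and is identically zero otherwise (such stages
        are listed in ``zero_survival_stages``).
    sigma, mu : ndarray, shape (s,)
        Survival probability (column sums of ``U``) and force of
        mortality ``-log(sigma)`` (``+inf`` where ``sigma == 0``).
    z : ndarray, shape (s,)
        0/1 indicator of offspring stages (rows of ``F`` receiving new
        recruits), possibly overridden by configuration.
    stage_labels : tuple of str
    seed_flags : ndarray, shape (s,)
        0/1 markers of seed or seedbank stages.
    fnss_index : int
        First non-seed stage (0-based), used for life-expectancy scaling.
    """

    U: np.ndarray
    F: np.ndarray
    G: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray
    z: np.ndarray
    stage_labels: tuple
    seed_flags: np.ndarray
    fnss_index: int
    zero_survival_stages: tuple = field(default_factory=tuple)

    @property
    def s(self) -> int:
        return self.U.shape[0]

    @property
    def A(self) -> np.ndarray:
        return self.U + self.F

    def phi_matrix(self, phi: np.ndarray) -> np.ndarray:
        """Fertility perturbation matrix ``Phi = outer(z, phi)``."""
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (self.s,):
            raise StageMatrixError(f"phi must have length {self.s}")
        return np.outer(self.z, phi)


def _validate_square(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise StageMatrixError(f"{name} must be square, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise StageMatrixError(f"{name} contains non-finite entries")
    bad = np.argwhere(M < 0)
    if bad.size:
        i, j = bad[0]
        raise StageMatrixError(
            f"negative entry in {name} at (row {i + 1}, col {j + 1}): {M[i, j]}"
        )
    return M


def offspring_indicator(F: np.ndarray, override: Sequence[int] | None = None) -> np.ndarray:
    """0/1 indicator of offspring stages.

    By default stage ``i`` is an offspring type iff row ``i`` of ``F``
    has a positive entry. ``override`` (0-based indices) replaces the
    default, for life cycles where recruitment rows are known a priori.
    """
    F = _validate_square(F, "F")
    s = F.shape[0]
    if override is not None:
        z = np.zeros(s)
        for i in override:
            if not (0 <= int(i) < s):
                raise StageMatrixError(f"offspring stage index {i} out of range 0..{s - 1}")
            z[int(i)] = 1.0
        return z
    return (F.max(axis=1) > 0).astype(float)


def build_stage_set(
    U: np.ndarray,
    F: np.ndarray,
    *,
    config: AnalysisConfig | None = None,
    stage_labels: Sequence[str] | None = None,
) -> StageMatrixSet:
    """Validate ``U`` and ``F`` and derive ``G``, ``sigma``, ``mu``, ``z``.

    Raises
    ------
    StageMatrixError
        On dimension mismatch, negative entries, or a column sum of ``U``
        exceeding 1 beyond tolerance when rescaling is not enabled.
    """
    cfg = config or AnalysisConfig()
    U = _validate_square(U, "U")
    F = _validate_square(F, "F")
    if U.shape != F.shape:
        raise StageMatrixError(f"U and F dimensions differ: {U.shape} vs {F.shape}")
    s = U.shape[0]

    sigma = U.sum(axis=0)
    excess = sigma - 1.0
    if np.any(excess > SURVIVAL_TOL):
        j = int(np.argmax(excess))
        if cfg.rescale_survival:
            U = _rescale_columns(U, sigma, cfg.max_excess)
            sigma = U.sum(axis=0)
        else:
            raise StageMatrixError(
                f"column sum of U for stage {j + 1} is {sigma[j]:.6g} > 1; "
                "enable rescale_survival if this is rounding error"
            )
    sigma = np.minimum(sigma, 1.0)

    with np.errstate(divide="ignore"):
        mu = -np.log(sigma)

    zero = sigma <= 0
    G = np.zeros_like(U)
    if np.any(~zero):
        G[:, ~zero] = U[:, ~zero] / sigma[~zero]

    override = None if cfg.offspring_stages == "auto" else cfg.offspring_stages
    z = offspring_indicator(F, override)

    seed_flags = np.zeros(s)
    for i in cfg.seed_stages:
        if not (0 <= int(i) < s):
            raise StageMatrixError(f"seed stage index {i} out of range 0..{s - 1}")
        seed_flags[int(i)] = 1.0

    if cfg.fnss_index == "first_non_seed":
        non_seed = np.flatnonzero(seed_flags == 0)
        if non_seed.size == 0:
            raise StageMatrixError("all stages flagged as seed; no first non-seed stage")
        fnss = int(non_seed[0])
    else:
        fnss = int(cfg.fnss_index)
        if not (0 <= fnss < s):
            raise StageMatrixError(f"fnss_index {fnss} out of range 0..{s - 1}")
        if seed_flags[fnss] != 0:
            raise StageMatrixError(f"fnss_index {fnss + 1} refers to a seed stage")

    if stage_labels is None:
        stage_labels = tuple(f"stage_{i + 1}" for i in range(s))
    else:
        if len(stage_labels) != s:
            raise StageMatrixError("stage_labels length does not match matrix dimension")
        stage_labels = tuple(str(x) for x in stage_labels)

    return StageMatrixSet(
        U=U,
        F=F,
        G=G,
        sigma=sigma,
        mu=mu,
        z=z,
        stage_labels=stage_labels,
        seed_flags=seed_flags,
        fnss_index=fnss,
        zero_survival_stages=tuple(int(j) for j in np.flatnonzero(zero)),
    )


def _rescale_columns(U: np.ndarray, sigma: np.ndarray, max_excess: float) -> np.ndarray:
    """Scale columns of U with sum > 1 back to exactly 1."""
    too_big = np.flatnonzero(sigma > 1.0 + max_excess)
    if too_big.size:
        j = int(too_big[0])
        raise StageMatrixError(
            f"column sum of U for stage {j + 1} is {sigma[j]:.6g}, exceeding "
            f"1 + max_excess ({1 + max_excess:.3g}); this suggests a fertility "
            "entry misplaced in U rather than rounding error"
        )
    out = U.copy()
    scaled = np.flatnonzero(sigma > 1.0)
    for j in scaled:
        out[:, j] /= sigma[j]
    if scaled.size:
        logger.warning(
            "rescaled U columns with survival > 1 for stages %s",
            [int(j) + 1 for j in scaled],
        )
    return out


def rescale_excess_survival(m: StageMatrixSet, tol: float = SURVIVAL_TOL) -> StageMatrixSet:
    """Return a copy with any U column summing above ``1 + tol`` scaled to sum 1.

    ``F`` is unchanged. Idempotent: applying twice equals applying once.
    Column sums exceeding ``1 + max_excess`` (default 0.1) are refused by
    :func:`build_stage_set`; here any excess above ``tol`` is rescaled.
    """
    sigma = m.U.sum(axis=0)
    if not np.any(sigma > 1.0 + tol):
        return m
    U = _rescale_columns(m.U, sigma, np.inf)
    cfg = AnalysisConfig(
        offspring_stages=tuple(np.flatnonzero(m.z)),
        seed_stages=tuple(np.flatnonzero(m.seed_flags)),
        fnss_index=m.fnss_index,
    )
    return build_stage_set(U, m.F, config=cfg, stage_labels=m.stage_labels)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square matrix from CSV, auto-detecting label headers.

    Accepts headerless numeric CSV, or CSV with a leading label row
    and/or label column. Returns the matrix and the labels (or None).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, header=None, dtype=str)
    labels: list[str] | None = None

    def _numeric(x) -> bool:
        try:
            float(x)
            return True
        except (TypeError, ValueError):
            return False

    if not df.iloc[0].map(_numeric).all():
        # header row present; its entries (minus a possible corner cell) label stages
        labels = [str(x) for x in df.iloc[0].tolist()]
        df = df.iloc[1:].reset_index(drop=True)
    if not df.iloc[:, 0].map(_numeric).all():
        if labels is None:
            labels = [str(x) for x in df.iloc[:, 0].tolist()]
        df = df.iloc[:, 1:]
        if labels is not None and len(labels) == df.shape[1] + 1:
            labels = labels[1:]  # drop corner cell
    try:
        M = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise StageMatrixError(f"non-numeric entries in {path}: {exc}") from exc
    if labels is not None and len(labels) != M.shape[0]:
        labels = None
    return M, labels


def read_stage_matrices(
    u_path: str | Path,
    f_path: str | Path,
    config: AnalysisConfig | None = None,
) -> StageMatrixSet:
    """Read ``U`` and ``F`` from CSV and return a validated StageMatrixSet."""
    U, labels_u = read_matrix_csv(u_path)
    F, labels_f = read_matrix_csv(f_path)
    if U.shape != F.shape:
        raise StageMatrixError(
            f"dimension mismatch: U is {U.shape} ({u_path}), F is {F.shape} ({f_path})"
        )
    return build_stage_set(U, F, config=config, stage_labels=labels_u or labels_f)


def write_stage_matrices(
    m: StageMatrixSet, u_path: str | Path, f_path: str | Path, digits: int = 10
) -> None:
    """Write ``U`` and ``F`` as headerless CSV at ``digits`` significant digits."""
    fmt = f"%.{digits}g"
    np.savetxt(u_path, m.U, delimiter=",", fmt=fmt)
    np.savetxt(f_path, m.F, delimiter=",", fmt=fmt)
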