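"""Selection gradients of fitness on age-by-stage mortality and fertility.

The selection gradient on a trait vector ``theta`` is the row vector of
partial derivatives of fitness (``r = log(lambda)`` by default, or
``lambda``) with respect to ``theta``. Two trait families are analysed,
both as additive perturbations evaluated at the observed life history:

* mortality: the force of mortality ``mu_j`` of stage ``j``, acting in a
  single age class ``i`` only. Since ``U = G @ diag(exp(-mu))``,
  ``d vec(U) / d mu_j = -sigma_j * (e_j kron G e_j)`` placed at the
  column-``j`` coordinates, i.e. the whole ``j``-th column of ``U``
  scales down.
* fertility: the perturbation parameter ``phi_j``, adding one offspring
  of every offspring type (indicator ``z``) to the per-capita output of
  stage ``j``, in a single age class ``i``.

Both gradients follow from the eigenvalue sensitivity
``d lambda / d vec(Atilde) = (w' kron v') / (v'w)`` chained through the
two-term structure ``Atilde = MU @ blockU + MF @ blockF``: only the
``(i, j)`` column of the corresponding block diagonal moves, giving

    d lambda / d mu_{j,i}  = -(v' MU)_[i] @ U[:, j] * w[i*s + j] / (v'w)
    d lambda / d phi_{j,i} =  (v' MF)_[i] @ z       * w[i*s + j] / (v'w)

where ``_[i]`` selects the age-``i`` block. Increasing mortality can
never raise fitness and adding offspring can never lower it, so the
mortality array is nonpositive and the fertility array nonnegative.
Stages with no within-stage survival have an identically zero mortality
row (there is no survival to scale).

A central finite-difference oracle over the age-expanded model verifies
every entry; see :class:`FiniteDifferenceOracle` for the compensated
difference scheme that keeps the oracle meaningful for entries many
orders of magnitude below the leading ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .build import AgeStageModel, EigenSystem, build_projection, eigen_analysis
from .stage_io import StageMatrixSet

__all__ = [
    "GradientField",
    "sensitivity_of_lambda",
    "mortality_gradient",
    "fertility_gradient",
    "compute_gradients",
    "marginalize",
    "stage_gradients",
    "FiniteDifferenceOracle",
    "finite_difference_oracle",
]


def _metric_factor(metric: str, lam: float) -> float:
    if metric == "r":
        return 1.0 / lam
    if metric == "lambda":
        return 1.0
    raise ValueError(f"metric must be 'r' or 'lambda', got {metric!r}")


def sensitivity_of_lambda(eig: EigenSystem, metric: str = "lambda") -> np.ndarray:
    """Sensitivity of the dominant eigenvalue to every matrix entry.

    Returns the dense array ``S`` with ``S[k, l] = v_k w_l / (v'w)``,
    the derivative of ``lambda`` with respect to entry ``(k, l)``;
    ``vec(S)`` row-wise is ``d lambda / d vec(A)' = w' kron v'``. For
    metric ``"r"`` the array is divided by ``lambda``. The ratio form
    makes the result invariant to eigenvector scaling.
    """
    n = eig.w.size
    if n * n > 5 * 10**7:
        raise ValueError("sensitivity matrix too large to densify; use the gradient functions")
    return np.outer(eig.v, eig.w) / (eig.v @ eig.w) * _metric_factor(metric, eig.lam)


def mortality_gradient(
    model: AgeStageModel, eig: EigenSystem, metric: str = "r"
) -> np.ndarray:
    """s x omega array of selection gradients on age-by-stage mortality.

    Entry ``(j, i)`` is the derivative of fitness with respect to an
    additive perturbation of the mortality rate of stage ``j`` applied
    in age class ``i`` only. All entries are <= 0.
    """
    s, omega = model.s, model.omega
    U = model.source.U
    vMU = model.MU.T @ eig.v
    vw = float(eig.v @ eig.w)
    fac = _metric_factor(metric, eig.lam) / vw
    grad = np.empty((s, omega))
    for i in range(omega):
        blk = model.age_block(i)
        grad[:, i] = -(vMU[blk] @ U) * eig.w[blk] * fac
    return grad


def fertility_gradient(
    model: AgeStageModel, eig: EigenSystem, metric: str = "r"
) -> np.ndarray:
    """s x omega array of selection gradients on age-by-stage fertility.

    Entry ``(j, i)`` is the derivative of fitness with respect to the
    perturbation parameter ``phi_j`` in age class ``i``: one extra
    offspring of every offspring type per capita of stage ``j`` at age
    ``i``. All entries are >= 0. If no stage is an offspring type the
    result is identically zero (with a warning).
    """
    s, omega = model.s, model.omega
    z = model.source.z
    if not np.any(z):
        warnings.warn("offspring indicator z is all-zero; fertility gradients are 0", RuntimeWarning)
        return np.zeros((s, omega))
    vMF = model.MF.T @ eig.v
    vw = float(eig.v @ eig.w)
    fac = _metric_factor(metric, eig.lam) / vw
    grad = np.empty((s, omega))
    for i in range(omega):
        blk = model.age_block(i)
        grad[:, i] = (vMF[blk] @ z) * eig.w[blk] * fac
    return grad


@dataclass(frozen=True)
class GradientField:
    """Age-by-stage selection gradients and their marginals.

    ``grad_mu[j, i]`` / ``grad_phi[j, i]`` are the gradients on
    mortality / fertility of stage ``j`` in age class ``i`` (0-based;
    the final class ``omega - 1`` is the open class aggregating ages
    >= omega and is flagged for exclusion from senescence diagnostics).
    Age marginals sum over stages (the gradient on a purely
    age-dependent trait); stage marginals sum over ages (the gradient on
    a purely stage-dependent trait).
    """

    grad_mu: np.ndarray
    grad_phi: np.ndarray
    metric: str

    @property
    def s(self) -> int:
        return self.grad_mu.shape[0]

    @property
    def omega(self) -> int:
        return self.grad_mu.shape[1]

    @property
    def open_age_class(self) -> int:
        return self.omega - 1

    @property
    def age_marginal_mu(self) -> np.ndarray:
        return self.grad_mu.sum(axis=0)

    @property
    def age_marginal_phi(self) -> np.ndarray:
        return self.grad_phi.sum(axis=0)

    @property
    def stage_marginal_mu(self) -> np.ndarray:
        return self.grad_mu.sum(axis=1)

    @property
    def stage_marginal_phi(self) -> np.ndarray:
        return self.grad_phi.sum(axis=1)


def compute_gradients(
    model: AgeStageModel, eig: EigenSystem | None = None, metric: str = "r"
) -> GradientField:
    """Convenience wrapper computing both gradient arrays."""
    if eig is None:
        eig = eigen_analysis(model)
    return GradientField(
        grad_mu=mortality_gradient(model, eig, metric),
        grad_phi=fertility_gradient(model, eig, metric),
        metric=metric,
    )


def marginalize(field: GradientField, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Sum the gradient arrays over stages (``axis="age"``, returning
    age profiles) or over ages (``axis="stage"``, returning stage
    profiles). Returns ``(mortality, fertility)`` marginals."""
    if axis == "age":
        return field.age_marginal_mu, field.age_marginal_phi
    if axis == "stage":
        return field.stage_marginal_mu, field.stage_marginal_phi
    raise ValueError(f"axis must be 'age' or 'stage', got {axis!r}")


def stage_gradients(m: StageMatrixSet, metric: str = "r") -> tuple[np.ndarray, np.ndarray]:
    """Selection gradients of the stage-classified model ``A = U + F``.

    Returns length-s arrays ``(d fitness / d mu_j, d fitness / d phi_j)``
    for perturbations applied at every age at once (i.e. directly to the
    stage matrices). The age-by-stage arrays summed over age classes
    reproduce these exactly.
    """
    eig = eigen_analysis(sp.csr_matrix(m.A))
    vw = float(eig.v @ eig.w)
    fac = _metric_factor(metric, eig.lam) / vw
    gmu = -(eig.v @ m.U) * eig.w * fac
    gphi = float(eig.v @ m.z) * eig.w * fac * (1.0 if np.any(m.z) else 0.0)
    return gmu, np.asarray(gphi)


# ---------------------------------------------------------------------------
# Finite-difference oracle


class FiniteDifferenceOracle:
    """Central finite differences of fitness over the age-expanded model.

    For a perturbation of size ``h`` of a single (stage, age) cell the
    oracle rebuilds the projection matrix with age-specific stage
    matrices differing only in that age class and returns
    ``(fit(+h) - fit(-h)) / (2h)``.

    Two evaluation methods are provided:

    * ``"direct"``: rebuild and fully re-solve the eigenproblem on each
      side, then subtract. Simple and fully independent, but the
      subtraction of two nearly equal eigenvalues limits the absolute
      accuracy to roughly machine epsilon over ``2h``.
    * ``"compensated"`` (default): the perturbed matrix is still rebuilt
      through :func:`build_projection`, but the eigenvalue *shift*
      ``d = lambda(perturbed) - lambda`` is computed directly, by Newton
      iteration on the bordered eigenvalue system in increment form, so
      that no large quantities are ever subtracted. The base residual is
      evaluated in extended precision once per model. This keeps the
      central difference accurate for gradient entries many orders of
      magnitude below the dominant ones.

    Both methods evaluate the same central difference; ``"compensated"``
    differs only in how the difference of eigenvalues is carried out.
    """

    def __init__(self, m: StageMatrixSet, omega: int, metric: str = "r"):
        self.m = m
        self.omega = omega
        self.metric = metric
        self.model = build_projection(m, omega)
        self.eig = eigen_analysis(self.model)
        self._lu = None
        self._r0 = None

    # -- shared plumbing ----------------------------------------------------

    def _perturbed_matrices(self, target: str, j: int, i: int, h: float, sign: int):
        """Age-specific (U_age, F_age) lists with one cell perturbed."""
        m, omega = self.m, self.omega
        if not (0 <= j < m.s):
            raise ValueError(f"stage index {j} out of range 0..{m.s - 1}")
        if not (0 <= i < omega):
            raise ValueError(f"age index {i} out of range 0..{omega - 1}")
        Ulist = [m.U] * omega
        Flist = [m.F] * omega
        if target == "mu":
            # mu_j -> mu_j + sign*h scales column j of U by exp(-sign*h)
            Up = m.U.copy()
            Up[:, j] = np.exp(-sign * h) * m.U[:, j]
            Ulist[i] = Up
        elif target == "phi":
            Fp = m.F.copy()
            Fp[:, j] = m.F[:, j] + sign * h * m.z
            Flist[i] = Fp
        else:
            raise ValueError(f"target must be 'mu' or 'phi', got {target!r}")
        return Ulist, Flist

    # -- direct method ------------------------------------------------------

    def _lambda_direct(self, target: str, j: int, i: int, h: float, sign: int) -> float:
        Ulist, Flist = self._perturbed_matrices(target, j, i, h, sign)
        model = build_projection(self.m, self.omega, U_age=Ulist, F_age=Flist)
        return eigen_analysis(model).lam

    def gradient_direct(self, target: str, j: int, i: int, h: float = 1e-6) -> float:
        lp = self._lambda_direct(target, j, i, h, +1)
        lm = self._lambda_direct(target, j, i, h, -1)
        d = (lp - lm) / (2 * h)
        if self.metric == "r":
            d /= self.eig.lam
        return float(d)

    # -- compensated method -------------------------------------------------

    def _prepare_newton(self) -> None:
        if self._lu is not None:
            return
        A, w, v, lam = self.model.Atilde, self.eig.w, self.eig.v, self.eig.lam
        n = self.model.dim
        M = sp.bmat(
            [[A - lam * sp.identity(n), -w.reshape(-1, 1)], [v.reshape(1, -1), None]],
            format="csc",
        )
        self._lu = spla.splu(M)
        # base residual in extended precision: identical on both sides of the
        # central difference, so its rounding does not bias the difference
        Ald = A.toarray().astype(np.longdouble)
        r0 = Ald @ w.astype(np.longdouble) - np.longdouble(lam) * w.astype(np.longdouble)
        self._r0 = r0.astype(np.float64)

    def _eigenvalue_shift(self, E: sp.spmatrix) -> float:
        """``lambda(Atilde + E) - lambda`` via bordered Newton increments."""
        self._prepare_newton()
        A, w, lam = self.model.Atilde, self.eig.w, self.eig.lam
        n = self.model.dim
        x = np.zeros(n)
        d = 0.0
        settled = 0
        for _ in range(60):
            f = self._r0 + (A @ x - lam * x) + E @ (w + x) - d * w - d * x
            delta = self._lu.solve(np.concatenate([-f, [0.0]]))
            x += delta[:n]
            d += float(delta[n])
            # the eigenvalue shift is the quantity of interest; stop once its
            # increments are at rounding level for two consecutive iterations
            settled = settled + 1 if abs(delta[n]) <= 1e-300 + 5e-13 * abs(d) else 0
            if settled >= 2:
                break
        else:
            warnings.warn("bordered Newton iteration did not fully stabilize", RuntimeWarning)
        return d

    def _perturbation_matrix(self, target: str, j: int, i: int, h: float, sign: int) -> sp.csr_matrix:
        """``Atilde(perturbed) - Atilde``, assembled through the same
        two-term construction. Assembly is linear in the per-age block
        diagonals, so only the single changed column propagates; this is
        exact (no subtractive cancellation) and equals rebuilding in full,
        which the tests cross-check via the direct method."""
        m, omega = self.m, self.omega
        if not (0 <= j < m.s):
            raise ValueError(f"stage index {j} out of range 0..{m.s - 1}")
        if not (0 <= i < omega):
            raise ValueError(f"age index {i} out of range 0..{omega - 1}")
        n = self.model.dim
        col = i * m.s + j
        rows = np.arange(i * m.s, (i + 1) * m.s)
        if target == "mu":
            vals = np.expm1(-sign * h) * m.U[:, j]
            carrier = self.model.MU
        elif target == "phi":
            vals = sign * h * m.z
            carrier = self.model.MF
        else:
            raise ValueError(f"target must be 'mu' or 'phi', got {target!r}")
        dblock = sp.csr_matrix(
            (vals, (rows, np.full(m.s, col))), shape=(n, n)
        )
        return (carrier @ dblock).tocsr()

    def gradient_compensated(self, target: str, j: int, i: int, h: float = 1e-6) -> float:
        dp = self._eigenvalue_shift(self._perturbation_matrix(target, j, i, h, +1))
        dm = self._eigenvalue_shift(self._perturbation_matrix(target, j, i, h, -1))
        lam = self.eig.lam
        if self.metric == "r":
            # log(lam+dp) - log(lam+dm) without cancellation of the leading lam
            return float(np.log1p((dp - dm) / (lam + dm)) / (2 * h))
        return float((dp - dm) / (2 * h))

    # -- public entry point -------------------------------------------------

    def gradient(
        self,
        target: str,
        j: int,
        i: int,
        h: float = 1e-6,
        method: str = "compensated",
        check_step: bool = False,
    ) -> float:
        """Central-difference gradient for stage ``j`` at age class ``i``.

        With ``check_step=True`` the difference is recomputed at ``h/2``
        and ``h/4``: a second-order scheme must contract its successive
        differences by about 4 under halving. A warning is emitted when
        the contraction fails (sign flip, or shrink factor below 2),
        which happens when ``h`` is too large for the curvature of the
        fitness surface or small enough to hit the rounding floor.
        """
        if h <= 0:
            raise ValueError("h must be positive")
        fn = self.gradient_compensated if method == "compensated" else self.gradient_direct
        g = fn(target, j, i, h)
        if check_step:
            g_half = fn(target, j, i, h / 2)
            g_quarter = fn(target, j, i, h / 4)
            q1 = g - g_half
            q2 = g_half - g_quarter
            ratio = abs(q1) / abs(q2) if q2 != 0 else np.inf
            if (q1 != 0 or q2 != 0) and (q1 * q2 <= 0 or not 2 <= ratio <= 8):
                warnings.warn(
                    f"finite-difference step h={h:g} looks too large (or is "
                    "below the noise floor): halving contracts the difference "
                    f"by {ratio:.2g} instead of ~4", RuntimeWarning
                )
        return g

    def gradient_array(self, target: str, h: float = 1e-6, method: str = "compensated") -> np.ndarray:
        """Full s x omega array of central-difference gradients."""
        s, omega = self.model.s, self.omega
        out = np.empty((s, omega))
        for i in range(omega):
            for j in range(s):
                out[j, i] = self.gradient(target, j, i, h=h, method=method)
        return out


def finite_difference_oracle(
    m: StageMatrixSet,
    omega: int,
    target: str,
    j: int,
    i: int,
    h: float = 1e-6,
    metric: str = "r",
    method: str = "compensated",
) -> float:
    """One-shot central-difference gradient; see :class:`FiniteDifferenceOracle`."""
    return FiniteDifferenceOracle(m, omega, metric=metric).gradient(
        target, j, i, h=h, method=method
    )
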