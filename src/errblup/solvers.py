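"""Penalized least-squares solvers for polynomial marker models.

All three fitters minimise the sum of squared residuals plus a
per-coefficient penalty:

* :func:`ols_fit` — no penalty (requires q ≤ n, well-conditioned);
* :func:`ridge_fit` — generalized ridge, ``SSR + Σ_c λ_c b_c²``.  With
  λ = λ1 on additive terms and λ2 on interactions this is the mixed-model
  family RRBLUP (degree 1) / eRRBLUP-1 (both degrees penalized) /
  eRRBLUP-2 (λ1 = 0, additive effects fixed, only interactions
  penalized).  Unpenalized coefficients sit in the same normal-equations
  system with zeros on the penalty diagonal.
* :func:`lasso_fit` — ``SSR + Σ_c λ_c |b_c|`` by cyclic coordinate
  descent with soft-thresholding.

Penalty factors derive from variance-component ratios:
λ1 = σ_ε²/σ_β², λ2 = σ_ε²/σ_h².  A fit records the coding shift of its
training matrix; :func:`predict` re-applies it to new data so that
predictions never silently mix codings — translation sensitivity of the
penalized fits is exactly the failure mode this package exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (CodingError, ConvergenceError, DimensionError,
                         SingularSystemError)
from .markers import MarkerMatrix, Phenotype
from .polydesign import (DesignMatrix, Monomial, PolynomialModel,
                         build_design, evaluate)

__all__ = ["PenaltySpec", "FitResult", "ols_fit", "ridge_fit", "lasso_fit",
           "predict"]

#: reciprocal-condition threshold below which normal equations are
#: declared singular rather than silently pseudo-inverted
RCOND_LIMIT = 1e-12


@dataclass
class PenaltySpec:
    """Nonnegative per-coefficient penalty factors (0 = unpenalized)."""

    per_coefficient: np.ndarray

    def __post_init__(self):
        self.per_coefficient = np.asarray(self.per_coefficient,
                                          dtype=float).reshape(-1)
        if (self.per_coefficient < 0).any():
            raise DimensionError("penalty factors must be >= 0")

    @classmethod
    def zeros(cls, q: int) -> "PenaltySpec":
        return cls(np.zeros(q))

    @classmethod
    def from_lambdas(cls, monomials: list[Monomial], lambda1: float,
                     lambda2: float = 0.0,
                     lambda_squares: float | None = None) -> "PenaltySpec":
        """λ1 on degree-1 terms, λ2 on pair interactions, intercept free.

        Squares M_j² (the dominance device) default to the degree-2
        group λ2; pass ``lambda_squares`` to penalize them separately.
        """
        lam_sq = lambda2 if lambda_squares is None else lambda_squares
        out = np.empty(len(monomials))
        for c, m in enumerate(monomials):
            d = m.total_degree
            if d == 0:
                out[c] = 0.0
            elif d == 1:
                out[c] = lambda1
            elif len(m.exponents) == 1:  # square
                out[c] = lam_sq
            else:
                out[c] = lambda2
        return cls(out)

    def matching(self, X: DesignMatrix) -> np.ndarray:
        if self.per_coefficient.shape[0] != X.q:
            raise DimensionError(
                f"penalty length {self.per_coefficient.shape[0]} does not "
                f"match design with q={X.q}")
        return self.per_coefficient


@dataclass
class FitResult:
    """Fitted coefficients plus the context needed to reuse them."""

    model: PolynomialModel
    fitted: np.ndarray
    ssr: float
    penalty: PenaltySpec
    coding_shift: np.ndarray | None = field(default=None)
    iterations: int | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return self.model.coefficients

    def coefficient(self, m) -> float:
        return self.model.coefficient(m)

    def interaction_effects(self) -> np.ndarray:
        return self.model.interaction_effects()


def _pheno_values(y) -> np.ndarray:
    if isinstance(y, Phenotype):
        return y.values
    return np.asarray(y, dtype=float).reshape(-1)


def _check_condition(A: np.ndarray, context: str) -> None:
    # A is symmetric PSD + diag; use 2-norm condition via eigvalsh
    w = np.linalg.eigvalsh(A)
    wmax = float(w[-1])
    if wmax <= 0 or w[0] <= 0 or w[0] / wmax < RCOND_LIMIT:
        raise SingularSystemError(
            f"{context}: normal-equations matrix is singular or "
            f"ill-conditioned (rcond ~ {max(w[0], 0.0) / max(wmax, 1e-300):.2e})")


def _solve_penalized(X: DesignMatrix, y: np.ndarray, lam: np.ndarray,
                     context: str) -> np.ndarray:
    A = X.values.T @ X.values + np.diag(lam)
    _check_condition(A, context)
    return np.linalg.solve(A, X.values.T @ y)


def _result(X: DesignMatrix, y: np.ndarray, beta: np.ndarray,
            penalty: PenaltySpec, iterations=None) -> FitResult:
    fitted = X.values @ beta
    ssr = float(np.sum((y - fitted) ** 2))
    return FitResult(PolynomialModel(X.monomial_index, beta), fitted, ssr,
                     penalty, None if X.coding_shift is None
                     else X.coding_shift.copy(), iterations)


def ols_fit(X: DesignMatrix, y) -> FitResult:
    """Ordinary least squares, ``(XᵗX)⁻¹Xᵗy``; requires q ≤ n and a
    well-conditioned system (no silent pseudo-inverse)."""
    yv = _pheno_values(y)
    if X.q > X.n:
        raise SingularSystemError(
            f"OLS needs q <= n, got q={X.q} > n={X.n}")
    beta = _solve_penalized(X, yv, np.zeros(X.q), "ols_fit")
    return _result(X, yv, beta, PenaltySpec.zeros(X.q))


def ridge_fit(X: DesignMatrix, y, penalty: PenaltySpec) -> FitResult:
    """Generalized ridge ``(XᵗX + diag(λ))⁻¹Xᵗy``.

    Coefficients with λ_c = 0 (intercept, and the additive block in the
    interactions-only-penalty model) are estimated as fixed effects in
    the same system.  With all λ = 0 on a full-rank design this equals
    :func:`ols_fit`.
    """
    yv = _pheno_values(y)
    lam = penalty.matching(X)
    beta = _solve_penalized(X, yv, lam, "ridge_fit")
    return _result(X, yv, beta, penalty)


def lasso_fit(X: DesignMatrix, y, penalty: PenaltySpec, tol: float = 1e-8,
              max_iter: int = 10_000) -> FitResult:
    """ℓ1-penalized least squares: minimise ``Σ(y−Xb)² + Σ λ_c |b_c|``.

    Cyclic coordinate descent in deterministic column order; each
    coordinate update is the exact one-dimensional minimiser
    ``b_c = S(x_cᵗr_c, λ_c/2) / x_cᵗx_c`` (soft-threshold S), which for
    λ_c = 0 reduces to the OLS update.  Converged when the largest
    coefficient change in a sweep is below ``tol``.
    """
    yv = _pheno_values(y)
    lam = penalty.matching(X)
    V = X.values
    colsq = np.einsum("ij,ij->j", V, V)
    if (colsq <= 0).any():
        raise SingularSystemError("lasso_fit: design has an all-zero column")
    beta = np.zeros(X.q)
    resid = yv.copy()
    for sweep in range(1, max_iter + 1):
        max_delta = 0.0
        for c in range(X.q):
            b_old = beta[c]
            rho = V[:, c] @ resid + colsq[c] * b_old
            thr = lam[c] / 2.0
            b_new = np.sign(rho) * max(abs(rho) - thr, 0.0) / colsq[c]
            if b_new != b_old:
                resid += V[:, c] * (b_old - b_new)
                beta[c] = b_new
                max_delta = max(max_delta, abs(b_new - b_old))
        if max_delta < tol:
            return _result(X, yv, beta, penalty, iterations=sweep)
    raise ConvergenceError(
        f"lasso_fit did not converge in {max_iter} sweeps "
        f"(last max coefficient change {max_delta:.3e})", iterations=max_iter)


def predict(fit: FitResult, M_new: MarkerMatrix) -> np.ndarray:
    """Evaluate a fit on new genotypes, re-applying the training coding.

    ``M_new`` may be raw or partially translated; its recorded shift is
    compared with the training shift and the difference applied, so the
    polynomial is always evaluated in the coding it was estimated in.
    """
    shift = fit.coding_shift
    if shift is None:
        shift = np.zeros(M_new.p)
    if shift.shape[0] != M_new.p:
        raise CodingError(
            f"training coding shift has length {shift.shape[0]} but new "
            f"matrix has p={M_new.p}")
    values = M_new.values - (shift - M_new.shift)
    return evaluate(fit.model, values)
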