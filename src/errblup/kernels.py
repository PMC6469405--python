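"""Genomic relationship matrices and REML variance components.

The additive kernel is ``G = MMᵗ`` in the matrix's current coding; the
pairwise-epistasis kernel is

    H = 0.5 (MMᵗ ∘ MMᵗ) − 0.5 (M∘M)(M∘M)ᵗ ,

(∘ the Hadamard product), which equals ``H_ij = Σ_{k<l} M_ik M_il M_jk
M_jl`` — the covariance structure induced by i.i.d. pairwise interaction
effects.  H is conventionally divided by its maximum entry; note that
any kernel rescaling rescales the estimated variance component and
hence the penalty factor λ = σ_ε²/σ² derived from it, so λ values are
only meaningful together with the normalization used.

Variance components for ``y = Xb + Σ_k u_k + ε`` with
``u_k ~ N(0, σ_k² K_k)`` are estimated by restricted maximum likelihood
using average-information updates with an EM-style fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import (ConvergenceError, DegenerateKernelError,
                         DimensionError, ZeroVarianceError)
from .markers import MarkerMatrix, Phenotype
from .polydesign import DesignMatrix

__all__ = ["KernelMatrix", "VarianceComponents", "additive_kernel",
           "epistatic_kernel", "reml", "penalty_from_varcomp",
           "PenaltyFactors"]

#: relative eigenvalue tolerance for accepting a kernel as PSD
PSD_TOL = 1e-8


@dataclass
class KernelMatrix:
    """Symmetric PSD n×n relationship matrix."""

    values: np.ndarray
    kind: Literal["additive", "epistatic", "identity"] = "additive"
    normalization: Literal["none", "max", "trace_n"] = "none"
    name: str | None = None
    line_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, m = self.values.shape
        if n != m:
            raise DimensionError("kernel must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DimensionError("kernel must be symmetric within 1e-10")
        self.values = 0.5 * (self.values + self.values.T)
        w = np.linalg.eigvalsh(self.values)
        wmax = max(float(w[-1]), 0.0)
        if w[0] < -PSD_TOL * max(wmax, 1.0):
            raise DimensionError(
                f"kernel is not positive semidefinite "
                f"(min eigenvalue {w[0]:.3e})")
        if self.name is None:
            self.name = self.kind

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = self.line_ids or [str(i) for i in range(self.n)]
        return pd.DataFrame(self.values, index=ids, columns=ids)


def additive_kernel(M: MarkerMatrix,
                    normalization: Literal["none", "trace_n"] = "none",
                    ) -> KernelMatrix:
    """``G = MMᵗ`` in the current coding, optionally scaled to trace n."""
    G = M.values @ M.values.T
    if normalization == "trace_n":
        tr = np.trace(G)
        if tr <= 0:
            raise DegenerateKernelError("cannot trace-normalize a zero kernel")
        G = G * (M.n / tr)
    elif normalization != "none":
        raise DimensionError(f"unknown normalization {normalization!r}")
    return KernelMatrix(G, "additive", normalization,
                        line_ids=list(M.line_ids))


def epistatic_kernel(M: MarkerMatrix,
                     normalization: Literal["max", "none"] = "max",
                     ) -> KernelMatrix:
    """Pairwise-interaction kernel 0.5(MMᵗ∘MMᵗ) − 0.5(M∘M)(M∘M)ᵗ.

    With ``normalization='max'`` (the default) the matrix is divided by
    its largest entry.  For p = 1 there are no pairs and H ≡ 0 (an error
    under max normalization).
    """
    V = M.values
    G = V @ V.T
    V2 = V * V
    H = 0.5 * (G * G) - 0.5 * (V2 @ V2.T)
    if normalization == "max":
        hmax = float(H.max())
        if hmax <= 0:
            raise DegenerateKernelError(
                "epistatic kernel is identically zero (or nonpositive); "
                "cannot divide by its maximum")
        H = H / hmax
    elif normalization != "none":
        raise DimensionError(f"unknown normalization {normalization!r}")
    return KernelMatrix(H, "epistatic", normalization,
                        line_ids=list(M.line_ids))


@dataclass
class VarianceComponents:
    """REML estimates: one σ² per kernel plus the residual."""

    sigma2: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    iterations: int
    loglik: float
    warnings: list[str] = field(default_factory=list)

    @property
    def residual(self) -> float:
        return self.sigma2["residual"]


class PenaltyFactors(NamedTuple):
    lambda1: float
    lambda2: float


def _fixed_values(fixed_design, n: int) -> np.ndarray:
    if fixed_design is None:
        return np.ones((n, 1))
    if isinstance(fixed_design, DesignMatrix):
        return fixed_design.values
    X = np.atleast_2d(np.asarray(fixed_design, dtype=float))
    return X


def _unique_names(kernels: Sequence[KernelMatrix]) -> list[str]:
    names, seen = [], {}
    for k in kernels:
        base = k.name or k.kind
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}{seen[base]}")
    return names


def _kernel_similarity_warnings(mats: list[np.ndarray],
                                labels: list[str]) -> list[str]:
    out = []
    flat = [m.ravel() for m in mats]
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            ni, nj = np.linalg.norm(flat[i]), np.linalg.norm(flat[j])
            if ni == 0 or nj == 0:
                continue
            cos = float(flat[i] @ flat[j] / (ni * nj))
            if cos > 1 - 1e-6:
                out.append(f"kernels '{labels[i]}' and '{labels[j]}' are "
                           f"numerically indistinguishable "
                           f"(cosine similarity {cos:.8f}); variance "
                           f"components are not separately identifiable")
    return out


def _restricted_loglik_terms(V, X, y):
    cho = linalg.cho_factor(V, lower=True)
    Vinv = linalg.cho_solve(cho, np.eye(V.shape[0]))
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    XtVinvX = X.T @ Vinv @ X
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise DimensionError("fixed-effect design is rank deficient")
    B = np.linalg.solve(XtVinvX, X.T @ Vinv)
    P = Vinv - Vinv @ X @ B
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, P, Py


def reml(y, kernels: Sequence[KernelMatrix], fixed_design=None, *,
         max_iter: int = 200, tol: float = 1e-8) -> VarianceComponents:
    """Average-information REML for a multi-kernel mixed model.

    ``y = Xb + Σ_k u_k + ε`` with ``u_k ~ N(0, σ_k² K_k)`` and
    ``ε ~ N(0, σ_ε² I)``; ``fixed_design`` defaults to an intercept.
    AI proposals that would leave the nonnegative orthant, or that
    decrease the restricted log-likelihood, fall back to step-halving
    and then to the EM-style ratio update (always nonnegative).
    Standard errors come from the inverse AI matrix at convergence.
    Near-duplicate kernels (including a kernel ≈ identity, which
    duplicates the residual) are reported in ``warnings`` but estimated
    anyway.  Convergence is a relative log-likelihood change below
    ``tol``.
    """
    yv = y.values if isinstance(y, Phenotype) else \
        np.asarray(y, dtype=float).reshape(-1)
    n = yv.shape[0]
    X = _fixed_values(fixed_design, n)
    if X.shape[0] != n:
        raise DimensionError("fixed design rows must match y")
    if n <= X.shape[1]:
        raise DimensionError("need n > number of fixed-effect columns")
    for k in kernels:
        if k.n != n:
            raise DimensionError("kernel size must match y")
    names = _unique_names(kernels) + ["residual"]
    Ks = [k.values for k in kernels] + [np.eye(n)]
    m = len(Ks)
    warnings = _kernel_similarity_warnings(Ks, names)

    vary = float(np.var(yv))
    if vary < 1e-14:
        return VarianceComponents({nm: 0.0 for nm in names},
                                  {nm: float("nan") for nm in names},
                                  True, 0, 0.0, warnings)
    if not kernels:
        # residual-only REML has the closed form RSS / (n - rank(X))
        b, *_ = np.linalg.lstsq(X, yv, rcond=None)
        rss = float(np.sum((yv - X @ b) ** 2))
        dof = n - np.linalg.matrix_rank(X)
        s2 = rss / dof
        ll, _, _ = _restricted_loglik_terms(s2 * np.eye(n), X, yv)
        return VarianceComponents({"residual": s2},
                                  {"residual": s2 * np.sqrt(2.0 / dof)},
                                  True, 0, ll, warnings)

    s = np.full(m, vary / m)
    floor = 1e-10 * vary
    ll_prev = -np.inf
    AI = np.eye(m)
    trajectory = []
    it = 0
    for it in range(1, max_iter + 1):
        V = sum(si * Ki for si, Ki in zip(s, Ks))
        ll, P, Py = _restricted_loglik_terms(V, X, yv)
        trajectory.append((s.copy(), ll))
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (1 + abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
        KPy = np.column_stack([Ki @ Py for Ki in Ks])        # n×m
        PKPy = P @ KPy
        yPKPy = KPy.T @ Py                                    # quadratic forms
        trPK = np.array([np.sum(P * Ki) for Ki in Ks])        # tr(P K_i)
        score = -0.5 * (trPK - yPKPy.ravel())
        AI = 0.5 * (KPy.T @ PKPy)
        AI = 0.5 * (AI + AI.T)

        def _ll_at(cand: np.ndarray) -> float:
            Vc = sum(ci * Ki for ci, Ki in zip(cand, Ks))
            try:
                llc, _, _ = _restricted_loglik_terms(Vc, X, yv)
            except (np.linalg.LinAlgError, ValueError):
                return -np.inf
            return llc

        try:
            step = np.linalg.solve(AI + 1e-12 * np.eye(m) * np.trace(AI),
                                   score)
        except np.linalg.LinAlgError:
            step = None
        accepted = False
        if step is not None:
            frac = 1.0
            for _ in range(6):
                cand = s + frac * step
                if (cand >= 0).all() and _ll_at(np.maximum(cand, floor)) \
                        >= ll - 1e-10:
                    s = np.maximum(cand, floor)
                    accepted = True
                    break
                frac *= 0.5
        if not accepted:
            # EM-style ratio update: nonnegative by construction
            ratio = np.where(trPK > 0, yPKPy.ravel() / np.maximum(trPK, 1e-300),
                             1.0)
            s = np.maximum(s * ratio, floor)
    else:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations",
            iterations=max_iter, trajectory=trajectory)

    try:
        se = np.sqrt(np.diag(np.linalg.inv(AI)))
    except np.linalg.LinAlgError:
        se = np.full(m, np.nan)
    s_out = np.where(s <= 2 * floor, 0.0, s)
    return VarianceComponents(dict(zip(names, map(float, s_out))),
                              dict(zip(names, map(float, se))),
                              True, it, float(ll_prev), warnings)


def penalty_from_varcomp(vc: VarianceComponents,
                         additive: str = "additive",
                         epistatic: str = "epistatic") -> PenaltyFactors:
    """λ1 = σ_ε²/σ_β² and λ2 = σ_ε²/σ_h² from a fitted two-kernel model.

    Either component may be absent (its λ is returned as 0.0, i.e. the
    corresponding effects are treated as fixed); a *zero* estimated
    component is an error, since its penalty would be infinite.
    """
    eps = vc.residual

    def ratio(name: str) -> float:
        if name not in vc.sigma2:
            return 0.0
        s2 = vc.sigma2[name]
        if s2 <= 0:
            raise ZeroVarianceError(
                f"variance component '{name}' is zero; its penalty factor "
                f"is infinite — drop the term instead of penalizing it")
        return eps / s2

    return PenaltyFactors(ratio(additive), ratio(epistatic))
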