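"""Polynomial models over marker dosages: monomials, design matrices,
completeness, and the translation transform.

A genotype–phenotype regression with pairwise interactions is a
polynomial of total degree 2 in the dosages,

    f(M_i) = μ + Σ_j β_j M_ij + Σ_{j<k} h_jk M_ij M_ik ,

and more generally any total degree D.  When the coding is translated,
``M̃ = M − 1_n Pᵗ``, the *same* fitted surface can be written in the new
variables as ``f̃(m̃) := f(m̃ + P)``.  Expanding that substitution maps
coefficients of lower total degree onto each other while leaving all
coefficients of the top total degree D unchanged — provided the model is
*complete*: every componentwise-smaller monomial of an included monomial
must itself carry a free coefficient, otherwise the expansion has
nowhere to put the generated terms.  This module implements that
machinery exactly (integer binomial expansion), for arbitrary degree.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (CompletenessError, DimensionError,
                         UnsupportedDegreeError)
from .markers import MarkerMatrix

__all__ = [
    "Monomial",
    "PolynomialModel",
    "DesignMatrix",
    "enumerate_monomials",
    "is_complete",
    "build_design",
    "translate_polynomial",
    "evaluate",
    "write_effects_table",
    "read_effects_table",
]


@dataclass(frozen=True)
class Monomial:
    """A product of dosage powers, stored as sorted (locus, power) pairs.

    The empty product is the intercept monomial (total degree 0).
    Locus indices are 0-based internally; the string form is 1-based
    (``"1"``, ``"M3"``, ``"M1*M2"``, ``"M2^2"``).
    """

    exponents: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        exps = tuple(sorted((int(j), int(d)) for j, d in self.exponents
                            if int(d) != 0))
        if any(d < 0 or j < 0 for j, d in exps):
            raise DimensionError("exponents must map loci >= 0 to powers >= 1")
        if len({j for j, _ in exps}) != len(exps):
            raise DimensionError("duplicate locus in monomial")
        object.__setattr__(self, "exponents", exps)

    @classmethod
    def intercept(cls) -> "Monomial":
        return cls(())

    @classmethod
    def linear(cls, j: int) -> "Monomial":
        return cls(((j, 1),))

    @classmethod
    def pair(cls, j: int, k: int) -> "Monomial":
        if j == k:
            return cls(((j, 2),))
        return cls(((j, 1), (k, 1)))

    @classmethod
    def from_dict(cls, d: Mapping[int, int]) -> "Monomial":
        return cls(tuple(d.items()))

    @property
    def total_degree(self) -> int:
        return sum(d for _, d in self.exponents)

    @property
    def loci(self) -> tuple[int, ...]:
        return tuple(j for j, _ in self.exponents)

    def power(self, j: int) -> int:
        return dict(self.exponents).get(j, 0)

    def __str__(self) -> str:
        if not self.exponents:
            return "1"
        parts = []
        for j, d in self.exponents:
            parts.append(f"M{j + 1}" if d == 1 else f"M{j + 1}^{d}")
        return "*".join(parts)

    @classmethod
    def parse(cls, spec: str) -> "Monomial":
        spec = spec.strip()
        if spec == "1":
            return cls.intercept()
        exps = []
        for part in spec.split("*"):
            m = re.fullmatch(r"M(\d+)(?:\^(\d+))?", part.strip())
            if m is None:
                raise DimensionError(f"cannot parse monomial spec {spec!r}")
            exps.append((int(m.group(1)) - 1, int(m.group(2) or 1)))
        return cls(tuple(exps))


def _sort_key(m: Monomial):
    # intercept, degree-1 by locus, pairs (j,k) j<k lexicographic, squares
    if m.total_degree == 2:
        is_square = len(m.exponents) == 1
        return (2, 1 if is_square else 0, m.loci)
    return (m.total_degree if m.total_degree < 2 else 3, 0, m.loci)


@dataclass
class PolynomialModel:
    """An ordered set of monomials with matching real coefficients."""

    monomials: list[Monomial]
    coefficients: np.ndarray

    def __post_init__(self):
        self.monomials = list(self.monomials)
        self.coefficients = np.asarray(self.coefficients,
                                       dtype=float).reshape(-1)
        if len(self.monomials) != self.coefficients.shape[0]:
            raise DimensionError("one coefficient per monomial required")
        if len(set(self.monomials)) != len(self.monomials):
            raise DimensionError("monomials must be pairwise distinct")

    @property
    def total_degree(self) -> int:
        return max((m.total_degree for m in self.monomials), default=0)

    def coefficient(self, m: Monomial | str) -> float:
        if isinstance(m, str):
            m = Monomial.parse(m)
        return float(self.coefficients[self.monomials.index(m)])

    def coefficients_of_degree(self, degree: int) -> np.ndarray:
        return np.array([c for m, c in zip(self.monomials, self.coefficients)
                         if m.total_degree == degree])

    def interaction_effects(self) -> np.ndarray:
        """All degree-2 coefficients in model order (pairs then squares)."""
        return self.coefficients_of_degree(2)


@dataclass
class DesignMatrix:
    """Monomial-expanded regression design.

    ``values[i, c]`` is monomial ``monomial_index[c]`` evaluated at row
    ``i`` of the marker matrix the design was built from.
    ``coding_shift`` records that matrix's accumulated translation so a
    fit can carry it through to prediction.
    """

    values: np.ndarray
    monomial_index: list[Monomial]
    coding_shift: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.monomial_index = list(self.monomial_index)
        if self.values.shape[1] != len(self.monomial_index):
            raise DimensionError("design columns must match monomial count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


def enumerate_monomials(p: int, degree: int, include_squares: bool = False,
                        selected_pairs: Sequence[tuple[int, int]] | None = None,
                        ) -> list[Monomial]:
    """Intercept, all degree-1 terms, and (for degree 2) pairwise products.

    Pairs are ordered (j, k) with j < k, lexicographically; squares, if
    requested, are appended after all pairs.  ``selected_pairs``
    restricts the degree-2 pair set (0-based locus indices).  ``p = 1``
    with degree 2 simply yields no pairs.
    """
    if p < 1:
        raise DimensionError("p must be >= 1")
    if degree not in (1, 2):
        raise UnsupportedDegreeError(
            f"total degree {degree} unsupported (only 1 and 2)")
    out = [Monomial.intercept()]
    out += [Monomial.linear(j) for j in range(p)]
    if degree == 2:
        if selected_pairs is None:
            pairs = [(j, k) for j in range(p) for k in range(j + 1, p)]
        else:
            pairs = []
            for j, k in selected_pairs:
                if not (0 <= j < p and 0 <= k < p) or j == k:
                    raise DimensionError(f"invalid pair ({j}, {k}) for p={p}")
                pairs.append((min(j, k), max(j, k)))
            pairs = sorted(set(pairs))
        out += [Monomial.pair(j, k) for j, k in pairs]
        if include_squares:
            out += [Monomial(((j, 2),)) for j in range(p)]
    return out


def is_complete(monomials: Iterable[Monomial]) -> bool:
    """True iff every componentwise-smaller monomial of each member is
    also a member (the condition under which a fitted polynomial can be
    re-expressed exactly in any translated coding)."""
    have = set(monomials)
    for m in have:
        loci = [j for j, _ in m.exponents]
        powers = [d for _, d in m.exponents]
        for sub in itertools.product(*(range(d + 1) for d in powers)):
            cand = Monomial(tuple((j, s) for j, s in zip(loci, sub) if s))
            if cand not in have:
                return False
    return True


def _marker_values(M) -> np.ndarray:
    if isinstance(M, MarkerMatrix):
        return M.values
    return np.atleast_2d(np.asarray(M, dtype=float))


def build_design(M, monomials: Sequence[Monomial]) -> DesignMatrix:
    """Evaluate each monomial rowwise to form the n × q design matrix."""
    V = _marker_values(M)
    n, p = V.shape
    cols = np.empty((n, len(monomials)))
    for c, m in enumerate(monomials):
        col = np.ones(n)
        for j, d in m.exponents:
            if j >= p:
                raise DimensionError(f"monomial {m} references locus "
                                     f"{j + 1} but p={p}")
            col = col * V[:, j] ** d
        cols[:, c] = col
    shift = M.shift.copy() if isinstance(M, MarkerMatrix) else np.zeros(p)
    return DesignMatrix(cols, list(monomials), shift)


def translate_polynomial(f: PolynomialModel, P) -> PolynomialModel:
    """Re-express ``f`` in the coding translated by ``P``.

    Returns ``f̃`` with ``f̃(m̃) = f(m̃ + P)`` identically, by exact
    binomial expansion of each monomial.  Coefficients of the top total
    degree are unchanged; lower-degree coefficients absorb the shift
    (e.g. for degree ≤ 2: ``μ̃ = μ + βᵗP + Σ_{j<k} h_jk P_j P_k``).
    Raises :class:`CompletenessError` if the expansion generates a term
    with a nonzero coefficient that has no slot in ``f``'s monomial set.
    """
    P = np.asarray(P, dtype=float).reshape(-1)
    slots = {m: i for i, m in enumerate(f.monomials)}
    out = np.zeros_like(f.coefficients)
    for m, c in zip(f.monomials, f.coefficients):
        loci = [j for j, _ in m.exponents]
        powers = [d for _, d in m.exponents]
        for j in loci:
            if j >= P.size:
                raise DimensionError(f"monomial {m} references locus "
                                     f"{j + 1} but P has length {P.size}")
        for sub in itertools.product(*(range(d + 1) for d in powers)):
            coef = c
            for j, d, s in zip(loci, powers, sub):
                coef *= math.comb(d, s) * P[j] ** (d - s)
            target = Monomial(tuple((j, s) for j, s in zip(loci, sub) if s))
            if target not in slots:
                if coef != 0.0:
                    raise CompletenessError(
                        f"translation generates monomial {target} which the "
                        f"model does not include; the monomial set is not "
                        f"complete")
                continue
            out[slots[target]] += coef
    return PolynomialModel(list(f.monomials), out)


def evaluate(f: PolynomialModel, M) -> np.ndarray:
    """Rowwise polynomial value of ``f`` at the rows of ``M``."""
    X = build_design(M, f.monomials)
    return X.values @ f.coefficients


def write_effects_table(f: PolynomialModel, path, sep: str = "\t") -> None:
    pd.DataFrame({
        "monomial": [str(m) for m in f.monomials],
        "coefficient": f.coefficients,
    }).to_csv(path, sep=sep, index=False)


def read_effects_table(path, sep: str | None = None) -> PolynomialModel:
    df = pd.read_csv(path, sep=sep, engine="python")
    monos = [Monomial.parse(s) for s in df["monomial"]]
    return PolynomialModel(monos, df["coefficient"].to_numpy(dtype=float))
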