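"""Synthetic genotypes and phenotypes with the generative structure the
solvers assume.

Genotypes are biallelic: marker ``j`` gets an allele frequency ``q_j``
drawn uniformly from ``maf_range`` and line dosages are
``Binomial(ploidy, q_j)`` — ploidy 1 gives presence/absence (0/1)
markers like dominant marker panels, ploidy 2 gives 0/1/2 SNP dosages.
Phenotypes follow the first-order epistasis model

    y_i = μ + Σ_j β_j M_ij + Σ_{j<k} h_jk M_ij M_ik + ε_i

with β_j ~ N(0, σ_β²), h_jk ~ N(0, σ_h²), ε_i ~ N(0, σ_ε²) i.i.d.
Effects are drawn in the *raw* 0..ploidy coding and the generating
polynomial is stored, so the truth can be re-expressed exactly in any
translated coding via :func:`~errblup.polydesign.translate_polynomial`.

Default sizes (300 lines × 50 presence/absence markers, variances
0.5 / 0.1 / 0.25) match the marker-subset study design the experiment
harness emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DimensionError
from .markers import MarkerMatrix, Phenotype
from .polydesign import PolynomialModel, build_design, enumerate_monomials

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_genotypes",
           "simulate_phenotypes", "simulate_dataset"]


@dataclass
class SimulationConfig:
    n_lines: int = 300
    n_markers: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    ploidy: int = 1
    mu: float = 0.0
    sigma2_beta: float = 0.5
    sigma2_h: float = 0.1
    sigma2_eps: float = 0.25
    sparsity: float = 1.0  # fraction of nonzero effects
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DimensionError("maf_range must lie in (0, 0.5]")
        if self.ploidy not in (1, 2):
            raise DimensionError("ploidy must be 1 or 2")
        if not (0 <= self.sparsity <= 1):
            raise DimensionError("sparsity must be in [0, 1]")
        if self.n_lines < 1 or self.n_markers < 1:
            raise DimensionError("need at least one line and one marker")
        if min(self.sigma2_beta, self.sigma2_h, self.sigma2_eps) < 0:
            raise DimensionError("variances must be >= 0")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SimulatedDataset:
    markers: MarkerMatrix
    phenotype: Phenotype
    true_model: PolynomialModel
    true_varcomps: dict[str, float]
    noise: np.ndarray = field(repr=False, default=None)  # type: ignore


def _geno_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 0])


def _pheno_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 1])


def simulate_genotypes(cfg: SimulationConfig) -> MarkerMatrix:
    """Draw the raw (shift = 0) dosage matrix; deterministic under seed."""
    rng = _geno_rng(cfg)
    q = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    values = rng.binomial(cfg.ploidy, q,
                          size=(cfg.n_lines, cfg.n_markers)).astype(float)
    width = len(str(cfg.n_lines))
    lines = [f"L{i + 1:0{width}d}" for i in range(cfg.n_lines)]
    markers = [f"M{j + 1}" for j in range(cfg.n_markers)]
    return MarkerMatrix(values, lines, markers)


def simulate_phenotypes(M: MarkerMatrix, cfg: SimulationConfig,
                        ) -> SimulatedDataset:
    """Draw effects and noise, returning data plus the generating truth.

    ``sparsity < 1`` zeroes a uniformly-drawn subset of the additive and
    interaction effects (for sparse-architecture / LASSO settings).
    """
    rng = _pheno_rng(cfg)
    p = M.p
    monos = enumerate_monomials(p, degree=2)
    n_pairs = p * (p - 1) // 2
    beta = rng.normal(0.0, np.sqrt(cfg.sigma2_beta), size=p) \
        if cfg.sigma2_beta > 0 else np.zeros(p)
    h = rng.normal(0.0, np.sqrt(cfg.sigma2_h), size=n_pairs) \
        if cfg.sigma2_h > 0 else np.zeros(n_pairs)
    if cfg.sparsity < 1.0:
        keep_b = rng.random(p) < cfg.sparsity
        keep_h = rng.random(n_pairs) < cfg.sparsity
        beta = beta * keep_b
        h = h * keep_h
    coefs = np.concatenate([[cfg.mu], beta, h])
    truth = PolynomialModel(monos, coefs)
    genetic = build_design(M, monos).values @ coefs
    noise = rng.normal(0.0, np.sqrt(cfg.sigma2_eps), size=M.n) \
        if cfg.sigma2_eps > 0 else np.zeros(M.n)
    y = Phenotype(genetic + noise, list(M.line_ids))
    vc = {"mu": cfg.mu, "sigma2_beta": cfg.sigma2_beta,
          "sigma2_h": cfg.sigma2_h, "sigma2_eps": cfg.sigma2_eps}
    return SimulatedDataset(M, y, truth, vc, noise)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Genotypes + phenotypes in one call (both streams seeded from cfg)."""
    return simulate_phenotypes(simulate_genotypes(cfg), cfg)
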