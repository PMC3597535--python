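"""Rotation-test significance and Storey–Tibshirani q-values.

With far more genes than samples and strong within-pathway correlation,
permutation nulls are coarse (few distinct permutations) and parametric nulls
are untrustworthy.  A rotation test sidesteps both: under the null the sample
vectors are spherically symmetric within the residual space of the nuisance
model, so multiplying them by a random orthogonal matrix yields a new,
equally likely dataset while preserving the gene-gene correlation structure.
Repeating this builds a Monte-Carlo null for any statistic.

The rotation matrix is the Q factor of the QR decomposition of a standard
normal matrix, with the sign of the R diagonal fixed so that Q is Haar
(uniformly) distributed on the orthogonal group — plain QR output is not.
Nuisance terms (intercept, covariates, blocks) are handled by projecting the
data onto the residual space of the nuisance model, rotating there, and
adding the fitted component back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .expression import (PAIRED, UNPAIRED, ExpressionStudy, ExpressionSummary,
                         expression_summary)
from .scoring import deap_statistic

__all__ = [
    "RotationConfig",
    "NullSample",
    "random_rotation",
    "rotate_study",
    "rotation_pvalue",
    "rotated_summaries",
    "storey_qvalues",
]


@dataclass
class RotationConfig:
    """Configuration of the rotation null.

    ``nuisance`` is an (n_samples x k) design block whose fitted component is
    held fixed (k may be 0: rotate the raw sample vectors, the correct choice
    when testing the mean of paired log-ratios).  For unpaired designs the
    intercept is the natural nuisance term, so that rotation destroys the
    condition alignment while preserving each gene's overall level.
    """

    n_rotations: int = 1000
    nuisance: np.ndarray | None = None
    seed: int | None = None
    plus_one: bool = True

    def __post_init__(self) -> None:
        if self.n_rotations < 1:
            raise ValueError("n_rotations must be >= 1")

    @classmethod
    def for_study(cls, study: ExpressionStudy, n_rotations: int = 1000,
                  seed: int | None = None, plus_one: bool = True
                  ) -> "RotationConfig":
        """Default nuisance block for a study: none (paired), intercept (unpaired)."""
        if study.mode == UNPAIRED:
            nuisance = np.ones((study.n_samples, 1))
        else:
            nuisance = None
        return cls(n_rotations=n_rotations, nuisance=nuisance, seed=seed,
                   plus_one=plus_one)


@dataclass
class NullSample:
    """Rotated statistics s_1..s_R for one pathway (all non-negative)."""

    statistics: np.ndarray

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)

    def __len__(self) -> int:
        return len(self.statistics)


def random_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    """A Haar-distributed random orthogonal matrix of the given dimension.

    QR of a standard normal matrix, with Q's columns sign-fixed by the R
    diagonal so the distribution is uniform over the orthogonal group.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    x = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(x)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


def _residual_basis(nuisance: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of the nuisance span."""
    if nuisance is None or nuisance.size == 0 or nuisance.shape[1] == 0:
        return np.eye(n)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.shape[0] != n:
        raise ValueError(
            f"nuisance block has {nuisance.shape[0]} rows, expected {n}")
    k = nuisance.shape[1]
    if np.linalg.matrix_rank(nuisance) < k:
        raise ValueError("nuisance design block is rank deficient")
    # Full QR: the trailing columns span the residual space.
    q, _ = np.linalg.qr(nuisance, mode="complete")
    return q[:, k:]


def rotate_study(study: ExpressionStudy, config: RotationConfig,
                 rng: np.random.Generator,
                 rotation: np.ndarray | None = None) -> ExpressionStudy:
    """One rotation draw applied to a whole study.

    Each protein's sample vector is projected onto the residual space of the
    nuisance model, rotated by a single shared orthogonal matrix (preserving
    inter-gene correlation), transformed back, and the fitted nuisance
    component is re-added.
    """
    n = study.n_samples
    basis = _residual_basis(config.nuisance, n)
    m = basis.shape[1]
    if rotation is None:
        rotation = random_rotation(m, rng)
    y = study.values.to_numpy(dtype=float)
    coords = y @ basis                      # residual-space coordinates
    fitted = y - coords @ basis.T           # nuisance component
    rotated = fitted + (coords @ rotation.T) @ basis.T
    return study.with_values(rotated)


def rotated_summaries(study: ExpressionStudy, config: RotationConfig,
                      rng: np.random.Generator) -> list[ExpressionSummary]:
    """The rotation stream for one dataset: R rotated E(x) summaries.

    All pathways analysed against one dataset should share this single
    stream, mirroring how permutation nulls share shuffles — cross-pathway
    correlation of the statistics is preserved.
    """
    n = study.n_samples
    basis = _residual_basis(config.nuisance, n)
    m = basis.shape[1]
    y = study.values.to_numpy(dtype=float)
    coords = y @ basis
    fitted = y - coords @ basis.T
    proteins = list(study.values.index)
    out = []
    paired = study.mode == PAIRED
    for _ in range(config.n_rotations):
        q = random_rotation(m, rng)
        if paired:
            # Row mean of fitted + (coords @ q.T) @ basis.T, without
            # materialising the rotated matrix.
            weights = q.T @ (basis.sum(axis=0) / n)
            e = fitted.mean(axis=1) + coords @ weights
            out.append(ExpressionSummary(dict(zip(proteins, e))))
        else:
            rotated = study.with_values(fitted + (coords @ q.T) @ basis.T)
            out.append(expression_summary(rotated))
    return out


def rotation_pvalue(graph, study: ExpressionStudy,
                    summary_fn: Callable[[ExpressionStudy], ExpressionSummary]
                    | None = None,
                    statistic_fn: Callable = deap_statistic,
                    config: RotationConfig | None = None
                    ) -> tuple[float, NullSample]:
    """Monte-Carlo p-value of one pathway's statistic under rotation.

    ``p = (1 + #{s_i >= s*}) / (R + 1)`` by default — the add-one form keeps
    p away from zero, as is standard for randomisation tests; setting
    ``config.plus_one=False`` restores the plain proportion.
    """
    if config is None:
        config = RotationConfig.for_study(study)
    rng = np.random.default_rng(config.seed)
    if summary_fn is None:
        observed_summary = expression_summary(study)
        nulls = rotated_summaries(study, config, rng)
        null_stats = np.array([statistic_fn(graph, s) for s in nulls])
    else:
        observed_summary = summary_fn(study)
        null_stats = np.empty(config.n_rotations)
        for i in range(config.n_rotations):
            rotated = rotate_study(study, config, rng)
            null_stats[i] = statistic_fn(graph, summary_fn(rotated))
    observed = statistic_fn(graph, observed_summary)
    exceed = int(np.sum(null_stats >= observed))
    if config.plus_one:
        p = (1.0 + exceed) / (config.n_rotations + 1.0)
    else:
        p = exceed / config.n_rotations
    return p, NullSample(null_stats)


def storey_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Storey–Tibshirani q-values.

    The null proportion pi0 is estimated on the grid lambda = 0.05..0.95 by a
    three-parameter smoother (an inverse-variance-weighted quadratic fit of
    pi0(lambda), the same effective df as the classical df=3 smoothing
    spline) evaluated at the largest lambda; with fewer than 50 tests the
    smoother is unstable and the fixed lambda = 0.5 estimate is used
    instead.  q-values are monotone in p and lie in [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m < 50:
        pi0 = float(np.mean(p > 0.5) / 0.5)
    else:
        lam = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([np.mean(p > la) / (1.0 - la) for la in lam])
        # var(pi0_lam) ~ pi0 / (m (1 - lambda)): weight by sqrt(1 - lambda).
        coef = np.polyfit(lam, pi0_lam, 2, w=np.sqrt(1.0 - lam))
        pi0 = float(np.polyval(coef, lam[-1]))
    pi0 = min(1.0, max(pi0, 1.0 / m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]    # enforce monotonicity in p
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
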