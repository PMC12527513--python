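"""Simulator for CRT-based meta-analytic datasets.

Each simulated study is a two-arm cluster-randomized trial with equal
arm sizes. Cluster counts per arm and students per cluster are drawn
jointly from a correlated bivariate lognormal (education-trial sizes
vary over orders of magnitude and the two dimensions co-vary), rounded
to integers. The study's standard error follows from the CRT SMD
variance at the configured intraclass correlation, and the observed
effect is an unbiased normal draw around the true SMD:
``d_j ~ N(delta, v_j)``.

A single seeded generator drives each ``simulate_meta`` call; sizes are
drawn first, then effects, so size draws can be reproduced on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .meta import (
    DEFAULT_CONFIDENCE_LEVEL,
    MetaDataset,
    StudyEffect,
    crt_smd_variance,
    pool_fixed,
)

__all__ = [
    "SimulationConfig",
    "SampleSizeDraw",
    "draw_sample_sizes",
    "simulate_meta",
    "summarize_datasets",
    "STUDY_COUNT_LEVELS",
]

#: The four dataset sizes used as study-count factor levels in evaluation designs.
STUDY_COUNT_LEVELS = (10, 20, 50, 100)

#: Minimum clusters per arm / students per cluster after rounding,
#: keeping every CRT variance finite and well defined.
MIN_CLUSTERS_PER_ARM = 2
MIN_STUDENTS_PER_CLUSTER = 2

_DEFAULT_LOG_MEAN = (math.log(10.0), math.log(22.0))
_DEFAULT_LOG_COV = (
    (0.25, 0.05),
    (0.05, 0.25),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Truth parameters for the meta-analytic data generator.

    Parameters
    ----------
    k : int
        Number of studies per dataset.
    rho : float
        Intraclass correlation in ``[0, 1)``. Required: no default is
        assumed because the value drives every standard error.
    delta : float
        True SMD; 0.15 by default (a small effect on education outcomes).
    size_log_mean : (float, float)
        Log-scale means of (clusters per arm, students per cluster).
        Defaults target median sizes of ~10 clusters/arm and ~22
        students/cluster, typical of education CRTs.
    size_log_cov : 2x2 array-like
        Log-scale covariance; must be symmetric positive semi-definite.
        Default: log-sd 0.5 on both margins with correlation 0.2.
    seed : int
        RNG seed; every draw is reproducible from it.
    level : float
        Confidence level used when pooling, default 0.95.
    """

    k: int
    rho: float
    delta: float = 0.15
    size_log_mean: tuple[float, float] = _DEFAULT_LOG_MEAN
    size_log_cov: tuple[tuple[float, float], tuple[float, float]] = _DEFAULT_LOG_COV
    seed: int = 0
    level: float = DEFAULT_CONFIDENCE_LEVEL

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho!r}")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        cov = np.asarray(self.size_log_cov, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("size_log_cov must be 2x2")
        if not np.allclose(cov, cov.T):
            raise ValueError("size_log_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-12:
            raise ValueError("size_log_cov must be positive semi-definite")

    @property
    def log_cov(self) -> np.ndarray:
        return np.asarray(self.size_log_cov, dtype=float)


@dataclass(frozen=True)
class SampleSizeDraw:
    """Integer sample sizes for one simulated CRT (equal arms)."""

    m_per_arm: int
    n_per_cluster: int

    def __post_init__(self) -> None:
        if self.m_per_arm < 1 or self.n_per_cluster < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_total_t(self) -> int:
        return self.m_per_arm * self.n_per_cluster

    @property
    def n_total_c(self) -> int:
        return self.m_per_arm * self.n_per_cluster

    @property
    def n_students(self) -> int:
        """Total students across both arms."""
        return self.n_total_t + self.n_total_c


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def draw_sample_sizes(
    config: SimulationConfig,
    k: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[SampleSizeDraw]:
    """Draw ``k`` correlated lognormal (clusters/arm, students/cluster) pairs.

    Continuous draws are rounded half-up and floored at 2 clusters/arm
    and 2 students/cluster. A degenerate (zero) covariance returns the
    exponentiated log-means for every study.
    """
    if k is None:
        k = config.k
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean = np.asarray(config.size_log_mean, dtype=float)
    logs = rng.multivariate_normal(mean, config.log_cov, size=k, method="svd")
    sizes = _round_half_up(np.exp(logs))
    m = np.maximum(sizes[:, 0], MIN_CLUSTERS_PER_ARM)
    n = np.maximum(sizes[:, 1], MIN_STUDENTS_PER_CLUSTER)
    return [SampleSizeDraw(int(mi), int(ni)) for mi, ni in zip(m, n)]


def simulate_meta(config: SimulationConfig) -> MetaDataset:
    """Generate one meta-analytic dataset of ``config.k`` CRT studies.

    Draw order under the single seeded generator: all sample sizes
    first, then all effect sizes, so ``draw_sample_sizes`` with the same
    config reproduces the sizes exactly.
    """
    rng = np.random.default_rng(config.seed)
    sizes = draw_sample_sizes(config, config.k, rng)
    ses = np.array(
        [
            math.sqrt(
                crt_smd_variance(
                    s.n_total_t, s.n_total_c, s.n_per_cluster, config.rho, config.delta
                )
            )
            for s in sizes
        ]
    )
    smds = rng.normal(loc=config.delta, scale=ses)
    studies = [
        StudyEffect(
            study_id=f"Study {i + 1}",
            smd=float(d),
            se=float(se),
            n_students=s.n_students,
            n_clusters_t=s.m_per_arm,
            n_clusters_c=s.m_per_arm,
            cluster_size=s.n_per_cluster,
        )
        for i, (d, se, s) in enumerate(zip(smds, ses, sizes))
    ]
    return MetaDataset(studies)


def summarize_datasets(
    datasets: Iterable[MetaDataset], level: float = DEFAULT_CONFIDENCE_LEVEL
) -> pd.DataFrame:
    """Per-dataset meta-analytic summary table.

    One row per dataset: k, pooled estimate/se/CI, the smallest and
    largest study standard error, and the total student count (where
    recorded).
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    rows = []
    for ds in datasets:
        pooled = pool_fixed(ds, level=level)
        n_students = [s.n_students for s in ds if s.n_students is not None]
        rows.append(
            {
                "k": ds.k,
                "estimate": pooled.estimate,
                "se": pooled.se,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "min_study_se": float(ds.se.min()),
                "max_study_se": float(ds.se.max()),
                "total_students": int(sum(n_students)) if n_students else None,
            }
        )
    return pd.DataFrame(rows)
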