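"""Fixed-effects meta-analysis core.

Data model for standardized-mean-difference (SMD) effect sizes,
inverse-variance weighting, fixed-effects pooling, and the sampling
variance of an SMD estimated from a cluster-randomized trial (CRT).

The fixed-effects model assumes a single common true effect ``delta``:
each study ``j`` contributes an estimate ``d_j`` with standard error
``se_j``, receives weight ``w_j = 1 / se_j**2``, and the pooled estimate
is the weight-weighted mean with standard error ``(sum w_j)**-0.5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StudyEffect",
    "MetaDataset",
    "WeightSet",
    "PooledEffect",
    "compute_weights",
    "pool_fixed",
    "crt_smd_variance",
]

DEFAULT_CONFIDENCE_LEVEL = 0.95


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect size with its uncertainty and size metadata.

    Parameters
    ----------
    study_id : str
        Non-empty label, unique within a dataset.
    smd : float
        Standardized mean difference estimate ``d_j``.
    se : float
        Standard error of ``smd``; strictly positive. Exactly one of
        ``se``, ``variance`` or ``weight`` must be given at construction
        (use :meth:`from_uncertainty`); the others are derived.
    n_students : int, optional
        Total number of students across both arms.
    n_clusters_t, n_clusters_c : int, optional
        Number of clusters in the treatment / control arm.
    cluster_size : int, optional
        Students per cluster (assumed equal across clusters).
    """

    study_id: str
    smd: float
    se: float
    n_students: Optional[int] = None
    n_clusters_t: Optional[int] = None
    n_clusters_c: Optional[int] = None
    cluster_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be a non-empty string")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(
                f"study {self.study_id!r}: se must be finite and > 0, got {self.se!r}"
            )
        if not math.isfinite(self.smd):
            raise ValueError(f"study {self.study_id!r}: smd must be finite")

    @classmethod
    def from_uncertainty(
        cls,
        study_id: str,
        smd: float,
        *,
        se: Optional[float] = None,
        variance: Optional[float] = None,
        weight: Optional[float] = None,
        **meta,
    ) -> "StudyEffect":
        """Build a study from exactly one of se, variance or raw weight."""
        given = {k: v for k, v in dict(se=se, variance=variance, weight=weight).items()
                 if v is not None}
        if len(given) != 1:
            raise ValueError(
                f"study {study_id!r}: exactly one of se/variance/weight required, "
                f"got {sorted(given) or 'none'}"
            )
        if se is None:
            if variance is not None:
                if variance <= 0:
                    raise ValueError(f"study {study_id!r}: variance must be > 0")
                se = math.sqrt(variance)
            else:
                if weight is None or weight <= 0:
                    raise ValueError(f"study {study_id!r}: weight must be > 0")
                se = 1.0 / math.sqrt(weight)
        return cls(study_id=study_id, smd=smd, se=se, **meta)

    @property
    def variance(self) -> float:
        return self.se ** 2


@dataclass(frozen=True)
class MetaDataset:
    """An ordered collection of study effects (one effect per study)."""

    studies: tuple[StudyEffect, ...]

    def __init__(self, studies: Iterable[StudyEffect]):
        object.__setattr__(self, "studies", tuple(studies))
        if len(self.studies) < 1:
            raise ValueError("a MetaDataset needs at least one study")
        seen: set[str] = set()
        for s in self.studies:
            if s.study_id in seen:
                raise ValueError(f"duplicate study_id {s.study_id!r}")
            seen.add(s.study_id)

    @property
    def k(self) -> int:
        """Number of studies."""
        return len(self.studies)

    @property
    def smd(self) -> np.ndarray:
        return np.array([s.smd for s in self.studies])

    @property
    def se(self) -> np.ndarray:
        return np.array([s.se for s in self.studies])

    def __iter__(self):
        return iter(self.studies)

    def __len__(self) -> int:
        return self.k


@dataclass(frozen=True)
class WeightSet:
    """Inverse-variance weights, raw (1/se^2) and relative (sum to 1)."""

    raw: np.ndarray
    relative: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.raw <= 0):
            raise ValueError("raw weights must be strictly positive")
        if abs(float(self.relative.sum()) - 1.0) > 1e-9:
            raise ValueError("relative weights must sum to 1")


@dataclass(frozen=True)
class PooledEffect:
    """Fixed-effects summary SMD with its confidence interval."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("pooled se must be > 0")
        if not (self.ci_low < self.estimate < self.ci_high):
            raise ValueError("CI must bracket the estimate")
        if not (0.0 < self.level < 1.0):
            raise ValueError("confidence level must lie in (0, 1)")


def compute_weights(dataset: MetaDataset) -> WeightSet:
    """Inverse-variance weights ``w_j = 1/se_j**2`` and their shares.

    Raises
    ------
    ValueError
        If any study has a non-positive or non-finite standard error
        (the offending ``study_id`` is named; enforced at construction
        for :class:`StudyEffect`, re-checked here for safety).
    """
    for s in dataset:
        if not (math.isfinite(s.se) and s.se > 0):
            raise ValueError(
                f"study {s.study_id!r}: se must be finite and > 0, got {s.se!r}"
            )
    raw = 1.0 / dataset.se ** 2
    return WeightSet(raw=raw, relative=raw / raw.sum())


def pool_fixed(
    dataset: MetaDataset, level: float = DEFAULT_CONFIDENCE_LEVEL, method: str = "fixed"
) -> PooledEffect:
    """Pool a dataset under the fixed-effects model.

    ``estimate = sum(w_j d_j) / sum(w_j)``, ``se = (sum w_j)**-0.5``, and
    the CI is the normal-quantile interval at ``level``. ``method`` is a
    tag reserved for future pooling models; only ``"fixed"`` is accepted.
    """
    if method != "fixed":
        raise NotImplementedError(f"pooling method {method!r} not available")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    w = compute_weights(dataset).raw
    est = float(np.sum(w * dataset.smd) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = float(stats.norm.ppf(1.0 - (1.0 - level) / 2.0))
    return PooledEffect(
        estimate=est, se=se, ci_low=est - z * se, ci_high=est + z * se, level=level
    )


def crt_smd_variance(
    n_total_t: int,
    n_total_c: int,
    cluster_size: int,
    rho: float,
    delta: float,
) -> float:
    """Sampling variance of a total-variance-standardized SMD from a CRT.

    For a two-arm cluster-randomized trial with equal cluster size ``n``,
    arm totals ``N_T`` and ``N_C`` (``N = N_T + N_C``) and intraclass
    correlation ``rho``, the large-sample variance of the SMD ``d`` that
    standardizes by the total (within + between cluster) variance is

    ``v = (N_T + N_C)/(N_T N_C) * (1 + (n - 1) rho) + delta**2 / (2 h)``

    where ``h = B**2 / A`` with ``B = (N - 2) - 2 (n - 1) rho`` and
    ``A = (N-2)(1-rho)**2 + n (N - 2n) rho**2 + 2 (N - 2n) rho (1-rho)``.
    The mean-difference term carries the usual design effect
    ``1 + (n - 1) rho``; at ``rho = 0`` the whole expression reduces to
    the non-clustered SMD variance ``(N_T+N_C)/(N_T N_C) + delta**2/(2(N-2))``.

    Parameters
    ----------
    n_total_t, n_total_c : int
        Total students per arm; ``cluster_size`` must divide each.
    cluster_size : int
        Students per cluster, >= 1.
    rho : float
        Intraclass correlation, in ``[0, 1)``.
    delta : float
        True SMD (enters only the second-order term).
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1), got {rho!r}")
    if n_total_t < 1 or n_total_c < 1 or cluster_size < 1:
        raise ValueError("sample sizes must be positive")
    if cluster_size > min(n_total_t, n_total_c):
        raise ValueError("cluster_size cannot exceed an arm total")
    if n_total_t % cluster_size or n_total_c % cluster_size:
        raise ValueError("cluster_size must divide each arm total")
    n = cluster_size
    N = n_total_t + n_total_c
    if N <= 2:
        raise ValueError("need more than 2 students in total")
    B = (N - 2) - 2 * (n - 1) * rho
    if B <= 0:
        raise ValueError("degrees of freedom non-positive for this rho/cluster size")
    A = (
        (N - 2) * (1 - rho) ** 2
        + n * (N - 2 * n) * rho ** 2
        + 2 * (N - 2 * n) * rho * (1 - rho)
    )
    mean_diff_term = (n_total_t + n_total_c) / (n_total_t * n_total_c) * (
        1 + (n - 1) * rho
    )
    return float(mean_diff_term + delta ** 2 * A / (2.0 * B ** 2))
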