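"""Resolved plot layouts: MARC (v1/v2), forest, and bar.

A layout is the fully computed geometry and encoding of a plot — every
coordinate, mark area, color class and hover string — independent of any
drawing backend. Renderers (:mod:`marcplot.render`) only translate a
layout to pixels; they add no computation, so every number visible in an
output file is decided here.

The MARC (Meta-Analytic Rain Cloud) plot encodes each study as a dot at
(SMD, relative weight) with dot *area* also proportional to relative
weight, so precise studies sit higher and larger. The pooled effect is a
"cloud": a beeswarm of dots spread over its confidence interval, a
frequency-format uncertainty display. Version 1 places the cloud on the
same weight axis at y = 1.0 (the combined weight of the evidence);
version 2 moves it to a separate pane with its own vertical scale so
that for large k the studies' small relative weights still spread out
instead of pooling at the axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .meta import MetaDataset, PooledEffect, StudyEffect, compute_weights

__all__ = [
    "StudyMark",
    "SummaryCloud",
    "Pane",
    "Annotations",
    "MarcLayout",
    "ForestRow",
    "ForestLayout",
    "BarRow",
    "BarLayout",
    "marc_layout",
    "summary_cloud",
    "forest_layout",
    "bar_layout",
    "relabel_studies",
]

#: Mark area (in renderer points^2) given to the highest-weight study.
MAX_MARK_AREA = 300.0
#: v2 lower-pane headroom above the largest relative weight.
V2_PAD_FACTOR = 1.15
#: v2 pane height ratio, summary : studies.
V2_HEIGHT_RATIO = (1, 3)
DEFAULT_CLOUD_DOTS = 50

CERTAINTY_ARROWS = ("More certain", "Less certain")
DIRECTION_LABELS = ("Decreased scores", "Increased scores")


def _sign_class(x: float) -> str:
    return "negative" if x < 0 else ("positive" if x > 0 else "zero")


@dataclass(frozen=True)
class StudyMark:
    """One study's resolved mark."""

    study_id: str
    x: float                 # SMD
    y: float                 # relative weight (MARC) or row index (forest/bar)
    area: float              # mark area, proportional to relative weight
    color: str               # "negative" | "positive" | "zero", by sign of x
    hover: tuple[str, ...]   # lines shown on pointer-over

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("mark area must be > 0")
        if self.color != _sign_class(self.x):
            raise ValueError("color class must follow the sign of x")


@dataclass(frozen=True)
class SummaryCloud:
    """Beeswarm of dots spanning the pooled effect's CI.

    ``dots`` holds (x, y_offset) pairs; x positions are deterministic
    quantiles of the pooled sampling distribution truncated to the CI,
    y offsets come from a collision-avoiding packing around 0.
    """

    dots: np.ndarray     # shape (G, 2)
    center: float
    dot_radius: float

    @property
    def x(self) -> np.ndarray:
        return self.dots[:, 0]

    @property
    def y_offset(self) -> np.ndarray:
        return self.dots[:, 1]


@dataclass(frozen=True)
class Pane:
    """One vertical pane with its own y scale."""

    role: Literal["all", "summary", "studies"]
    y_range: tuple[float, float]
    height_ratio: float


@dataclass(frozen=True)
class Annotations:
    """Interpretive annotations; always present on a MARC layout."""

    certainty_arrows: tuple[str, str] = CERTAINTY_ARROWS
    direction_labels: tuple[str, str] = DIRECTION_LABELS


@dataclass(frozen=True)
class MarcLayout:
    version: Literal["v1", "v2"]
    marks: tuple[StudyMark, ...]
    cloud: SummaryCloud
    summary_y: float
    panes: tuple[Pane, ...]
    annotations: Annotations
    pooled: PooledEffect
    zero_line: float = 0.0
    #: MARC uses a continuous weight axis: height does not grow with k.
    height_grows_with_k: bool = False
    kind: str = "marc"


@dataclass(frozen=True)
class ForestRow:
    study_id: str
    x: float
    row: int
    area: float          # square area proportional to raw weight
    ci_low: float
    ci_high: float
    color: str
    hover: tuple[str, ...]


@dataclass(frozen=True)
class ForestLayout:
    rows: tuple[ForestRow, ...]
    diamond_row: int
    diamond_x: tuple[float, float, float]   # (ci_low, estimate, ci_high)
    pooled: PooledEffect
    zero_line: float = 0.0
    height_grows_with_k: bool = True
    kind: str = "forest"

    @property
    def n_rows(self) -> int:
        return len(self.rows) + 1


@dataclass(frozen=True)
class BarRow:
    study_id: str
    length: float        # |SMD|
    signed_end: float    # SMD (bar drawn from 0 to here)
    row: int
    color: str
    hover: tuple[str, ...]
    is_summary: bool = False


@dataclass(frozen=True)
class BarLayout:
    rows: tuple[BarRow, ...]
    pooled: PooledEffect
    zero_line: float = 0.0
    height_grows_with_k: bool = True
    kind: str = "bar"

    @property
    def n_rows(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# summary cloud

def _beeswarm_offsets(x: np.ndarray, radius: float) -> np.ndarray:
    """Collision-avoiding vertical offsets for dots of a given radius.

    Greedy packing: dots are placed in order of distance from the median
    x; each takes the offset of smallest magnitude that avoids overlap
    with already-placed dots (ties broken toward positive offsets), so
    the result is deterministic and densest near the center.
    """
    n = len(x)
    offsets = np.zeros(n)
    order = np.argsort(np.abs(x - np.median(x)), kind="stable")
    placed: list[tuple[float, float]] = []
    min_sep = 2.0 * radius
    for i in order:
        xi = x[i]
        neighbors = [(px, py) for px, py in placed if abs(px - xi) < min_sep]
        candidates = [0.0]
        for px, py in neighbors:
            dy = math.sqrt(max(min_sep ** 2 - (px - xi) ** 2, 0.0))
            candidates.extend((py + dy, py - dy))
        candidates.sort(key=lambda c: (abs(c), -c))
        for cand in candidates:
            if all(
                (px - xi) ** 2 + (py - cand) ** 2 >= min_sep ** 2 * (1 - 1e-9)
                for px, py in neighbors
            ):
                offsets[i] = cand
                placed.append((xi, cand))
                break
    return offsets


def summary_cloud(
    pooled: PooledEffect,
    n_dots: int = DEFAULT_CLOUD_DOTS,
    dot_radius: Optional[float] = None,
) -> SummaryCloud:
    """Frequency-format display of the pooled effect's uncertainty.

    Dot x positions are the ``i/(G+1)`` quantiles (``i = 1..G``) of the
    pooled-estimate sampling distribution, a normal truncated to the
    confidence interval — so every dot lies inside the CI, the spread of
    dots *is* the interval, and dot density is highest near the
    estimate. Placement is fully deterministic.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    a = (pooled.ci_low - pooled.estimate) / pooled.se
    b = (pooled.ci_high - pooled.estimate) / pooled.se
    probs = np.arange(1, n_dots + 1) / (n_dots + 1)
    z = stats.truncnorm.ppf(probs, a, b)
    x = pooled.estimate + pooled.se * z
    # guard against roundoff pushing the extreme quantiles past the bounds
    x = np.clip(x, pooled.ci_low, pooled.ci_high)
    if dot_radius is None:
        dot_radius = (pooled.ci_high - pooled.ci_low) / 60.0
    offsets = _beeswarm_offsets(x, dot_radius)
    return SummaryCloud(
        dots=np.column_stack([x, offsets]), center=pooled.estimate,
        dot_radius=float(dot_radius),
    )


# ---------------------------------------------------------------------------
# MARC layouts

def _marc_hover(study: StudyEffect, rel_w: float, smd_fmt: str, w_fmt: str) -> tuple[str, ...]:
    return (
        study.study_id,
        f"SMD: {study.smd:{smd_fmt}}",
        f"Relative weight: {rel_w:{w_fmt}}",
    )


def marc_layout(
    dataset: MetaDataset,
    pooled: PooledEffect,
    version: Literal["v1", "v2"] = "v2",
    n_dots: int = DEFAULT_CLOUD_DOTS,
    smd_fmt: str = ".2f",
    weight_fmt: str = ".1%",
) -> MarcLayout:
    """Resolve a MARC plot layout.

    Marks sit at (SMD_j, relative weight_j) with area proportional to
    relative weight (largest study gets :data:`MAX_MARK_AREA`). v1 is a
    single pane whose axis reaches the cloud at y = 1.0; v2 gives the
    cloud its own pane and rescales the study pane to
    ``[0, V2_PAD_FACTOR * max relative weight]``.
    """
    if version not in ("v1", "v2"):
        raise ValueError(f"unknown MARC version {version!r}")
    w = compute_weights(dataset)
    wmax = float(w.relative.max())
    marks = tuple(
        StudyMark(
            study_id=s.study_id,
            x=s.smd,
            y=float(rw),
            area=MAX_MARK_AREA * float(rw) / wmax,
            color=_sign_class(s.smd),
            hover=_marc_hover(s, float(rw), smd_fmt, weight_fmt),
        )
        for s, rw in zip(dataset, w.relative)
    )
    cloud = summary_cloud(pooled, n_dots=n_dots)
    if version == "v1":
        summary_y = 1.0
        panes = (Pane(role="all", y_range=(0.0, 1.05), height_ratio=1.0),)
    else:
        summary_y = 0.5  # vertical center of the dedicated summary pane
        panes = (
            Pane(role="summary", y_range=(0.0, 1.0),
                 height_ratio=float(V2_HEIGHT_RATIO[0])),
            Pane(role="studies", y_range=(0.0, V2_PAD_FACTOR * wmax),
                 height_ratio=float(V2_HEIGHT_RATIO[1])),
        )
    return MarcLayout(
        version=version,
        marks=marks,
        cloud=cloud,
        summary_y=summary_y,
        panes=panes,
        annotations=Annotations(),
        pooled=pooled,
    )


# ---------------------------------------------------------------------------
# reference layouts: forest and bar

def forest_layout(
    dataset: MetaDataset,
    pooled: PooledEffect,
    smd_fmt: str = ".2f",
    weight_fmt: str = ".2f",
) -> ForestLayout:
    """Conventional forest plot: squares (area ∝ weight) with CI whiskers,
    one row per study in input order, pooled diamond on the bottom row.
    Hover shows the raw inverse-variance weight."""
    w = compute_weights(dataset)
    z = float(stats.norm.ppf(1.0 - (1.0 - pooled.level) / 2.0))
    wmax = float(w.raw.max())
    rows = tuple(
        ForestRow(
            study_id=s.study_id,
            x=s.smd,
            row=i,
            area=MAX_MARK_AREA * float(rw) / wmax,
            ci_low=s.smd - z * s.se,
            ci_high=s.smd + z * s.se,
            color=_sign_class(s.smd),
            hover=(
                s.study_id,
                f"SMD: {s.smd:{smd_fmt}}",
                f"Weight: {rw:{weight_fmt}}",
            ),
        )
        for i, (s, rw) in enumerate(zip(dataset, w.raw))
    )
    return ForestLayout(
        rows=rows,
        diamond_row=len(rows),
        diamond_x=(pooled.ci_low, pooled.estimate, pooled.ci_high),
        pooled=pooled,
    )


def bar_layout(
    dataset: MetaDataset,
    pooled: PooledEffect,
    smd_fmt: str = ".2f",
) -> BarLayout:
    """Horizontal bar chart of |SMD| per study (What Works Clearinghouse
    style), rows in input order, plus a summary bar. Hover shows the
    student count; a study without one gets a warning and a hover that
    omits it."""
    rows: list[BarRow] = []
    missing: list[str] = []
    for i, s in enumerate(dataset):
        hover = [s.study_id, f"SMD: {s.smd:{smd_fmt}}"]
        if s.n_students is not None:
            hover.append(f"Students: {s.n_students}")
        else:
            missing.append(s.study_id)
        rows.append(
            BarRow(
                study_id=s.study_id,
                length=abs(s.smd),
                signed_end=s.smd,
                row=i,
                color=_sign_class(s.smd),
                hover=tuple(hover),
            )
        )
    if missing:
        warnings.warn(
            f"n_students missing for {', '.join(missing)}; hover omits it",
            stacklevel=2,
        )
    rows.append(
        BarRow(
            study_id="Summary",
            length=abs(pooled.estimate),
            signed_end=pooled.estimate,
            row=len(rows),
            color=_sign_class(pooled.estimate),
            hover=("Summary", f"SMD: {pooled.estimate:{smd_fmt}}"),
            is_summary=True,
        )
    )
    return BarLayout(rows=tuple(rows), pooled=pooled)


# ---------------------------------------------------------------------------
# utilities

def relabel_studies(dataset: MetaDataset, seed: int) -> MetaDataset:
    """Deterministically shuffle study-ID labels among studies.

    Useful when the same dataset is shown repeatedly (e.g., once per
    visualization type in an experiment) and labels should not let a
    viewer match studies across charts.
    """
    rng = np.random.default_rng(seed)
    ids = [s.study_id for s in dataset]
    perm = rng.permutation(len(ids))
    return MetaDataset(
        StudyEffect(
            study_id=ids[j],
            smd=s.smd,
            se=s.se,
            n_students=s.n_students,
            n_clusters_t=s.n_clusters_t,
            n_clusters_c=s.n_clusters_c,
            cluster_size=s.cluster_size,
        )
        for j, s in zip(perm, dataset)
    )
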