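"""Silhouette-selected K-means over the ⟨stress, closeness, co-expression⟩ space.

Every threshold-surviving (gene, member, stress) record becomes one point in
a three-dimensional feature space: the stress's fixed integer code (1..7),
the gene's closeness centrality in its subunit network, and the record's
Pearson score. A gene therefore contributes up to |members| x |stresses|
points (35 / 70 / 14 for the default A / B / C layouts).

K-means (k-means++ init, 10 restarts, 300 iterations, tolerance 1e-4) is fit
for K in 2..9 and the mean silhouette over all points selects K: the chosen
K is the smallest one whose silhouette lies within a tolerance (default
0.01) of the maximum, preferring parsimonious models when higher K offers no
real gain. Features are clustered raw by default — stress is an ordinal code
and intentionally dominates in dense subunits — with an optional z-score
flag for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .centrality import CentralityTable
from .config_io import CoexpressionTable, StressSet, ValidationError

__all__ = [
    "FeaturePoint",
    "SilhouetteCurve",
    "ClusterModel",
    "ClusterSummary",
    "build_feature_table",
    "points_to_array",
    "select_k",
    "fit_kmeans",
    "summarize_clusters",
]


class FeaturePoint(NamedTuple):
    """One clustered observation: a surviving record plus its gene's CCS."""

    gene_id: str
    stress_code: int
    ccs: float
    score: float


def build_feature_table(
    filtered: CoexpressionTable,
    centrality: CentralityTable,
    stresses: StressSet,
) -> list[FeaturePoint]:
    """One feature point per surviving record.

    The centrality table must cover every gene present in the filtered
    table; a missing gene is an error naming it.
    """
    points: list[FeaturePoint] = []
    for r in filtered:
        if r.gene_id not in centrality.scores:
            raise ValidationError(
                f"gene {r.gene_id!r} missing from the centrality table"
            )
        points.append(
            FeaturePoint(
                r.gene_id,
                stresses.code(r.stress),
                centrality.scores[r.gene_id],
                r.score,
            )
        )
    return points


def points_to_array(points: Sequence[FeaturePoint], scale: bool = False) -> np.ndarray:
    x = np.array([[p.stress_code, p.ccs, p.score] for p in points], dtype=float)
    if scale and len(x):
        std = x.std(axis=0)
        std[std == 0] = 1.0
        x = (x - x.mean(axis=0)) / std
    return x


@dataclass
class KMeansParams:
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-4
    init: str = "k-means++"


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int
    params: KMeansParams = field(default_factory=KMeansParams)


def fit_kmeans(
    points: Sequence[FeaturePoint],
    k: int,
    params: Optional[KMeansParams] = None,
    seed: int = 0,
    scale: bool = False,
) -> ClusterModel:
    """Best-inertia K-means over ``params.n_init`` restarts; deterministic per seed."""
    params = params or KMeansParams()
    x = points_to_array(points, scale=scale)
    n_distinct = len(np.unique(x, axis=0)) if len(x) else 0
    if k > n_distinct:
        raise ValidationError(
            f"k={k} exceeds the {n_distinct} distinct points available"
        )
    km = KMeans(
        n_clusters=k,
        init=params.init,
        n_init=params.n_init,
        max_iter=params.max_iter,
        tol=params.tol,
        random_state=seed,
    ).fit(x)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=km.labels_.copy(),
        inertia=float(km.inertia_),
        seed=seed,
        params=params,
    )


@dataclass
class SilhouetteCurve:
    k_values: tuple[int, ...]
    mean_silhouette: dict[int, float]
    chosen_k: int
    selection_tolerance: float

    def write_tsv(self, path) -> None:
        from pathlib import Path

        with Path(path).open("w") as fh:
            fh.write("k\tmean_silhouette\tchosen\n")
            for k in self.k_values:
                fh.write(
                    f"{k}\t{self.mean_silhouette[k]:.6f}\t"
                    f"{int(k == self.chosen_k)}\n"
                )


def select_k(
    points: Sequence[FeaturePoint],
    k_range: range = range(2, 10),
    params: Optional[KMeansParams] = None,
    seed: int = 0,
    selection_tolerance: float = 0.01,
    scale: bool = False,
    subsample: Optional[int] = None,
) -> SilhouetteCurve:
    """Fit K-means across ``k_range`` and pick K by mean silhouette.

    The chosen K is the smallest whose silhouette is within
    ``selection_tolerance`` of the maximum. If fewer points than the top of
    the range are available the range is shrunk with a warning; fewer than 3
    points is an error (no non-trivial clustering exists). ``subsample``
    caps the number of points used for the silhouette computation (the fit
    still uses all points), for very large tables.
    """
    n = len(points)
    if n < 3:
        raise ValidationError("need at least 3 points to select k")
    x = points_to_array(points, scale=scale)
    n_distinct = len(np.unique(x, axis=0))
    k_max_allowed = min(max(k_range), n - 1, n_distinct)
    if k_max_allowed < max(k_range):
        warnings.warn(
            f"shrinking k range to 2..{k_max_allowed} for {n} points "
            f"({n_distinct} distinct)",
            stacklevel=2,
        )
    k_values = tuple(k for k in k_range if 2 <= k <= k_max_allowed)
    if not k_values:
        raise ValidationError("no feasible k in range for this point set")

    rng = np.random.default_rng(seed)
    sil_idx = None
    if subsample is not None and subsample < n:
        sil_idx = rng.choice(n, size=subsample, replace=False)

    mean_sil: dict[int, float] = {}
    for k in k_values:
        model = fit_kmeans(points, k, params=params, seed=seed, scale=scale)
        labels = model.assignments
        if sil_idx is not None:
            mean_sil[k] = float(silhouette_score(x[sil_idx], labels[sil_idx]))
        else:
            mean_sil[k] = float(silhouette_score(x, labels))
    best = max(mean_sil.values())
    chosen = min(k for k, s in mean_sil.items() if s >= best - selection_tolerance)
    return SilhouetteCurve(
        k_values=k_values,
        mean_silhouette=mean_sil,
        chosen_k=chosen,
        selection_tolerance=selection_tolerance,
    )


@dataclass
class ClusterSummary:
    cluster_id: int
    size: int
    dominant_stress_codes: tuple[int, ...]
    gene_multiplicity: dict[str, int]
    singleton_genes: tuple[str, ...]


def summarize_clusters(
    model: ClusterModel, points: Sequence[FeaturePoint]
) -> list[ClusterSummary]:
    """Per-cluster occupancy bookkeeping.

    For each cluster: its size, the modal stress code(s), how many of each
    gene's points it holds, and the genes appearing exactly once in it.
    """
    if len(points) == 0:
        raise ValidationError("no points to summarise")
    if len(points) != len(model.assignments):
        raise ValidationError("model was not fitted on these points")
    summaries = []
    for cid in range(model.k):
        idx = [i for i, a in enumerate(model.assignments) if a == cid]
        stress_counts = Counter(points[i].stress_code for i in idx)
        gene_counts = Counter(points[i].gene_id for i in idx)
        top = max(stress_counts.values(), default=0)
        summaries.append(
            ClusterSummary(
                cluster_id=cid,
                size=len(idx),
                dominant_stress_codes=tuple(
                    sorted(c for c, n in stress_counts.items() if n == top)
                ),
                gene_multiplicity=dict(gene_counts),
                singleton_genes=tuple(
                    sorted(g for g, n in gene_counts.items() if n == 1)
                ),
            )
        )
    return summaries
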