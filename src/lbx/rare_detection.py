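"""Unsupervised separation of rare events from the leukocyte background.

Within each slide, descriptors are standardized, projected onto the
smallest set of principal components explaining a configured variance
fraction, and grouped by agglomerative (Ward, Euclidean) clustering.
Clusters far smaller than the slide population are flagged as
rare-event candidates; the dominant cluster is always called common.
Anucleate DAPI- | PanCK+ candidates bypass this path entirely and are
merged in afterwards, tagged for the vesicle size gate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .segmentation import FeatureMatrix

logger = logging.getLogger(__name__)

CALL_COMMON = "common"
CALL_RARE = "rare-candidate"


@dataclass
class RareDetectionParams:
    """Knobs of the PCA + clustering stage (all config-exposed).

    ``variance_fraction``: retained PCA explained-variance fraction.
    ``rarity_fraction``: clusters smaller than this fraction of the
    slide's events are candidate-rare.
    ``ceiling_fraction``: hard cap on the rare-candidate share per slide.
    ``n_clusters``: number of flat clusters cut from the Ward tree.
    ``separation_min``: a small cluster is only called rare when its
    centroid lies at least this many background-RMS radii from the
    dominant cluster's centroid in PCA space; this keeps ordinary
    distribution-tail clusters of a homogeneous background from being
    flagged (they sit within a few radii, while marker-discordant cells
    land an order of magnitude away).
    ``min_events``: below this many events per slide everything is
    passed through as rare-candidate (too few cells to model a
    background population).
    """

    variance_fraction: float = 0.90
    rarity_fraction: float = 0.01
    ceiling_fraction: float = 0.05
    n_clusters: int = 12
    separation_min: float = 6.0
    min_events: int = 50


@dataclass
class RareCallResult:
    """Per-event common/rare-candidate calls plus the PCA/linkage record."""

    calls: pd.DataFrame  # event_id, slide_id, call, cluster_id, lev_candidate
    explained_variance: dict[str, list[float]] = field(default_factory=dict)
    n_components: dict[str, int] = field(default_factory=dict)
    params: RareDetectionParams = field(default_factory=RareDetectionParams)

    @property
    def rare_ids(self) -> list[str]:
        return self.calls.loc[self.calls["call"] == CALL_RARE, "event_id"].tolist()


def _pca_scores(x: np.ndarray, variance_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PCA via full SVD; sign fixed by making the
    largest-magnitude loading of each component positive."""
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    k = int(np.searchsorted(np.cumsum(explained), variance_fraction) + 1)
    k = min(k, len(s))
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    return scores, explained[:k]


def detect_rare(
    matrix: FeatureMatrix, params: RareDetectionParams | None = None
) -> RareCallResult:
    """Call each nucleated event common or rare-candidate, per slide.

    Requires a per-slide-normalized matrix. Events are processed in
    input order (ties in the linkage resolve by that order), and a
    fixed matrix with fixed parameters always yields identical calls.
    """
    if not matrix.normalized:
        raise ValueError("detect_rare requires a per-slide-normalized FeatureMatrix")
    params = params or RareDetectionParams()

    df = matrix.data
    nucleated = df[~df["dapi_negative"]]
    pieces = []
    explained_record: dict[str, list[float]] = {}
    ncomp_record: dict[str, int] = {}

    for slide_id, sub in nucleated.groupby("slide_id", sort=False):
        calls = pd.DataFrame(
            {
                "event_id": sub["event_id"].to_numpy(),
                "slide_id": slide_id,
                "call": CALL_COMMON,
                "cluster_id": 0,
                "lev_candidate": False,
            }
        )
        n = len(sub)
        if n < params.min_events:
            warnings.warn(
                f"slide {slide_id}: only {n} events (< {params.min_events}); "
                "passing all through as rare-candidates",
                stacklevel=2,
            )
            calls["call"] = CALL_RARE
            pieces.append(calls)
            continue

        x = sub[list(matrix.feature_columns)].to_numpy(dtype=float)
        sd = x.std(axis=0)
        keep = sd > 0
        if not keep.any():
            warnings.warn(
                f"slide {slide_id}: degenerate (zero-variance) feature matrix; "
                "all events called common",
                stacklevel=2,
            )
            pieces.append(calls)
            continue
        z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

        scores, explained = _pca_scores(z, params.variance_fraction)
        explained_record[str(slide_id)] = [float(v) for v in explained]
        ncomp_record[str(slide_id)] = scores.shape[1]

        tree = linkage(scores, method="ward", metric="euclidean")
        cluster_ids = fcluster(tree, t=params.n_clusters, criterion="maxclust")
        calls["cluster_id"] = cluster_ids

        sizes = pd.Series(cluster_ids).value_counts()
        dominant = int(sizes.idxmax())
        small = sizes[sizes < params.rarity_fraction * n].drop(dominant, errors="ignore")
        dom_points = scores[cluster_ids == dominant]
        dom_centroid = dom_points.mean(axis=0)
        dom_rms = float(np.sqrt(((dom_points - dom_centroid) ** 2).sum(axis=1).mean()))
        ceiling = int(params.ceiling_fraction * n)
        budget = 0
        rare_clusters = []
        for cid, size in small.sort_values().items():
            if budget + size > ceiling:
                break
            centroid = scores[cluster_ids == cid].mean(axis=0)
            separation = float(np.linalg.norm(centroid - dom_centroid)) / max(dom_rms, 1e-12)
            if separation < params.separation_min:
                continue
            rare_clusters.append(int(cid))
            budget += int(size)
        calls.loc[calls["cluster_id"].isin(rare_clusters), "call"] = CALL_RARE
        pieces.append(calls)

    calls_df = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(
            columns=["event_id", "slide_id", "call", "cluster_id", "lev_candidate"]
        )
    )
    return RareCallResult(calls_df, explained_record, ncomp_record, params)


def merge_dapi_negative(result: RareCallResult, matrix: FeatureMatrix) -> RareCallResult:
    """Append anucleate candidates as LEV-tagged rare-candidates.

    DAPI- events with positive PanCK signal bypass the PCA/clustering
    path; DAPI- events without PanCK signal are carried as common so
    that the final call table partitions the full event set.
    """
    df = matrix.data
    negatives = df[df["dapi_negative"]]
    if negatives.empty:
        return result
    panck_col = "mean_PanCK"
    positive = negatives[panck_col].to_numpy(dtype=float) > 0.0
    extra = pd.DataFrame(
        {
            "event_id": negatives["event_id"].to_numpy(),
            "slide_id": negatives["slide_id"].to_numpy(),
            "call": np.where(positive, CALL_RARE, CALL_COMMON),
            "cluster_id": -1,
            "lev_candidate": positive,
        }
    )
    existing = set(result.calls["event_id"])
    overlap = existing.intersection(extra["event_id"])
    if overlap:
        raise ValueError(f"DAPI- events already present in call table: {sorted(overlap)[:3]}")
    merged = pd.concat([result.calls, extra], ignore_index=True)
    return RareCallResult(merged, result.explained_variance, result.n_components, result.params)
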