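"""Consensus meta-clustering of grid-run label vectors.

Rather than clustering the raw data, the label outputs of every
sanity-passing run are stacked into a block one-hot membership matrix
(one block of indicator columns per run). The squared Euclidean distance
between two patients' rows then equals twice the number of runs that
assign them to different clusters, so principal components of this matrix
order patients by ensemble disagreement. Mean shift on the reduced
coordinates yields the final consensus partition without ever choosing a
"winner" combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import MeanShift
from sklearn.decomposition import PCA

from .grid import GridRunResult

logger = logging.getLogger(__name__)

BANDWIDTH_QUANTILE = 0.3  # of the pairwise-distance distribution in the embedding
BANDWIDTH_SCALE = 0.5  # kernel radius must undercut the separation the quantile measures


@dataclass
class MembershipMatrix:
    """Patient x (sum of per-run cluster counts) block one-hot array."""

    matrix: np.ndarray
    run_index: list[tuple[tuple, slice]]  # (combo_id, iteration) -> column block

    @property
    def n_runs(self) -> int:
        return len(self.run_index)


@dataclass
class MetaClusterModel:
    labels: np.ndarray
    embedding: np.ndarray
    bandwidth: float
    n_final_clusters: int


def build_membership_matrix(passing_runs: list[GridRunResult]) -> MembershipMatrix:
    """Block one-hot encoding of every passing run's label vector.

    Each run contributes one column per cluster it found; a patient's entries
    within a block sum to 1. Patients co-clustered in every run get
    identical rows.
    """
    runs = [r for r in passing_runs if r.labels is not None]
    if not runs:
        raise ValueError("no passing runs to aggregate")
    n = len(runs[0].labels)
    blocks: list[np.ndarray] = []
    run_index: list[tuple[tuple, slice]] = []
    start = 0
    for r in runs:
        labels = np.asarray(r.labels)
        if len(labels) != n:
            raise ValueError("runs disagree on patient count")
        uniq = np.unique(labels)
        block = (labels[:, None] == uniq[None, :]).astype(float)
        blocks.append(block)
        run_index.append(((r.combo_id, r.iteration), slice(start, start + len(uniq))))
        start += len(uniq)
    return MembershipMatrix(np.hstack(blocks), run_index)


def _pairwise_quantile_bandwidth(
    X: np.ndarray, quantile: float, seed: int = 0, max_points: int = 2000
) -> float:
    """Bandwidth = given quantile of the pairwise Euclidean distances
    (subsampled deterministically above ``max_points``)."""
    rng = np.random.default_rng(seed)
    if len(X) > max_points:
        X = X[rng.choice(len(X), size=max_points, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(len(X), k=1)
    return float(np.sqrt(np.quantile(d2[iu], quantile)))


def _labels_from_unique_rows(X: np.ndarray) -> np.ndarray:
    """Group patients by (rounded) identical embedding rows.

    Fallback for the degenerate case where the ensemble is unanimous: all
    pairwise distances within consensus groups are 0, the estimated
    bandwidth collapses, and mean shift is unnecessary.
    """
    _, labels = np.unique(np.round(X, 9), axis=0, return_inverse=True)
    return labels


def reduce_and_cluster(
    membership: MembershipMatrix,
    d: int = 3,
    bandwidth: float | str = "auto",
    seed: int = 0,
) -> MetaClusterModel:
    """Principal components of the membership matrix, then mean shift.

    ``bandwidth="auto"`` estimates the kernel bandwidth as
    :data:`BANDWIDTH_SCALE` times the :data:`BANDWIDTH_QUANTILE` quantile of
    pairwise distances in the embedding. Consensus embeddings are strongly
    bimodal — near-zero distances within consensus groups, large distances
    between them — so the quantile measures the between-group separation
    scale and the flat kernel's radius must stay below it to resolve the
    groups; the final cluster count is sensitive to this choice. An
    estimated bandwidth of (near) zero means the ensemble is unanimous up to
    consensus groups, which are then returned directly.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    X = membership.matrix
    d_eff = min(d, min(X.shape))
    emb = PCA(n_components=d_eff, svd_solver="full", random_state=0).fit_transform(X)
    if bandwidth == "auto":
        bw = BANDWIDTH_SCALE * _pairwise_quantile_bandwidth(emb, BANDWIDTH_QUANTILE, seed=seed)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("explicit bandwidth must be positive")
    if bw <= 1e-12:
        labels = _labels_from_unique_rows(emb)
        logger.info("unanimous ensemble: %d consensus groups", labels.max() + 1)
    else:
        labels = MeanShift(bandwidth=bw).fit_predict(emb)
    return MetaClusterModel(
        labels=np.asarray(labels),
        embedding=emb,
        bandwidth=bw,
        n_final_clusters=len(np.unique(labels)),
    )


def export_embedding(
    model: MetaClusterModel, path, patient_ids: np.ndarray | None = None
) -> pd.DataFrame:
    """Write patient id, embedding coordinates and meta-cluster label as CSV."""
    n, d = model.embedding.shape
    ids = np.arange(n) if patient_ids is None else np.asarray(patient_ids)
    coord_names = ["x", "y", "z", *[f"dim{i}" for i in range(3, d)]][:d]
    df = pd.DataFrame(model.embedding, columns=coord_names)
    df.insert(0, "patient_id", ids)
    df["meta_cluster"] = model.labels
    df.to_csv(path, index=False)
    return df
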