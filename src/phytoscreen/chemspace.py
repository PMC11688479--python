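"""Chemical-space clustering: 3-D embedding, Ward linkage, representatives.

The cascade mirrors a common ligand-clustering recipe: binary fingerprints
are embedded to three dimensions with t-SNE, the embedded coordinates are
clustered agglomeratively with Ward linkage cut at k clusters, and each
cluster is summarized by the member with the highest mean Tanimoto
similarity to the rest of its cluster (its similarity medoid).

t-SNE requires perplexity < n; :func:`clamp_perplexity` provides the
pipeline's auto-clamp (min(perplexity, (n-1)/3)) for small libraries
where a conventional perplexity of 30 would be unrunnable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.manifold import TSNE

from .fingerprints import Fingerprint, tanimoto

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Embedding:
    """t-SNE coordinates (n x 3) for an ordered id list."""

    ids: tuple[str, ...]
    coords: np.ndarray
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.ids), 3):
            raise ValueError("coords must be n x 3, one row per id")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


@dataclass(frozen=True)
class ClusterModel:
    """Cluster labels in {1..k} plus (optionally) one representative per cluster."""

    labels: dict[str, int]
    k: int
    representatives: dict[int, str] = field(default_factory=dict)
    linkage: str = "ward"

    def members(self, cluster: int) -> list[str]:
        return [cid for cid, lab in self.labels.items() if lab == cluster]


def clamp_perplexity(perplexity: float, n: int) -> float:
    """Clamp perplexity below n for small libraries, warning when it bites.

    The clamp targets min(perplexity, (n - 1) / 3): comfortably inside the
    perplexity < n constraint and in line with the usual guidance that
    perplexity stay well below the sample count.
    """
    limit = (n - 1) / 3
    if perplexity > limit:
        clamped = max(1.0, limit)
        warnings.warn(
            f"perplexity {perplexity} is too large for n={n}; clamped to {clamped:.2f}",
            stacklevel=2,
        )
        return clamped
    return float(perplexity)


def embed_3d(
    fps: Sequence[Fingerprint],
    perplexity: float = 30.0,
    seed: int = 0,
    ids: Sequence[str] | None = None,
    metric: str = "euclidean",
    learning_rate: float = 10.0,
    max_iter: int = 5000,
) -> Embedding:
    """Embed binary fingerprints into 3-D with t-SNE (exact method, seeded).

    Distances are computed on the 0/1 fingerprint vectors; ``metric`` may
    be ``"euclidean"`` (default) or ``"jaccard"``.  Raises ValueError when
    n < 4 or perplexity >= n (use :func:`clamp_perplexity` upstream).

    The optimizer defaults (PCA initialization, small learning rate, long
    iteration budget) are tuned for library-sized inputs (tens of
    molecules), where the stock stochastic settings routinely shear
    well-separated chemotypes apart; for thousands of molecules a larger
    learning rate is preferable.
    """
    n = len(fps)
    if n < 4:
        raise ValueError(f"need at least 4 molecules to embed, got {n}")
    if perplexity >= n:
        raise ValueError(
            f"perplexity ({perplexity}) must be < number of molecules ({n}); "
            f"clamp it, e.g. with clamp_perplexity()"
        )
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    x = np.stack([fp.to_array() for fp in fps]).astype(float)
    # Exact (non-Barnes-Hut) gradients: exact is required for 3 output
    # dimensions in scikit-learn and is cheap at library scale.
    tsne = TSNE(
        n_components=3,
        perplexity=perplexity,
        random_state=seed,
        method="exact",
        metric=metric,
        init="pca",
        learning_rate=learning_rate,
        max_iter=max_iter,
    )
    coords = tsne.fit_transform(x)
    return Embedding(tuple(ids), np.asarray(coords, dtype=float), perplexity, seed)


def cluster_ward(e: Embedding, k: int) -> ClusterModel:
    """Ward-linkage agglomerative clustering of embedded coordinates, cut at k.

    Labels are renumbered 1..k by first appearance in input order, so the
    labelling is stable across runs with identical coordinates.
    """
    n = len(e.ids)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == n:
        raw = np.arange(n)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        raw = model.fit_predict(e.coords)
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for cid, lab in zip(e.ids, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[cid] = remap[lab]
    return ClusterModel(labels=labels, k=k, linkage="ward")


def select_representatives(
    fps: Mapping[str, Fingerprint],
    model: ClusterModel,
    include_self: bool = False,
) -> ClusterModel:
    """Pick each cluster's similarity medoid: max mean Tanimoto to its cluster.

    The mean excludes the candidate itself by default (``include_self=False``);
    including it only adds a constant term and cannot change the argmax
    except at exact ties.  Ties break by input order (first member wins);
    a singleton cluster is represented by its sole member.
    """
    missing = [cid for cid in model.labels if cid not in fps]
    if missing:
        raise KeyError(f"no fingerprint for ids: {missing[:5]}")
    reps: dict[int, str] = {}
    for cluster in sorted(set(model.labels.values())):
        members = model.members(cluster)
        if len(members) == 1:
            reps[cluster] = members[0]
            continue
        best_id, best_score = members[0], -1.0
        for cid in members:
            sims = [
                tanimoto(fps[cid], fps[other])
                for other in members
                if include_self or other != cid
            ]
            score = float(np.mean(sims))
            if score > best_score + 1e-12:
                best_id, best_score = cid, score
        reps[cluster] = best_id
    return ClusterModel(
        labels=dict(model.labels),
        k=model.k,
        representatives=reps,
        linkage=model.linkage,
    )


def cluster_cascade(
    fps: Mapping[str, Fingerprint],
    k: int = 3,
    perplexity: float = 30.0,
    seed: int = 0,
    metric: str = "euclidean",
) -> tuple[Embedding, ClusterModel]:
    """Full cascade: clamp perplexity, embed, Ward-cluster, pick representatives."""
    ids = tuple(fps.keys())
    fplist = [fps[cid] for cid in ids]
    perp = clamp_perplexity(perplexity, len(ids))
    emb = embed_3d(fplist, perplexity=perp, seed=seed, ids=ids, metric=metric)
    model = cluster_ward(emb, k)
    model = select_representatives(fps, model)
    return emb, model


def cluster_report(emb: Embedding, model: ClusterModel) -> "pd.DataFrame":
    """Tabular report mirroring the published layout: smiles/id, V1..V3, cluster, flag."""
    import pandas as pd

    rows = []
    for i, cid in enumerate(emb.ids):
        cluster = model.labels[cid]
        rows.append(
            {
                "id": cid,
                "V1": emb.coords[i, 0],
                "V2": emb.coords[i, 1],
                "V3": emb.coords[i, 2],
                "cluster": cluster,
                "is_representative": model.representatives.get(cluster) == cid,
            }
        )
    return pd.DataFrame(rows)
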