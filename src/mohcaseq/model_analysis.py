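"""Low-energy selection, greedy RMSD clustering, and precision analytics.

Given an ensemble of scored 3D models, the analysis keeps the
lowest-energy fraction, clusters it greedily — repeatedly taking the model
with the most neighbors within an RMSD threshold as a cluster center and
removing it with its neighbors — and reports the top cluster's center as
the single representative structure.  The clustering threshold is chosen
automatically as the smallest observed pairwise RMSD at which the most
populous cluster holds at least 1/6 of the models.

The threshold doubles as the intra-cluster RMSD; multiplying it by sqrt(2)
gives the in situ precision — an estimate of the cluster center's distance
to the (unknown) true structure, from the triangle through the cluster's
most accurate member.  When several independent modeling runs exist, the
mean pairwise RMSD between their top-cluster centers plays the role of the
intra-cluster RMSD instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .errors import ConfigurationError, EvaluationError, ValidationError
from .maps_io import ModelCoordinates

SELECTION_FRACTIONS = {
    "prerefinement": 1.0 / 6.0,  # low-resolution models handed to refinement
    "refined": 0.03,             # refined models handed to clustering
    "unrefined": 0.005,          # clustering directly on unrefined models
}


@dataclass
class Cluster:
    center_id: str
    member_ids: list[str]


@dataclass
class ClusterResult:
    threshold: float
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def top_fraction(self) -> float:
        total = sum(len(c.member_ids) for c in self.clusters)
        return len(self.clusters[0].member_ids) / total if total else 0.0

    @property
    def intra_cluster_rmsd(self) -> float:
        # the clustering radius is used as the intra-cluster RMSD estimate
        return self.threshold

    @property
    def precision(self) -> float:
        return in_situ_precision(self.intra_cluster_rmsd)


def select_low_energy(models: list[ModelCoordinates], stage: str) -> list[ModelCoordinates]:
    """Keep the lowest-scoring fraction for the given pipeline stage.

    The count is ceil(fraction * N) so at least one model survives; score
    ties are broken by model id.
    """
    if stage not in SELECTION_FRACTIONS:
        raise ConfigurationError(
            f"stage must be one of {sorted(SELECTION_FRACTIONS)}, got {stage!r}")
    for m in models:
        if m.score is None:
            raise ValidationError(f"model {m.model_id} has no score")
    n = math.ceil(SELECTION_FRACTIONS[stage] * len(models))
    ranked = sorted(models, key=lambda m: (m.score, m.model_id))
    return ranked[:n]


def _common_atoms(a: ModelCoordinates, b: ModelCoordinates,
                  atom_set: str | list = "all_heavy") -> list[tuple[int, str]]:
    if atom_set == "all_heavy":
        keys = [k for k in a.atom_keys() if not k[1].startswith("H")]
    else:
        keys = list(atom_set)
    missing = [k for k in keys if b.coord(*k) is None]
    missing += [k for k in keys if a.coord(*k) is None]
    if missing:
        raise EvaluationError(f"atoms missing from compared models: {sorted(set(missing))[:5]}")
    return keys


def pairwise_rmsd(a: ModelCoordinates, b: ModelCoordinates,
                  atom_set: str | list = "all_heavy") -> float:
    """RMSD after optimal rigid-body superposition (SVD/Kabsch).

    ``atom_set`` is either "all_heavy" (every non-hydrogen atom, matched by
    (residue, name)) or an explicit list of (residue, atom name) keys.
    """
    keys = _common_atoms(a, b, atom_set)
    xa = a.coords_for(keys)
    xb = b.coords_for(keys)
    sup = SVDSuperimposer()
    sup.set(xa, xb)
    sup.run()
    return float(sup.get_rms())


def rmsd_matrix(models: list[ModelCoordinates],
                atom_set: str | list = "all_heavy") -> np.ndarray:
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_rmsd(models[i], models[j], atom_set)
    return D


def _greedy_from_matrix(D: np.ndarray, threshold: float,
                        scores: list[float | None], ids: list[str]) -> list[list[int]]:
    remaining = list(range(len(ids)))
    clusters: list[list[int]] = []
    while remaining:
        best = None
        for idx in remaining:
            neighbors = [k for k in remaining if D[idx, k] <= threshold]
            score = scores[idx] if scores[idx] is not None else math.inf
            key = (-len(neighbors), score, ids[idx])
            if best is None or key < best[0]:
                best = (key, idx, neighbors)
        _, center, neighbors = best
        members = sorted(set(neighbors) | {center})
        # center listed first
        members = [center] + [m for m in members if m != center]
        clusters.append(members)
        remaining = [k for k in remaining if k not in members]
    clusters.sort(key=lambda ms: (-len(ms), ids[ms[0]]))
    return clusters


def greedy_cluster(models: list[ModelCoordinates], threshold: float,
                   atom_set: str | list = "all_heavy",
                   D: np.ndarray | None = None) -> ClusterResult:
    """Greedy neighbor clustering at a fixed RMSD threshold.

    Repeatedly: the model with the largest number of neighbors within the
    threshold (ties: lowest score, then id) becomes a cluster center and is
    removed together with its neighbors.  Cluster 0 is the largest.
    """
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    if D is None:
        D = rmsd_matrix(models, atom_set)
    ids = [m.model_id for m in models]
    scores = [m.score for m in models]
    groups = _greedy_from_matrix(D, threshold, scores, ids)
    clusters = [Cluster(center_id=ids[g[0]], member_ids=[ids[k] for k in g])
                for g in groups]
    return ClusterResult(threshold=threshold, clusters=clusters)


def select_threshold(models: list[ModelCoordinates], target_fraction: float = 1.0 / 6.0,
                     atom_set: str | list = "all_heavy",
                     D: np.ndarray | None = None) -> float:
    """Smallest observed-RMSD threshold putting >= target_fraction in cluster 0.

    The achieved top-cluster fraction is a step function of the threshold,
    so only the finite set of observed pairwise RMSDs (plus 0) needs to be
    scanned, in ascending order.
    """
    if len(models) < 2:
        return 0.0
    if D is None:
        D = rmsd_matrix(models, atom_set)
    ids = [m.model_id for m in models]
    scores = [m.score for m in models]
    n = len(models)
    candidates = np.unique(np.concatenate([[0.0], D[np.triu_indices(n, k=1)]]))
    for threshold in candidates:
        groups = _greedy_from_matrix(D, float(threshold), scores, ids)
        if len(groups[0]) / n >= target_fraction:
            return float(threshold)
    return float(candidates[-1])


def in_situ_precision(intra_cluster_rmsd: float) -> float:
    """Precision estimate: intra-cluster RMSD times sqrt(2)."""
    if intra_cluster_rmsd < 0:
        raise ValidationError("intra-cluster RMSD must be non-negative")
    return intra_cluster_rmsd * math.sqrt(2.0)


def cross_setup_precision(centers: list[ModelCoordinates],
                          atom_set: str | list = "all_heavy") -> float:
    """Mean pairwise RMSD among top-cluster centers of independent runs.

    Serves as the intra-cluster RMSD when precision is estimated across
    several modeling setups rather than within one cluster.
    """
    if len(centers) < 2:
        raise ValidationError("need at least two cluster centers")
    vals = [pairwise_rmsd(a, b, atom_set)
            for idx, a in enumerate(centers) for b in centers[idx + 1:]]
    return float(np.mean(vals))


def cluster_models(models: list[ModelCoordinates], stage: str = "refined",
                   target_fraction: float = 1.0 / 6.0,
                   atom_set: str | list = "all_heavy") -> ClusterResult:
    """Convenience pipeline: low-energy selection, threshold choice, clustering."""
    selected = select_low_energy(models, stage)
    D = rmsd_matrix(selected, atom_set)
    threshold = select_threshold(selected, target_fraction, atom_set, D=D)
    return greedy_cluster(selected, threshold, atom_set, D=D)
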