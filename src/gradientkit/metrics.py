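"""Manifold eccentricity and graph-theoretic context measures.

Eccentricity condenses a subject's k-dimensional embedding into one
scalar per parcel: Euclidean distance from the template manifold's
center. Larger eccentricity means a region sits further out in gradient
space, i.e. is more functionally differentiated. The modular measures
(within-module degree z, participation coefficient), Louvain community
detection and classic centralities contextualize where on the
integration/segregation axis those shifts occur.

Graph measures operate on a symmetrized, nonnegative weight matrix
(max(W, W^T) with negatives zeroed), the standard convention for
weighted modular metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
import scipy.linalg

from .connectome import ConnectivityMatrix

__all__ = [
    "EccentricityMap",
    "ModulePartition",
    "manifold_eccentricity",
    "within_module_degree",
    "participation_coefficient",
    "louvain_partition",
    "centralities",
    "symmetrize_nonnegative",
]


@dataclass
class EccentricityMap:
    values: np.ndarray  # per-parcel nonnegative distance
    subject_id: str = ""


@dataclass
class ModulePartition:
    """Per-parcel module labels from atlas communities, Louvain or hierarchy."""

    labels: np.ndarray
    source: str = "atlas_communities"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("partition needs at least 2 modules")

    @property
    def modules(self) -> list:
        return sorted(set(self.labels.tolist()), key=str)


def symmetrize_nonnegative(W: np.ndarray) -> np.ndarray:
    """max(W, W^T) with negative weights zeroed and zero diagonal."""
    W = np.maximum(np.asarray(W, float), np.asarray(W, float).T)
    W = np.where(W > 0, W, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def _weights(W) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        W = W.values
    return symmetrize_nonnegative(W)


def manifold_eccentricity(
    subject_embedding: np.ndarray,
    template_center: np.ndarray,
    subject_id: str = "",
) -> EccentricityMap:
    """Per-parcel Euclidean distance from the template manifold center."""
    E = np.asarray(subject_embedding, float)
    c = np.asarray(template_center, float)
    if E.ndim != 2 or c.shape != (E.shape[1],):
        raise ValueError(
            f"center dimension {c.shape} does not match embedding {E.shape}"
        )
    return EccentricityMap(
        values=np.linalg.norm(E - c[None, :], axis=1), subject_id=subject_id
    )


def within_module_degree(W, partition: ModulePartition) -> np.ndarray:
    """Within-module degree z-score (population SD within each module).

    z_p = (kappa_p - mean_m) / sd_m, where kappa_p is parcel p's summed
    edge weight to its own module; z = 0 where the module SD is zero
    (including singleton modules, which trigger a warning).
    """
    W = _weights(W)
    labels = partition.labels
    z = np.zeros(W.shape[0])
    for m in partition.modules:
        idx = np.flatnonzero(labels == m)
        if idx.size == 1:
            warnings.warn(f"singleton module {m!r}: z set to 0", stacklevel=2)
            continue
        kappa = W[np.ix_(idx, idx)].sum(axis=1)
        sd = kappa.std()  # population SD
        if sd > 0:
            z[idx] = (kappa - kappa.mean()) / sd
    return z


def participation_coefficient(W, partition: ModulePartition) -> np.ndarray:
    """PC_p = 1 - sum_m (kappa_pm / kappa_p)^2, in [0, 1].

    0 when all of a node's strength stays within one module, approaching
    1 as strength spreads evenly across modules. Isolated nodes get 0
    with a warning.
    """
    W = _weights(W)
    labels = partition.labels
    strength = W.sum(axis=1)
    isolated = np.flatnonzero(strength == 0)
    if isolated.size:
        warnings.warn(f"isolated node(s) {isolated.tolist()}: PC set to 0", stacklevel=2)
    pc = np.zeros(W.shape[0])
    ok = strength > 0
    acc = np.zeros(W.shape[0])
    for m in partition.modules:
        idx = np.flatnonzero(labels == m)
        kappa_m = W[:, idx].sum(axis=1)
        acc[ok] += (kappa_m[ok] / strength[ok]) ** 2
    pc[ok] = 1.0 - acc[ok]
    return pc


def louvain_partition(
    W, resolution: float = 1.0, n_restarts: int = 100, seed: int = 0
) -> ModulePartition:
    """Best-modularity Louvain partition over seeded restarts."""
    W = _weights(W)
    if W.sum() == 0:
        raise ValueError("empty graph: no positive edges")
    G = nx.from_numpy_array(W)
    best, best_q = None, -np.inf
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed + r
        )
        q = nx.community.modularity(G, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best, best_q = comms, q
    labels = np.empty(W.shape[0], dtype=int)
    for m, nodes in enumerate(sorted(best, key=min)):
        labels[list(nodes)] = m
    return ModulePartition(labels=labels, source="louvain")


def modularity(W, partition: ModulePartition, resolution: float = 1.0) -> float:
    """Newman modularity of a labeled partition on weights W."""
    W = _weights(W)
    G = nx.from_numpy_array(W)
    groups = [
        set(np.flatnonzero(partition.labels == m).tolist()) for m in partition.modules
    ]
    return nx.community.modularity(G, groups, weight="weight", resolution=resolution)


def centralities(W) -> dict[str, np.ndarray]:
    """Betweenness, eigenvector and degree (strength) centrality.

    Betweenness uses edge lengths 1/weight and is normalized by
    (n-1)(n-2)/2; on a disconnected graph it is computed per component
    with a warning. Eigenvector centrality is the nonnegative unit-norm
    principal eigenvector of W; degree is the row-sum strength.
    """
    W = _weights(W)
    n = W.shape[0]
    G = nx.from_numpy_array(W)
    for _, _, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    if not nx.is_connected(G):
        warnings.warn(
            "disconnected graph: betweenness computed within components",
            stacklevel=2,
        )
    btw = nx.betweenness_centrality(G, weight="length", normalized=True)
    betweenness = np.array([btw[i] for i in range(n)])
    evals, evecs = scipy.linalg.eigh(W)
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector of a nonnegative matrix
    eigen = v / np.linalg.norm(v)
    return {"betweenness": betweenness, "eigenvector": eigen, "degree": W.sum(axis=1)}
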