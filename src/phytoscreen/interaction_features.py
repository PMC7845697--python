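"""Molecular-interaction features from network propagation on a PPI graph.

A compound's targets seed a random walk with restart (RWR); the stationary
probability over disease-related proteins is its interaction profile, reduced
by PCA at a cumulative-explained-variance threshold.  The module also provides
the five network-proximity baselines (closest, shortest, kernel, centre,
separation) used to benchmark propagation-based scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io_core import CompoundProfile

__all__ = [
    "PropagationProblem",
    "ReductionModel",
    "normalize_adjacency",
    "build_seed_vector",
    "rwr",
    "rwr_closed_form",
    "disease_score",
    "fit_reduction",
    "apply_reduction",
    "interaction_block",
    "proximity_closest",
    "proximity_shortest",
    "proximity_kernel",
    "proximity_centre",
    "proximity_separation",
    "proximity_auroc",
    "PROXIMITY_METHODS",
]

#: direct binding seeds get weight 1.0, indirect (downstream effects) 0.3
DIRECT_WEIGHT = 1.0
INDIRECT_WEIGHT = 0.3

#: default restart probability of the walker
DEFAULT_RESTART = 0.7


@dataclass
class PropagationProblem:
    """One RWR instance: p_{t+1} = (1−r)·Wᵀ·p_t + r·p0.

    ``W`` is the column-normalized adjacency (nonzero columns sum to 1,
    zero-degree columns stay zero); ``p0`` is the seed distribution.
    """

    W: sp.spmatrix
    p0: np.ndarray
    r: float = DEFAULT_RESTART
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        if not 0 < self.r < 1:
            raise ValueError("restart probability must be in (0,1)")
        if (self.p0 < 0).any() or not np.isclose(self.p0.sum(), 1.0):
            raise ValueError("p0 must be a probability vector")


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"RWR did not converge within {max_iter} iterations "
            f"(last L1 residual {residual:.3e})"
        )
        self.residual = residual


def node_index(graph: nx.Graph) -> dict[str, int]:
    """Stable node → row index mapping (sorted node order)."""
    return {n: i for i, n in enumerate(sorted(graph.nodes))}


def normalize_adjacency(graph: nx.Graph) -> sp.csr_matrix:
    """Column-normalized adjacency: each nonzero column sums to 1.

    Zero-degree columns are left all-zero; the restart term re-injects their
    mass during propagation.
    """
    order = sorted(graph.nodes)
    A = nx.to_scipy_sparse_array(graph, nodelist=order, format="csc", dtype=float)
    degrees = np.asarray(A.sum(axis=0)).ravel()
    inv = np.divide(1.0, degrees, out=np.zeros_like(degrees), where=degrees > 0)
    return (A @ sp.diags(inv)).tocsr()


def build_seed_vector(
    profile: CompoundProfile, index: Mapping[str, int]
) -> tuple[np.ndarray, int]:
    """Seed distribution from a compound's targets.

    Direct targets get raw weight 1.0 and indirect targets 0.3; the vector is
    then normalized to sum 1 (preserving the 10:3 ratio).  Returns the vector
    and the number of targets that did not map to the network.
    """
    p0 = np.zeros(len(index))
    unmapped = 0
    for t in profile.direct_targets:
        if t in index:
            p0[index[t]] += DIRECT_WEIGHT
        else:
            unmapped += 1
    for t in profile.indirect_targets:
        if t in index:
            p0[index[t]] += INDIRECT_WEIGHT
        else:
            unmapped += 1
    total = p0.sum()
    if total == 0:
        raise ValueError(f"empty seed: no target of {profile.id!r} is in the network")
    return p0 / total, unmapped


def rwr(problem: PropagationProblem) -> tuple[np.ndarray, int]:
    """Iterate the restart walk to stationarity (L1 residual < tol).

    Returns the stationary vector and the number of iterations performed.
    """
    WT = problem.W.T.tocsr()
    p = problem.p0.copy()
    hold = problem.r * problem.p0
    for it in range(1, problem.max_iter + 1):
        p_next = (1.0 - problem.r) * (WT @ p) + hold
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < problem.tol:
            return p, it
    raise ConvergenceError(residual, problem.max_iter)


def rwr_closed_form(problem: PropagationProblem) -> np.ndarray:
    """Direct linear solve p = r·(I − (1−r)·Wᵀ)⁻¹·p0 (dense; small graphs)."""
    n = problem.W.shape[0]
    WT = problem.W.T.toarray() if sp.issparse(problem.W) else np.asarray(problem.W).T
    return problem.r * np.linalg.solve(
        np.eye(n) - (1.0 - problem.r) * WT, problem.p0
    )


def disease_score(
    p: np.ndarray, disease_genes: set[str], index: Mapping[str, int]
) -> float:
    """Sum of stationary probability over disease genes present in the network."""
    if not disease_genes:
        raise ValueError("empty disease gene set")
    rows = [index[g] for g in disease_genes if g in index]
    return float(p[rows].sum()) if rows else 0.0


# ---------------------------------------------------------------------------
# dimensionality reduction


@dataclass
class ReductionModel:
    """PCA basis truncated at a cumulative explained-variance threshold."""

    center: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    n_components: int
    explained_variance_ratio: np.ndarray
    threshold: float = 0.8

    def __post_init__(self) -> None:
        G = self.components @ self.components.T
        if not np.allclose(G, np.eye(self.n_components), atol=1e-8):
            raise ValueError("components are not orthonormal")


def fit_reduction(training_rows: np.ndarray, threshold: float = 0.8) -> ReductionModel:
    """Fit PCA on training rows; keep the smallest k reaching the threshold.

    The cumulative explained-variance threshold (default 0.8) picks k; if the
    data rank is too low to reach it, k = rank with a warning.
    """
    X = np.asarray(training_rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    ratios = pca.explained_variance_ratio_
    # treat numerically-zero components as absent rank
    rank = int((pca.explained_variance_ > 1e-12 * max(pca.explained_variance_[0], 1)).sum())
    cumulative = np.cumsum(ratios)
    reachable = np.nonzero(cumulative >= threshold - 1e-12)[0]
    if len(reachable) and reachable[0] < rank:
        k = int(reachable[0]) + 1
    else:
        warnings.warn(
            f"variance threshold {threshold} unreachable; using k = rank = {rank}"
        )
        k = max(rank, 1)
    return ReductionModel(
        center=pca.mean_,
        components=pca.components_[:k],
        n_components=k,
        explained_variance_ratio=ratios[:k],
        threshold=threshold,
    )


def apply_reduction(model: ReductionModel, rows: np.ndarray) -> np.ndarray:
    """Project rows with the stored training center and basis."""
    X = np.asarray(rows, dtype=float)
    return (X - model.center) @ model.components.T


def interaction_block(
    profiles: Sequence[CompoundProfile],
    graph: nx.Graph,
    disease_genes: Sequence[str],
    r: float = DEFAULT_RESTART,
    tol: float = 1e-8,
) -> np.ndarray:
    """Raw (unreduced) interaction profiles: one RWR per compound.

    The stationary vector is restricted to the ordered disease-related protein
    list before any reduction, mirroring the restriction of the full proteome
    to disease-associated proteins.
    """
    index = node_index(graph)
    W = normalize_adjacency(graph)
    gene_rows = [index[g] for g in disease_genes if g in index]
    out = np.zeros((len(profiles), len(gene_rows)))
    for i, profile in enumerate(profiles):
        p0, _ = build_seed_vector(profile, index)
        p, _ = rwr(PropagationProblem(W=W, p0=p0, r=r, tol=tol))
        out[i] = p[gene_rows]
    return out


# ---------------------------------------------------------------------------
# network-proximity baselines


def _distances_from(graph: nx.Graph, sources: set[str]) -> dict[str, dict[str, int]]:
    return {
        s: nx.single_source_shortest_path_length(graph, s)
        for s in sources
        if s in graph
    }


def _check_sets(graph, targets, disease_genes):
    T = {t for t in targets if t in graph}
    G = {g for g in disease_genes if g in graph}
    if not T or not G:
        raise ValueError("both sets must intersect the network")
    return T, G


def proximity_closest(targets, disease_genes, graph: nx.Graph) -> float:
    """Mean over targets of the distance to the nearest disease gene."""
    T, G = _check_sets(graph, targets, disease_genes)
    dist = _distances_from(graph, T)
    mins = []
    for t in sorted(T):
        finite = [dist[t][g] for g in G if g in dist[t]]
        if finite:
            mins.append(min(finite))
    if not mins:
        raise ValueError("no finite path between the sets")
    return float(np.mean(mins))


def proximity_shortest(targets, disease_genes, graph: nx.Graph) -> float:
    """Mean shortest distance over all finite target–gene pairs."""
    T, G = _check_sets(graph, targets, disease_genes)
    dist = _distances_from(graph, T)
    vals = [dist[t][g] for t in sorted(T) for g in G if g in dist[t]]
    if not vals:
        raise ValueError("no finite path between the sets")
    return float(np.mean(vals))


def proximity_kernel(targets, disease_genes, graph: nx.Graph) -> float:
    """Exponentially path-downweighted distance.

    d = −(1/|G|)·Σ_g ln[(1/|T|)·Σ_t exp(−(d(t,g)+1))]; unreachable pairs
    contribute 0 inside the sum, and a gene unreachable from every target is
    excluded with a warning.
    """
    T, G = _check_sets(graph, targets, disease_genes)
    dist = _distances_from(graph, T)
    terms = []
    for g in sorted(G):
        inner = sum(
            np.exp(-(dist[t][g] + 1)) for t in T if g in dist[t]
        ) / len(T)
        if inner == 0:
            warnings.warn(f"gene {g!r} unreachable from all targets; excluded")
            continue
        terms.append(-np.log(inner))
    if not terms:
        raise ValueError("all disease genes unreachable")
    return float(np.mean(terms))


def proximity_centre(targets, disease_genes, graph: nx.Graph) -> float:
    """Mean distance from targets to the disease-module centre.

    The centre is the disease gene with the largest closeness centrality in
    the network (unscaled, over its reachable set); ties broken
    lexicographically by gene id.
    """
    T, G = _check_sets(graph, targets, disease_genes)

    def closeness(g: str) -> float:
        d = nx.single_source_shortest_path_length(graph, g)
        total = sum(v for v in d.values())
        return (len(d) - 1) / total if total > 0 else 0.0

    centre = max(sorted(G), key=closeness)
    dist = nx.single_source_shortest_path_length(graph, centre)
    vals = [dist[t] for t in sorted(T) if t in dist]
    if not vals:
        raise ValueError("no finite path from targets to the centre")
    return float(np.mean(vals))


def _closest_between(dist_T, T, G) -> float:
    mins = []
    for t in sorted(T):
        finite = [dist_T[t][g] for g in G if g in dist_T[t]]
        if finite:
            mins.append(min(finite))
    return float(np.mean(mins)) if mins else np.nan


def _closest_within(graph, S) -> float:
    # nearest-other-member distance, averaged; singleton sets contribute 0
    if len(S) < 2:
        return 0.0
    dist = _distances_from(graph, S)
    mins = []
    for s in sorted(S):
        finite = [dist[s][o] for o in S if o != s and o in dist[s]]
        if finite:
            mins.append(min(finite))
    return float(np.mean(mins)) if mins else 0.0


def proximity_separation(targets, disease_genes, graph: nx.Graph) -> float:
    """Separation score s = ⟨d_TG⟩ − (⟨d_TT⟩ + ⟨d_GG⟩)/2.

    ⟨d_TG⟩ is the symmetric closest-based mean between the sets (shared nodes
    contribute distance 0); the within-set terms use the nearest *other*
    member, with singleton sets contributing 0.
    """
    T, G = _check_sets(graph, targets, disease_genes)
    dist_T = _distances_from(graph, T)
    dist_G = _distances_from(graph, G)
    tg = _closest_between(dist_T, T, G)
    gt = _closest_between(dist_G, G, T)
    if np.isnan(tg) or np.isnan(gt):
        raise ValueError("no finite path between the sets")
    d_tg = (tg * len(T) + gt * len(G)) / (len(T) + len(G))
    return float(d_tg - (_closest_within(graph, T) + _closest_within(graph, G)) / 2)


PROXIMITY_METHODS = {
    "closest": proximity_closest,
    "shortest": proximity_shortest,
    "kernel": proximity_kernel,
    "centre": proximity_centre,
    "separation": proximity_separation,
}


def proximity_auroc(
    profiles: Sequence[CompoundProfile],
    disease_gene_sets: Mapping[str, set[str]],
    labels,
    graph: nx.Graph,
    method: str = "closest",
    r: float = DEFAULT_RESTART,
) -> dict[str, float]:
    """Per-disease AUROC of one scoring method against binary labels.

    Distance-based methods score by the negated distance (smaller distance =
    stronger prediction); ``method="rwr"`` scores by the propagated disease
    score.  ``labels`` is a LabelMatrix whose rows align with ``profiles``.
    """
    from .evaluation import auroc

    if method == "rwr":
        index = node_index(graph)
        W = normalize_adjacency(graph)
        vectors = []
        for profile in profiles:
            p0, _ = build_seed_vector(profile, index)
            p, _ = rwr(PropagationProblem(W=W, p0=p0, r=r))
            vectors.append(p)
    elif method not in PROXIMITY_METHODS:
        raise ValueError(f"unknown method {method!r}")

    out = {}
    for disease in labels.disease_ids:
        genes = disease_gene_sets[disease]
        scores = np.zeros(len(profiles))
        for i, profile in enumerate(profiles):
            if method == "rwr":
                scores[i] = disease_score(vectors[i], genes, node_index(graph))
            else:
                scores[i] = -PROXIMITY_METHODS[method](profile.targets, genes, graph)
        out[disease] = auroc(scores, labels.column(disease))
    return out
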