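"""Gene homology groups via pairwise global alignment and Markov clustering.

This replaces the BLAST → MCL stage of a conventional pangenome workflow at
desk scale: all-vs-all exact global alignment identity builds a similarity
graph, and a dense Markov Cluster (MCL) iteration partitions it into homology
groups.  Everything is deterministic: node order is lexicographic gene id and
every tie-break is specified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RES_INDEX = {c: i for i, c in enumerate(CANONICAL_RESIDUES)}


@dataclass
class MCLParams:
    """Markov clustering parameters.

    ``inflation`` is the granularity knob (larger → finer clusters); the
    default of 8 matches the aggressive setting used for splitting protein
    families in pangenome work.
    """

    inflation: float = 8.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-6
    max_iterations: int = 200

    def __post_init__(self):
        if self.inflation <= 1:
            raise InputError("inflation must be > 1")
        if self.expansion < 2:
            raise InputError("expansion power must be ≥ 2")
        if self.prune_threshold <= 0 or self.convergence_tol <= 0:
            raise InputError("thresholds must be positive")


@dataclass
class SimilarityGraph:
    """Undirected gene-similarity graph with weights in (0, 1]."""

    graph: nx.Graph
    min_similarity: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def _encode(seq: str, name: str) -> np.ndarray:
    try:
        return np.array([_RES_INDEX[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise InputError(f"{name}: non-canonical residue {exc.args[0]!r}")


@njit(cache=True)
def _nw_identity(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover
    """Global alignment identity, match +1 / mismatch -1 / gap -1.

    Propagates (identical matches, alignment length) along the optimal path;
    score ties are broken diagonal > up > left, which pins down a unique
    alignment, so the returned identity is well defined.
    """
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    ident = np.empty((n + 1, m + 1), dtype=np.int64)
    alen = np.empty((n + 1, m + 1), dtype=np.int64)
    for j in range(m + 1):
        score[0, j] = -j
        ident[0, j] = 0
        alen[0, j] = j
    for i in range(1, n + 1):
        score[i, 0] = -i
        ident[i, 0] = 0
        alen[i, 0] = i
        for j in range(1, m + 1):
            match = 1 if a[i - 1] == b[j - 1] else -1
            d = score[i - 1, j - 1] + match
            u = score[i - 1, j] - 1
            l = score[i, j - 1] - 1
            if d >= u and d >= l:
                score[i, j] = d
                ident[i, j] = ident[i - 1, j - 1] + (1 if match == 1 else 0)
                alen[i, j] = alen[i - 1, j - 1] + 1
            elif u >= l:
                score[i, j] = u
                ident[i, j] = ident[i - 1, j]
                alen[i, j] = alen[i - 1, j] + 1
            else:
                score[i, j] = l
                ident[i, j] = ident[i, j - 1]
                alen[i, j] = alen[i, j - 1] + 1
    return ident[n, m] / alen[n, m]


def global_identity(a: str, b: str) -> float:
    """Fraction of identical positions in the optimal global alignment.

    Needleman–Wunsch with match +1, mismatch −1, linear gap −1; identity is
    (identical aligned positions) / (alignment length).  Stands in for BLAST
    percent identity at desk scale.
    """
    if not a or not b:
        raise InputError("sequences must be non-empty")
    return float(_nw_identity(_encode(a, "a"), _encode(b, "b")))


def global_align(a: str, b: str) -> tuple[str, str, int]:
    """Global alignment returning the aligned strings and the score.

    Same scoring and tie-breaking as :func:`global_identity` (match +1,
    mismatch −1, gap −1; ties diagonal > up > left).  Pure Python; used where
    the aligned strings themselves are needed (homogeneity of unequal-length
    groups), not in the all-vs-all stage.
    """
    if not a or not b:
        raise InputError("sequences must be non-empty")
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 0=diag 1=up 2=left
    for j in range(1, m + 1):
        score[0][j] = -j
        move[0][j] = 2
    for i in range(1, n + 1):
        score[i][0] = -i
        move[i][0] = 1
        row, prow = score[i], score[i - 1]
        for j in range(1, m + 1):
            d = prow[j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
            u = prow[j] - 1
            l = row[j - 1] - 1
            if d >= u and d >= l:
                row[j], move[i][j] = d, 0
            elif u >= l:
                row[j], move[i][j] = u, 1
            else:
                row[j], move[i][j] = l, 2
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif mv == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_similarity_graph(
    proteins: dict[str, str],
    min_similarity: float = 0.35,
    prescreen_kmer: int | None = 4,
) -> SimilarityGraph:
    """All-vs-all similarity graph: edge (i, j) iff identity ≥ threshold.

    ``prescreen_kmer`` enables a BLAST-like seeding heuristic: pairs sharing
    no exact k-mer are skipped without alignment.  Unrelated random proteins
    essentially never share a 4-mer while diverged homologues essentially
    always do; pass ``None`` to force alignment of every pair.
    """
    if not proteins:
        raise InputError("need at least one protein")
    ids = sorted(proteins)
    encoded = {gid: _encode(proteins[gid], gid) for gid in ids}
    kmers = (
        {gid: _kmer_set(proteins[gid], prescreen_kmer) for gid in ids}
        if prescreen_kmer
        else None
    )
    g = nx.Graph()
    g.add_nodes_from(ids)
    for ii, gi in enumerate(ids):
        for gj in ids[ii + 1 :]:
            if kmers is not None and not (kmers[gi] & kmers[gj]):
                continue
            identity = float(_nw_identity(encoded[gi], encoded[gj]))
            if identity >= min_similarity and identity > 0:
                g.add_edge(gi, gj, weight=identity)
    return SimilarityGraph(graph=g, min_similarity=min_similarity)


def read_similarity_tsv(path, min_similarity: float = 0.35) -> SimilarityGraph:
    """Import precomputed pairwise identities (gene_a, gene_b, identity)."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_a", "gene_b", "identity"]:
            raise ParseError(f"bad header {header!r}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 3:
                raise ParseError(f"expected 3 columns, got {len(f)}", path, lineno)
            w = float(f[2])
            if not 0 < w <= 1:
                raise ParseError(f"identity {w} outside (0, 1]", path, lineno)
            g.add_node(f[0])
            g.add_node(f[1])
            if f[0] != f[1] and w >= min_similarity:
                g.add_edge(f[0], f[1], weight=w)
    return SimilarityGraph(graph=g, min_similarity=min_similarity)


class MCLConvergenceWarning(UserWarning):
    """Raised as a warning when MCL hits max_iterations without converging."""


def _mcl_component(
    nodes: list[str], graph: nx.Graph, params: MCLParams
) -> tuple[list[list[str]], bool]:
    """Run dense MCL on one connected component; returns (clusters, converged)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((n, n))
    for u, v, d in graph.edges(nodes, data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = d["weight"]
    # self-loop regularisation: loop weight = max incident weight (1 if isolated)
    loops = w.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(w, loops)
    m = w / w.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(params.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = m ** params.inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < params.prune_threshold] = 0.0
        m /= m.sum(axis=0, keepdims=True)
        if np.abs(m - prev).max() < params.convergence_tol:
            converged = True
            break
    # attractors: rows with mass on the diagonal; every column joins the
    # attractor holding most of its mass (ties → lowest attractor index)
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:  # degenerate; treat max row per column as attractor
        attractors = sorted(set(int(np.argmax(m[:, j])) for j in range(n)))
    att = np.array(attractors)
    owner = {}
    for j in range(n):
        col = m[att, j]
        owner[j] = int(att[int(np.argmax(col))])  # argmax takes first on ties
    # merge attractor systems: if attractor a is owned by attractor b, they
    # belong to one cluster
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in attractors:
        b = owner[a]
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[int, list[str]] = {}
    for j in range(n):
        root = find(owner[j])
        clusters.setdefault(root, []).append(nodes[j])
    return [sorted(c) for c in clusters.values()], converged


def mcl_cluster(
    sim: SimilarityGraph, params: MCLParams | None = None
) -> list[list[str]]:
    """Partition the similarity graph into homology groups via MCL.

    Connected components are clustered independently (disconnected nodes can
    never merge under expansion).  Returns clusters as sorted member lists,
    ordered by first member; every node appears in exactly one cluster.
    """
    params = params or MCLParams()
    g = sim.graph
    if g.number_of_nodes() == 0:
        raise InputError("empty graph")
    clusters: list[list[str]] = []
    any_unconverged = False
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(nodes)
            continue
        cl, ok = _mcl_component(nodes, g, params)
        if not ok:
            any_unconverged = True
        clusters.extend(cl)
    if any_unconverged:
        warnings.warn(
            "MCL hit max_iterations without converging; returning current "
            "partition",
            MCLConvergenceWarning,
        )
    return sorted(clusters, key=lambda c: c[0])
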