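"""Pangenome partitioning and genome trees.

Homology groups are binned into core (present in every genome), accessory
(some genomes) and singleton (exactly one genome) bins; single-copy core
groups (scg) are refined with functional/geometric homogeneity filters and
feed a Jukes–Cantor + UPGMA genome phylogeny.  A second genome tree comes
from gene presence/absence (Jaccard + UPGMA).

The homogeneity indices here are explicit reconstructions: functional
homogeneity measures how often aligned residue pairs share a chemical class,
geometric homogeneity how congruent the gap structures are.  Both live in
[0, 1] and are filtered with the conventional thresholds (max functional 0.9,
min geometric 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, InputError
from .homology import global_align

logger = logging.getLogger(__name__)

GAP = "-"

#: Chemical classes for functional homogeneity.
RESIDUE_CLASSES = {
    "hydrophobic": "AVLIMC",
    "aromatic": "FWY",
    "polar": "STNQ",
    "positive": "KRH",
    "negative": "DE",
    "special": "GP",
}
_CLASS_OF = {res: name for name, members in RESIDUE_CLASSES.items() for res in members}


@dataclass
class HomologyGroup:
    """A cluster of protein-coding genes across genomes (the pangenome unit)."""

    group_id: str
    members: dict[str, list[str]]  # genome_id -> gene ids

    @property
    def n_genomes(self) -> int:
        return sum(1 for genes in self.members.values() if genes)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(g for genes in self.members.values() for g in genes)

    def max_genes_per_genome(self) -> int:
        return max(len(genes) for genes in self.members.values() if genes)


@dataclass
class PangenomeBins:
    bin_of_group: dict[str, str]  # group_id -> core | accessory | singleton
    scg_ids: set[str] = field(default_factory=set)
    n_genomes_total: int = 0

    def counts(self) -> dict[str, int]:
        out = {"core": 0, "accessory": 0, "singleton": 0}
        for b in self.bin_of_group.values():
            out[b] += 1
        return out


@dataclass
class HomogeneityParams:
    max_functional: float = 0.9
    min_geometric: float = 1.0

    def __post_init__(self):
        if not (0 <= self.max_functional <= 1 and 0 <= self.min_geometric <= 1):
            raise InputError("homogeneity thresholds must lie in [0, 1]")


def groups_from_clusters(
    clusters: Iterable[Sequence[str]], genome_of_gene: Mapping[str, str]
) -> list[HomologyGroup]:
    """Turn MCL clusters of gene ids into HomologyGroups keyed by genome."""
    groups = []
    for i, cluster in enumerate(sorted(map(sorted, clusters), key=lambda c: c[0])):
        members: dict[str, list[str]] = {}
        for gid in cluster:
            if gid not in genome_of_gene:
                raise CrossReferenceError(f"gene {gid!r} has no genome assignment")
            members.setdefault(genome_of_gene[gid], []).append(gid)
        groups.append(HomologyGroup(group_id=f"HG{i + 1:05d}", members=members))
    return groups


def bin_homology_groups(
    groups: Iterable[HomologyGroup],
    n_genomes_total: int,
    known_genomes: set[str] | None = None,
) -> PangenomeBins:
    """Core iff present in all genomes; singleton iff in exactly one.

    With a single-genome collection every group is core (the singleton bin
    only makes sense against a backdrop of other genomes).
    """
    if n_genomes_total < 1:
        raise InputError("need at least one genome")
    bin_of: dict[str, str] = {}
    for g in groups:
        if known_genomes is not None:
            unknown = set(g.members) - known_genomes
            if unknown:
                raise CrossReferenceError(
                    f"group {g.group_id} references unknown genomes {sorted(unknown)}"
                )
        n = g.n_genomes
        if n == n_genomes_total:
            bin_of[g.group_id] = "core"
        elif n == 1 and n_genomes_total > 1:
            bin_of[g.group_id] = "singleton"
        else:
            bin_of[g.group_id] = "accessory"
    return PangenomeBins(bin_of_group=bin_of, n_genomes_total=n_genomes_total)


# ---------------------------------------------------------------------------
# homogeneity indices

def _check_alignment(aligned: Sequence[str]) -> int:
    if len(aligned) < 2:
        raise InputError("need at least two sequences")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise InputError("aligned sequences must have equal length")
    return length


def functional_homogeneity(aligned: Sequence[str]) -> float:
    """Fraction of same-column residue pairs sharing a chemical class.

    Columns contribute one term per unordered pair of sequences with both
    residues non-gap; columns with fewer than two residues are ignored.  An
    alignment where every column is ignored is perfectly homogeneous (1.0).
    """
    length = _check_alignment(aligned)
    same = total = 0
    for col in range(length):
        residues = [s[col] for s in aligned if s[col] != GAP]
        for a, b in combinations(residues, 2):
            total += 1
            if _CLASS_OF.get(a) == _CLASS_OF.get(b) and a in _CLASS_OF:
                same += 1
    return same / total if total else 1.0


def geometric_homogeneity(aligned: Sequence[str]) -> float:
    """1 − mean pairwise Hamming distance between gap masks, over length.

    An ungapped alignment scores 1; fully complementary gap patterns score 0.
    """
    length = _check_alignment(aligned)
    masks = [tuple(c == GAP for c in s) for s in aligned]
    pairs = list(combinations(masks, 2))
    mean_hamming = sum(
        sum(x != y for x, y in zip(ma, mb)) for ma, mb in pairs
    ) / len(pairs)
    return 1.0 - mean_hamming / length


def _group_alignment(group: HomologyGroup, proteins: Mapping[str, str]) -> list[str]:
    """Member sequences as a trivially aligned block.

    Equal-length members are used as-is (the default generator produces
    ungapped families).  Unequal-length pairs are globally aligned; for
    groups of more than two unequal sequences the longest member anchors a
    star alignment — deliberate avoidance of full MSA.
    """
    seqs = [proteins[g] for g in group.gene_ids]
    if len({len(s) for s in seqs}) == 1:
        return seqs
    if len(seqs) == 2:
        a, b, _ = global_align(seqs[0], seqs[1])
        return [a, b]
    anchor = max(seqs, key=len)
    aligned = []
    for s in seqs:
        if s is anchor:
            aligned.append(anchor)
        else:
            _, bb, _ = global_align(anchor, s)
            aligned.append(bb[: len(anchor)].ljust(len(anchor), GAP))
    return aligned


def select_scg(
    groups: Iterable[HomologyGroup],
    bins: PangenomeBins,
    proteins: Mapping[str, str],
    params: HomogeneityParams | None = None,
) -> set[str]:
    """Refined single-copy core groups.

    A group qualifies iff it is core, has exactly one gene in every genome,
    functional homogeneity ≤ max_functional (too-uniform groups carry no
    phylogenetic signal) and geometric homogeneity ≥ min_geometric.
    """
    params = params or HomogeneityParams()
    scg: set[str] = set()
    for g in groups:
        if bins.bin_of_group.get(g.group_id) != "core":
            continue
        if g.max_genes_per_genome() != 1:
            continue
        aligned = _group_alignment(g, proteins)
        if functional_homogeneity(aligned) > params.max_functional:
            continue
        if geometric_homogeneity(aligned) < params.min_geometric:
            continue
        scg.add(g.group_id)
    bins.scg_ids = scg
    return scg


# ---------------------------------------------------------------------------
# distances and trees

def jukes_cantor_distance(p: float, mode: str = "protein") -> float:
    """Jukes–Cantor evolutionary distance from an observed difference fraction.

    Corrects the raw difference fraction ``p`` for multiple substitutions:
    nucleotide mode d = −(3/4)·ln(1 − 4p/3) (saturates at p = 3/4), protein
    (20-state) mode d = −(19/20)·ln(1 − 20p/19) (saturates at p = 19/20).
    """
    if mode == "nucleotide":
        states = 4
    elif mode == "protein":
        states = 20
    else:
        raise InputError(f"unknown mode {mode!r}")
    sat = (states - 1) / states
    if not 0 <= p < sat:
        raise InputError(f"p={p} outside [0, {sat}) for {mode} mode (saturation)")
    return -sat * math.log(1.0 - p / sat)


@dataclass
class TreeNode:
    """Rooted ultrametric tree node; leaves carry labels, internals a height."""

    label: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves()]

    def newick(self) -> str:
        return self._newick_part(parent_height=None) + ";"

    def _newick_part(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.label
        else:
            body = "(" + ",".join(
                c._newick_part(self.height) for c in self.children
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:g}"

    def cophenetic(self) -> pd.DataFrame:
        """Matrix of path distances (2 × merge height) between all leaves."""
        labels = sorted(self.leaves())
        idx = {l: i for i, l in enumerate(labels)}
        d = np.zeros((len(labels), len(labels)))

        def visit(node: TreeNode):
            if node.is_leaf:
                return
            for c in node.children:
                visit(c)
            for ca, cb in combinations(node.children, 2):
                for la in ca.leaves():
                    for lb in cb.leaves():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = 2 * node.height

        visit(self)
        return pd.DataFrame(d, index=labels, columns=labels)


def upgma(dist: pd.DataFrame) -> TreeNode:
    """UPGMA: agglomerate the closest pair, size-weighted average update.

    Node heights are half the merge distance, so leaves sit at height 0 and
    the tree is ultrametric.  Ties in the minimum distance are broken by the
    lexicographically smallest (min label, max label) pair, making the output
    deterministic.
    """
    labels = list(dist.index)
    if list(dist.columns) != labels:
        raise InputError("distance matrix must have matching index and columns")
    mat = dist.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise InputError("distance matrix must be square")
    if np.abs(mat - mat.T).max() > 1e-9:
        raise InputError("distance matrix must be symmetric (tolerance 1e-9)")
    if (mat < 0).any():
        raise InputError("distances must be non-negative")
    clusters: dict[str, TreeNode] = {
        l: TreeNode(label=l) for l in labels
    }
    sizes = {l: 1 for l in labels}
    # working distances keyed by frozenset of cluster keys (cluster key = its
    # lexicographically smallest leaf)
    d: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d[frozenset((a, b))] = mat[labels.index(a), labels.index(b)]
    while len(clusters) > 1:
        best = min(
            (
                (d[frozenset((a, b))], (min(a, b), max(a, b)))
                for i, a in enumerate(sorted(clusters))
                for b in sorted(clusters)[i + 1 :]
            ),
            key=lambda t: (t[0], t[1]),
        )
        dist_ab, (a, b) = best
        node = TreeNode(
            height=dist_ab / 2.0, children=[clusters[a], clusters[b]]
        )
        na, nb = sizes[a], sizes[b]
        del clusters[a], clusters[b]
        new_key = min(a, b)
        for other in clusters:
            da = d.pop(frozenset((a, other)))
            db = d.pop(frozenset((b, other)))
            d[frozenset((new_key, other))] = (na * da + nb * db) / (na + nb)
        d.pop(frozenset((a, b)), None)
        clusters[new_key] = node
        sizes[new_key] = na + nb
    return next(iter(clusters.values()))


def scg_distance_matrix(
    groups: Iterable[HomologyGroup],
    scg_ids: set[str],
    proteins: Mapping[str, str],
    mode: str = "protein",
) -> pd.DataFrame:
    """Genome × genome Jukes–Cantor distances averaged over scg groups.

    For each scg group the single member per genome is compared pairwise
    (Hamming fraction for equal lengths, otherwise 1 − global identity); the
    per-group p-distances are averaged and Jukes–Cantor corrected.
    """
    scg_groups = [g for g in groups if g.group_id in scg_ids]
    if not scg_groups:
        raise InputError("no scg groups to build distances from")
    genomes = sorted(scg_groups[0].members)
    pmat = np.zeros((len(genomes), len(genomes)))
    for g in scg_groups:
        seqs = {gen: proteins[g.members[gen][0]] for gen in genomes}
        for i, ga in enumerate(genomes):
            for j in range(i + 1, len(genomes)):
                a, b = seqs[ga], seqs[genomes[j]]
                if len(a) == len(b):
                    p = sum(x != y for x, y in zip(a, b)) / len(a)
                else:
                    from .homology import global_identity

                    p = 1.0 - global_identity(a, b)
                pmat[i, j] += p
                pmat[j, i] += p
    pmat /= len(scg_groups)
    sat = 0.75 if mode == "nucleotide" else 0.95
    dmat = np.zeros_like(pmat)
    for i in range(len(genomes)):
        for j in range(len(genomes)):
            if i != j:
                p = min(pmat[i, j], sat - 1e-9)  # clamp just below saturation
                dmat[i, j] = jukes_cantor_distance(p, mode)
    return pd.DataFrame(dmat, index=genomes, columns=genomes)


def presence_absence_matrix(
    groups: Iterable[HomologyGroup], genomes: Sequence[str]
) -> pd.DataFrame:
    """Binary groups × genomes matrix (1 = genome carries the group)."""
    groups = list(groups)
    data = np.zeros((len(groups), len(genomes)), dtype=int)
    for i, g in enumerate(groups):
        for j, gen in enumerate(genomes):
            if g.members.get(gen):
                data[i, j] = 1
    return pd.DataFrame(
        data, index=[g.group_id for g in groups], columns=list(genomes)
    )


def presence_absence_dendrogram(matrix: pd.DataFrame) -> TreeNode:
    """Genome tree from the 0/1 matrix: Jaccard distance between genome
    columns, then UPGMA.  An all-zero genome sits at distance 1 from
    everything (logged)."""
    genomes = list(matrix.columns)
    cols = {g: set(matrix.index[matrix[g] == 1]) for g in genomes}
    empty = [g for g in genomes if not cols[g]]
    if empty:
        logger.warning("genomes with no groups (distance 1 to all): %s", empty)
    n = len(genomes)
    d = np.zeros((n, n))
    for i, a in enumerate(genomes):
        for j in range(i + 1, n):
            sa, sb = cols[a], cols[genomes[j]]
            if not sa or not sb:
                dist = 1.0
            else:
                union = sa | sb
                dist = len(sa ^ sb) / len(union)
            d[i, j] = d[j, i] = dist
    if n == 1:
        return TreeNode(label=genomes[0])
    return upgma(pd.DataFrame(d, index=genomes, columns=genomes))


def write_bins_tsv(groups: Iterable[HomologyGroup], bins: PangenomeBins, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tn_genomes\tbin\tis_scg\n")
        for g in sorted(groups, key=lambda g: g.group_id):
            fh.write(
                f"{g.group_id}\t{g.n_genomes}\t{bins.bin_of_group[g.group_id]}"
                f"\t{str(g.group_id in bins.scg_ids).lower()}\n"
            )
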