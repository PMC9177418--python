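"""BGC similarity network, GCF components and known/unknown classification.

Each BGC is reduced to an ordered profile of domain families (here: the
homology groups of its member genes; reference clusters supply their own
profiles).  Pairwise distance is a weighted composite of three [0, 1]
similarities — Jaccard of family sets, adjacency index (Jaccard over
unordered adjacent-family bigrams) and domain sequence similarity (mean
representative identity over shared families, damped by the shared-family
fraction).  Cutting the network at a distance cutoff yields gene cluster
families (GCFs); components that contain a reference cluster classify their
members as known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import InputError
from .homology import global_identity
from .io import BGCRegion, GenomeMetadata, ReferenceCluster

logger = logging.getLogger(__name__)


def _frange_cutoffs() -> list[float]:
    return [round(0.30 + 0.05 * i, 2) for i in range(14)]  # 0.30 … 0.95


@dataclass
class NetworkParams:
    """Composite-distance weights and network cutoffs.

    Weights follow the mixed-mode convention of BGC similarity networking
    (Jaccard 0.2, adjacency 0.05, sequence similarity 0.75) and must sum
    to 1.  The default cutoff of 0.65 is where GCFs are read off; the sweep
    0.30–0.95 in steps of 0.05 maps how the partition coarsens.
    """

    w_jaccard: float = 0.2
    w_adjacency: float = 0.05
    w_dss: float = 0.75
    cutoff: float = 0.65
    cutoff_sweep: list[float] = field(default_factory=_frange_cutoffs)

    def __post_init__(self):
        if min(self.w_jaccard, self.w_adjacency, self.w_dss) < 0:
            raise InputError("weights must be non-negative")
        if abs(self.w_jaccard + self.w_adjacency + self.w_dss - 1.0) > 1e-9:
            raise InputError("weights must sum to 1")
        for c in [self.cutoff, *self.cutoff_sweep]:
            if not 0 < c < 1:
                raise InputError(f"cutoff {c} outside (0, 1)")


@dataclass
class DomainProfile:
    """Ordered domain-family profile of one BGC (or reference cluster)."""

    bgc_id: str
    families: tuple[str, ...]
    representatives: Mapping[str, str] = field(default_factory=dict)
    is_reference: bool = False
    product_class: str = "others"

    def __post_init__(self):
        if not self.families:
            raise InputError(f"profile {self.bgc_id} has no families")


@dataclass
class GCFComponent:
    """A connected component of the BGC network at a cutoff."""

    gcf_id: str
    members: tuple[str, ...]  # non-reference BGC ids
    reference_members: tuple[str, ...] = ()
    class_composition: dict[str, int] = field(default_factory=dict)

    @property
    def contains_reference(self) -> bool:
        return bool(self.reference_members)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1 and not self.reference_members


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def _bigrams(families: Sequence[str]) -> set[frozenset]:
    return {
        frozenset((x, y))
        for x, y in zip(families, families[1:])
        if x != y
    } | {frozenset((x,)) for x, y in zip(families, families[1:]) if x == y}


def bgc_distance(a: DomainProfile, b: DomainProfile, params: NetworkParams) -> float:
    """Composite distance d = 1 − (w_J·J + w_AI·AI + w_DSS·DSS), in [0, 1].

    J: Jaccard of family sets.  AI: Jaccard of unordered adjacent-family
    pairs along each profile (1 when both profiles have no adjacencies).
    DSS: mean representative-sequence identity over shared families,
    weighted by shared/total distinct families; families lacking a
    representative on either side count identity 1 (same family already
    implies homology).  Identical profiles → 0; fully disjoint → 1.
    """
    sa, sb = set(a.families), set(b.families)
    j = _jaccard(sa, sb)
    ai = _jaccard(_bigrams(a.families), _bigrams(b.families))
    shared = sa & sb
    if shared:
        idents = []
        for fam in sorted(shared):
            ra, rb = a.representatives.get(fam), b.representatives.get(fam)
            if ra is None or rb is None:
                idents.append(1.0)
            elif ra == rb:
                idents.append(1.0)
            else:
                idents.append(global_identity(ra, rb))
        dss = (sum(idents) / len(idents)) * (len(shared) / len(sa | sb))
    else:
        dss = 0.0
    sim = params.w_jaccard * j + params.w_adjacency * ai + params.w_dss * dss
    return min(1.0, max(0.0, 1.0 - sim))


def profiles_from_regions(
    regions: Iterable[BGCRegion],
    group_of_gene: Mapping[str, str],
    group_representatives: Mapping[str, str] | None = None,
) -> list[DomainProfile]:
    """Build per-BGC profiles from the homology groups of member genes.

    Member gene order (positional, as stored on the trimmed region) gives
    the ordered family list; consecutive duplicates collapse to one entry.
    Regions whose members carry no homology group are skipped with a log.
    """
    reps = group_representatives or {}
    out = []
    for r in regions:
        fams: list[str] = []
        for gid in r.member_gene_ids:
            grp = group_of_gene.get(gid)
            if grp is not None and (not fams or fams[-1] != grp):
                fams.append(grp)
        if not fams:
            logger.warning("region %s has no grouped genes; skipped", r.region_id)
            continue
        out.append(
            DomainProfile(
                bgc_id=r.region_id,
                families=tuple(fams),
                representatives={f: reps[f] for f in fams if f in reps},
                is_reference=False,
                product_class=r.product_class,
            )
        )
    return out


def map_reference_profiles(
    refs: Iterable[ReferenceCluster],
    group_representatives: Mapping[str, str],
    min_identity: float = 0.35,
) -> list[DomainProfile]:
    """Translate reference profiles into the collection's family namespace.

    Each reference family is mapped onto the homology group whose
    representative sequence is most similar (global identity, threshold
    ``min_identity``; ties → lexicographically smallest group id).  Families
    matching no group keep a private ``ref_id:family`` id and can never
    contribute shared-family similarity — exactly the behaviour wanted for a
    reference with no counterpart in the collection.
    """
    groups = sorted(group_representatives)
    out = []
    for ref in refs:
        fams: list[str] = []
        reps: dict[str, str] = {}
        for fam in ref.families:
            seq = ref.representatives.get(fam)
            best_id, best = None, min_identity
            if seq:
                for grp in groups:
                    ident = global_identity(seq, group_representatives[grp])
                    if ident > best or (ident == best and best_id is None):
                        best_id, best = grp, ident
            mapped = best_id if best_id is not None else f"{ref.ref_id}:{fam}"
            if not fams or fams[-1] != mapped:
                fams.append(mapped)
            if seq:
                reps[mapped] = seq
        out.append(
            DomainProfile(
                bgc_id=ref.ref_id,
                families=tuple(fams),
                representatives=reps,
                is_reference=True,
                product_class=ref.product_class,
            )
        )
    return out


def build_gcf_network(
    profiles: Sequence[DomainProfile],
    params: NetworkParams | None = None,
    cutoff: float | None = None,
) -> tuple[list[tuple[str, str, float]], list[GCFComponent]]:
    """All-vs-all distances, edges at ``distance ≤ cutoff``, components.

    Returns (edges, components).  Components consisting solely of reference
    clusters are discarded from the GCF list; the rest get deterministic ids
    from their sorted member lists.
    """
    params = params or NetworkParams()
    if cutoff is None:
        cutoff = params.cutoff
    if not profiles:
        raise InputError("need at least one profile")
    ids = [p.bgc_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate profile ids")
    g = nx.Graph()
    g.add_nodes_from(ids)
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(profiles):
        for b in profiles[i + 1 :]:
            d = bgc_distance(a, b, params)
            if d <= cutoff:
                g.add_edge(a.bgc_id, b.bgc_id, weight=d)
                edges.append((a.bgc_id, b.bgc_id, d))
    by_id = {p.bgc_id: p for p in profiles}
    comps = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(m for m in comp if not by_id[m].is_reference))
        refs = tuple(sorted(m for m in comp if by_id[m].is_reference))
        if not members:
            continue
        classes: dict[str, int] = {}
        for m in members:
            classes[by_id[m].product_class] = classes.get(by_id[m].product_class, 0) + 1
        comps.append((members, refs, classes))
    comps.sort(key=lambda c: c[0])
    return edges, [
        GCFComponent(
            gcf_id=f"GCF{i + 1:04d}",
            members=members,
            reference_members=refs,
            class_composition=classes,
        )
        for i, (members, refs, classes) in enumerate(comps)
    ]


def sweep_cutoffs(
    profiles: Sequence[DomainProfile], params: NetworkParams | None = None
) -> dict[float, int]:
    """GCF count at each cutoff of the sweep (coarsens as cutoff rises)."""
    params = params or NetworkParams()
    return {
        c: len(build_gcf_network(profiles, params, cutoff=c)[1])
        for c in params.cutoff_sweep
    }


def classify_bgcs(
    components: Iterable[GCFComponent],
    contig_edge: Mapping[str, bool],
    curated_known: set[str] | None = None,
) -> dict[str, str]:
    """Label every BGC as fragmented, known or unknown.

    Precedence: fragmented (contig-edge truncation — the cluster is
    incompletely observed) > known (shares a component with a reference, or
    curated as experimentally identified) > unknown.
    """
    curated = curated_known or set()
    labels: dict[str, str] = {}
    for comp in components:
        for m in comp.members:
            if contig_edge.get(m, False):
                labels[m] = "fragmented"
            elif comp.contains_reference or m in curated:
                labels[m] = "known"
            else:
                labels[m] = "unknown"
    return labels


def _pct(part: int, whole: int) -> int:
    return (100 * part) // whole if whole else 0


def summarize_collection(
    regions: Sequence[BGCRegion],
    classifications: Mapping[str, str],
    components: Sequence[GCFComponent],
    metadata: Sequence[GenomeMetadata],
) -> dict:
    """Dataset-level summary with truncated integer percentages/averages.

    Reports total and per-genome BGC counts, the truncated per-genome
    average, per-class counts with truncated percentages and per-genome
    averages, the known/unknown/fragmented split, and GCF statistics: total
    GCFs, isolated clades (components of ≥2 members with no reference
    connection) and singletons.
    """
    n_genomes = len(metadata)
    per_genome: dict[str, int] = {m.genome_id: 0 for m in metadata}
    per_class: dict[str, int] = {}
    for r in regions:
        per_genome[r.genome_id] = per_genome.get(r.genome_id, 0) + 1
        per_class[r.product_class] = per_class.get(r.product_class, 0) + 1
    total = len(regions)
    by_label = {"known": 0, "unknown": 0, "fragmented": 0}
    for r in regions:
        label = classifications.get(r.region_id)
        if label in by_label:
            by_label[label] += 1
    n_isolated = sum(
        1 for c in components if len(c.members) >= 2 and not c.contains_reference
    )
    n_single = sum(1 for c in components if c.is_singleton)
    n_unconnected = n_isolated + n_single  # GCFs with no reference connection
    return {
        "n_genomes": n_genomes,
        "n_bgcs": total,
        "bgcs_per_genome": dict(sorted(per_genome.items())),
        "avg_bgcs_per_genome": total // n_genomes if n_genomes else 0,
        "class_counts": dict(sorted(per_class.items())),
        "class_pct": {c: _pct(n, total) for c, n in sorted(per_class.items())},
        "class_avg_per_genome": {
            c: n // n_genomes if n_genomes else 0
            for c, n in sorted(per_class.items())
        },
        "label_counts": by_label,
        "label_pct": {k: _pct(v, total) for k, v in by_label.items()},
        "n_gcfs": len(components),
        "n_isolated_clades": n_isolated,
        "n_singletons": n_single,
        "n_gcfs_without_reference": n_unconnected,
        "n_gcfs_with_reference": len(components) - n_unconnected,
    }
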