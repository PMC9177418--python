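"""Integration of BGC annotations with the pangenome.

This is the analytical heart of the pipeline: BGC boundaries are trimmed to
the span of their biosynthetic genes (peripheral transporters/regulators
excluded), genes are linked to BGCs by interval containment, biosynthetic
genes are distributed over pangenome bins, conserved consecutive
biosynthetic-gene runs are detected across genomes, and per-genus GCF
prevalence is reported as truncated integer percentages (28/29 → 96).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CrossReferenceError, InputError
from .io import BGCRegion, GeneCall, GenomeMetadata, PRODUCT_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class BGAnnotation:
    """A gene inside a (trimmed) BGC boundary: a biosynthetic gene (BG)."""

    gene_id: str
    genome_id: str
    region_id: str
    product_class: str
    homology_group_id: str | None = None
    pangenome_bin: str | None = None


@dataclass
class ConservedRun:
    """A maximal run of consecutive biosynthetic genes in one genome, linked
    to homologous runs elsewhere via its homology-group signature."""

    run_id: str
    genome_id: str
    gene_ids: tuple[str, ...]
    group_signature: tuple[str, ...]
    bin: str
    product_class: str
    cluster_id: str | None = None
    homologous_runs: tuple[str, ...] = ()


@dataclass(frozen=True)
class PrevalenceRecord:
    gcf_id: str
    genus: str
    n_carriers: int
    n_genomes: int

    @property
    def prevalence_pct(self) -> int:
        return (100 * self.n_carriers) // self.n_genomes


def apply_exclusions(
    regions: Iterable[BGCRegion], metadata: Iterable[GenomeMetadata]
) -> tuple[list[BGCRegion], list[str]]:
    """Drop regions flagged in the metadata exclusion lists (e.g. known
    false-positive annotations); returns (kept, excluded ids)."""
    excluded = {
        rid for m in metadata for rid in m.excluded_regions
    }
    kept, dropped = [], []
    for r in regions:
        if r.region_id in excluded:
            dropped.append(r.region_id)
        else:
            kept.append(r)
    if dropped:
        logger.info("excluded %d regions: %s", len(dropped), sorted(dropped))
    return kept, sorted(dropped)


def trim_bgc_boundary(
    region: BGCRegion, genes: Sequence[GeneCall]
) -> BGCRegion | None:
    """Trim a raw region to [first biosynthetic gene start, last stop].

    ``genes`` are the gene calls on the region's contig.  Non-structural
    genes on the periphery fall outside the trimmed interval and are thereby
    excluded; member_gene_ids becomes every gene fully inside the new
    interval (any role), in positional order.  A region with no biosynthetic
    gene is untrimmable and dropped (returns None, reason logged).
    """
    inside = [
        g
        for g in genes
        if g.contig_id == region.contig_id
        and g.genome_id == region.genome_id
        and region.start <= g.start
        and g.stop <= region.stop
    ]
    bio = [g for g in inside if g.role == "biosynthetic"]
    if not bio:
        logger.warning(
            "region %s untrimmable: no biosynthetic gene inside raw interval",
            region.region_id,
        )
        return None
    new_start = min(g.start for g in bio)
    new_stop = max(g.stop for g in bio)
    members = sorted(
        (g for g in inside if new_start <= g.start and g.stop <= new_stop),
        key=lambda g: g.start,
    )
    return region.with_interval(new_start, new_stop, [g.gene_id for g in members])


def trim_regions(
    regions: Iterable[BGCRegion], gene_calls: Sequence[GeneCall]
) -> tuple[list[BGCRegion], list[str]]:
    """Trim every region; returns (trimmed regions, untrimmable region ids)."""
    by_contig: dict[tuple[str, str], list[GeneCall]] = {}
    for g in gene_calls:
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    trimmed, dropped = [], []
    for r in regions:
        t = trim_bgc_boundary(r, by_contig.get((r.genome_id, r.contig_id), []))
        if t is None:
            dropped.append(r.region_id)
        else:
            trimmed.append(t)
    return trimmed, dropped


def assign_genes_to_bgcs(
    gene_calls: Sequence[GeneCall], regions: Sequence[BGCRegion]
) -> list[BGAnnotation]:
    """Annotate genes that fall within a trimmed BGC boundary.

    A gene is annotated iff its interval is fully contained in a region on
    the same genome and contig; it inherits the region's product class.
    Regions overlapping on one contig are an input error.
    """
    by_contig: dict[tuple[str, str], list[BGCRegion]] = {}
    for r in regions:
        by_contig.setdefault((r.genome_id, r.contig_id), []).append(r)
    for key, rs in by_contig.items():
        rs.sort(key=lambda r: (r.start, r.stop))
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.stop:
                raise InputError(
                    f"regions {a.region_id} and {b.region_id} overlap on "
                    f"{key[0]}/{key[1]}"
                )
    out: list[BGAnnotation] = []
    for g in sorted(gene_calls, key=lambda g: (g.genome_id, g.contig_id, g.start)):
        for r in by_contig.get((g.genome_id, g.contig_id), []):
            if r.start <= g.start and g.stop <= r.stop:
                out.append(
                    BGAnnotation(
                        gene_id=g.gene_id,
                        genome_id=g.genome_id,
                        region_id=r.region_id,
                        product_class=r.product_class,
                    )
                )
                break  # containment in ≤1 region (regions don't overlap)
    return out


def annotate_with_groups(
    annotations: Iterable[BGAnnotation],
    group_of_gene: Mapping[str, str],
    bin_of_group: Mapping[str, str],
) -> list[BGAnnotation]:
    """Attach homology group and pangenome bin to each BG annotation."""
    out = []
    for a in annotations:
        grp = group_of_gene.get(a.gene_id)
        if grp is None:
            raise CrossReferenceError(f"gene {a.gene_id} has no homology group")
        b = bin_of_group.get(grp)
        if b is None:
            raise CrossReferenceError(f"group {grp} has no pangenome bin")
        out.append(replace(a, homology_group_id=grp, pangenome_bin=b))
    return out


def bg_bin_distribution(annotations: Iterable[BGAnnotation]) -> pd.DataFrame:
    """Contingency counts of biosynthetic genes: pangenome bin × BGC class.

    Marginal totals equal the number of annotations (conservation).
    """
    rows = []
    for a in annotations:
        if a.pangenome_bin is None:
            raise CrossReferenceError(f"annotation {a.gene_id} lacks a bin")
        rows.append((a.pangenome_bin, a.product_class))
    table = pd.DataFrame(
        0,
        index=pd.Index(["core", "accessory", "singleton"], name="bin"),
        columns=pd.Index(list(PRODUCT_CLASSES), name="product_class"),
    )
    for b, c in rows:
        table.loc[b, c] += 1
    return table


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    dp = [0] * (len(b) + 1)
    for x in a:
        prev = 0
        for j, y in enumerate(b, start=1):
            cur = dp[j]
            dp[j] = prev + 1 if x == y else max(dp[j], dp[j - 1])
            prev = cur
    return dp[len(b)]


def detect_conserved_bg_runs(
    annotations: Iterable[BGAnnotation],
    gene_calls: Sequence[GeneCall],
    min_run: int = 3,
    max_gap: int = 1,
    min_genome_fraction: float = 1.0,
    target_bin: str = "core",
    linkage: str = "ordered",
) -> list[ConservedRun]:
    """Detect runs of consecutive biosynthetic genes conserved across genomes.

    Per genome, genes are taken in positional order per contig; a run is a
    maximal stretch of BG-annotated genes whose homology groups sit in
    ``target_bin``, tolerating up to ``max_gap`` intervening non-qualifying
    genes between members.  Runs of length ≥ min_run from different genomes
    are linked into one conserved cluster when their homology-group
    signatures share ≥ min_run groups — as an ordered common subsequence
    (forward or reversed, ``linkage='ordered'``, tolerant of local strand
    flips) or as plain set overlap (``linkage='set'``).  A cluster is
    reported when it spans ≥ min_genome_fraction of all genomes in the
    collection.
    """
    if min_run < 2:
        raise InputError("min_run must be ≥ 2")
    if max_gap < 0:
        raise InputError("max_gap must be ≥ 0")
    ann_by_gene = {a.gene_id: a for a in annotations}
    genomes = sorted({g.genome_id for g in gene_calls})

    runs: list[ConservedRun] = []
    for genome in genomes:
        contigs: dict[str, list[GeneCall]] = {}
        for g in gene_calls:
            if g.genome_id == genome:
                contigs.setdefault(g.contig_id, []).append(g)
        for contig in sorted(contigs):
            order = sorted(contigs[contig], key=lambda g: g.start)
            qual = [
                g.gene_id in ann_by_gene
                and ann_by_gene[g.gene_id].pangenome_bin == target_bin
                for g in order
            ]
            current: list[GeneCall] = []
            gap = 0

            def flush():
                if len(current) >= min_run:
                    sig = tuple(
                        ann_by_gene[g.gene_id].homology_group_id for g in current
                    )
                    classes = [
                        ann_by_gene[g.gene_id].product_class for g in current
                    ]
                    runs.append(
                        ConservedRun(
                            run_id=f"{genome}_run{len(runs) + 1}",
                            genome_id=genome,
                            gene_ids=tuple(g.gene_id for g in current),
                            group_signature=sig,
                            bin=target_bin,
                            product_class=max(set(classes), key=classes.count),
                        )
                    )
                current.clear()

            for g, q in zip(order, qual):
                if q:
                    current.append(g)
                    gap = 0
                elif current:
                    gap += 1
                    if gap > max_gap:
                        flush()
                        gap = 0
            flush()

    # cross-genome linkage by signature sharing (union-find)
    parent = list(range(len(runs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            a, b = runs[i].group_signature, runs[j].group_signature
            if linkage == "set":
                shared = len(set(a) & set(b))
            else:
                shared = max(_lcs_length(a, b), _lcs_length(a, b[::-1]))
            if shared >= min_run:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(len(runs)):
        clusters.setdefault(find(i), []).append(i)
    n_genomes = len(genomes)
    out: list[ConservedRun] = []
    cid = 0
    for root in sorted(clusters):
        members = clusters[root]
        span = {runs[i].genome_id for i in members}
        if len(span) < min_genome_fraction * n_genomes:
            continue
        cid += 1
        cluster_id = f"CR{cid:03d}"
        ids = [runs[i].run_id for i in members]
        for i in members:
            out.append(
                replace(
                    runs[i],
                    cluster_id=cluster_id,
                    homologous_runs=tuple(r for r in ids if r != runs[i].run_id),
                )
            )
    return out


def gcf_prevalence(
    gcf_membership: Mapping[str, set[str] | Sequence[str]],
    metadata: Sequence[GenomeMetadata],
) -> list[PrevalenceRecord]:
    """Per-(GCF, genus) prevalence with truncated integer percentages.

    prevalence_pct = floor(100 · carriers / genus size), matching how such
    fractions are conventionally printed (28/29 → 96%, 15/16 → 93%).
    """
    genus_of = {m.genome_id: m.genus for m in metadata}
    genomes_of_genus: dict[str, set[str]] = {}
    for m in metadata:
        genomes_of_genus.setdefault(m.genus, set()).add(m.genome_id)
    out: list[PrevalenceRecord] = []
    for gcf_id in sorted(gcf_membership):
        members = set(gcf_membership[gcf_id])
        unknown = members - set(genus_of)
        if unknown:
            raise CrossReferenceError(
                f"GCF {gcf_id} carries unknown genomes {sorted(unknown)}"
            )
        for genus in sorted(genomes_of_genus):
            pool = genomes_of_genus[genus]
            if not pool:
                continue
            out.append(
                PrevalenceRecord(
                    gcf_id=gcf_id,
                    genus=genus,
                    n_carriers=len(members & pool),
                    n_genomes=len(pool),
                )
            )
    return out


# ---------------------------------------------------------------------------
# writers

def write_annotations_tsv(annotations: Iterable[BGAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgenome_id\tregion_id\tproduct_class\tgroup_id\tbin\n")
        for a in annotations:
            fh.write(
                f"{a.gene_id}\t{a.genome_id}\t{a.region_id}\t{a.product_class}"
                f"\t{a.homology_group_id or ''}\t{a.pangenome_bin or ''}\n"
            )


def write_runs_tsv(runs: Iterable[ConservedRun], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trun_id\tgenome_id\tbin\tproduct_class\tgene_ids\n")
        for r in sorted(runs, key=lambda r: (r.cluster_id or "", r.run_id)):
            fh.write(
                f"{r.cluster_id or ''}\t{r.run_id}\t{r.genome_id}\t{r.bin}"
                f"\t{r.product_class}\t{','.join(r.gene_ids)}\n"
            )


def write_prevalence_tsv(records: Iterable[PrevalenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gcf_id\tgenus\tn_carriers\tn_genomes\tprevalence_pct\n")
        for r in records:
            fh.write(
                f"{r.gcf_id}\t{r.genus}\t{r.n_carriers}\t{r.n_genomes}"
                f"\t{r.prevalence_pct}\n"
            )


def read_prevalence_tsv(path) -> list[PrevalenceRecord]:
    from .errors import ParseError

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gcf_id", "genus", "n_carriers", "n_genomes", "prevalence_pct"]:
            raise ParseError(f"bad header {header!r}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 5:
                raise ParseError(f"expected 5 columns, got {len(f)}", path, lineno)
            rec = PrevalenceRecord(f[0], f[1], int(f[2]), int(f[3]))
            if rec.prevalence_pct != int(f[4]):
                raise ParseError(
                    f"stored percent {f[4]} inconsistent with "
                    f"{rec.n_carriers}/{rec.n_genomes}",
                    path,
                    lineno,
                )
            out.append(rec)
    return out
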