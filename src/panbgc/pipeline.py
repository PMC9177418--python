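"""End-to-end orchestration: simulate → cluster → pangenome → integrate →
network → report, with a provenance manifest.

Each stage is a pure function of its input files and the configuration, and
communicates with downstream stages only through files in the output
directory.  A fixed config (and seed, for the simulator) therefore
reproduces every output byte-identically, and any single stage can be re-run
from cached upstream outputs; the provenance manifest records a content
hash per output to make that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import integration, io as pio, network as net, pangenome as pg
from .errors import ConfigError, StageError
from .homology import MCLParams, build_similarity_graph, mcl_cluster, read_similarity_tsv
from .simulate import SimConfig, generate_pangenome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Either point the four required input paths at an existing dataset, or
    set ``simulate=True`` to generate one under ``outdir/dataset`` first.
    """

    outdir: str = "panbgc_out"
    simulate: bool = False
    gene_calls: str | None = None
    proteins: str | None = None
    bgc_regions: str | None = None
    metadata: str | None = None
    reference_clusters: str | None = None
    curated_known: str | None = None
    similarities: str | None = None  # optional precomputed pairwise identities
    exclude_regions: list[str] = field(default_factory=list)
    min_similarity: float = 0.35
    mcl: MCLParams = field(default_factory=MCLParams)
    homogeneity: pg.HomogeneityParams = field(default_factory=pg.HomogeneityParams)
    network: net.NetworkParams = field(default_factory=net.NetworkParams)
    min_run: int = 3
    max_gap: int = 1
    min_genome_fraction: float = 1.0
    run_bin: str = "core"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("mcl", MCLParams),
            ("homogeneity", pg.HomogeneityParams),
            ("network", net.NetworkParams),
            ("sim", SimConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return conv(self)

    def resolve_inputs(self) -> "PipelineConfig":
        """Point the input paths at the simulated dataset when simulating."""
        if not self.simulate:
            return self
        d = Path(self.outdir) / "dataset"
        return dataclasses.replace(
            self,
            gene_calls=str(d / "gene_calls.tsv"),
            proteins=str(d / "proteins.faa"),
            bgc_regions=str(d / "bgc_regions.tsv"),
            metadata=str(d / "metadata.tsv"),
            reference_clusters=str(d / "reference_clusters.json"),
        )


def _require(config: PipelineConfig, *names: str) -> None:
    for name in names:
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise ConfigError(f"missing required input {name!r}: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# cached-artifact helpers

def _write_groups(groups, genome_of_gene, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgene_id\tgenome_id\n")
        for g in groups:
            for gid in g.gene_ids:
                fh.write(f"{g.group_id}\t{gid}\t{genome_of_gene[gid]}\n")


def _load_groups(outdir: Path) -> list[pg.HomologyGroup]:
    members: dict[str, dict[str, list[str]]] = {}
    with open(outdir / "groups.tsv") as fh:
        fh.readline()
        for line in fh:
            group_id, gene_id, genome_id = line.rstrip("\n").split("\t")
            members.setdefault(group_id, {}).setdefault(genome_id, []).append(gene_id)
    return [
        pg.HomologyGroup(group_id=k, members=members[k]) for k in sorted(members)
    ]


def _load_bins(outdir: Path) -> pg.PangenomeBins:
    bin_of, scg = {}, set()
    with open(outdir / "bins.tsv") as fh:
        fh.readline()
        for line in fh:
            group_id, _n, b, is_scg = line.rstrip("\n").split("\t")
            bin_of[group_id] = b
            if is_scg == "true":
                scg.add(group_id)
    return pg.PangenomeBins(bin_of_group=bin_of, scg_ids=scg)


def _load_metadata(config: PipelineConfig) -> list[pio.GenomeMetadata]:
    meta = pio.read_metadata(config.metadata)
    if config.exclude_regions:
        extra = tuple(config.exclude_regions)
        meta = [
            dataclasses.replace(
                m,
                excluded_regions=m.excluded_regions
                + tuple(r for r in extra if r.startswith(m.genome_id)),
            )
            for m in meta
        ]
    return meta


def _load_regions(config: PipelineConfig, meta) -> list[pio.BGCRegion]:
    regions = pio.read_bgc_regions(
        config.bgc_regions, known_genomes={m.genome_id for m in meta}
    )
    kept, _excluded = integration.apply_exclusions(regions, meta)
    return kept


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig) -> dict:
    sim = dataclasses.replace(config.sim, rng_seed=config.seed)
    paths, _truth = generate_pangenome(sim, Path(config.outdir) / "dataset")
    return {k: str(v) for k, v in paths.items()}


def stage_cluster(config: PipelineConfig) -> None:
    """All-vs-all similarity + MCL; writes groups.tsv (and any warnings)."""
    config = config.resolve_inputs()
    _require(config, "proteins", "gene_calls")
    outdir = Path(config.outdir)
    proteins = pio.read_proteins(config.proteins)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if config.similarities:
            sim_graph = read_similarity_tsv(config.similarities, config.min_similarity)
        else:
            sim_graph = build_similarity_graph(proteins, config.min_similarity)
        clusters = mcl_cluster(sim_graph, config.mcl)
        caught.extend(str(w.message) for w in wlist)
    genome_of_gene = {
        g.gene_id: g.genome_id for g in pio.read_gene_calls(config.gene_calls)
    }
    groups = pg.groups_from_clusters(clusters, genome_of_gene)
    _write_groups(groups, genome_of_gene, outdir / "groups.tsv")
    (outdir / "cluster_warnings.txt").write_text(
        "".join(w + "\n" for w in caught)
    )


def stage_pangenome(config: PipelineConfig) -> None:
    """Bin groups, refine scg, build both genome trees."""
    config = config.resolve_inputs()
    _require(config, "proteins", "metadata")
    outdir = Path(config.outdir)
    meta = _load_metadata(config)
    proteins = pio.read_proteins(config.proteins)
    groups = _load_groups(outdir)
    genomes = {m.genome_id for m in meta}
    bins = pg.bin_homology_groups(groups, len(meta), known_genomes=genomes)
    pg.select_scg(groups, bins, proteins, config.homogeneity)
    pg.write_bins_tsv(groups, bins, outdir / "bins.tsv")
    pam = pg.presence_absence_matrix(groups, sorted(genomes))
    pio.write_newick(
        pg.presence_absence_dendrogram(pam).newick(), outdir / "presence_absence.nwk"
    )
    if bins.scg_ids:
        dmat = pg.scg_distance_matrix(groups, bins.scg_ids, proteins)
        pio.write_newick(pg.upgma(dmat).newick(), outdir / "scg_tree.nwk")
    else:
        logger.warning("[pangenome] no scg groups passed the homogeneity filters")


def stage_integrate(config: PipelineConfig) -> None:
    """Trim boundaries, link genes to BGCs, tabulate bins × classes, detect
    conserved runs; writes trimmed_regions, annotations, table, runs."""
    config = config.resolve_inputs()
    _require(config, "gene_calls", "bgc_regions", "metadata")
    outdir = Path(config.outdir)
    meta = _load_metadata(config)
    gene_calls = pio.read_gene_calls(config.gene_calls)
    regions = _load_regions(config, meta)
    groups = _load_groups(outdir)
    bins = _load_bins(outdir)
    trimmed, untrimmable = integration.trim_regions(regions, gene_calls)
    pio.write_bgc_regions(trimmed, outdir / "trimmed_regions.tsv")
    (outdir / "untrimmable_regions.txt").write_text(
        "".join(r + "\n" for r in untrimmable)
    )
    annotations = integration.assign_genes_to_bgcs(gene_calls, trimmed)
    group_of_gene = {gid: g.group_id for g in groups for gid in g.gene_ids}
    annotations = integration.annotate_with_groups(
        annotations, group_of_gene, bins.bin_of_group
    )
    integration.write_annotations_tsv(annotations, outdir / "annotations.tsv")
    integration.bg_bin_distribution(annotations).to_csv(
        outdir / "bin_class_table.tsv", sep="\t"
    )
    runs = integration.detect_conserved_bg_runs(
        annotations,
        gene_calls,
        min_run=config.min_run,
        max_gap=config.max_gap,
        min_genome_fraction=config.min_genome_fraction,
        target_bin=config.run_bin,
    )
    integration.write_runs_tsv(runs, outdir / "runs.tsv")


def stage_network(config: PipelineConfig) -> None:
    """Composite-distance network, GCF components at the cutoff, cutoff
    sweep, known/unknown/fragmented labels and per-genus prevalence."""
    config = config.resolve_inputs()
    _require(config, "proteins", "metadata")
    outdir = Path(config.outdir)
    meta = _load_metadata(config)
    proteins = pio.read_proteins(config.proteins)
    groups = _load_groups(outdir)
    trimmed = pio.read_bgc_regions(outdir / "trimmed_regions.tsv")
    refs = (
        pio.read_reference_clusters(config.reference_clusters)
        if config.reference_clusters and Path(config.reference_clusters).exists()
        else []
    )
    curated = set()
    if config.curated_known and Path(config.curated_known).exists():
        curated = {
            l.strip()
            for l in Path(config.curated_known).read_text().splitlines()
            if l.strip()
        }
    group_of_gene = {gid: g.group_id for g in groups for gid in g.gene_ids}
    reps = {g.group_id: proteins[min(g.gene_ids)] for g in groups}
    profiles = net.profiles_from_regions(trimmed, group_of_gene, reps)
    profiles += net.map_reference_profiles(refs, reps, config.min_similarity)
    edges, components = net.build_gcf_network(profiles, config.network)
    pio.write_edge_list(edges, outdir / "network_edges.tsv")
    with open(outdir / "gcf_components.tsv", "w") as fh:
        fh.write("gcf_id\tmember\tcontains_reference\n")
        for c in components:
            for m in c.members + c.reference_members:
                fh.write(f"{c.gcf_id}\t{m}\t{str(c.contains_reference).lower()}\n")
    sweep = net.sweep_cutoffs(profiles, config.network)
    (outdir / "gcf_count_by_cutoff.json").write_text(
        json.dumps({f"{c:.2f}": n for c, n in sorted(sweep.items())}, indent=1) + "\n"
    )
    labels = net.classify_bgcs(
        components, {r.region_id: r.contig_edge for r in trimmed}, curated
    )
    with open(outdir / "classifications.tsv", "w") as fh:
        fh.write("bgc_id\tlabel\n")
        for bgc in sorted(labels):
            fh.write(f"{bgc}\t{labels[bgc]}\n")
    genome_of_region = {r.region_id: r.genome_id for r in trimmed}
    membership = {
        c.gcf_id: {genome_of_region[m] for m in c.members} for c in components
    }
    prevalence = integration.gcf_prevalence(membership, meta)
    integration.write_prevalence_tsv(prevalence, outdir / "prevalence.tsv")


def stage_report(config: PipelineConfig) -> dict:
    """Aggregate everything into summary.json plus the provenance manifest."""
    config = config.resolve_inputs()
    _require(config, "metadata")
    outdir = Path(config.outdir)
    meta = _load_metadata(config)
    trimmed = pio.read_bgc_regions(outdir / "trimmed_regions.tsv")
    labels = {}
    with open(outdir / "classifications.tsv") as fh:
        fh.readline()
        for line in fh:
            bgc, label = line.rstrip("\n").split("\t")
            labels[bgc] = label
    comp_members: dict[str, dict[str, list[str]]] = {}
    with open(outdir / "gcf_components.tsv") as fh:
        fh.readline()
        region_ids = {r.region_id for r in trimmed}
        for line in fh:
            gcf_id, member, _ref = line.rstrip("\n").split("\t")
            d = comp_members.setdefault(gcf_id, {"members": [], "refs": []})
            d["members" if member in region_ids else "refs"].append(member)
    class_of = {r.region_id: r.product_class for r in trimmed}
    components = [
        net.GCFComponent(
            gcf_id=k,
            members=tuple(sorted(v["members"])),
            reference_members=tuple(sorted(v["refs"])),
            class_composition={},
        )
        for k, v in sorted(comp_members.items())
    ]
    summary = net.summarize_collection(trimmed, labels, components, meta)
    summary["untrimmable_regions"] = [
        l.strip()
        for l in (outdir / "untrimmable_regions.txt").read_text().splitlines()
        if l.strip()
    ]
    with open(outdir / "runs.tsv") as fh:
        fh.readline()
        summary["n_conserved_run_clusters"] = len(
            {line.split("\t")[0] for line in fh if line.strip()}
        )
    summary["gcf_count_by_cutoff"] = json.loads(
        (outdir / "gcf_count_by_cutoff.json").read_text()
    )
    bins = _load_bins(outdir)
    summary["bin_counts"] = bins.counts()
    summary["n_scg"] = len(bins.scg_ids)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    warns_path = outdir / "cluster_warnings.txt"
    caught = (
        [l for l in warns_path.read_text().splitlines() if l]
        if warns_path.exists()
        else []
    )
    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "provenance.json"
    )
    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "warnings": caught,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True) + "\n"
    )
    return summary


_STAGES = (
    ("cluster", stage_cluster),
    ("pangenome", stage_pangenome),
    ("integrate", stage_integrate),
    ("network", stage_network),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the summary report dict.

    Any stage failure aborts with a stage-named message.
    """
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    if config.simulate:
        stage_simulate(config)
    config = config.resolve_inputs()
    _require(config, "gene_calls", "proteins", "bgc_regions", "metadata")
    for name, fn in _STAGES:
        try:
            fn(config)
        except Exception as exc:
            raise StageError(f"[{name}] {exc}") from exc
    try:
        return stage_report(config)
    except Exception as exc:
        raise StageError(f"[report] {exc}") from exc
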