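"""Synthetic pangenome generator with planted ground truth.

Emulates the statistical structure of a two-genus bacterial collection:
gene families with planted core/accessory/singleton presence patterns,
protein divergence within families, BGC loci laid out as consecutive genes
(structural biosynthetic genes flanked by peripheral non-structural genes),
gene-cluster families (GCFs) planted at per-genus prevalences, and a
known/unknown split against a MIBiG-like reference set.

Every draw flows from one seeded generator, so (config, seed) fully
determines the output bytes.  The planted truth records *realised* structure
(actual carrier sets, actual bins), which is what the downstream stages must
recover.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as pio
from .errors import ConfigError, InputError
from .homology import CANONICAL_RESIDUES

_RESIDUES = np.frombuffer(CANONICAL_RESIDUES.encode(), dtype=np.uint8)

INTERGENIC_SPACER = 50  # bp between consecutive genes


@dataclass(frozen=True)
class GCFTemplate:
    """Blueprint for one planted gene-cluster family.

    ``n_structural`` biosynthetic genes form the conserved run;
    ``n_peripheral`` non-structural genes (transporter/regulator stand-ins)
    flank it and fall inside the raw region interval but outside the trimmed
    boundary.  ``prevalence`` maps genus label → target carrier fraction.
    Reference-like templates are also emitted as MIBiG-like reference
    clusters, so their GCFs classify as known downstream.
    """

    product_class: str
    n_structural: int
    n_peripheral: int
    prevalence: Mapping[str, float]
    is_reference_like: bool = False


def _default_templates() -> list[GCFTemplate]:
    # mirrors the field situation: one conserved known GCF shared by both
    # genera, one widespread unknown hybrid, one genus-specific RiPP
    return [
        GCFTemplate("NRPS", 5, 2, {"X": 1.0, "P": 1.0}, is_reference_like=True),
        GCFTemplate("PKS/NRPS hybrid", 4, 2, {"X": 0.6, "P": 0.8}),
        GCFTemplate("RiPP", 3, 1, {"X": 0.0, "P": 1.0}),
    ]


@dataclass
class SimConfig:
    """Generator parameters; defaults are the desk-scale study conditions."""

    n_genomes_per_genus: Mapping[str, int] = field(
        default_factory=lambda: {"X": 7, "P": 5}
    )
    n_core_families: int = 40
    n_accessory_families: int = 60
    accessory_presence_prob: float = 0.5
    n_singleton_families: int = 20
    protein_length: int = 60
    mutation_rate: float = 0.05
    gcf_templates: list[GCFTemplate] = field(default_factory=_default_templates)
    rng_seed: int = 0
    contig_length: int | None = None  # optional cap; None = auto-sized

    def __post_init__(self):
        if any(n < 0 for n in self.n_genomes_per_genus.values()):
            raise ConfigError("genome counts must be ≥ 0")
        if sum(self.n_genomes_per_genus.values()) < 1:
            raise ConfigError("need at least one genome")
        for name in ("n_core_families", "n_accessory_families", "n_singleton_families"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be ≥ 0")
        if not 0 < self.accessory_presence_prob < 1:
            raise ConfigError("accessory_presence_prob must be in (0, 1)")
        if not 0 <= self.mutation_rate < 1:
            raise ConfigError("mutation_rate must be in [0, 1)")
        if self.protein_length < 1:
            raise ConfigError("protein_length must be ≥ 1")
        for t in self.gcf_templates:
            if t.n_structural < 1:
                raise ConfigError("each GCF template needs ≥ 1 structural gene")
            for genus, p in t.prevalence.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"prevalence {p} for genus {genus} not in [0,1]")


@dataclass
class PlantedRegion:
    region_id: str
    genome_id: str
    contig_id: str
    start: int
    stop: int
    product_class: str
    gcf_id: str
    structural_gene_ids: tuple[str, ...]
    peripheral_gene_ids: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """The planted structure every downstream stage must recover."""

    family_of_gene: dict[str, str]
    bin_of_family: dict[str, str]
    planted_regions: list[PlantedRegion]
    planted_prevalence: dict[tuple[str, str], float]  # (gcf_id, genus) -> fraction
    gcf_known: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "family_of_gene": self.family_of_gene,
            "bin_of_family": self.bin_of_family,
            "planted_regions": [dataclasses.asdict(r) for r in self.planted_regions],
            "planted_prevalence": {
                f"{gcf}|{genus}": frac
                for (gcf, genus), frac in sorted(self.planted_prevalence.items())
            },
            "gcf_known": self.gcf_known,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            family_of_gene=raw["family_of_gene"],
            bin_of_family=raw["bin_of_family"],
            planted_regions=[
                PlantedRegion(
                    **{
                        **r,
                        "structural_gene_ids": tuple(r["structural_gene_ids"]),
                        "peripheral_gene_ids": tuple(r["peripheral_gene_ids"]),
                    }
                )
                for r in raw["planted_regions"]
            ],
            planted_prevalence={
                tuple(k.split("|")): v for k, v in raw["planted_prevalence"].items()
            },
            gcf_known=raw.get("gcf_known", {}),
        )


def random_protein(length: int, rng: np.random.Generator) -> str:
    """An i.i.d.-uniform protein over the 20 canonical residues."""
    return bytes(rng.choice(_RESIDUES, size=length)).decode()


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``.

    A substituted position becomes a uniformly chosen *different* residue, so
    rate 1 shares no position with the input.  Length is preserved (no
    indels).
    """
    if not seq:
        raise InputError("sequence must be non-empty")
    if not 0 <= rate <= 1:
        raise InputError("rate must be in [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if np.isin(arr, _RESIDUES, invert=True).any():
        bad = chr(arr[np.isin(arr, _RESIDUES, invert=True)][0])
        raise InputError(f"non-canonical residue {bad!r}")
    if rate == 0:
        return seq
    hit = rng.random(len(arr)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # draw an offset in 1..19 over the residue alphabet: always different
        cur = np.searchsorted(_RESIDUES, arr[hit])
        offsets = rng.integers(1, len(_RESIDUES), size=n_hit)
        arr[hit] = _RESIDUES[(cur + offsets) % len(_RESIDUES)]
    return bytes(arr).decode()


def _carriers(
    genomes_of_genus: Mapping[str, list[str]],
    prevalence: Mapping[str, float],
    rng: np.random.Generator,
) -> list[str]:
    chosen: list[str] = []
    for genus in sorted(genomes_of_genus):
        pool = genomes_of_genus[genus]
        p = prevalence.get(genus, 0.0)
        k = int(math.floor(p * len(pool) + 0.5))  # round half up
        if k > 0:
            picked = rng.choice(len(pool), size=k, replace=False)
            chosen.extend(pool[i] for i in sorted(picked))
    return chosen


def generate_pangenome(
    config: SimConfig, outdir
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write a complete synthetic dataset and return (paths, truth).

    Files written: ``gene_calls.tsv``, ``proteins.faa``, ``bgc_regions.tsv``,
    ``metadata.tsv``, ``reference_clusters.json`` and the truth sidecar
    ``truth.json``.  Genes of one family derive from one ancestral sequence
    via :func:`mutate_protein`; genes are laid consecutively on one contig
    per genome with a fixed 50-bp spacer, BGC loci as consecutive runs with
    peripherals flanking the structural genes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    L = config.protein_length

    genomes_of_genus = {
        genus: [f"{genus}{i + 1:02d}" for i in range(n)]
        for genus, n in sorted(config.n_genomes_per_genus.items())
    }
    genomes = [g for genus in sorted(genomes_of_genus) for g in genomes_of_genus[genus]]
    n_total = len(genomes)

    # ancestral sequences per family, in a fixed draw order
    ancestral: dict[str, str] = {}
    core_fams = [f"CORE{i + 1:04d}" for i in range(config.n_core_families)]
    acc_fams = [f"ACC{i + 1:04d}" for i in range(config.n_accessory_families)]
    sgl_fams = [f"SGL{i + 1:04d}" for i in range(config.n_singleton_families)]
    for fam in core_fams + acc_fams + sgl_fams:
        ancestral[fam] = random_protein(L, rng)

    gcf_ids = [f"GCF{i + 1:02d}" for i in range(len(config.gcf_templates))]
    gcf_struct_fams: dict[str, list[str]] = {}
    gcf_peri_fams: dict[str, list[str]] = {}
    for gcf_id, tpl in zip(gcf_ids, config.gcf_templates):
        gcf_struct_fams[gcf_id] = [
            f"{gcf_id}_S{j + 1:02d}" for j in range(tpl.n_structural)
        ]
        gcf_peri_fams[gcf_id] = [
            f"{gcf_id}_P{j + 1:02d}" for j in range(tpl.n_peripheral)
        ]
        for fam in gcf_struct_fams[gcf_id] + gcf_peri_fams[gcf_id]:
            ancestral[fam] = random_protein(L, rng)

    # presence patterns
    members_of_genome: dict[str, list[str]] = {g: list(core_fams) for g in genomes}
    for fam in acc_fams:
        present = rng.random(n_total) < config.accessory_presence_prob
        for g, keep in zip(genomes, present):
            if keep:
                members_of_genome[g].append(fam)
    for fam in sgl_fams:
        g = genomes[int(rng.integers(n_total))]
        members_of_genome[g].append(fam)

    gcf_carriers: dict[str, list[str]] = {}
    for gcf_id, tpl in zip(gcf_ids, config.gcf_templates):
        gcf_carriers[gcf_id] = _carriers(genomes_of_genus, tpl.prevalence, rng)

    # layout + sequence emission, genome by genome in sorted order
    gene_calls: list[pio.GeneCall] = []
    proteins: dict[str, str] = {}
    regions: list[pio.BGCRegion] = []
    family_of_gene: dict[str, str] = {}
    planted_regions: list[PlantedRegion] = []
    gene_bp = 3 * L

    for genome in genomes:
        contig = f"{genome}_c1"
        pos = 1
        k = 0

        def place(fam: str, role: str) -> pio.GeneCall:
            nonlocal pos, k
            k += 1
            gid = f"{genome}_g{k:04d}"
            call = pio.GeneCall(
                genome, contig, gid, pos, pos + gene_bp - 1, "+", role
            )
            proteins[gid] = mutate_protein(
                ancestral[fam], config.mutation_rate, rng
            )
            family_of_gene[gid] = fam
            pos = call.stop + 1 + INTERGENIC_SPACER
            return call

        for fam in members_of_genome[genome]:
            gene_calls.append(place(fam, "unknown"))
        r = 0
        for gcf_id, tpl in zip(gcf_ids, config.gcf_templates):
            if genome not in gcf_carriers[gcf_id]:
                continue
            r += 1
            peri = gcf_peri_fams[gcf_id]
            n_lead = (len(peri) + 1) // 2
            block: list[tuple[str, str]] = (
                [(f, "non_structural") for f in peri[:n_lead]]
                + [(f, "biosynthetic") for f in gcf_struct_fams[gcf_id]]
                + [(f, "non_structural") for f in peri[n_lead:]]
            )
            calls = [place(fam, role) for fam, role in block]
            struct = [c.gene_id for c in calls if c.role == "biosynthetic"]
            periph = [c.gene_id for c in calls if c.role == "non_structural"]
            region_id = f"{genome}_r{r}"
            regions.append(
                pio.BGCRegion(
                    region_id=region_id,
                    genome_id=genome,
                    contig_id=contig,
                    start=calls[0].start,
                    stop=calls[-1].stop,
                    product_class=tpl.product_class,
                    contig_edge=False,
                )
            )
            planted_regions.append(
                PlantedRegion(
                    region_id=region_id,
                    genome_id=genome,
                    contig_id=contig,
                    start=calls[0].start,
                    stop=calls[-1].stop,
                    product_class=tpl.product_class,
                    gcf_id=gcf_id,
                    structural_gene_ids=tuple(struct),
                    peripheral_gene_ids=tuple(periph),
                )
            )
            gene_calls.extend(calls)
        if config.contig_length is not None and pos - 1 > config.contig_length:
            raise ConfigError(
                f"genome {genome} needs {pos - 1} bp but contig_length is "
                f"{config.contig_length}"
            )

    # realised truth: bins from actual carrier counts
    carriers_of_family: dict[str, set[str]] = {}
    for gid, fam in family_of_gene.items():
        carriers_of_family.setdefault(fam, set()).add(gid.rsplit("_g", 1)[0])
    bin_of_family: dict[str, str] = {}
    for fam, carr in carriers_of_family.items():
        n = len(carr)
        if n == n_total:
            bin_of_family[fam] = "core"
        elif n == 1 and n_total > 1:
            bin_of_family[fam] = "singleton"
        else:
            bin_of_family[fam] = "accessory"

    planted_prevalence = {
        (gcf_id, genus): len(
            [g for g in gcf_carriers[gcf_id] if g in genomes_of_genus[genus]]
        )
        / len(genomes_of_genus[genus])
        for gcf_id in gcf_ids
        for genus in sorted(genomes_of_genus)
        if genomes_of_genus[genus]
    }

    refs = [
        pio.ReferenceCluster(
            ref_id=f"REF_{gcf_id}",
            product_class=tpl.product_class,
            families=tuple(gcf_struct_fams[gcf_id]),
            representatives={f: ancestral[f] for f in gcf_struct_fams[gcf_id]},
        )
        for gcf_id, tpl in zip(gcf_ids, config.gcf_templates)
        if tpl.is_reference_like
    ]

    truth = SyntheticTruth(
        family_of_gene=family_of_gene,
        bin_of_family=bin_of_family,
        planted_regions=planted_regions,
        planted_prevalence=planted_prevalence,
        gcf_known={
            gcf_id: tpl.is_reference_like
            for gcf_id, tpl in zip(gcf_ids, config.gcf_templates)
        },
    )

    meta = [
        pio.GenomeMetadata(g, genus)
        for genus in sorted(genomes_of_genus)
        for g in genomes_of_genus[genus]
    ]

    paths = {
        "gene_calls": outdir / "gene_calls.tsv",
        "proteins": outdir / "proteins.faa",
        "bgc_regions": outdir / "bgc_regions.tsv",
        "metadata": outdir / "metadata.tsv",
        "reference_clusters": outdir / "reference_clusters.json",
        "truth": outdir / "truth.json",
    }
    pio.write_gene_calls(gene_calls, paths["gene_calls"])
    pio.write_proteins(proteins, paths["proteins"])
    pio.write_bgc_regions(regions, paths["bgc_regions"])
    pio.write_metadata(meta, paths["metadata"])
    pio.write_reference_clusters(refs, paths["reference_clusters"])
    truth.to_json(paths["truth"])
    return paths, truth
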