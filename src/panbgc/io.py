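"""Readers and writers for the pipeline's tabular, FASTA and tree formats.

All genomic coordinates are 1-based inclusive (GenBank convention), matching
the antiSMASH-style region annotations this package consumes.  Every parser is
total: malformed input raises :class:`~panbgc.errors.ParseError` naming the
line, never a silent partial result.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CrossReferenceError, InputError, ParseError

logger = logging.getLogger(__name__)

#: The eight product classes used throughout the analysis.
PRODUCT_CLASSES = (
    "NRPS",
    "PKS/NRPS hybrid",
    "PKSI",
    "other PKS",
    "RiPP",
    "terpene",
    "saccharide",
    "others",
)

GENE_ROLES = ("biosynthetic", "non_structural", "unknown")

# Raw antiSMASH product strings -> eight-class vocabulary.  The aggregation
# below is a documented reconstruction from antiSMASH 5 category definitions;
# it is overridable wherever a mapping is accepted.
_NRPS_TOKENS = {"nrps", "nrps-like", "thioamide-nrp", "cdps"}
_PKSI_TOKENS = {"t1pks"}
_OTHER_PKS_TOKENS = {
    "t2pks",
    "t3pks",
    "transat-pks",
    "transat-pks-like",
    "pks-like",
    "hgle-ks",
    "ppys-ks",
}
_RIPP_TOKENS = {
    "ripp",
    "ripp-like",
    "bacteriocin",
    "lanthipeptide",
    "lassopeptide",
    "thiopeptide",
    "lap",
    "sactipeptide",
    "microviridin",
    "bottromycin",
    "cyanobactin",
    "linaridin",
    "glycocin",
    "proteusin",
    "head_to_tail",
    "microcin",
}
_TERPENE_TOKENS = {"terpene"}
_SACCHARIDE_TOKENS = {"saccharide", "oligosaccharide", "amglyccycl"}


def classify_product(raw: str, overrides: Mapping[str, str] | None = None) -> str:
    """Map a raw antiSMASH product string to one of the eight classes.

    Composite products (comma- or hybrid-joined) that combine an NRPS part
    with any PKS part map to ``PKS/NRPS hybrid``.  Unrecognised products map
    to ``others`` with a logged warning.
    """
    raw = raw.strip()
    if overrides and raw in overrides:
        cls = overrides[raw]
        if cls not in PRODUCT_CLASSES:
            raise InputError(f"override maps {raw!r} to unknown class {cls!r}")
        return cls
    if raw in PRODUCT_CLASSES:
        return raw
    tokens = {t.strip().lower() for t in raw.replace("+", ",").split(",") if t.strip()}
    has_nrps = bool(tokens & _NRPS_TOKENS)
    has_pks = bool(tokens & (_PKSI_TOKENS | _OTHER_PKS_TOKENS))
    if has_nrps and has_pks:
        return "PKS/NRPS hybrid"
    if tokens & _NRPS_TOKENS:
        return "NRPS"
    if tokens & _PKSI_TOKENS:
        return "PKSI"
    if tokens & _OTHER_PKS_TOKENS:
        return "other PKS"
    if tokens & _RIPP_TOKENS:
        return "RiPP"
    if tokens & _TERPENE_TOKENS:
        return "terpene"
    if tokens & _SACCHARIDE_TOKENS:
        return "saccharide"
    if not tokens & {"others", "other"}:
        logger.warning("product %r not in the class map; assigned to 'others'", raw)
    return "others"


@dataclass(frozen=True)
class GeneCall:
    """One annotated gene with 1-based inclusive genomic coordinates."""

    genome_id: str
    contig_id: str
    gene_id: str
    start: int
    stop: int
    strand: str = "+"
    role: str = "unknown"

    def __post_init__(self):
        if self.start > self.stop:
            raise InputError(
                f"gene {self.gene_id}: start {self.start} > stop {self.stop}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.role not in GENE_ROLES:
            raise InputError(f"gene {self.gene_id}: bad role {self.role!r}")


@dataclass(frozen=True)
class BGCRegion:
    """A predicted biosynthetic gene cluster locus."""

    region_id: str
    genome_id: str
    contig_id: str
    start: int
    stop: int
    product_class: str
    contig_edge: bool = False
    member_gene_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.start > self.stop:
            raise InputError(
                f"region {self.region_id}: start {self.start} > stop {self.stop}"
            )
        if self.product_class not in PRODUCT_CLASSES:
            raise InputError(
                f"region {self.region_id}: class {self.product_class!r} not in "
                f"the eight-class vocabulary"
            )

    def with_interval(self, start: int, stop: int, members: Sequence[str]) -> "BGCRegion":
        return replace(
            self, start=start, stop=stop, member_gene_ids=tuple(members)
        )


@dataclass(frozen=True)
class GenomeMetadata:
    """Genome-level metadata: genus label and region exclusion flags."""

    genome_id: str
    genus: str
    excluded_regions: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# gene calls

_GENE_HEADER = ["genome_id", "contig_id", "gene_id", "start", "stop", "strand", "role"]


def write_gene_calls(genes: Iterable[GeneCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_HEADER) + "\n")
        for g in genes:
            fh.write(
                f"{g.genome_id}\t{g.contig_id}\t{g.gene_id}\t{g.start}\t{g.stop}"
                f"\t{g.strand}\t{g.role}\n"
            )


def read_gene_calls(path) -> list[GeneCall]:
    """Parse a tab-separated gene-call table.

    The ``role`` column is optional; absent roles default to ``unknown``.
    Duplicate gene ids within one genome, inverted coordinates and missing
    columns are parse errors naming the offending line.
    """
    genes: list[GeneCall] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = _GENE_HEADER[:-1]
        if header[: len(required)] != required:
            raise ParseError(
                f"bad header {header!r}, expected {required} [+ optional role]",
                path,
                1,
            )
        has_role = len(header) > 6 and header[6] == "role"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"expected ≥6 columns, got {len(fields)}", path, lineno)
            try:
                start, stop = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path, lineno)
            key = (fields[0], fields[2])
            if key in seen:
                raise ParseError(f"duplicate gene id {fields[2]!r}", path, lineno)
            seen.add(key)
            role = fields[6] if has_role and len(fields) > 6 else "unknown"
            try:
                genes.append(
                    GeneCall(fields[0], fields[1], fields[2], start, stop, fields[5], role)
                )
            except InputError as exc:
                raise ParseError(str(exc), path, lineno)
    return genes


# ---------------------------------------------------------------------------
# BGC regions

_REGION_HEADER = [
    "region_id",
    "genome_id",
    "contig_id",
    "start",
    "stop",
    "product",
    "contig_edge",
    "member_gene_ids",
]


def write_bgc_regions(regions: Iterable[BGCRegion], path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = [
            {
                "region_id": r.region_id,
                "genome_id": r.genome_id,
                "contig_id": r.contig_id,
                "start": r.start,
                "stop": r.stop,
                "product": r.product_class,
                "contig_edge": r.contig_edge,
                "member_gene_ids": list(r.member_gene_ids),
            }
            for r in regions
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    with open(path, "w") as fh:
        fh.write("\t".join(_REGION_HEADER) + "\n")
        for r in regions:
            fh.write(
                f"{r.region_id}\t{r.genome_id}\t{r.contig_id}\t{r.start}\t{r.stop}"
                f"\t{r.product_class}\t{str(r.contig_edge).lower()}"
                f"\t{','.join(r.member_gene_ids)}\n"
            )


def read_bgc_regions(
    path,
    class_map: Mapping[str, str] | None = None,
    known_genomes: set[str] | None = None,
) -> list[BGCRegion]:
    """Parse a region table (TSV or JSON dialect, chosen by extension).

    Raw product strings are mapped onto the eight-class vocabulary via
    :func:`classify_product` (``class_map`` overrides win).  If
    ``known_genomes`` is given, regions referencing other genomes raise
    :class:`CrossReferenceError`.
    """
    path = Path(path)
    rows: list[dict] = []
    if path.suffix == ".json":
        for rec in json.loads(path.read_text()):
            rows.append(rec)
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _REGION_HEADER:
                raise ParseError(f"bad header {header!r}", path, 1)
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != len(_REGION_HEADER):
                    raise ParseError(
                        f"expected {len(_REGION_HEADER)} columns, got {len(f)}",
                        path,
                        lineno,
                    )
                rows.append(
                    {
                        "region_id": f[0],
                        "genome_id": f[1],
                        "contig_id": f[2],
                        "start": int(f[3]),
                        "stop": int(f[4]),
                        "product": f[5],
                        "contig_edge": f[6].lower() in ("true", "1", "yes"),
                        "member_gene_ids": [x for x in f[7].split(",") if x],
                    }
                )
    regions = []
    for rec in rows:
        if known_genomes is not None and rec["genome_id"] not in known_genomes:
            raise CrossReferenceError(
                f"region {rec['region_id']} references unknown genome "
                f"{rec['genome_id']!r}"
            )
        regions.append(
            BGCRegion(
                region_id=rec["region_id"],
                genome_id=rec["genome_id"],
                contig_id=rec["contig_id"],
                start=int(rec["start"]),
                stop=int(rec["stop"]),
                product_class=classify_product(rec["product"], class_map),
                contig_edge=bool(rec["contig_edge"]),
                member_gene_ids=tuple(rec.get("member_gene_ids") or ()),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# genome metadata

_META_HEADER = ["genome_id", "genus", "excluded_regions"]


def write_metadata(meta: Iterable[GenomeMetadata], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_HEADER) + "\n")
        for m in meta:
            fh.write(f"{m.genome_id}\t{m.genus}\t{','.join(m.excluded_regions)}\n")


def read_metadata(path) -> list[GenomeMetadata]:
    out: list[GenomeMetadata] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _META_HEADER:
            raise ParseError(f"bad header {header!r}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 3:
                raise ParseError(f"expected 3 columns, got {len(f)}", path, lineno)
            if f[0] in seen:
                raise ParseError(f"duplicate genome {f[0]!r}", path, lineno)
            seen.add(f[0])
            out.append(
                GenomeMetadata(f[0], f[1], tuple(x for x in f[2].split(",") if x))
            )
    return out


# ---------------------------------------------------------------------------
# proteins (FASTA), edge lists, trees

def write_proteins(proteins: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteins(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate protein id {rec.id!r}", path)
        out[rec.id] = str(rec.seq)
    return out


def write_edge_list(edges: Iterable[tuple[str, str, float]], path) -> None:
    """Write a TSV edge list (node_a, node_b, weight), endpoints sorted."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in sorted((min(a, b), max(a, b), w) for a, b, w in edges):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_edge_list(path) -> list[tuple[str, str, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["node_a", "node_b", "weight"]:
            raise ParseError(f"bad header {header!r}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 3:
                raise ParseError(f"expected 3 columns, got {len(f)}", path, lineno)
            out.append((f[0], f[1], float(f[2])))
    return out


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n")


def read_newick(path) -> str:
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise ParseError("newick string must end with ';'", path)
    return text


# ---------------------------------------------------------------------------
# reference clusters (MIBiG-like)

@dataclass(frozen=True)
class ReferenceCluster:
    """An experimentally characterised reference cluster profile.

    ``families`` is the ordered domain-family profile; ``representatives``
    holds one representative protein sequence per family for similarity
    scoring.
    """

    ref_id: str
    product_class: str
    families: tuple[str, ...]
    representatives: Mapping[str, str] = field(default_factory=dict)


def write_reference_clusters(refs: Iterable[ReferenceCluster], path) -> None:
    payload = [
        {
            "ref_id": r.ref_id,
            "product_class": r.product_class,
            "families": list(r.families),
            "representatives": dict(r.representatives),
        }
        for r in refs
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_reference_clusters(path) -> list[ReferenceCluster]:
    refs = []
    for rec in json.loads(Path(path).read_text()):
        refs.append(
            ReferenceCluster(
                ref_id=rec["ref_id"],
                product_class=classify_product(rec["product_class"]),
                families=tuple(rec["families"]),
                representatives=dict(rec.get("representatives", {})),
            )
        )
    return refs
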