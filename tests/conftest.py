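import json
from pathlib import Path
from types import SimpleNamespace

import pytest

from panbgc.pipeline import PipelineConfig, run_pipeline
from panbgc.simulate import SyntheticTruth


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One full pipeline run on the default synthetic study design.

    12 genomes in two genera, 40 core + 60 accessory + 20 singleton
    families, mutation rate 0.05, three planted GCFs (one conserved known
    NRPS with a 5-gene structural run, one widespread unknown hybrid, one
    genus-specific RiPP).
    """
    outdir = tmp_path_factory.mktemp("study") / "run"
    cfg = PipelineConfig(outdir=str(outdir), simulate=True, seed=7)
    summary = run_pipeline(cfg)
    truth = SyntheticTruth.from_json(outdir / "dataset" / "truth.json")
    return SimpleNamespace(
        cfg=cfg.resolve_inputs(),
        outdir=Path(outdir),
        summary=summary,
        truth=truth,
    )


def load_clusters(outdir: Path) -> set[frozenset]:
    """Homology groups from groups.tsv as a set of frozen gene-id sets."""
    members: dict[str, set[str]] = {}
    with open(outdir / "groups.tsv") as fh:
        fh.readline()
        for line in fh:
            group_id, gene_id, _genome = line.rstrip("\n").split("\t")
            members.setdefault(group_id, set()).add(gene_id)
    return {frozenset(v) for v in members.values()}


def load_summary(outdir: Path) -> dict:
    return json.loads((outdir / "summary.json").read_text())
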