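import random

import pytest
from hypothesis import given, settings, strategies as st

from panbgc import integration as it
from panbgc.errors import CrossReferenceError, InputError
from panbgc.io import BGCRegion, GeneCall, GenomeMetadata


def gene(gid, start, stop, role="unknown", genome="G1", contig="c1"):
    return GeneCall(genome, contig, gid, start, stop, "+", role)


def region(rid, start, stop, cls="NRPS", genome="G1", contig="c1", edge=False):
    return BGCRegion(rid, genome, contig, start, stop, cls, edge)


# ---------------------------------------------------------------------------
# boundary trimming


def test_trim_to_biosynthetic_span():
    genes = [
        gene("reg", 100, 400, "non_structural"),
        gene("bg1", 500, 2000, "biosynthetic"),
        gene("bg2", 2100, 4000, "biosynthetic"),
        gene("tpt", 4100, 4500, "non_structural"),
    ]
    t = it.trim_bgc_boundary(region("r1", 50, 4600), genes)
    assert (t.start, t.stop) == (500, 4000)
    assert t.member_gene_ids == ("bg1", "bg2")


def test_trim_all_biosynthetic_is_identity():
    genes = [gene("bg1", 100, 200, "biosynthetic"), gene("bg2", 300, 400, "biosynthetic")]
    t = it.trim_bgc_boundary(region("r1", 100, 400), genes)
    assert (t.start, t.stop) == (100, 400)
    assert t.member_gene_ids == ("bg1", "bg2")


def test_trim_without_biosynthetic_gene_drops_region():
    genes = [gene("reg", 100, 400, "non_structural")]
    assert it.trim_bgc_boundary(region("r1", 50, 500), genes) is None
    trimmed, dropped = it.trim_regions([region("r1", 50, 500)], genes)
    assert trimmed == [] and dropped == ["r1"]


def test_trimmed_interval_contained_in_raw():
    genes = [
        gene("a", 10, 90, "non_structural"),
        gene("b", 100, 190, "biosynthetic"),
        gene("c", 200, 290, "unknown"),
        gene("d", 300, 390, "biosynthetic"),
    ]
    raw = region("r1", 1, 500)
    t = it.trim_bgc_boundary(raw, genes)
    assert raw.start <= t.start <= t.stop <= raw.stop
    # internal non-biosynthetic gene stays a member (only periphery trimmed)
    assert t.member_gene_ids == ("b", "c", "d")


# ---------------------------------------------------------------------------
# gene → BGC assignment


def test_assignment_requires_full_containment():
    genes = [
        gene("inside", 600, 900),
        gene("straddle", 450, 600),
        gene("outside", 5000, 5100),
        gene("othercontig", 600, 900, contig="c2"),
    ]
    anns = it.assign_genes_to_bgcs(genes, [region("r1", 500, 4000)])
    assert [a.gene_id for a in anns] == ["inside"]
    assert anns[0].product_class == "NRPS"


def test_overlapping_regions_rejected():
    with pytest.raises(InputError):
        it.assign_genes_to_bgcs(
            [], [region("r1", 100, 500), region("r2", 400, 900)]
        )


def test_each_gene_in_at_most_one_region():
    genes = [gene(f"g{i}", 100 * i, 100 * i + 50) for i in range(1, 30)]
    regions = [region("r1", 100, 1000), region("r2", 1500, 2500)]
    anns = it.assign_genes_to_bgcs(genes, regions)
    assert len({a.gene_id for a in anns}) == len(anns)


# ---------------------------------------------------------------------------
# bin × class distribution


def test_bin_distribution_conservation():
    anns = [
        it.BGAnnotation("g1", "G1", "r1", "NRPS", "hg1", "core"),
        it.BGAnnotation("g2", "G1", "r1", "NRPS", "hg2", "core"),
        it.BGAnnotation("g3", "G1", "r2", "RiPP", "hg3", "singleton"),
    ]
    table = it.bg_bin_distribution(anns)
    assert table.loc["core", "NRPS"] == 2
    assert table.loc["singleton", "RiPP"] == 1
    assert int(table.to_numpy().sum()) == len(anns)


def test_bin_distribution_missing_bin_rejected():
    with pytest.raises(CrossReferenceError):
        it.bg_bin_distribution([it.BGAnnotation("g1", "G1", "r1", "NRPS")])


# ---------------------------------------------------------------------------
# conserved runs


def _run_setup(n_genomes=3, sig=("h1", "h2", "h3", "h4", "h5")):
    """Each genome carries the same 5-gene core-BG run."""
    genes, anns = [], []
    for gi in range(n_genomes):
        genome = f"G{gi + 1}"
        for k, grp in enumerate(sig):
            gid = f"{genome}_g{k + 1}"
            genes.append(
                GeneCall(genome, f"{genome}_c1", gid, 1000 * (k + 1), 1000 * (k + 1) + 500)
            )
            anns.append(
                it.BGAnnotation(gid, genome, f"{genome}_r1", "NRPS", grp, "core")
            )
    return genes, anns


def test_planted_run_detected_in_all_genomes():
    genes, anns = _run_setup()
    runs = it.detect_conserved_bg_runs(anns, genes, min_run=3)
    assert len(runs) == 3
    assert len({r.cluster_id for r in runs}) == 1
    for r in runs:
        assert len(r.gene_ids) == 5
        assert len(r.homologous_runs) == 2


def test_run_broken_by_large_gap_splits():
    genes, anns = _run_setup(n_genomes=1)
    # insert two non-qualifying genes between h2 and h3 (gap 2 > max_gap 1)
    genes.insert(2, GeneCall("G1", "G1_c1", "G1_x1", 2600, 2700))
    genes.insert(3, GeneCall("G1", "G1_c1", "G1_x2", 2800, 2900))
    runs = it.detect_conserved_bg_runs(
        anns, genes, min_run=2, max_gap=1, min_genome_fraction=0.0
    )
    sigs = sorted(tuple(r.group_signature) for r in runs)
    assert sigs == [("h1", "h2"), ("h3", "h4", "h5")]


def test_isolated_bg_is_not_a_run():
    genes = [gene("g1", 100, 200)]
    anns = [it.BGAnnotation("g1", "G1", "r1", "NRPS", "h1", "core")]
    assert (
        it.detect_conserved_bg_runs(anns, genes, min_run=2, min_genome_fraction=0.0)
        == []
    )


def test_run_detection_invariant_to_input_order():
    genes, anns = _run_setup()
    runs_a = it.detect_conserved_bg_runs(anns, genes, min_run=3)
    rng = random.Random(1)
    genes2, anns2 = genes[:], anns[:]
    rng.shuffle(genes2)
    rng.shuffle(anns2)
    runs_b = it.detect_conserved_bg_runs(anns2, genes2, min_run=3)
    assert {(r.genome_id, r.gene_ids) for r in runs_a} == {
        (r.genome_id, r.gene_ids) for r in runs_b
    }


def test_reversed_gene_order_still_links():
    genes, anns = _run_setup(n_genomes=2)
    # reverse the positional order of genome G2's genes
    g2 = [g for g in genes if g.genome_id == "G2"]
    flipped = [
        GeneCall("G2", "G2_c1", g.gene_id, 10000 - g.stop, 10000 - g.start)
        for g in g2
    ]
    genes = [g for g in genes if g.genome_id != "G2"] + flipped
    runs = it.detect_conserved_bg_runs(anns, genes, min_run=3)
    assert len({r.cluster_id for r in runs}) == 1


# ---------------------------------------------------------------------------
# prevalence


@pytest.fixture
def xp_metadata():
    return [GenomeMetadata(f"X{i:02d}", "X") for i in range(1, 30)] + [
        GenomeMetadata(f"P{i:02d}", "P") for i in range(1, 17)
    ]


def test_prevalence_truncated_percentages(xp_metadata):
    membership = {
        "gcfA": {f"X{i:02d}" for i in range(1, 29)},  # 28 of 29
        "gcfB": {f"P{i:02d}" for i in range(1, 16)},  # 15 of 16
    }
    recs = {(r.gcf_id, r.genus): r for r in it.gcf_prevalence(membership, xp_metadata)}
    assert recs[("gcfA", "X")].prevalence_pct == 96
    assert recs[("gcfB", "P")].prevalence_pct == 93
    assert recs[("gcfA", "P")].prevalence_pct == 0


def test_prevalence_table_round_trip(tmp_path, xp_metadata):
    membership = {"g1": {"X01", "X02"}, "g2": set()}
    recs = it.gcf_prevalence(membership, xp_metadata)
    path = tmp_path / "prev.tsv"
    it.write_prevalence_tsv(recs, path)
    assert it.read_prevalence_tsv(path) == recs


def test_prevalence_unknown_genome_rejected(xp_metadata):
    with pytest.raises(CrossReferenceError):
        it.gcf_prevalence({"g": {"nope"}}, xp_metadata)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=28), st.integers(min_value=1, max_value=29))
def test_prevalence_monotone_in_carriers(k, n):
    meta = [GenomeMetadata(f"X{i:02d}", "X") for i in range(n)]
    genomes = sorted(m.genome_id for m in meta)
    k = min(k, n - 1)
    before = it.gcf_prevalence({"g": set(genomes[:k])}, meta)[0].prevalence_pct
    after = it.gcf_prevalence({"g": set(genomes[: k + 1])}, meta)[0].prevalence_pct
    assert after >= before
    assert before == (100 * k) // n
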