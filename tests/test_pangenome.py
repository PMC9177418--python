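import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from panbgc.errors import InputError
from panbgc.pangenome import (
    HomogeneityParams,
    HomologyGroup,
    bin_homology_groups,
    functional_homogeneity,
    geometric_homogeneity,
    jukes_cantor_distance,
    presence_absence_dendrogram,
    presence_absence_matrix,
    select_scg,
    upgma,
)


def group(gid, members):
    return HomologyGroup(group_id=gid, members=members)


# ---------------------------------------------------------------------------
# binning


def test_binning_thresholds():
    groups = [
        group("core", {f"g{i}": [f"g{i}_a"] for i in range(45)}),
        group("sgl", {"g0": ["g0_b"]}),
        group("acc", {f"g{i}": [f"g{i}_c"] for i in range(10)}),
    ]
    bins = bin_homology_groups(groups, 45)
    assert bins.bin_of_group == {"core": "core", "sgl": "singleton", "acc": "accessory"}
    assert bins.counts() == {"core": 1, "accessory": 1, "singleton": 1}


def test_single_genome_collection_everything_core():
    groups = [group("a", {"g0": ["x"]}), group("b", {"g0": ["y"]})]
    bins = bin_homology_groups(groups, 1)
    assert set(bins.bin_of_group.values()) == {"core"}


def test_bins_partition_all_groups():
    rng = np.random.default_rng(0)
    groups = []
    for i in range(50):
        n = int(rng.integers(1, 13))
        groups.append(
            group(f"hg{i}", {f"g{j}": [f"hg{i}_g{j}"] for j in range(n)})
        )
    bins = bin_homology_groups(groups, 12)
    assert len(bins.bin_of_group) == 50
    assert sum(bins.counts().values()) == 50


# ---------------------------------------------------------------------------
# homogeneity indices


def test_functional_homogeneity_identical_sequences():
    assert functional_homogeneity(["ACDEF", "ACDEF"]) == 1.0


def test_functional_homogeneity_opposite_classes():
    assert functional_homogeneity(["K", "D"]) == 0.0


def test_functional_homogeneity_same_class_swap():
    assert functional_homogeneity(["KR", "RK"]) == 1.0


def test_functional_homogeneity_all_gap_columns_ignored():
    assert functional_homogeneity(["A-", "-C"]) == 1.0


def test_geometric_homogeneity_examples():
    assert geometric_homogeneity(["ACDEFACDEF", "ACDEFACDEF"]) == 1.0
    # gap state differs at exactly one of ten columns
    assert geometric_homogeneity(["ACDEFACDE-", "ACDEFACDEF"]) == pytest.approx(0.9)
    # fully complementary masks, L=4
    assert geometric_homogeneity(["AC--", "--AC"]) == 0.0


def test_homogeneity_rejects_unequal_lengths():
    with pytest.raises(InputError):
        functional_homogeneity(["ACD", "AC"])
    with pytest.raises(InputError):
        geometric_homogeneity(["ACD", "AC"])


# ---------------------------------------------------------------------------
# scg selection


def test_select_scg_filters():
    proteins = {
        # variable core group (FH 0.5 across classes), single copy
        "a1": "KKKK", "a2": "DDKK",
        # doubled gene in one genome
        "b1": "AAAA", "b2": "AAAA", "b3": "AAAA",
        # too-homogeneous group (identical -> FH 1.0 > 0.9)
        "c1": "CCCC", "c2": "CCCC",
    }
    groups = [
        group("varied", {"g1": ["a1"], "g2": ["a2"]}),
        group("doubled", {"g1": ["b1", "b2"], "g2": ["b3"]}),
        group("uniform", {"g1": ["c1"], "g2": ["c2"]}),
    ]
    bins = bin_homology_groups(groups, 2)
    assert set(bins.bin_of_group.values()) == {"core"}
    scg = select_scg(groups, bins, proteins, HomogeneityParams())
    assert scg == {"varied"}
    assert bins.scg_ids == scg


def test_scg_is_subset_of_core():
    proteins = {"a1": "KKDD", "a2": "DDKK", "s1": "AAAA"}
    groups = [
        group("core1", {"g1": ["a1"], "g2": ["a2"]}),
        group("sgl1", {"g1": ["s1"]}),
    ]
    bins = bin_homology_groups(groups, 2)
    scg = select_scg(groups, bins, proteins)
    core = {g for g, b in bins.bin_of_group.items() if b == "core"}
    assert scg <= core


# ---------------------------------------------------------------------------
# Jukes–Cantor


def test_jc_zero_and_closed_form():
    assert jukes_cantor_distance(0.0, "nucleotide") == 0.0
    expected = -0.75 * math.log(1 - 4 * 0.3 / 3)
    assert jukes_cantor_distance(0.3, "nucleotide") == pytest.approx(
        expected, abs=1e-15
    )


def test_jc_saturation_domain_error():
    with pytest.raises(InputError):
        jukes_cantor_distance(0.75, "nucleotide")
    with pytest.raises(InputError):
        jukes_cantor_distance(0.95, "protein")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.7499, exclude_max=True))
def test_jc_increasing_and_dominates_p(p):
    d = jukes_cantor_distance(p, "nucleotide")
    assert d >= p - 1e-12
    if p >= 1e-6:
        assert d > jukes_cantor_distance(p * (1 - 1e-6), "nucleotide")


# ---------------------------------------------------------------------------
# UPGMA


def mat(labels, rows):
    return pd.DataFrame(rows, index=labels, columns=labels, dtype=float)


def test_upgma_two_taxa():
    tree = upgma(mat(["A", "B"], [[0, 2], [2, 0]]))
    assert tree.newick() == "(A:1,B:1);"


def test_upgma_three_taxa_hand_case():
    d = mat(["A", "B", "C"], [[0, 2, 6], [2, 0, 6], [6, 6, 0]])
    tree = upgma(d)
    assert tree.newick() == "((A:1,B:1):2,C:3);"


def test_upgma_ultrametric_input_reproduced_exactly():
    labels = ["A", "B", "C", "D"]
    d = mat(
        labels,
        [
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0],
        ],
    )
    coph = upgma(d).cophenetic()
    pd.testing.assert_frame_equal(coph, d.loc[coph.index, coph.columns])


def test_upgma_rejects_asymmetry():
    with pytest.raises(InputError):
        upgma(mat(["A", "B"], [[0, 1], [2, 0]]))


@pytest.mark.parametrize("seed", range(5))
def test_upgma_matches_scipy_average_linkage(seed):
    """Cophenetic distances agree with scipy's UPGMA on random matrices."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    labels = [f"t{i}" for i in range(n)]
    condensed = rng.uniform(0.5, 3.0, size=n * (n - 1) // 2)
    d = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    ours = upgma(d).cophenetic().to_numpy()
    theirs = squareform(cophenet(linkage(condensed, method="average")))
    assert np.allclose(ours, theirs, atol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_upgma_output_is_ultrametric(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(3, 9))
    labels = [f"t{i}" for i in range(n)]
    d = pd.DataFrame(
        squareform(rng.uniform(0.1, 5.0, size=n * (n - 1) // 2)),
        index=labels,
        columns=labels,
    )
    coph = upgma(d).cophenetic().to_numpy()
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert coph[i, j] <= max(coph[i, k], coph[k, j]) + 1e-9


# ---------------------------------------------------------------------------
# presence/absence dendrogram


def test_identical_genomes_cluster_first():
    m = pd.DataFrame(
        {"g1": [1, 1, 0], "g2": [1, 1, 0], "g3": [0, 0, 1]},
        index=["h1", "h2", "h3"],
    )
    tree = presence_absence_dendrogram(m)
    coph = tree.cophenetic()
    assert coph.loc["g1", "g2"] == 0.0
    assert coph.loc["g1", "g3"] > 0


def test_jaccard_distance_value():
    m = pd.DataFrame({"a": [1, 1, 0], "b": [1, 0, 1]}, index=["h1", "h2", "h3"])
    tree = presence_absence_dendrogram(m)
    assert tree.cophenetic().loc["a", "b"] == pytest.approx(2 / 3)


def test_single_genome_tree():
    m = pd.DataFrame({"only": [1, 0]}, index=["h1", "h2"])
    tree = presence_absence_dendrogram(m)
    assert tree.leaves() == ["only"]


def test_all_zero_genome_at_distance_one():
    m = pd.DataFrame({"a": [1, 1], "b": [0, 0]}, index=["h1", "h2"])
    tree = presence_absence_dendrogram(m)
    assert tree.cophenetic().loc["a", "b"] == 1.0


def test_presence_absence_matrix_marks_carriers():
    groups = [
        HomologyGroup("hg1", {"g1": ["a"], "g2": ["b"]}),
        HomologyGroup("hg2", {"g1": ["c"]}),
    ]
    m = presence_absence_matrix(groups, ["g1", "g2"])
    assert m.loc["hg1"].tolist() == [1, 1]
    assert m.loc["hg2"].tolist() == [1, 0]
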