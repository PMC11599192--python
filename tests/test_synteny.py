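"""Marker support, cassette detection and WGD copy counting."""

import pytest

from cd28fam.errors import TableError
from cd28fam.simulate import CASSETTE_MARKERS, SimGenomeConfig, simulate_genome
from cd28fam.synteny import (
    Gene,
    GeneOrderTable,
    count_paralogous_regions,
    detect_cassette,
    marker_support,
    names_equal,
    reverse_table,
)


def make_table(names, species="sp", chromosome="chr1", strands=None):
    genes = tuple(
        Gene(
            name=n,
            start=i * 1000 + 1,
            end=i * 1000 + 500,
            strand=(strands[i] if strands else "+"),
        )
        for i, n in enumerate(names)
    )
    return GeneOrderTable(species=species, chromosome=chromosome, genes=genes)


def test_marker_support_counts_flanking_markers():
    table = make_table(["a", "fsd1", "cand", "stap2", "b"])
    hit = marker_support(table, "cand", {"fsd1", "stap2"})
    assert hit.shared_count == 2
    assert hit.shared_markers == {"fsd1", "stap2"}


def test_marker_support_empty_marker_set():
    table = make_table(["fsd1", "cand", "stap2"])
    assert marker_support(table, "cand", set()).shared_count == 0


def test_marker_support_window_limits_reach():
    # distinct letter-only names avoid the ohnolog-suffix tolerance
    left = [f"l{c}" for c in "cdefghijklmnopq"]  # 15 genes left of cand
    right = [f"r{c}" for c in "cdefghijklmnopq"]
    table = make_table(left + ["cand"] + right)
    hit = marker_support(table, "cand", {left[0], left[-1], right[0], right[-1]}, k=10)
    # the outermost genes are 16 ranks away, outside the k=10 window
    assert hit.shared_markers == {left[-1], right[0]}


def test_marker_support_orientation_and_strand_invariant():
    table = make_table(["a", "fsd1", "cand", "stap2", "b"], strands=list("+-+-+"))
    forward = marker_support(table, "cand", {"fsd1", "stap2"})
    backward = marker_support(reverse_table(table), "cand", {"fsd1", "stap2"})
    assert forward.shared_count == backward.shared_count == 2


def test_marker_support_missing_candidate_raises():
    with pytest.raises(TableError):
        marker_support(make_table(["a", "b"]), "cand", {"a"})


def test_name_matching_tolerates_case_and_ohnolog_suffixes():
    assert names_equal("tacc3", "TACC3")
    assert names_equal("tacc3", "tacc3.2")
    assert names_equal("prkab1", "prkab1b")
    assert not names_equal("fsd1", "stap2")


def test_detect_cassette_three_consecutive_genes():
    table = make_table(["raph1", "abi2", "co1", "co2", "co3", "wdr12", "cyp20a1"])
    calls = detect_cassette(table, {"co1", "co2", "co3"})
    assert len(calls) == 1
    assert calls[0].size == 3
    assert calls[0].member_genes == ("co1", "co2", "co3")
    assert calls[0].flanking_markers == {"abi2", "wdr12"}


def test_detect_cassette_singleton_not_emitted():
    table = make_table(["a", "co1", "b"])
    assert detect_cassette(table, {"co1"}) == []


def test_detect_cassette_runs_split_by_large_gaps():
    # 12-gene toy: two family runs separated by 3 interleaving genes
    names = ["m1", "f1", "f2", "x1", "x2", "x3", "f3", "f4", "m2", "x4", "x5", "m3"]
    table = make_table(names)
    calls = detect_cassette(table, {"f1", "f2", "f3", "f4"}, max_gap=1)
    assert [c.member_genes for c in calls] == [("f1", "f2"), ("f3", "f4")]
    # raising max_gap merges them into one cassette
    merged = detect_cassette(table, {"f1", "f2", "f3", "f4"}, max_gap=3)
    assert len(merged) == 1 and merged[0].size == 4


def test_detect_cassette_tolerates_one_interleaving_gene():
    table = make_table(["a", "f1", "x", "f2", "b"])
    calls = detect_cassette(table, {"f1", "f2"}, max_gap=1)
    assert len(calls) == 1 and calls[0].size == 2


def test_detect_cassette_is_a_partition():
    names = ["f1", "x", "f2", "x2", "x3", "f3", "f4"]
    calls = detect_cassette(make_table(names), {"f1", "f2", "f3", "f4"})
    seen = [g for c in calls for g in c.member_genes]
    assert len(seen) == len(set(seen))


@pytest.mark.parametrize("wgd_events, expected", [(0, 1), (1, 2), (2, 4)])
def test_wgd_doubles_paralogous_region_count(wgd_events, expected, catalog):
    tables, truth = simulate_genome(
        SimGenomeConfig(wgd_events=wgd_events, loss_probability=0.0, seed=8),
        profiles=catalog,
    )
    assert len(tables) == expected
    count = count_paralogous_regions(tables, CASSETTE_MARKERS, min_shared=2)
    assert count == expected == truth.surviving_copies["cassette"]


def test_full_region_loss_reduces_count(catalog):
    # two WGDs then loss of every gene on one copy leaves 3 regions
    tables, truth = simulate_genome(
        SimGenomeConfig(wgd_events=2, loss_probability=1.0, loss_copies=(0,), seed=8),
        profiles=catalog,
    )
    kept = [t for t in tables if len(t.genes) > 0]
    assert count_paralogous_regions(kept, CASSETTE_MARKERS) == 3
    assert truth.surviving_copies["cassette"] == 3


def test_distant_windows_on_one_chromosome_count_separately():
    names = (
        ["fsd1", "stap2"]
        + [f"x{i}" for i in range(60)]
        + ["fsd1b", "stap2b"]
    )
    table = make_table(names)
    assert count_paralogous_regions([table], {"fsd1", "stap2"}) == 2


def test_table_invariants():
    with pytest.raises(TableError):
        GeneOrderTable(
            species="sp",
            chromosome="c",
            genes=(
                Gene("a", 100, 200, "+"),
                Gene("b", 50, 80, "+"),  # starts must increase
            ),
        )
    with pytest.raises(TableError):
        Gene("a", 10, 5, "+")
    with pytest.raises(TableError):
        Gene("a", 1, 5, "*")
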