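"""Synthetic receptor and genome generators: determinism, planted truth and
divergence calibration."""

import numpy as np
import pytest

from cd28fam.catalog import CANONICAL_FAMILIES, get_profile
from cd28fam.errors import Cd28FamError
from cd28fam.motif import scan
from cd28fam.simulate import (
    CASSETTE_MARKERS,
    SimGenomeConfig,
    SimProteinConfig,
    simulate_family_protein,
    simulate_genome,
)
from cd28fam.synteny import count_paralogous_regions, detect_cassette


def test_protein_generator_deterministic_per_seed(catalog):
    a, ta = simulate_family_protein(SimProteinConfig(family="CD28", seed=5), profiles=catalog)
    b, tb = simulate_family_protein(SimProteinConfig(family="CD28", seed=5), profiles=catalog)
    c, _ = simulate_family_protein(SimProteinConfig(family="CD28", seed=6), profiles=catalog)
    assert a.sequence == b.sequence and ta == tb
    assert a.sequence != c.sequence


def test_cd28_exemplar_carries_its_diagnostic_motifs(catalog, exemplar):
    record, truth = exemplar("CD28", seed=0)
    profile = get_profile(catalog, "CD28")
    cdr3 = next(m for m in profile.motif_requirements if m.pattern.notation == "P-P-P")
    cyt = next(
        m for m in profile.motif_requirements
        if m.pattern.notation == "[D/E/V/I]-Y-M-[N/D]-[M/I/V/T]"
    )
    assert scan(record.sequence, cdr3.pattern, window=truth.motif_positions["P-P-P"])
    assert scan(
        record.sequence,
        cyt.pattern,
        window=truth.motif_positions["[D/E/V/I]-Y-M-[N/D]-[M/I/V/T]"],
    )


@pytest.mark.parametrize("family", CANONICAL_FAMILIES)
def test_required_motifs_planted_inside_their_regions(family, catalog, exemplar):
    record, truth = exemplar(family, seed=21)
    profile = get_profile(catalog, family)
    for req in profile.required_motifs():
        if truth.divergent_igv and req.region in ("CDR3_NEIGHBORHOOD", "G_STRAND", "E_STRAND"):
            continue
        assert req.pattern.notation in truth.motif_positions, (family, req.pattern.notation)
        window = truth.motif_positions[req.pattern.notation]
        assert scan(record.sequence, req.pattern, window=window)


def test_divergence_rate_calibration(catalog):
    # protected motifs, 10% per-site substitution: mean identity to the
    # divergence-0 exemplar should sit near 90% (binomial expectation,
    # slightly above because protected sites never change)
    identities = []
    for i in range(200):
        base, _ = simulate_family_protein(
            SimProteinConfig(family="CD28", divergence=0.0, seed=3000 + i), profiles=catalog
        )
        mutated, _ = simulate_family_protein(
            SimProteinConfig(family="CD28", divergence=0.10, seed=3000 + i), profiles=catalog
        )
        same = sum(x == y for x, y in zip(base.sequence, mutated.sequence))
        identities.append(100.0 * same / len(base.sequence))
    assert abs(float(np.mean(identities)) - 90.0) <= 3.0


def test_protected_positions_never_substituted(catalog):
    for i in range(20):
        base, truth0 = simulate_family_protein(
            SimProteinConfig(family="CTLA4", divergence=0.0, seed=4000 + i), profiles=catalog
        )
        mutated, truth = simulate_family_protein(
            SimProteinConfig(family="CTLA4", divergence=0.3, seed=4000 + i), profiles=catalog
        )
        for pos in truth.protected:
            assert base.sequence[pos - 1] == mutated.sequence[pos - 1]


def test_divergent_igv_only_for_tolerant_families(catalog):
    _, truth = simulate_family_protein(SimProteinConfig(family="PD1", seed=0), profiles=catalog)
    assert truth.divergent_igv and truth.framework is None
    with pytest.raises(Cd28FamError):
        simulate_family_protein(
            SimProteinConfig(family="CD28", seed=0, divergent_igv=True), profiles=catalog
        )


def test_unknown_family_rejected(catalog):
    with pytest.raises(Cd28FamError):
        simulate_family_protein(SimProteinConfig(family="CD99", seed=0), profiles=catalog)


def test_genome_no_wgd_single_ancestral_table(catalog):
    tables, truth = simulate_genome(SimGenomeConfig(seed=1), profiles=catalog)
    assert len(tables) == 1
    assert truth.n_copies == 1
    assert detect_cassette(tables[0], truth.family_genes)[0].size == 3


def test_genome_two_wgds_four_cassette_copies(catalog):
    tables, truth = simulate_genome(
        SimGenomeConfig(wgd_events=2, loss_probability=0.0, seed=1), profiles=catalog
    )
    assert len(tables) == 4
    for table in tables:
        calls = detect_cassette(table, truth.family_genes)
        assert len(calls) == 1 and calls[0].size == 3
    assert truth.surviving_copies["cassette"] == 4


def test_genome_deterministic_per_seed(catalog):
    t1, _ = simulate_genome(SimGenomeConfig(wgd_events=1, loss_probability=0.3, seed=9), profiles=catalog)
    t2, _ = simulate_genome(SimGenomeConfig(wgd_events=1, loss_probability=0.3, seed=9), profiles=catalog)
    assert t1 == t2


def test_stratified_family_loss_truth(catalog):
    # one WGD, then forced loss of family genes on copy 2 only
    tables, truth = simulate_genome(
        SimGenomeConfig(
            wgd_events=1,
            loss_probability=1.0,
            loss_scope="family",
            loss_copies=(1,),
            seed=2,
        ),
        profiles=catalog,
    )
    assert truth.family_surviving["cassette"] == 1
    # markers untouched: both copies still count as conserved regions
    assert truth.surviving_copies["cassette"] == 2
    assert count_paralogous_regions(tables, CASSETTE_MARKERS) == 2


def test_truth_copy_counts_match_detector_without_loss(catalog):
    for wgd in (0, 1, 2):
        tables, truth = simulate_genome(
            SimGenomeConfig(
                families_placed=("CD28H", "CD28X"), wgd_events=wgd, seed=31
            ),
            profiles=catalog,
        )
        for block, markers in truth.block_markers.items():
            assert (
                count_paralogous_regions(tables, markers)
                >= truth.surviving_copies[block] == truth.n_copies
            )


def test_rearrangement_preserves_gene_content(catalog):
    plain, _ = simulate_genome(SimGenomeConfig(seed=3), profiles=catalog)
    shuffled, _ = simulate_genome(
        SimGenomeConfig(rearrangement_rate=0.5, seed=3), profiles=catalog
    )
    assert sorted(plain[0].names()) == sorted(shuffled[0].names())
    assert plain[0].names() != shuffled[0].names()
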