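"""ASPCR scoring, codon calls from ambiguous traces, catalogs and phasing."""

import random

import pytest

from oracles import iupac_expansion_oracle, phase_pairs_oracle

from kdrevo.domain import FailedReactionError, InputError
from kdrevo.genotyping import (
    IUPAC_EXPAND,
    SiteGenotype,
    build_haplotype_catalog,
    call_site_from_sequence,
    iupac_union,
    phase_heterozygote,
    score_aspcr,
    validate_inferred_haplotypes,
    DiploidRegionGenotype,
)


# ---------------------------------------------------------------------------
# ASPCR


@pytest.mark.parametrize(
    "sus,res,expected",
    [
        (True, False, SiteGenotype.SS),
        (False, True, SiteGenotype.RR),
        (True, True, SiteGenotype.RS),
    ],
)
def test_aspcr_band_scoring(sus, res, expected):
    assert score_aspcr(sus, res) is expected


def test_aspcr_no_band_is_a_failed_reaction_never_susceptible():
    with pytest.raises(FailedReactionError):
        score_aspcr(False, False)


# ---------------------------------------------------------------------------
# codon calls from sequence


def test_iupac_table_matches_hand_written_expansion():
    for code in "ACGTRYSWKMBDHVN":
        assert IUPAC_EXPAND[code] == frozenset(iupac_expansion_oracle(code))


def _site_at(catalog, name):
    return catalog.site(name)


def test_single_ambiguity_resolves_to_the_two_catalog_codons(catalog):
    site = catalog.site("S989P")  # E20-21 columns [99, 102)
    region = catalog.region("E20-21")
    seq = list("A" * region.width)
    seq[99:102] = "YCC"  # Y = C/T: TCC (S) or CCC (P)
    call = call_site_from_sequence("".join(seq), site)
    assert call.status == "het"
    assert call.codons == ("CCC", "TCC")


def test_unambiguous_codon_is_homozygous(catalog):
    site = catalog.site("V1016I")
    region = catalog.region("E20-21")
    seq = list("A" * region.width)
    seq[442:445] = "ATA"
    call = call_site_from_sequence("".join(seq), site)
    assert call.status == "hom" and call.codons == ("ATA",)


@pytest.mark.parametrize("window,reason_part", [("T-C", "gap"), ("YYC", "more than one")])
def test_uncallable_codons(catalog, window, reason_part):
    site = catalog.site("S989P")
    region = catalog.region("E20-21")
    seq = list("A" * region.width)
    seq[99:102] = window
    call = call_site_from_sequence("".join(seq), site)
    assert call.status == "uncallable"
    assert reason_part in call.reason


# ---------------------------------------------------------------------------
# haplotype catalog


def test_identical_sequences_collapse_to_one_supported_haplotype(catalog):
    region = catalog.region("E6-8")
    seq = "A" * region.width
    cat = build_haplotype_catalog([(f"i{k}", seq) for k in range(4)], region)
    assert len(cat.haplotypes) == 1
    assert cat.support_count(cat.haplotypes[0].haplotype_id) == 4


def test_ids_follow_discovery_order(catalog):
    region = catalog.region("E6-8")
    s1 = "A" * region.width
    s2 = "C" + "A" * (region.width - 1)
    cat = build_haplotype_catalog([("i1", s1), ("i2", s2), ("i3", s1)], region)
    assert [h.haplotype_id for h in cat.haplotypes] == ["e1", "e2"]
    assert cat.haplotypes[0].aligned_sequence == s1


def test_mixed_alignment_widths_rejected(catalog):
    region = catalog.region("E6-8")
    with pytest.raises(InputError):
        build_haplotype_catalog([("i1", "A" * region.width), ("i2", "A" * 10)], region)


def test_ambiguous_sequences_are_set_aside_not_cataloged(catalog):
    region = catalog.region("E6-8")
    seq = "R" + "A" * (region.width - 1)
    cat = build_haplotype_catalog([("i1", seq)], region)
    assert not cat.haplotypes and cat.ambiguous == [("i1", seq)]


def test_simulated_input_recovers_planted_haplotype_count(study_dataset, study_result):
    """192 simulated individuals yield exactly the planted 7/9/11 haplotypes."""
    expected = study_dataset.truth.expected_haplotype_counts()
    got = {r: len(c.haplotypes) for r, c in study_result.catalogs.items()}
    assert got == expected == {"E6-8": 7, "E20-21": 9, "E31-32": 11}


# ---------------------------------------------------------------------------
# phasing


def _random_haplotypes(rng, n, width=40):
    haps = set()
    while len(haps) < n:
        haps.add("".join(rng.choice("ACGT") for _ in range(width)))
    return {f"h{i}": h for i, h in enumerate(sorted(haps))}


def _catalog_from(catalog, seqs):
    """Small E6-8-width catalog built from short core sequences padded with A."""
    region = catalog.region("E6-8")
    pad = "A" * (region.width - len(next(iter(seqs.values()))))
    records = [(f"ind_{k}", s + pad) for k, s in seqs.items()]
    return build_haplotype_catalog(records, region), pad


def test_phasing_recovers_the_unique_generating_pair(catalog):
    rng = random.Random(42)
    for trial in range(25):
        haps = _random_haplotypes(rng, rng.randint(2, 6))
        cat, pad = _catalog_from(catalog, haps)
        a, b = rng.sample(sorted(haps), 2)
        ambiguous = iupac_union(haps[a] + pad, haps[b] + pad)
        oracle_pairs = phase_pairs_oracle(ambiguous, {k: v + pad for k, v in haps.items()})
        res = phase_heterozygote(ambiguous, cat, population_scoped=False)
        if len(oracle_pairs) == 1:
            assert res.status == "resolved"
            got = {cat.by_id(h).aligned_sequence for h in res.pair}
            assert got == {haps[a] + pad, haps[b] + pad}
        else:
            assert res.status == "unresolved"


def test_unambiguous_sequence_phases_as_homozygote(catalog):
    haps = {"x": "ACGTACGT", "y": "ACGTACGA"}
    cat, pad = _catalog_from(catalog, haps)
    res = phase_heterozygote(haps["x"] + pad, cat, population_scoped=False)
    assert res.status == "resolved"
    assert res.pair[0] == res.pair[1]


def test_constructed_pair_collision_is_unresolved(catalog):
    # union(v1, v4) == union(v2, v3): two consistent pairs -> unresolved
    haps = {"v1": "AA", "v2": "AC", "v3": "CA", "v4": "CC"}
    cat, pad = _catalog_from(catalog, haps)
    ambiguous = iupac_union("AA" + pad, "CC" + pad)
    assert phase_pairs_oracle(
        ambiguous, {k: v + pad for k, v in haps.items()}
    ) == [("v1", "v4"), ("v2", "v3")]
    res = phase_heterozygote(ambiguous, cat, population_scoped=False)
    assert res.status == "unresolved"


def test_single_known_member_proposes_inferred_complement(catalog):
    haps = {"v1": "ACGTACGT"}
    cat, pad = _catalog_from(catalog, haps)
    other = "ACGTACGA"
    ambiguous = iupac_union(haps["v1"] + pad, other + pad)
    res = phase_heterozygote(ambiguous, cat, population_scoped=False)
    assert res.status == "new_inferred"
    assert res.proposed_sequence == other + pad


def test_indel_heterozygote_is_unresolved(catalog):
    haps = {"v1": "ACGTACGT", "v2": "ACG-ACGT"}
    cat, pad = _catalog_from(catalog, haps)
    assert iupac_union(haps["v1"] + pad, haps["v2"] + pad) is None
    res = phase_heterozygote("ACGNACGT" + pad, cat, population_scoped=False)
    assert res.status == "unresolved"


def test_population_scoped_phasing_ignores_foreign_haplotypes(catalog):
    region = catalog.region("E6-8")
    w = region.width
    s1, s2 = "A" * w, "C" + "A" * (w - 1)
    cat = build_haplotype_catalog(
        [("i1", s1), ("i2", s2)], region, {"i1": "popA", "i2": "popB"}
    )
    ambiguous = iupac_union(s1, s2)
    # scoped to popA the foreign haplotype is invisible: the trace is explained
    # as popA's haplotype plus a newly inferred complement, not resolved directly
    scoped = phase_heterozygote(ambiguous, cat, "popA")
    assert scoped.status == "new_inferred" and scoped.known_member == "e1"
    unscoped = phase_heterozygote(ambiguous, cat, "popA", population_scoped=False)
    assert unscoped.status == "resolved" and set(unscoped.pair) == {"e1", "e2"}


# ---------------------------------------------------------------------------
# inferred-haplotype validation


def _geno(indiv, pair, source="phased"):
    return DiploidRegionGenotype(indiv, "E6-8", pair, source)


def test_inferred_support_rule(catalog):
    region = catalog.region("E6-8")
    w = region.width
    direct = "A" * w
    inferred_ok = "C" + "A" * (w - 1)
    inferred_weak = "G" + "A" * (w - 1)
    cat = build_haplotype_catalog([("i1", direct)], region)
    h_ok = cat.add(inferred_ok, "i2", provenance="inferred")
    cat.support[h_ok.haplotype_id].add("i3")  # seen in two individuals
    h_weak = cat.add(inferred_weak, "i4", provenance="inferred")
    genotypes = [
        _geno("i1", ("e1", "e1"), "direct"),
        _geno("i2", ("e1", h_ok.haplotype_id)),
        _geno("i4", ("e1", h_weak.haplotype_id)),
    ]
    cat, genotypes = validate_inferred_haplotypes(cat, genotypes)
    ids = {h.haplotype_id for h in cat.haplotypes}
    assert h_ok.haplotype_id in ids  # support 2: retained
    assert h_weak.haplotype_id not in ids  # support 1: dropped
    assert genotypes[2].pair is None and genotypes[2].source == "unresolved"
    assert genotypes[1].pair is not None
    # a direct haplotype seen once is retained
    assert "e1" in ids
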