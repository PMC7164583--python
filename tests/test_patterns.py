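"""Pattern registry, assembly rules, allele frequencies, variation summary."""

import pandas as pd
import pytest

from kdrevo.domain import default_catalog
from kdrevo.genotyping import build_haplotype_catalog
from kdrevo.patterns import (
    IndividualGenotype,
    PatternComponents,
    PatternRegistry,
    assemble_patterns,
    compute_allele_frequencies,
    intron_group,
    intron_lengths,
    round_half_up,
    summarize_variation,
)


# ---------------------------------------------------------------------------
# helpers: a tiny hand-built world with two haplotypes per region


@pytest.fixture()
def toy(catalog):
    catalogs = {}
    base = {}
    alt = {}
    for region_name in ("E6-8", "E20-21", "E31-32"):
        region = catalog.region(region_name)
        seq = ["A"] * region.width
        for locus in catalog.region_loci(region_name):
            _, s, e = locus.location
            sus = sorted(locus.susceptible_codons)[0]
            seq[s:e] = list(sus)
        base[region_name] = "".join(seq)
        alt_seq = list(seq)
        alt_seq[region.features[1].start] = "C"  # one intron SNP
        alt[region_name] = "".join(alt_seq)
        catalogs[region_name] = build_haplotype_catalog(
            [("i0", base[region_name]), ("i1", alt[region_name])], region
        )
    return catalogs, base, alt


def _geno(indiv, pop, pairs, c410=("GTA", "GTA"), c1534=("TTC", "TTC")):
    return IndividualGenotype(indiv, pop, "Asia", pairs, c410, c1534)


HOM = {"E6-8": ("e1", "e1"), "E20-21": ("v1", "v1"), "E31-32": ("w1", "w1")}


def test_registry_is_injective_and_discovery_ordered(toy):
    catalogs, *_ = toy
    reg = PatternRegistry()
    c1 = PatternComponents("e1", "GTA", "v1", "TTC", "w1")
    c2 = PatternComponents("e2", "GTA", "v1", "TTC", "w1")
    p1 = reg.register(c1, catalogs)
    p2 = reg.register(c2, catalogs)
    p1_again = reg.register(c1, catalogs)
    assert (p1.p_id, p2.p_id) == ("P1", "P2")
    assert p1_again is p1
    assert len(reg) == 2


def test_pattern_concatenation_length_invariant(toy, catalog):
    catalogs, *_ = toy
    reg = PatternRegistry()
    p = reg.register(PatternComponents("e1", "GTA", "v1", "TTC", "w1"), catalogs)
    expected = sum(catalog.region(r).width for r in ("E6-8", "E20-21", "E31-32")) + 6
    assert len(p.concatenated_sequence) == expected == catalog.pattern_width


def test_homozygote_yields_one_pattern_counted_twice(toy):
    catalogs, *_ = toy
    reg, assignments = assemble_patterns([_geno("i0", "pop", HOM)], catalogs)
    assert assignments[0].patterns == ("P1", "P1")
    assert reg.patterns[0].count == 2


def test_single_heterozygous_component_is_forced_and_resolved(toy):
    catalogs, *_ = toy
    genos = [_geno("i0", "pop", HOM, c1534=("TTC", "TGC"))]
    reg, assignments = assemble_patterns(genos, catalogs)
    assert assignments[0].status == "resolved"
    alleles = sorted(str(p.allele) for p in reg)
    assert alleles == ["1534C", "susceptible"]


def test_double_heterozygote_needs_homozygote_backing(toy):
    catalogs, *_ = toy
    het = {"E6-8": ("e1", "e2"), "E20-21": ("v1", "v1"), "E31-32": ("w1", "w1")}
    unbacked = [_geno("iX", "pop", het, c1534=("TTC", "TGC"))]
    _, assignments = assemble_patterns(unbacked, catalogs)
    assert assignments[0].status == "unresolved"

    # with both full patterns seen in homozygotes of the same population,
    # the unique backed phasing is accepted
    h1 = {"E6-8": ("e1", "e1"), "E20-21": ("v1", "v1"), "E31-32": ("w1", "w1")}
    h2 = {"E6-8": ("e2", "e2"), "E20-21": ("v1", "v1"), "E31-32": ("w1", "w1")}
    genos = [
        _geno("a", "pop", h1),
        _geno("b", "pop", h2, c1534=("TGC", "TGC")),
        _geno("c", "pop", het, c1534=("TTC", "TGC")),
    ]
    reg, assignments = assemble_patterns(genos, catalogs)
    assert assignments[2].status == "resolved"
    assert len(set(assignments[2].patterns)) == 2


def test_backing_is_population_scoped(toy):
    catalogs, *_ = toy
    het = {"E6-8": ("e1", "e2"), "E20-21": ("v1", "v1"), "E31-32": ("w1", "w1")}
    h1 = {"E6-8": ("e1", "e1"), "E20-21": ("v1", "v1"), "E31-32": ("w1", "w1")}
    h2 = {"E6-8": ("e2", "e2"), "E20-21": ("v1", "v1"), "E31-32": ("w1", "w1")}
    genos = [
        _geno("a", "other", h1),
        _geno("b", "other", h2, c1534=("TGC", "TGC")),
        _geno("c", "pop", het, c1534=("TTC", "TGC")),
    ]
    _, assignments = assemble_patterns(genos, catalogs)
    assert assignments[2].status == "unresolved"


def test_unresolved_region_excludes_individual(toy):
    catalogs, *_ = toy
    pairs = dict(HOM)
    pairs["E20-21"] = None
    _, assignments = assemble_patterns([_geno("i0", "pop", pairs)], catalogs)
    assert assignments[0].status == "unresolved"
    assert "E20-21" in assignments[0].reason


# ---------------------------------------------------------------------------
# frequencies


@pytest.mark.parametrize(
    "count,total,text",
    [(1, 8, "0.13"), (5, 16, "0.31"), (14, 16, "0.88"), (1, 16, "0.06"), (16, 16, "1.00")],
)
def test_half_away_from_zero_rounding(count, total, text):
    assert round_half_up(count / total) == text


def test_frequency_table_counts_and_sums(toy):
    catalogs, *_ = toy
    genos = [
        _geno("a", "pop", HOM),
        _geno("b", "pop", HOM, c1534=("TGC", "TGC")),
        _geno("c", "pop", HOM, c1534=("TTC", "TGC")),
    ]
    reg, assignments = assemble_patterns(genos, catalogs)
    df = compute_allele_frequencies(reg, assignments)
    pop = df[df.population == "pop"]
    assert pop.chromosomes.sum() == 6  # 2 x 3 resolved individuals
    assert set(pop.allele) == {"susceptible", "1534C"}
    assert pop[pop.allele == "1534C"].chromosomes.iloc[0] == 3
    assert pop[pop.allele == "1534C"].frequency.iloc[0] == "0.50"
    # absent alleles are omitted, not printed as zero
    assert "410L" not in set(pop.allele)


def test_per_population_chromosome_totals(study_result, study_dataset):
    df = study_result.frequencies
    truth = study_dataset.truth
    for pop, group in df.groupby("population"):
        total = group.total_chromosomes.iloc[0]
        assert group.chromosomes.sum() == total
        assert abs(group.frequency_raw.sum() - 1.0) < 1e-9
        # frequencies match the planted chromosome draws exactly
        for _, row in group.iterrows():
            assert row.chromosomes == round(
                truth.planted_frequency(pop, row.allele) * total
            )


# ---------------------------------------------------------------------------
# variation summary


def test_identical_haplotypes_have_zero_variation(catalog):
    region = catalog.region("E6-8")
    seq = "A" * region.width
    cat = build_haplotype_catalog([("a", seq), ("b", seq)], region)
    df = summarize_variation(cat)
    assert df.snps.sum() == 0 and df.indel_events.sum() == 0


def test_one_shared_gap_run_is_one_indel_event_not_sixteen(catalog):
    region = catalog.region("E20-21")
    feat = region.feature("intron20")
    base = ["A"] * region.width
    for locus in catalog.region_loci("E20-21"):
        _, s, e = locus.location
        base[s:e] = list(sorted(locus.susceptible_codons)[0])
    gapped = list(base)
    for col in range(feat.start + 10, feat.start + 26):
        gapped[col] = "-"
    cat = build_haplotype_catalog([("a", "".join(base)), ("b", "".join(gapped))], region)
    df = summarize_variation(cat)
    intron = df[df.feature == "intron20"].iloc[0]
    assert intron.snps == 0 and intron.indel_events == 1


def test_planted_synonymy_classification(study_dataset, study_result):
    """Exon SNPs classify against codon translation: 3 syn + 1 nonsyn in exon
    20 (S989P), 2 nonsyn 1016 columns in exon 21, 14 syn + 1 nonsyn (Q1835R)
    in exon 32, one syn SNP in exon 7."""
    v = study_result.variation
    e20 = v["E20-21"].set_index("feature")
    assert (e20.loc["exon20", "synonymous"], e20.loc["exon20", "nonsynonymous"]) == (3, 1)
    assert (e20.loc["exon21", "synonymous"], e20.loc["exon21", "nonsynonymous"]) == (0, 2)
    e32 = v["E31-32"].set_index("feature")
    assert (e32.loc["exon32", "synonymous"], e32.loc["exon32", "nonsynonymous"]) == (14, 1)
    e7 = v["E6-8"].set_index("feature")
    assert (e7.loc["exon7", "synonymous"], e7.loc["exon7", "nonsynonymous"]) == (1, 0)
    # syn + nonsyn never exceeds the exon SNP count
    for df in v.values():
        exons = df[df.kind == "exon"]
        assert ((exons.synonymous + exons.nonsynonymous) <= exons.snps).all()


# ---------------------------------------------------------------------------
# intron groups


def test_intron_length_classes(study_result):
    lengths = study_result.intron_lengths["E20-21"]
    by_group = lengths.groupby("intron_group").intron_length.unique()
    assert list(by_group["A"]) == [250]
    assert list(by_group["B"]) == [234]
    assert list(by_group["other"]) == [233]
    assert (lengths.intron_group == "A").sum() == 3  # the v4/v8/v9-like class
    assert (lengths.intron_group == "other").sum() == 1


def test_intron_group_is_e2021_only(catalog):
    region = catalog.region("E6-8")
    cat = build_haplotype_catalog([("a", "A" * region.width)], region)
    with pytest.raises(Exception):
        intron_group(cat.haplotypes[0], region)
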