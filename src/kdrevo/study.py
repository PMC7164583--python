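"""Synthetic study-condition dataset: 26 collections, 192 mosquitoes, 33
pattern sequences over 7 + 9 + 11 region haplotypes.

This module plants, as ground truth, the headline structure of the study
system (it is a synthetic stand-in for the field collections and deposited
sequences, which are not bundled):

* region variation — E6-8: one synonymous SNP in exon 7, 37 SNPs and 12
  indel events in introns 6+7; E20-21: 3 synonymous + 1 nonsynonymous
  (S989P) SNPs in exon 20, two nonsynonymous 1016 columns in exon 21, 49
  SNPs and 20 indel events in intron 20; E31-32: 14 synonymous + 1
  nonsynonymous (Q1835R) substitutions in exon 32, 3 SNPs in intron 31;
* E20-21 intron length classes — group A 250 bp (v4/v8/v9-like), group B
  234 bp, plus one 233-bp B-variant;
* genealogy — a susceptible pattern one step from a 1534C pattern and two
  steps from a 410L pattern; a second susceptible background whose 1534C
  and 410L+1534C derivatives sit one and two steps away; a
  410L+1016I+1534C lineage two codon steps from its 1534C ancestor; and a
  410L+1534C pattern that is simultaneously a perfect single-crossover
  mosaic of the 410L and an independent 1534C pattern;
* allele frequencies per collection mirroring the study conditions
  (e.g. 1534C from 0.31 to 0.88 in Asia, 989P+1016G 0.13 to 0.50, a 410L
  frequency of 0.13 in SD, 410L+1534C at 0.06 in NO, the triple mutant
  fixed in LM).

Within each collection, co-segregating patterns are chosen so that odd
leftover chromosomes pair into single-component heterozygotes (resolvable
without cloning); the intron-20 indel diversity is arranged in
length-compensating runs so every group-B haplotype keeps its 234-bp class.
"""

from __future__ import annotations

from .simulate import (
    CrossoverPlan,
    FeatureTargets,
    FixedIndel,
    KdrVariant,
    PatternPlan,
    PopulationPlan,
    RegionPlan,
    SimulatedDataset,
    SimulationConfig,
    simulate,
)

V, L, F, C = "GTA", "TTA", "TTC", "TGC"

#: intron-20 deletion plan: every group-B member (indices 1-6) totals 16
#: deleted bp (the 233-bp variant, index 1, one extra), spread over 20
#: maximal runs so indel-event counting sees 20 events while intron length
#: classes stay exact.
_INTRON20_INDELS = [
    FixedIndel("intron20", 4, (1, 2, 3, 4, 5, 6)),
    FixedIndel("intron20", 6, (1, 2, 3)),
    FixedIndel("intron20", 6, (4, 5, 6)),
    FixedIndel("intron20", 2, (1,)),
    FixedIndel("intron20", 2, (1,)),
    FixedIndel("intron20", 2, (1,)),
    FixedIndel("intron20", 2, (2,)),
    FixedIndel("intron20", 2, (2,)),
    FixedIndel("intron20", 2, (2,)),
    FixedIndel("intron20", 3, (3,)),
    FixedIndel("intron20", 3, (3,)),
    FixedIndel("intron20", 2, (4,)),
    FixedIndel("intron20", 2, (4,)),
    FixedIndel("intron20", 2, (4,)),
    FixedIndel("intron20", 3, (5,)),
    FixedIndel("intron20", 3, (5,)),
    FixedIndel("intron20", 2, (6,)),
    FixedIndel("intron20", 2, (6,)),
    FixedIndel("intron20", 2, (6,)),
    FixedIndel("intron20", 1, (1,)),  # the single-nucleotide 233-bp deletion
]


def study_config() -> SimulationConfig:
    """The full study-condition simulation configuration."""
    region_plans = {
        "E6-8": RegionPlan(
            n_backgrounds=7,
            # indices 0 and 1 are a near-identical pair separated by exactly
            # one intron-6 SNP (the 410L background one step off its
            # susceptible relative)
            atoms=[(0, 1), (2,), (3,), (4,), (5,), (6,)],
            targets={
                "exon7": FeatureTargets(syn=1),
                "intron6": FeatureTargets(snps=22, indels=7),
                "intron7": FeatureTargets(snps=15, indels=5),
            },
            fixed_snp_carriers={"intron6": [(1,)]},
        ),
        "E20-21": RegionPlan(
            n_backgrounds=7,
            # index 0: group A (250 bp intron); 1: 233-bp B variant; 2-6: group B
            targets={
                "exon20": FeatureTargets(syn=3),
                "intron20": FeatureTargets(snps=49, indels=20),
            },
            fixed_indels=_INTRON20_INDELS,
            kdr_variants=[
                KdrVariant(0, {"989": "CCC", "1016": "GGA"}),  # index 7: 989P+1016G
                KdrVariant(0, {"1016": "ATA"}),  # index 8: 1016I
            ],
        ),
        "E31-32": RegionPlan(
            n_backgrounds=10,
            atoms=[(0, 1), (2,), (3,), (4,), (5,), (6,), (7,), (8,), (9,)],
            targets={
                "intron31": FeatureTargets(snps=3),
                "exon32": FeatureTargets(syn=14),
            },
            fixed_snp_carriers={"intron31": [(1,)]},
            kdr_variants=[KdrVariant(3, {"1835": "CGA"})],  # index 10: Q1835R
        ),
    }

    patterns = [
        # clade on the group-A E20-21 background
        PatternPlan("P26", 0, V, 0, F, 0),  # susceptible ancestor
        PatternPlan("P27", 0, V, 0, C, 0),  # 1534C, one step from P26
        PatternPlan("P28", 1, L, 0, F, 0),  # 410L, two steps from P26
        PatternPlan("P29", 0, L, 8, C, 0),  # 410L+1016I+1534C, two steps from P27
        PatternPlan("P30", 0, L, 8, C, 1),  # second triple-mutant pattern
        # clade on a group-B E20-21 background
        PatternPlan("P23", 1, V, 2, F, 1),  # susceptible ancestor
        PatternPlan("P24", 1, V, 2, C, 1),  # 1534C, one step from P23
        PatternPlan("P20", 3, V, 2, C, 1),  # independent 1534C pattern
        # P25 (410L+1534C) is planted below as the P28 x P20 crossover child;
        # it equals P23 + 410L + 1534C, so it is also two codon steps from P23
        PatternPlan("Pbridge", 0, V, 2, F, 0),  # susceptible stepping stone
        # Asian patterns
        PatternPlan("pA1", 2, V, 7, F, 2),  # 989P+1016G
        PatternPlan("pA2", 2, V, 1, C, 2),  # 1534C on the 233-bp background
        PatternPlan("pA3", 2, V, 2, C, 2),  # 1534C on a group-B background
        PatternPlan("pA4", 4, V, 0, C, 3),  # 1534C on a group-A background
        PatternPlan("pS2", 2, V, 0, F, 2),  # susceptible relative of pA1
        # Puerto Rico triple mutant carrying the Q1835R annotation
        PatternPlan("pPRQ", 3, L, 8, C, 10),
        # susceptible diversity fillers (lab strains, Africa, resistant-free pops)
        PatternPlan("pSD", 1, V, 0, F, 0),  # susceptible relative of P28 (SD)
        PatternPlan("pF1", 4, V, 3, F, 4),
        PatternPlan("pF2", 5, V, 4, F, 5),
        PatternPlan("pF3", 6, V, 5, F, 6),
        PatternPlan("pF4", 4, V, 6, F, 7),
        PatternPlan("pF5", 5, V, 3, F, 8),
        PatternPlan("pF6", 6, V, 6, F, 9),
        PatternPlan("pG1", 0, V, 0, F, 1),
        PatternPlan("pG2", 1, V, 2, F, 0),
        PatternPlan("pG3", 2, V, 3, F, 2),
        PatternPlan("pG4", 4, V, 4, F, 4),
        PatternPlan("pG5", 5, V, 5, F, 5),
        PatternPlan("pG6", 6, V, 3, F, 6),
        PatternPlan("pG7", 2, V, 4, F, 3),
        PatternPlan("pG8", 3, V, 5, F, 7),
        PatternPlan("pG9", 5, V, 6, F, 2),
        PatternPlan("pG10", 6, V, 4, F, 8),
    ]
    crossovers = [CrossoverPlan("P25", "P28", "P20")]

    populations = [
        # Asia: 1534C 0.31-0.88, 989P+1016G 0.13-0.50
        PopulationPlan("SP", "Asia", 8, {"pA3": 14, "pA1": 2}),
        PopulationPlan("SP0", "Asia", 8, {"pA3": 12, "pA1": 4}),
        PopulationPlan("NSK", "Asia", 8, {"pA2": 8, "pA1": 4, "Pbridge": 4}),
        PopulationPlan("BKK", "Asia", 8, {"pA2": 14, "pA1": 2}),
        PopulationPlan("UBN", "Asia", 8, {"pA3": 10, "pA1": 6}),
        PopulationPlan("SNI", "Asia", 8, {"pA4": 8, "pA1": 8}),
        PopulationPlan("CMI", "Asia", 8, {"pA2": 12, "pA1": 4}),
        PopulationPlan("KPP", "Asia", 8, {"pA3": 10, "pA1": 6}),
        PopulationPlan("HN", "Asia", 8, {"P27": 8, "pA1": 4, "P26": 4}),
        PopulationPlan("DZ", "Asia", 8, {"pA1": 8, "pA4": 6, "pS2": 2}),
        PopulationPlan("RL", "Asia", 8, {"P27": 10, "pA1": 4, "P26": 2}),
        PopulationPlan("XSBN", "Asia", 8, {"P27": 5, "pA1": 6, "P26": 5}),
        # Americas
        PopulationPlan("SMK", "America", 8, {"P26": 8, "pF1": 8}),
        PopulationPlan("OL", "America", 8, {"pF2": 8, "pF3": 8}),
        PopulationPlan("AT", "America", 8, {"pF4": 6, "pF5": 6, "pG9": 4}),
        PopulationPlan("NO", "America", 8, {"P24": 9, "P25": 1, "P23": 6}),
        PopulationPlan("RK", "America", 8, {"pF6": 8, "pG1": 8}),
        PopulationPlan("MN", "America", 8, {"P24": 8, "P23": 6, "pG7": 2}),
        PopulationPlan("LM", "America", 8, {"P29": 16}),
        PopulationPlan("PR", "America", 8, {"pPRQ": 12, "P20": 2, "pG8": 2}),
        PopulationPlan("CR", "America", 8, {"pG2": 6, "pG3": 6, "pG10": 4}),
        PopulationPlan("LA", "America", 4, {"P29": 6, "P27": 2}),
        PopulationPlan("SD", "America", 4, {"pSD": 3, "P28": 1, "P29": 4}),
        PopulationPlan("TE", "America", 4, {"P29": 4, "P30": 4}),
        PopulationPlan("MD", "America", 4, {"P29": 6, "P27": 2}),
        # Africa
        PopulationPlan("LVP", "Africa", 8, {"pG4": 6, "pG5": 6, "pG6": 4}),
    ]
    return SimulationConfig(region_plans, patterns, crossovers, populations)


def simulate_study(seed: int) -> SimulatedDataset:
    """Generate the full synthetic study dataset for one seed."""
    return simulate(study_config(), seed)
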