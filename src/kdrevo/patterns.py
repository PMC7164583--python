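"""Pattern sequences, the P-number registry, allele frequencies and
per-feature sequence-variation summaries.

A *pattern sequence* is the unit of genealogical analysis: the concatenation
of an individual chromosome's E6-8 haplotype, the residue-410 codon, the
E20-21 haplotype, the residue-1534 codon and the E31-32 haplotype.  Unique
patterns are numbered (P1, P2, ...) in the order they are discovered.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domain import (
    GAP,
    ConfigError,
    InputError,
    KdrAlleleLabel,
    RegionSpec,
    VsscCatalog,
    annotations_from_codons,
    classify_kdr_allele,
    default_catalog,
    translate_codon,
)
from .genotyping import HaplotypeCatalog, RegionHaplotype


def round_half_up(x: float, ndigits: int = 2) -> str:
    """Round half away from zero and format with fixed decimals (1/8 -> '0.13')."""
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PatternComponents:
    """The five components of a pattern sequence (haplotype ids and codons)."""

    e68: str
    codon410: str
    e2021: str
    codon1534: str
    e3132: str

    def as_tuple(self) -> tuple[str, str, str, str, str]:
        return (self.e68, self.codon410, self.e2021, self.codon1534, self.e3132)


@dataclass
class PatternSequence:
    """One registered pattern: components, concatenation, allele and sightings."""

    p_id: str
    components: PatternComponents
    concatenated_sequence: str
    allele: KdrAlleleLabel
    annotations: frozenset[str] = frozenset()
    observed_in: Counter = field(default_factory=Counter)  # (individual, population) -> chroms

    @property
    def count(self) -> int:
        return sum(self.observed_in.values())

    def populations(self) -> set[str]:
        return {pop for (_, pop) in self.observed_in}


def concatenate(
    e68_seq: str, codon410: str, e2021_seq: str, codon1534: str, e3132_seq: str
) -> str:
    return e68_seq + codon410 + e2021_seq + codon1534 + e3132_seq


class PatternRegistry:
    """Discovery-ordered registry of unique pattern sequences.

    Registration is injective on the concatenated sequence: re-registering an
    identical concatenation returns the existing P-number; a new one gets the
    next integer.  Stable under re-runs with identical input order.
    """

    def __init__(self, catalog: VsscCatalog | None = None) -> None:
        self.catalog = catalog or default_catalog()
        self.patterns: list[PatternSequence] = []
        self._by_seq: dict[str, PatternSequence] = {}

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def by_id(self, p_id: str) -> PatternSequence:
        for p in self.patterns:
            if p.p_id == p_id:
                return p
        raise InputError(f"no pattern {p_id} in registry")

    def lookup(self, concatenated: str) -> PatternSequence | None:
        return self._by_seq.get(concatenated.upper())

    def register(
        self,
        components: PatternComponents,
        catalogs: Mapping[str, HaplotypeCatalog],
        individual: str | None = None,
        population: str | None = None,
        chromosomes: int = 1,
    ) -> PatternSequence:
        """Register (or look up) a pattern and record the observation."""
        e68 = catalogs["E6-8"].by_id(components.e68).aligned_sequence
        e2021 = catalogs["E20-21"].by_id(components.e2021).aligned_sequence
        e3132 = catalogs["E31-32"].by_id(components.e3132).aligned_sequence
        concat = concatenate(
            e68, components.codon410, e2021, components.codon1534, e3132
        ).upper()
        pattern = self._by_seq.get(concat)
        if pattern is None:
            codon_states = self._codon_states(components, e2021, e3132)
            allele = classify_kdr_allele(codon_states, self.catalog)
            annotations = annotations_from_codons(
                {k: v for k, v in codon_states.items() if self.catalog.locus(k).annotation_only},
                self.catalog,
            )
            pattern = PatternSequence(
                f"P{len(self.patterns) + 1}", components, concat, allele, annotations
            )
            self.patterns.append(pattern)
            self._by_seq[concat] = pattern
        if individual is not None:
            pattern.observed_in[(individual, population or "")] += chromosomes
        return pattern

    def _codon_states(
        self, components: PatternComponents, e2021_seq: str, e3132_seq: str
    ) -> dict[str, str]:
        states = {"410": components.codon410, "1534": components.codon1534}
        for region_name, seq in (("E20-21", e2021_seq), ("E31-32", e3132_seq)):
            for locus in self.catalog.region_loci(region_name):
                _, start, end = locus.location
                codon = seq[start:end]
                if GAP in codon:
                    raise InputError(
                        f"gap inside kdr codon at locus {locus.key} of {region_name}"
                    )
                states[locus.key] = codon
        return states


# ---------------------------------------------------------------------------
# pattern assembly from diploid genotypes


@dataclass
class IndividualGenotype:
    """Everything known about one individual going into pattern assembly."""

    individual_id: str
    population: str
    continent: str
    region_pairs: Mapping[str, tuple[str, str] | None]  # region -> sorted hap-id pair
    codon410_pair: tuple[str, str] | None  # unordered codon pair from ASPCR
    codon1534_pair: tuple[str, str] | None


@dataclass
class PatternAssignment:
    """Patterns (1 or 2) carried by one individual, or the reason it is excluded."""

    individual_id: str
    population: str
    patterns: tuple[str, ...] = ()  # P-ids; one id repeated means homozygous
    status: str = "resolved"  # "resolved" | "unresolved"
    reason: str = ""


def _component_options(geno: IndividualGenotype) -> list[tuple[str, str]] | None:
    """Per-component unordered pairs in concatenation order, or None if any unresolved."""
    out = []
    for key in ("E6-8", "codon410", "E20-21", "codon1534", "E31-32"):
        if key == "codon410":
            pair = geno.codon410_pair
        elif key == "codon1534":
            pair = geno.codon1534_pair
        else:
            pair = geno.region_pairs.get(key)
        if pair is None:
            return None
        out.append(tuple(sorted(pair)))
    return out


def assemble_patterns(
    genotypes: Iterable[IndividualGenotype],
    catalogs: Mapping[str, HaplotypeCatalog],
    registry: PatternRegistry | None = None,
) -> tuple[PatternRegistry, list[PatternAssignment]]:
    """Assemble per-individual pattern sequences and build the P-number registry.

    Fully homozygous individuals define patterns directly (two chromosomes of
    one pattern).  An individual heterozygous at exactly one component has a
    forced phasing and is resolved unconditionally.  With two or more
    heterozygous components the cross-region linkage is ambiguous; the
    phasing is accepted only if exactly one of the 2**(k-1) possibilities
    yields two patterns both already seen in homozygotes of the same
    population.  Anything else is excluded from pattern counts (logged on the
    assignment).

    Homozygote-derived patterns are registered in input order first, so
    P-numbers follow discovery order.
    """
    registry = registry or PatternRegistry()
    genotypes = list(genotypes)
    assignments: dict[str, PatternAssignment] = {}
    #: patterns seen in homozygous individuals, per population
    homozygote_backed: dict[str, set[str]] = defaultdict(set)
    deferred: list[tuple[IndividualGenotype, list[tuple[str, str]], list[int]]] = []

    for geno in genotypes:
        options = _component_options(geno)
        if options is None:
            missing = [
                k
                for k in ("E6-8", "codon410", "E20-21", "codon1534", "E31-32")
                if (
                    geno.region_pairs.get(k) is None
                    if k not in ("codon410", "codon1534")
                    else getattr(geno, f"{k}_pair") is None
                )
            ]
            assignments[geno.individual_id] = PatternAssignment(
                geno.individual_id,
                geno.population,
                status="unresolved",
                reason=f"unresolved component(s): {', '.join(missing)}",
            )
            continue
        het_slots = [i for i, (a, b) in enumerate(options) if a != b]
        if not het_slots:
            comp = PatternComponents(*(pair[0] for pair in options))
            pattern = registry.register(
                comp, catalogs, geno.individual_id, geno.population, chromosomes=2
            )
            homozygote_backed[geno.population].add(pattern.p_id)
            assignments[geno.individual_id] = PatternAssignment(
                geno.individual_id, geno.population, (pattern.p_id, pattern.p_id)
            )
        else:
            deferred.append((geno, options, het_slots))

    for geno, options, het_slots in deferred:
        phasings = _enumerate_phasings(options, het_slots)
        if len(het_slots) == 1:
            chosen = phasings[0]  # forced: a single heterozygous component
        else:
            backed = homozygote_backed[geno.population]
            admissible = []
            for pair in phasings:
                pids = []
                for comp in pair:
                    existing = registry.lookup(_concat_components(comp, catalogs))
                    pids.append(existing.p_id if existing else None)
                if all(p is not None and p in backed for p in pids):
                    admissible.append(pair)
            if len(admissible) != 1:
                assignments[geno.individual_id] = PatternAssignment(
                    geno.individual_id,
                    geno.population,
                    status="unresolved",
                    reason=(
                        f"{len(het_slots)} heterozygous components; "
                        f"{len(admissible)} homozygote-backed phasings"
                    ),
                )
                continue
            chosen = admissible[0]
        pids = []
        for comp in chosen:
            pattern = registry.register(comp, catalogs, geno.individual_id, geno.population)
            pids.append(pattern.p_id)
        assignments[geno.individual_id] = PatternAssignment(
            geno.individual_id, geno.population, tuple(sorted(pids))
        )

    ordered = [assignments[g.individual_id] for g in genotypes]
    return registry, ordered


def _concat_components(comp: PatternComponents, catalogs: Mapping[str, HaplotypeCatalog]) -> str:
    return concatenate(
        catalogs["E6-8"].by_id(comp.e68).aligned_sequence,
        comp.codon410,
        catalogs["E20-21"].by_id(comp.e2021).aligned_sequence,
        comp.codon1534,
        catalogs["E31-32"].by_id(comp.e3132).aligned_sequence,
    ).upper()


def _enumerate_phasings(
    options: Sequence[tuple[str, str]], het_slots: Sequence[int]
) -> list[tuple[PatternComponents, PatternComponents]]:
    """All 2**(k-1) distinct chromosome phasings over the heterozygous slots."""
    out = []
    k = len(het_slots)
    for mask in range(2 ** max(k - 1, 0)):
        chrom_a, chrom_b = [], []
        free = 0
        for i, pair in enumerate(options):
            if i not in het_slots:
                chrom_a.append(pair[0])
                chrom_b.append(pair[0])
            elif i == het_slots[0]:
                chrom_a.append(pair[0])  # anchor first het slot to kill mirror phasings
                chrom_b.append(pair[1])
            else:
                bit = (mask >> free) & 1
                free += 1
                chrom_a.append(pair[bit])
                chrom_b.append(pair[1 - bit])
        out.append((PatternComponents(*chrom_a), PatternComponents(*chrom_b)))
    return out


# ---------------------------------------------------------------------------
# allele frequencies


def compute_allele_frequencies(
    registry: PatternRegistry,
    assignments: Sequence[PatternAssignment],
    continents: Mapping[str, str] | None = None,
    include_susceptible: bool = True,
) -> pd.DataFrame:
    """Per-population kdr allele frequencies from resolved individuals.

    Frequency = chromosome count / (2 x resolved individuals), rounded half
    away from zero to two decimals (the ``frequency`` column is the formatted
    string; ``frequency_raw`` keeps the float).  Alleles absent from a
    population are omitted, not printed as zero.  Populations with no
    resolved individual are omitted with a warning row in the caller's log.
    """
    continents = continents or {}
    by_pop: dict[str, Counter] = defaultdict(Counter)
    resolved: Counter = Counter()
    by_id = {p.p_id: p for p in registry}
    for a in assignments:
        if a.status != "resolved":
            continue
        resolved[a.population] += 1
        for pid in a.patterns:
            by_pop[a.population][str(by_id[pid].allele)] += 1
    rows = []
    for pop in sorted(by_pop):
        total = 2 * resolved[pop]
        for allele, count in sorted(by_pop[pop].items()):
            if allele == "susceptible" and not include_susceptible:
                continue
            rows.append(
                {
                    "population": pop,
                    "continent": continents.get(pop, ""),
                    "allele": allele,
                    "chromosomes": count,
                    "total_chromosomes": total,
                    "frequency_raw": count / total,
                    "frequency": round_half_up(count / total),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "population",
            "continent",
            "allele",
            "chromosomes",
            "total_chromosomes",
            "frequency_raw",
            "frequency",
        ],
    )
    return df


# ---------------------------------------------------------------------------
# variation summary


def intron_group(
    haplotype: RegionHaplotype, region: RegionSpec, groups: Mapping[str, int] | None = None
) -> str:
    """E20-21 intron length class: 250 bp -> 'A', 234 bp -> 'B', else 'other'."""
    if region.name != "E20-21":
        raise InputError("intron groups are defined for E20-21 only")
    groups = dict(groups or {"A": 250, "B": 234})
    length = _intron_length(haplotype.aligned_sequence, region)
    for name, nominal in groups.items():
        if length == nominal:
            return name
    return "other"


def _intron_length(seq: str, region: RegionSpec) -> int:
    return sum(
        len(seq[f.start:f.end]) - seq[f.start:f.end].count(GAP) for f in region.introns
    )


def _gap_runs(seqs: Sequence[str], start: int, end: int) -> list[tuple[int, int, frozenset[int]]]:
    """Maximal column runs within [start,end) sharing the same gapped-haplotype subset."""
    runs = []
    current: frozenset[int] | None = None
    run_start = start
    for col in range(start, end):
        gapped = frozenset(i for i, s in enumerate(seqs) if s[col] == GAP)
        if not gapped:
            key = None
        else:
            key = gapped
        if key != current:
            if current is not None:
                runs.append((run_start, col, current))
            current = key
            run_start = col
    if current is not None:
        runs.append((run_start, end, current))
    return runs


def summarize_variation(
    catalog: HaplotypeCatalog, region: RegionSpec | None = None
) -> pd.DataFrame:
    """Per-feature SNP / indel / synonymy counts over a region's haplotypes.

    A SNP is an alignment column with >= 2 distinct non-gap bases (gaps
    excluded from the comparison).  An indel event is a maximal run of
    columns in which the same subset of haplotypes is gapped — one biological
    deletion spanning k columns counts once.  Exon substitutions are
    classified synonymous/nonsynonymous codon-by-codon against the
    majority-consensus haplotype; multi-hit codons are classified by direct
    translation comparison of each observed variant codon.
    """
    region = region or catalog.region
    seqs = [h.aligned_sequence for h in catalog.haplotypes]
    if not seqs:
        raise InputError("empty catalog")
    for f in region.features:
        if f.end > len(seqs[0]):
            raise ConfigError(f"feature {f.name} outside the alignment")

    consensus = _majority_consensus(seqs)
    rows = []
    for feat in region.features:
        snp_cols = []
        for col in range(feat.start, feat.end):
            bases = {s[col] for s in seqs} - {GAP}
            if len(bases) >= 2:
                snp_cols.append(col)
        indel_events = len(_gap_runs(seqs, feat.start, feat.end))
        syn = nonsyn = 0
        if feat.kind == "exon":
            syn, nonsyn = _classify_exon_snps(seqs, consensus, feat, snp_cols)
        rows.append(
            {
                "region": region.name,
                "feature": feat.name,
                "kind": feat.kind,
                "snps": len(snp_cols),
                "indel_events": indel_events,
                "synonymous": syn if feat.kind == "exon" else pd.NA,
                "nonsynonymous": nonsyn if feat.kind == "exon" else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def intron_lengths(catalog: HaplotypeCatalog, region: RegionSpec | None = None) -> pd.DataFrame:
    """Ungapped intron length (and group, for E20-21) per haplotype."""
    region = region or catalog.region
    rows = []
    groups_apply = region.name == "E20-21"
    for h in catalog.haplotypes:
        row = {
            "region": region.name,
            "haplotype": h.haplotype_id,
            "intron_length": _intron_length(h.aligned_sequence, region),
        }
        if groups_apply:
            row["intron_group"] = intron_group(h, region)
        rows.append(row)
    return pd.DataFrame(rows)


def _majority_consensus(seqs: Sequence[str]) -> str:
    out = []
    for col in range(len(seqs[0])):
        counts = Counter(s[col] for s in seqs)
        # prefer bases over gap; deterministic tie-break by count then base
        ranked = sorted(counts.items(), key=lambda kv: (kv[0] == GAP, -kv[1], kv[0]))
        out.append(ranked[0][0])
    return "".join(out)


def _classify_exon_snps(
    seqs: Sequence[str], consensus: str, feat, snp_cols: Sequence[int]
) -> tuple[int, int]:
    """Count synonymous vs nonsynonymous SNP columns in one exon.

    Codons tile the feature from its start (the catalog's exon intervals are
    framed that way); a trailing partial codon is ignored.  A SNP column is
    nonsynonymous if any observed variant codon at its codon changes the
    translated residue relative to the consensus codon.
    """
    syn = nonsyn = 0
    n_codons = (feat.end - feat.start) // 3
    for col in snp_cols:
        codon_idx = (col - feat.start) // 3
        if codon_idx >= n_codons:
            continue  # trailing partial codon: cannot classify
        c_start = feat.start + 3 * codon_idx
        ref_codon = consensus[c_start:c_start + 3]
        if GAP in ref_codon:
            continue
        changes_aa = False
        for s in seqs:
            codon = s[c_start:c_start + 3]
            if GAP in codon or codon[col - c_start] == ref_codon[col - c_start]:
                continue
            if translate_codon(codon) != translate_codon(ref_codon):
                changes_aa = True
                break
        if changes_aa:
            nonsyn += 1
        else:
            syn += 1
    return syn, nonsyn
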