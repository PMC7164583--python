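"""Synthetic three-region *Vssc* datasets with planted ground truth.

The generator is event-ledger based rather than a full coalescent with
recombination: region haplotype pools are built from a random ancestral
sequence by an explicit ledger of substitution and deletion events, kdr
codon changes create resistance lineages, and crossover children splice two
parent patterns at a breakpoint between the 410 and 1534 codons.  Replaying
the ledger regenerates every emitted sequence byte-for-byte, which makes the
planted truth exact — the claims under test concern the topology of a
handful of events, not population-genetic realism.

Diploid sampling renders heterozygotes the way superimposed Sanger traces
look: IUPAC two-base codes where the haplotypes differ by substitution, and
unreadable positions where they differ by an indel (such individuals are
unresolvable downstream, as in the wet lab without cloning).  All randomness
flows from a single seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import (
    ConfigError,
    KdrAlleleLabel,
    VsscCatalog,
    classify_kdr_allele,
    default_catalog,
    translate_codon,
)
from .genotyping import IUPAC_CODE

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]


# ---------------------------------------------------------------------------
# event ledger


@dataclass(frozen=True)
class SnpEvent:
    region: str
    column: int
    ref: str
    alt: str
    carriers: tuple[int, ...]  # background indices carrying the alt base


@dataclass(frozen=True)
class IndelEvent:
    region: str
    start: int
    end: int
    carriers: tuple[int, ...]  # background indices gapped over [start, end)


@dataclass(frozen=True)
class KdrEvent:
    """A kdr codon change defining a new pool member derived from a background."""

    region: str
    base_index: int
    new_index: int
    locus: str
    codon: str


@dataclass(frozen=True)
class FixedIndel:
    feature: str
    length: int
    carriers: tuple[int, ...]


@dataclass(frozen=True)
class KdrVariant:
    base: int
    codons: Mapping[str, str]  # locus key -> codon


@dataclass
class FeatureTargets:
    """Planted diversity for one feature: intron SNPs/indel events, exon syn/nonsyn."""

    snps: int = 0
    indels: int = 0
    syn: int = 0
    nonsyn: int = 0


@dataclass
class RegionPlan:
    """How to build one region's haplotype pool."""

    n_backgrounds: int
    targets: dict[str, FeatureTargets] = field(default_factory=dict)
    #: groups of background indices that must stay identical except where a
    #: fixed-carrier event separates them (e.g. a pair differing by one SNP)
    atoms: list[tuple[int, ...]] | None = None
    fixed_snp_carriers: dict[str, list[tuple[int, ...]]] = field(default_factory=dict)
    fixed_indels: list[FixedIndel] = field(default_factory=list)
    kdr_variants: list[KdrVariant] = field(default_factory=list)

    @property
    def pool_size(self) -> int:
        return self.n_backgrounds + len(self.kdr_variants)


# ---------------------------------------------------------------------------
# region pool construction


def _ancestral_sequence(region, catalog: VsscCatalog, rng: np.random.Generator) -> str:
    """Random ancestral region sequence; exons are stop-free codon runs and
    kdr codon cells carry the susceptible catalog codon."""
    seq = [""] * region.width
    for feat in region.features:
        if feat.kind == "intron":
            for col in feat.columns:
                seq[col] = "ACGT"[rng.integers(4)]
        else:
            cols = list(feat.columns)
            for i in range(0, len(cols) - len(cols) % 3, 3):
                codon = _CODONS[rng.integers(len(_CODONS))]
                for k in range(3):
                    seq[cols[i + k]] = codon[k]
            for i in range(len(cols) - len(cols) % 3, len(cols)):
                seq[cols[i]] = "ACGT"[rng.integers(4)]
    for locus in catalog.region_loci(region.name):
        _, start, end = locus.location
        sus = sorted(locus.susceptible_codons)[0]
        for k in range(3):
            seq[start + k] = sus[k]
    return "".join(seq)


def _branch_subsets(
    rng: np.random.Generator, atoms: Sequence[tuple[int, ...]]
) -> list[tuple[int, ...]]:
    """Carrier subsets from a random coalescent-like branching over the atoms.

    A random binary topology is drawn by successive joins; every branch
    except the root defines a carrier subset (the tips beneath it).  Events
    assigned uniformly over branches then produce tree-like background
    divergence rather than equidistant noise.
    """
    if len(atoms) < 2:
        raise ConfigError("need >= 2 atoms to plant polymorphism")
    nodes = [frozenset(a) for a in atoms]
    subsets = list(nodes)  # pendant branches
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
        if len(nodes) > 1:
            subsets.append(merged)  # internal branch; the root carries nothing
    return [tuple(sorted(s)) for s in subsets]


def _random_carriers(
    rng: np.random.Generator, branches: Sequence[tuple[int, ...]]
) -> tuple[int, ...]:
    """One event's carriers: a uniformly chosen branch of the background tree."""
    return branches[int(rng.integers(len(branches)))]


def _synonymous_alternatives(codon: str) -> list[tuple[int, str]]:
    out = []
    aa = translate_codon(codon)
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and translate_codon(alt) == aa:
                out.append((pos, b))
    return out


def _nonsynonymous_alternatives(codon: str) -> list[tuple[int, str]]:
    out = []
    aa = translate_codon(codon)
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and translate_codon(alt) != aa:
                out.append((pos, b))
    return out


def build_region_pool(
    plan: RegionPlan,
    region,
    catalog: VsscCatalog,
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> tuple[str, list[str], list]:
    """Build one region's haplotype pool; returns (ancestral, pool, events).

    Backgrounds come first (indices 0..n-1) and kdr variants are appended in
    plan order.  Raises on infeasible diversity targets.
    """
    for feat_name, t in plan.targets.items():
        feat = region.feature(feat_name)
        need = t.snps + 3 * (t.syn + t.nonsyn) + 2 * t.indels
        if need > feat.end - feat.start:
            raise ConfigError(
                f"diversity target for {region.name}/{feat_name} exceeds feature size"
            )
    for attempt in range(max_attempts):
        try:
            return _try_build(plan, region, catalog, rng)
        except _RetryBuild:
            continue
    raise ConfigError(f"could not realize diversity plan for {region.name}")


class _RetryBuild(Exception):
    pass


def _try_build(plan, region, catalog, rng):
    ancestral = _ancestral_sequence(region, catalog, rng)
    n = plan.n_backgrounds
    atoms = plan.atoms or [(i,) for i in range(n)]
    covered = sorted(i for a in atoms for i in a)
    if covered != list(range(n)):
        raise ConfigError("atoms must partition the background indices")
    haps = [list(ancestral) for _ in range(n)]
    branches = _branch_subsets(rng, atoms)
    events: list = []

    kdr_cols: set[int] = set()
    for locus in catalog.region_loci(region.name):
        _, start, end = locus.location
        kdr_cols.update(range(start, end))
    used: set[int] = set(kdr_cols)
    run_blocked: set[int] = set()

    def place_run(feat, length) -> tuple[int, int]:
        for _ in range(2000):
            start = int(rng.integers(feat.start, feat.end - length + 1))
            cols = set(range(start - 1, start + length + 1))  # 1-col separation buffer
            if cols & (used | run_blocked):
                continue
            return start, start + length
        raise _RetryBuild

    def apply_indel(feat_name: str, length: int, carriers: tuple[int, ...]):
        feat = region.feature(feat_name)
        start, end = place_run(feat, length)
        for i in carriers:
            for col in range(start, end):
                haps[i][col] = "-"
        run_blocked.update(range(start - 1, end + 1))
        events.append(IndelEvent(region.name, start, end, tuple(sorted(carriers))))

    def apply_snp(feat_name: str, carriers: tuple[int, ...], col: int, alt: str):
        for i in carriers:
            haps[i][col] = alt
        used.add(col)
        events.append(SnpEvent(region.name, col, ancestral[col], alt, tuple(sorted(carriers))))

    for fi in plan.fixed_indels:
        apply_indel(fi.feature, fi.length, fi.carriers)

    for feat_name, t in plan.targets.items():
        feat = region.feature(feat_name)
        fixed = plan.fixed_snp_carriers.get(feat_name, [])
        n_random_indels = t.indels - sum(
            1 for fi in plan.fixed_indels if fi.feature == feat_name
        )
        if n_random_indels < 0:
            raise ConfigError(f"more fixed indels than target in {feat_name}")
        for _ in range(n_random_indels):
            apply_indel(feat_name, int(rng.integers(1, 7)), _random_carriers(rng, branches))

        if feat.kind == "intron":
            carrier_list = list(fixed) + [
                _random_carriers(rng, branches) for _ in range(t.snps - len(fixed))
            ]
            for carriers in carrier_list:
                col = _free_intron_col(rng, feat, used, run_blocked)
                alt = _other_base(rng, ancestral[col])
                apply_snp(feat_name, carriers, col, alt)
        else:
            for kind, count in (("syn", t.syn), ("nonsyn", t.nonsyn)):
                for _ in range(count):
                    col, alt = _codon_snp(
                        rng, feat, ancestral, used, run_blocked, kdr_cols, kind
                    )
                    apply_snp(feat_name, _random_carriers(rng, branches), col, alt)

    seqs = ["".join(h) for h in haps]
    # with zero planted events an identical pool is the intended outcome
    background_events = bool(events)
    if background_events and len(set(seqs)) != len(seqs):
        raise _RetryBuild  # duplicate backgrounds: re-draw carrier subsets

    for v_idx, variant in enumerate(plan.kdr_variants):
        base = list(seqs[variant.base])
        for locus_key, codon in variant.codons.items():
            locus = catalog.locus(locus_key)
            if locus.location is None or locus.location[0] != region.name:
                raise ConfigError(f"locus {locus_key} is not inside {region.name}")
            _, start, _ = locus.location
            for k in range(3):
                base[start + k] = codon[k]
        seqs.append("".join(base))
        events.append(
            KdrEvent(region.name, variant.base, n + v_idx, ",".join(sorted(variant.codons)),
                     ";".join(variant.codons[k] for k in sorted(variant.codons)))
        )
    if background_events:
        if len(set(seqs)) != len(seqs):
            raise _RetryBuild
    elif plan.kdr_variants:
        # identical backgrounds are fine, but variants must be distinguishable
        distinct = set(seqs[n:]) | {seqs[0]}
        if len(distinct) != len(plan.kdr_variants) + 1:
            raise _RetryBuild
    return ancestral, seqs, events


def _free_intron_col(rng, feat, used, run_blocked) -> int:
    for _ in range(2000):
        col = int(rng.integers(feat.start, feat.end))
        if col not in used and col not in run_blocked:
            return col
    raise _RetryBuild


def _other_base(rng, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(3)]


def _codon_snp(rng, feat, ancestral, used, run_blocked, kdr_cols, kind):
    n_codons = (feat.end - feat.start) // 3
    for _ in range(2000):
        ci = int(rng.integers(n_codons))
        start = feat.start + 3 * ci
        cols = set(range(start, start + 3))
        if cols & (used | run_blocked | kdr_cols):
            continue
        codon = ancestral[start:start + 3]
        alts = (
            _synonymous_alternatives(codon)
            if kind == "syn"
            else _nonsynonymous_alternatives(codon)
        )
        if not alts:
            continue
        pos, b = alts[rng.integers(len(alts))]
        # reserve the whole codon so no second hit lands in it
        used.update(cols)
        return start + pos, b
    raise _RetryBuild


def replay_events(
    ancestral: Mapping[str, str],
    events: Iterable,
    pool_sizes: Mapping[str, int],
) -> dict[str, list[str]]:
    """Re-derive every pool from the ancestral sequences and the event ledger."""
    pools = {r: [list(seq) for _ in range(pool_sizes[r])] for r, seq in ancestral.items()}
    for ev in events:
        if isinstance(ev, SnpEvent):
            for i in ev.carriers:
                pools[ev.region][i][ev.column] = ev.alt
        elif isinstance(ev, IndelEvent):
            for i in ev.carriers:
                for col in range(ev.start, ev.end):
                    pools[ev.region][i][col] = "-"
        elif isinstance(ev, KdrEvent):
            base = list(pools[ev.region][ev.base_index])
            loci = ev.locus.split(",")
            codons = ev.codon.split(";")
            cat = default_catalog()
            for lk, codon in zip(loci, codons):
                _, start, _ = cat.locus(lk).location
                for k in range(3):
                    base[start + k] = codon[k]
            pools[ev.region][ev.new_index] = base
    return {r: ["".join(h) for h in hs] for r, hs in pools.items()}


# ---------------------------------------------------------------------------
# patterns, crossovers, populations


@dataclass(frozen=True)
class PatternPlan:
    """A planted chromosome type: pool indices for the regions plus the codons."""

    name: str
    e68: int
    codon410: str
    e2021: int
    codon1534: str
    e3132: int


@dataclass(frozen=True)
class CrossoverPlan:
    """A planted single-crossover child.

    The breakpoint sits at the start of E20-21 on the concatenated pattern
    (immediately downstream of the 410 codon), so the child is expressible
    as components: left parent's E6-8 + 410 codon, right parent's E20-21 +
    1534 codon + E31-32.  This keeps the breakpoint strictly between the
    410 and 1534 codon coordinates.
    """

    name: str
    left: str
    right: str


@dataclass(frozen=True)
class PopulationPlan:
    name: str
    continent: str
    n_individuals: int
    #: exact chromosome counts per pattern name (sum == 2n), or frequencies
    composition: Mapping[str, float]
    mode: str = "exact"  # "exact" | "multinomial"


@dataclass
class SimulationConfig:
    region_plans: dict[str, RegionPlan]
    patterns: list[PatternPlan]
    crossovers: list[CrossoverPlan] = field(default_factory=list)
    populations: list[PopulationPlan] = field(default_factory=list)

    def validate(self) -> None:
        names = [p.name for p in self.patterns] + [c.name for c in self.crossovers]
        if len(set(names)) != len(names):
            raise ConfigError("pattern/crossover names must be unique")
        for pop in self.populations:
            unknown = set(pop.composition) - set(names)
            if unknown:
                raise ConfigError(f"{pop.name}: unknown patterns {sorted(unknown)}")
            if pop.mode == "exact":
                if sum(pop.composition.values()) != 2 * pop.n_individuals:
                    raise ConfigError(
                        f"{pop.name}: exact composition must sum to 2n chromosomes"
                    )
            else:
                total = sum(pop.composition.values())
                if not np.isclose(total, 1.0):
                    raise ConfigError(f"{pop.name}: frequencies must sum to 1")


@dataclass
class TrueHistory:
    """The simulator's ledger: everything needed to score the pipeline."""

    catalog: VsscCatalog
    ancestral: dict[str, str]
    pools: dict[str, list[str]]
    events: list
    pattern_components: dict[str, PatternPlan]
    crossover_children: dict[str, CrossoverPlan]
    drawn_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    chromosomes: dict[str, tuple[str, str]] = field(default_factory=dict)  # individual -> names

    def pattern_sequence(self, name: str) -> str:
        p = self.pattern_components[name]
        return (
            self.pools["E6-8"][p.e68]
            + p.codon410
            + self.pools["E20-21"][p.e2021]
            + p.codon1534
            + self.pools["E31-32"][p.e3132]
        )

    def pattern_allele(self, name: str) -> KdrAlleleLabel:
        p = self.pattern_components[name]
        states = {"410": p.codon410, "1534": p.codon1534}
        for locus in self.catalog.region_loci("E20-21"):
            _, s, e = locus.location
            states[locus.key] = self.pools["E20-21"][p.e2021][s:e]
        return classify_kdr_allele(states, self.catalog)

    def sampled_pattern_names(self) -> set[str]:
        return {
            name
            for counts in self.drawn_counts.values()
            for name, c in counts.items()
            if c > 0
        }

    def expected_pattern_count(self) -> int:
        seqs = {self.pattern_sequence(n) for n in self.sampled_pattern_names()}
        return len(seqs)

    def expected_haplotype_counts(self) -> dict[str, int]:
        out = {}
        for region, attr in (("E6-8", "e68"), ("E20-21", "e2021"), ("E31-32", "e3132")):
            idx = {
                getattr(self.pattern_components[n], attr)
                for n in self.sampled_pattern_names()
            }
            out[region] = len({self.pools[region][i] for i in idx})
        return out

    def planted_frequency(self, population: str, allele: str) -> float:
        counts = self.drawn_counts[population]
        total = sum(counts.values())
        hit = sum(
            c for name, c in counts.items() if str(self.pattern_allele(name)) == allele
        )
        return hit / total

    def population_alleles(self, population: str) -> set[str]:
        return {
            str(self.pattern_allele(n))
            for n, c in self.drawn_counts[population].items()
            if c > 0
        }


@dataclass
class SimulatedDataset:
    """Pipeline-ready synthetic inputs plus the ground truth."""

    sequences: dict[str, list[tuple[str, str]]]  # region -> [(individual, seq)]
    aspcr: pd.DataFrame
    metadata: pd.DataFrame
    truth: TrueHistory


def simulate(config: SimulationConfig, seed: int) -> SimulatedDataset:
    """Run the full generative model from a single seed."""
    config.validate()
    catalog = default_catalog()
    rng = np.random.default_rng(seed)

    ancestral: dict[str, str] = {}
    pools: dict[str, list[str]] = {}
    events: list = []
    for region_name, plan in config.region_plans.items():
        region = catalog.region(region_name)
        anc, pool, evs = build_region_pool(plan, region, catalog, rng)
        ancestral[region_name] = anc
        pools[region_name] = pool
        events.extend(evs)

    components: dict[str, PatternPlan] = {p.name: p for p in config.patterns}
    crossovers: dict[str, CrossoverPlan] = {}
    for c in config.crossovers:
        left, right = components[c.left], components[c.right]
        components[c.name] = PatternPlan(
            c.name, left.e68, left.codon410, right.e2021, right.codon1534, right.e3132
        )
        crossovers[c.name] = c

    truth = TrueHistory(catalog, ancestral, pools, events, components, crossovers)
    seqs_by_plan = {name: truth.pattern_sequence(name) for name in components}
    if len(set(seqs_by_plan.values())) != len(seqs_by_plan):
        raise ConfigError("planted patterns are not pairwise distinct")

    seq_records: dict[str, list[tuple[str, str]]] = {r: [] for r in config.region_plans}
    aspcr_rows = []
    meta_rows = []
    for pop in config.populations:
        chrom_names = _draw_chromosomes(pop, rng)
        pairs = _pair_chromosomes(chrom_names)
        counts: dict[str, int] = {}
        for name in chrom_names:
            counts[name] = counts.get(name, 0) + 1
        truth.drawn_counts[pop.name] = counts
        for i, (na, nb) in enumerate(pairs, start=1):
            indiv = f"{pop.name}_{i:03d}"
            truth.chromosomes[indiv] = (na, nb)
            meta_rows.append(
                {"individual": indiv, "population": pop.name, "continent": pop.continent}
            )
            pa, pb = components[na], components[nb]
            for region_name, attr in (
                ("E6-8", "e68"),
                ("E20-21", "e2021"),
                ("E31-32", "e3132"),
            ):
                h1 = pools[region_name][getattr(pa, attr)]
                h2 = pools[region_name][getattr(pb, attr)]
                seq_records[region_name].append((indiv, _render_diploid(h1, h2)))
            for site, attr in (("V410L", "codon410"), ("F1534C", "codon1534")):
                locus = catalog.locus("410" if site == "V410L" else "1534")
                sus = locus.susceptible_codons
                c1, c2 = getattr(pa, attr), getattr(pb, attr)
                aspcr_rows.append(
                    {
                        "individual": indiv,
                        "population": pop.name,
                        "continent": pop.continent,
                        "site": site,
                        "band_S": int(c1 in sus or c2 in sus),
                        "band_R": int(c1 not in sus or c2 not in sus),
                    }
                )
    aspcr = pd.DataFrame(aspcr_rows)
    metadata = pd.DataFrame(meta_rows)
    return SimulatedDataset(seq_records, aspcr, metadata, truth)


def _draw_chromosomes(pop: PopulationPlan, rng: np.random.Generator) -> list[str]:
    names = list(pop.composition)
    if pop.mode == "exact":
        out = []
        for name in names:
            out.extend([name] * int(pop.composition[name]))
        return out
    probs = np.array([pop.composition[n] for n in names], dtype=float)
    counts = rng.multinomial(2 * pop.n_individuals, probs / probs.sum())
    out = []
    for name, c in zip(names, counts):
        out.extend([name] * int(c))
    return out


def _pair_chromosomes(chrom_names: Sequence[str]) -> list[tuple[str, str]]:
    """Pair same-pattern chromosomes first; leftovers pair in listed order."""
    counts: dict[str, int] = {}
    for n in chrom_names:
        counts[n] = counts.get(n, 0) + 1
    pairs = []
    leftovers = []
    for name, c in counts.items():
        pairs.extend([(name, name)] * (c // 2))
        if c % 2:
            leftovers.append(name)
    for a, b in zip(leftovers[::2], leftovers[1::2]):
        pairs.append((a, b))
    if len(leftovers) % 2:
        raise ConfigError("odd total chromosome count cannot be paired")
    return pairs


def _render_diploid(h1: str, h2: str) -> str:
    """Superimposed-trace rendering of a diploid region genotype."""
    if h1 == h2:
        return h1
    out = []
    for a, b in zip(h1, h2):
        if a == b:
            out.append(a)
        elif "-" in (a, b):
            out.append("N")  # frame-shifted trace: unreadable position
        else:
            out.append(IUPAC_CODE[frozenset((a, b))])
    return "".join(out)


# ---------------------------------------------------------------------------
# ready-made study configurations


def roundtrip_config(recombination: bool = False) -> SimulationConfig:
    """A compact multi-population study used by the round-trip tests.

    Plants the allele inventory of the study system (susceptible, 1534C,
    989P+1016G, 410L, 410L+1016I+1534C, and optionally a 410L+1534C
    crossover child) over three small haplotype pools.  Structure
    populations use exact even chromosome counts so every planted pattern is
    observed in homozygotes; two frequency populations draw multinomially
    from patterns differing at a single component, so heterozygotes are
    always resolvable and the frequency estimator can be scored against
    binomial sampling error.
    """
    region_plans = {
        "E6-8": RegionPlan(
            n_backgrounds=3,
            targets={
                "intron6": FeatureTargets(snps=6, indels=2),
                "intron7": FeatureTargets(snps=4, indels=1),
                "exon7": FeatureTargets(syn=1),
            },
        ),
        "E20-21": RegionPlan(
            n_backgrounds=3,
            targets={
                "intron20": FeatureTargets(snps=8, indels=3),
                "exon20": FeatureTargets(syn=1),
            },
            fixed_indels=[FixedIndel("intron20", 16, (1, 2))],  # group B intron class
            kdr_variants=[
                KdrVariant(0, {"989": "CCC", "1016": "GGA"}),  # index 3: 989P+1016G
                KdrVariant(0, {"1016": "ATA"}),  # index 4: 1016I
            ],
        ),
        "E31-32": RegionPlan(
            n_backgrounds=3,
            targets={
                "intron31": FeatureTargets(snps=3),
                "exon32": FeatureTargets(syn=2),
            },
        ),
    }
    V, L, F, C = "GTA", "TTA", "TTC", "TGC"
    patterns = [
        PatternPlan("sus_a", 0, V, 0, F, 0),
        PatternPlan("sus_b", 1, V, 1, F, 1),
        PatternPlan("c1534_a", 0, V, 0, C, 0),
        PatternPlan("c1534_b", 1, V, 1, C, 1),
        PatternPlan("pg_asia", 0, V, 3, F, 0),  # 989P+1016G on sus_a background
        PatternPlan("triple", 0, L, 4, C, 0),  # 410L+1016I+1534C from c1534_a
        PatternPlan("l410", 2, L, 2, F, 2),  # 410L on a divergent background
    ]
    crossovers = []
    sp2 = {"sus_b": 8, "l410": 4, "c1534_b": 4}
    if recombination:
        crossovers.append(CrossoverPlan("xchild", "l410", "c1534_b"))
        sp2 = {"sus_b": 4, "l410": 4, "c1534_b": 4, "xchild": 4}
    populations = [
        PopulationPlan("SP1", "Asia", 8, {"sus_a": 8, "c1534_a": 4, "triple": 4}),
        PopulationPlan("SP2", "America", 8, sp2),
        PopulationPlan("SP3", "Asia", 8, {"pg_asia": 8, "sus_a": 8}),
        PopulationPlan(
            "FP1", "Asia", 12, {"sus_a": 0.5, "c1534_a": 0.5}, mode="multinomial"
        ),
        PopulationPlan(
            "FP2", "Asia", 12, {"sus_a": 0.6, "pg_asia": 0.4}, mode="multinomial"
        ),
    ]
    return SimulationConfig(region_plans, patterns, crossovers, populations)
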