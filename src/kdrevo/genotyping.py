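"""Per-individual genotyping: ASPCR scoring, Sanger-style sequence calls,
haplotype catalogs and comparison-based phasing of heterozygotes.

A *haplotype* is the unique allele of one sequenced region (E6-8, E20-21 or
E31-32).  Direct (unambiguous) sequences come from homozygotes; heterozygous
individuals show IUPAC ambiguity codes wherever their two haplotypes differ,
and are phased by comparison against haplotypes already known from the same
population.  Phasing is exhaustive over catalog pairs — catalogs hold at most
a few dozen haplotypes, so no statistical phasing is needed or wanted.
Indel heterozygotes (superimposed traces after an indel) are not phased; they
are reported unresolved.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Data import IUPACData

from .domain import (
    GAP,
    AlignmentError,
    FailedReactionError,
    InputError,
    KdrSite,
    Locus,
    RegionSpec,
)

#: base -> expansion set, and frozenset of bases -> IUPAC code
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    code.upper(): frozenset(bases.upper())
    for code, bases in IUPACData.ambiguous_dna_values.items()
}
IUPAC_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPAND.items()}

UNAMBIGUOUS = frozenset("ACGT-")


class SiteGenotype(str, enum.Enum):
    """Diploid genotype at one ASPCR-typed kdr site."""

    SS = "SS"  # homozygous susceptible
    RS = "RS"  # heterozygous
    RR = "RR"  # homozygous resistant


@dataclass(frozen=True)
class AspcrResult:
    """Raw allele-specific PCR band calls for one individual at one site."""

    individual_id: str
    site_name: str
    band_susceptible: bool
    band_resistant: bool

    @property
    def genotype(self) -> SiteGenotype:
        return score_aspcr(self.band_susceptible, self.band_resistant)


def score_aspcr(band_susceptible: bool, band_resistant: bool) -> SiteGenotype:
    """Score an ASPCR reaction from its two bands.

    A band only with the susceptible primer is homozygous susceptible, only
    with the resistance (kdr) primer homozygous resistant, and with both
    heterozygous.  No band at all is a failed reaction and raises — it is
    never silently treated as susceptible.
    """
    if band_susceptible and band_resistant:
        return SiteGenotype.RS
    if band_susceptible:
        return SiteGenotype.SS
    if band_resistant:
        return SiteGenotype.RR
    raise FailedReactionError("no ASPCR band with either primer; re-genotype the sample")


def aspcr_codon_pair(locus: Locus, genotype: SiteGenotype) -> tuple[str, str]:
    """The unordered codon pair implied by an ASPCR genotype at a standalone locus."""
    sus = sorted(locus.susceptible_codons)[0]
    res_codons = sorted(c for c, r in locus.codon_states.items() if r in locus.resistance_residues)
    if not res_codons:
        raise InputError(f"locus {locus.key} has no catalog resistance codon")
    res = res_codons[0]
    if genotype is SiteGenotype.SS:
        return (sus, sus)
    if genotype is SiteGenotype.RR:
        return (res, res)
    return (sus, res)


# ---------------------------------------------------------------------------
# sequence-based site calls


@dataclass(frozen=True)
class CodonCall:
    """Result of reading one kdr codon from a (possibly ambiguous) sequence."""

    status: str  # "hom" | "het" | "uncallable"
    codons: tuple[str, ...] = ()
    reason: str = ""


def call_site_from_sequence(aligned_seq: str, site: KdrSite | Locus) -> CodonCall:
    """Read the codon at a kdr site from an aligned region sequence.

    A single IUPAC two-base ambiguity inside the codon is resolved into the
    heterozygous codon pair it implies; more than one ambiguous position (or
    a three/four-base code) cannot be phased from one trace and is uncallable,
    as is a gap inside the codon.
    """
    if site.location is None:
        raise InputError(f"site {getattr(site, 'site_name', site)} is standalone; use ASPCR")
    _, start, end = site.location
    if end > len(aligned_seq):
        raise InputError("site lies outside the sequence")
    window = aligned_seq[start:end].upper()
    if GAP in window:
        return CodonCall("uncallable", reason="gap inside codon")
    ambiguous = [i for i, ch in enumerate(window) if ch not in "ACGT"]
    for i in ambiguous:
        if window[i] not in IUPAC_EXPAND:
            return CodonCall("uncallable", reason=f"invalid base {window[i]!r}")
    if not ambiguous:
        return CodonCall("hom", (window,))
    if len(ambiguous) > 1:
        return CodonCall("uncallable", reason="more than one ambiguous codon position")
    i = ambiguous[0]
    bases = sorted(IUPAC_EXPAND[window[i]])
    if len(bases) != 2:
        return CodonCall("uncallable", reason=f"{window[i]} expands to {len(bases)} bases")
    codons = tuple(sorted(window[:i] + b + window[i + 1:] for b in bases))
    return CodonCall("het", codons)


# ---------------------------------------------------------------------------
# haplotype catalog


@dataclass
class RegionHaplotype:
    """A unique aligned sequence for one amplicon, with a discovery-order id."""

    region: str
    haplotype_id: str
    aligned_sequence: str
    provenance: str = "direct"  # "direct" | "inferred"

    def __post_init__(self) -> None:
        self.aligned_sequence = self.aligned_sequence.upper()
        bad = set(self.aligned_sequence) - UNAMBIGUOUS
        if bad:
            raise InputError(f"haplotype contains ambiguity codes: {sorted(bad)}")

    @property
    def ungapped_length(self) -> int:
        return len(self.aligned_sequence) - self.aligned_sequence.count(GAP)


_REGION_PREFIX = {"E6-8": "e", "E20-21": "v", "E31-32": "w"}


@dataclass
class HaplotypeCatalog:
    """Discovery-ordered haplotypes of one region, with observation support.

    ``support`` counts individuals in which each haplotype was observed
    (directly or by phasing); ``populations`` records where.  Inferred
    haplotypes (proposed during phasing, never seen in a homozygote or clone)
    must be supported by more than one individual to be retained.
    """

    region: RegionSpec
    haplotypes: list[RegionHaplotype] = field(default_factory=list)
    support: dict[str, set[str]] = field(default_factory=dict)  # hap_id -> individuals
    populations: dict[str, set[str]] = field(default_factory=dict)  # hap_id -> populations
    ambiguous: list[tuple[str, str]] = field(default_factory=list)  # (individual, seq)

    def _check_width(self, seq: str) -> None:
        if len(seq) != self.region.width:
            raise InputError(
                f"sequence width {len(seq)} != {self.region.name} alignment width "
                f"{self.region.width}"
            )

    def by_id(self, hap_id: str) -> RegionHaplotype:
        for h in self.haplotypes:
            if h.haplotype_id == hap_id:
                return h
        raise InputError(f"no haplotype {hap_id} in {self.region.name} catalog")

    def lookup(self, seq: str) -> RegionHaplotype | None:
        seq = seq.upper()
        for h in self.haplotypes:
            if h.aligned_sequence == seq:
                return h
        return None

    def add(
        self,
        seq: str,
        individual: str | None = None,
        population: str | None = None,
        provenance: str = "direct",
    ) -> RegionHaplotype:
        """Record an observation, creating a new haplotype if the sequence is new."""
        seq = seq.upper()
        self._check_width(seq)
        hap = self.lookup(seq)
        if hap is None:
            prefix = _REGION_PREFIX.get(self.region.name, "h")
            hap = RegionHaplotype(
                self.region.name, f"{prefix}{len(self.haplotypes) + 1}", seq, provenance
            )
            self.haplotypes.append(hap)
            self.support[hap.haplotype_id] = set()
            self.populations[hap.haplotype_id] = set()
        elif provenance == "direct" and hap.provenance == "inferred":
            hap.provenance = "direct"
        if individual is not None:
            self.support[hap.haplotype_id].add(individual)
        if population is not None:
            self.populations[hap.haplotype_id].add(population)
        return hap

    def support_count(self, hap_id: str) -> int:
        return len(self.support.get(hap_id, ()))

    def in_population(self, population: str) -> list[RegionHaplotype]:
        return [h for h in self.haplotypes if population in self.populations.get(h.haplotype_id, ())]


def is_ambiguous(seq: str) -> bool:
    return bool(set(seq.upper()) - UNAMBIGUOUS)


def build_haplotype_catalog(
    sequences: Iterable[tuple[str, str]],
    region: RegionSpec,
    populations: Mapping[str, str] | None = None,
) -> HaplotypeCatalog:
    """Catalog the unique unambiguous sequences of one region.

    Ids are assigned in first-observation order and are a deterministic
    function of input order.  Sequences containing IUPAC ambiguity codes
    (heterozygotes) are set aside in ``catalog.ambiguous`` for phasing.
    """
    populations = populations or {}
    catalog = HaplotypeCatalog(region)
    for individual, seq in sequences:
        seq = seq.upper()
        if len(seq) != region.width:
            raise InputError(
                f"{individual}: sequence width {len(seq)} != {region.name} width {region.width}"
            )
        if is_ambiguous(seq):
            catalog.ambiguous.append((individual, seq))
            continue
        catalog.add(seq, individual, populations.get(individual))
    return catalog


# ---------------------------------------------------------------------------
# phasing


def iupac_union(h1: str, h2: str) -> str | None:
    """Render the superimposed Sanger trace of two aligned haplotypes.

    Columns where the haplotypes share a base stay plain; columns where they
    differ become the two-base IUPAC code.  A gap in exactly one haplotype has
    no single-column rendering (frame-shifted superimposed traces) — returns
    None, the caller treats the pair as not phaseable by comparison.
    """
    if len(h1) != len(h2):
        raise AlignmentError("haplotypes must share alignment width")
    out = []
    for a, b in zip(h1.upper(), h2.upper()):
        if a == b:
            out.append(a)
        elif GAP in (a, b):
            return None
        else:
            out.append(IUPAC_CODE[frozenset((a, b))])
    return "".join(out)


@dataclass(frozen=True)
class PhaseResult:
    """Outcome of phasing one ambiguous region sequence."""

    status: str  # "resolved" | "new_inferred" | "unresolved"
    pair: tuple[str, str] | None = None  # haplotype ids (unordered, sorted)
    proposed_sequence: str | None = None  # complement proposed as inferred haplotype
    known_member: str | None = None
    reason: str = ""


def _complement_against(ambiguous: str, hap: str) -> str | None:
    """The haplotype that, together with ``hap``, would produce ``ambiguous``."""
    out = []
    for obs, a in zip(ambiguous.upper(), hap.upper()):
        if obs in "ACGT-":
            if obs != a:
                return None
            out.append(obs)
        else:
            bases = IUPAC_EXPAND.get(obs)
            if bases is None or len(bases) != 2 or a not in bases:
                return None
            (other,) = bases - {a}
            out.append(other)
    return "".join(out)


def phase_heterozygote(
    ambiguous_seq: str,
    catalog: HaplotypeCatalog,
    population: str | None = None,
    population_scoped: bool = True,
) -> PhaseResult:
    """Phase an ambiguous sequence by comparison with known haplotypes.

    All unordered pairs of candidate haplotypes are tried; the pair whose
    site-wise IUPAC union reproduces the observed sequence wins if unique.
    If no pair works but exactly one catalog haplotype is consistent with the
    trace, its complement is proposed as a new *inferred* haplotype (subject
    to the support >= 2 rule applied later).  Multiple consistent solutions
    are reported unresolved — the wet-lab fallback was cloning, which is not
    modelled.

    By default only haplotypes already observed in the same population are
    consulted; pass ``population_scoped=False`` for a global-catalog fallback.
    """
    if not catalog.haplotypes:
        return PhaseResult("unresolved", reason="empty catalog")
    catalog._check_width(ambiguous_seq)
    ambiguous_seq = ambiguous_seq.upper()
    if population_scoped and population is not None:
        candidates = catalog.in_population(population)
    else:
        candidates = list(catalog.haplotypes)
    if not is_ambiguous(ambiguous_seq):
        hap = catalog.lookup(ambiguous_seq)
        if hap is not None and hap in candidates:
            return PhaseResult("resolved", (hap.haplotype_id, hap.haplotype_id))
        return PhaseResult("unresolved", reason="unambiguous sequence not in catalog scope")

    pairs = []
    for i, h1 in enumerate(candidates):
        for h2 in candidates[i:]:
            union = iupac_union(h1.aligned_sequence, h2.aligned_sequence)
            if union == ambiguous_seq:
                pairs.append(tuple(sorted((h1.haplotype_id, h2.haplotype_id))))
    if len(pairs) == 1:
        return PhaseResult("resolved", pairs[0])
    if len(pairs) > 1:
        return PhaseResult(
            "unresolved", reason=f"multiple consistent pairs: {sorted(pairs)}"
        )

    proposals = []
    for h in candidates:
        comp = _complement_against(ambiguous_seq, h.aligned_sequence)
        if comp is not None and comp != h.aligned_sequence:
            proposals.append((h.haplotype_id, comp))
    if len(proposals) == 1:
        known, comp = proposals[0]
        return PhaseResult("new_inferred", known_member=known, proposed_sequence=comp)
    if len(proposals) > 1:
        return PhaseResult("unresolved", reason="multiple single-member solutions")
    return PhaseResult("unresolved", reason="inconsistent with every catalog haplotype")


# ---------------------------------------------------------------------------
# diploid genotypes and inferred-haplotype validation


@dataclass
class DiploidRegionGenotype:
    """Resolved (or not) haplotype pair of one individual at one region."""

    individual_id: str
    region: str
    pair: tuple[str, str] | None  # haplotype ids, sorted; None if unresolved
    source: str  # "direct" | "phased" | "unresolved"
    raw_sequence: str | None = None
    reason: str = ""

    @property
    def resolved(self) -> bool:
        return self.pair is not None


def validate_inferred_haplotypes(
    catalog: HaplotypeCatalog, genotypes: Sequence[DiploidRegionGenotype]
) -> tuple[HaplotypeCatalog, list[DiploidRegionGenotype]]:
    """Drop inferred haplotypes seen in fewer than two individuals.

    Genotypes that relied on a dropped haplotype revert to unresolved.  Direct
    haplotypes (observed in a homozygote or clone) are kept regardless of
    support.  Ids of retained haplotypes are preserved.
    """
    dropped = {
        h.haplotype_id
        for h in catalog.haplotypes
        if h.provenance == "inferred" and catalog.support_count(h.haplotype_id) < 2
    }
    catalog.haplotypes = [h for h in catalog.haplotypes if h.haplotype_id not in dropped]
    for hid in dropped:
        catalog.support.pop(hid, None)
        catalog.populations.pop(hid, None)
    out = []
    for g in genotypes:
        if g.pair is not None and (g.pair[0] in dropped or g.pair[1] in dropped):
            out.append(
                replace(
                    g,
                    pair=None,
                    source="unresolved",
                    reason="relied on an inferred haplotype with support < 2",
                )
            )
        else:
            out.append(g)
    return catalog, out
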