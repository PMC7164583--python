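"""Core domain model for the *Aedes aegypti* Vssc pyrethroid-resistance analysis.

The voltage-sensitive sodium channel gene (*Vssc*) is the target of pyrethroid
insecticides; point mutations in it cause knockdown resistance (*kdr*).  The
analysis works on three amplified regions of the gene (E6-8, E20-21, E31-32)
plus two standalone codons (residues 410 and 1534, genotyped by allele-specific
PCR).  This module holds the region alignment architecture, the catalog of kdr
codon states, and the classification of a full codon genotype into a resistance
allele label such as ``410L+1016I+1534C``.

Residue numbers follow the house-fly VSSC numbering convention throughout; they
are labels, never sequence coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table

DNA_BASES = frozenset("ACGT")
GAP = "-"

#: residues 410 and 1534 are genotyped as standalone codons (ASPCR), the other
#: catalog residues live inside the sequenced regions.
REQUIRED_LOCI = ("410", "989", "1016", "1534")


class KdrError(Exception):
    """Base class for all package errors."""


class InputError(KdrError):
    """Malformed user input (sequences, tables, codons)."""


class ConfigError(KdrError):
    """Invalid configuration (catalog, thresholds, simulation plans)."""


class IncompleteGenotypeError(KdrError):
    """A genotype is missing a locus required for allele classification."""


class FailedReactionError(KdrError):
    """An ASPCR reaction produced no band; the sample needs re-genotyping."""


class AlignmentError(KdrError):
    """Sequences that should share an alignment architecture do not."""


class NonCatalogCodonWarning(UserWarning):
    """A kdr-site codon was not in the catalog and was translated instead."""


def translate_codon(codon: str) -> str:
    """Translate one DNA codon with the standard genetic code ('*' for stop)."""
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= DNA_BASES:
        raise InputError(f"not a DNA codon: {codon!r}")
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class Feature:
    """One exon or intron on a region alignment (half-open column interval)."""

    name: str
    kind: str  # "exon" | "intron"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ConfigError(f"feature kind must be exon/intron, got {self.kind}")
        if not 0 <= self.start < self.end:
            raise ConfigError(f"bad feature interval {self.name}: [{self.start},{self.end})")

    @property
    def columns(self) -> range:
        return range(self.start, self.end)


@dataclass(frozen=True)
class RegionSpec:
    """Alignment architecture of one sequenced Vssc amplicon."""

    name: str
    features: tuple[Feature, ...]
    width: int
    nominal_length: int

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate feature names in {self.name}")
        pos = 0
        for f in self.features:
            if f.start != pos:
                raise ConfigError(
                    f"features of {self.name} must tile the alignment; "
                    f"gap/overlap at column {pos} (feature {f.name})"
                )
            pos = f.end
        if pos != self.width:
            raise ConfigError(f"features of {self.name} do not cover width {self.width}")

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise ConfigError(f"region {self.name} has no feature {name!r}")

    @property
    def exons(self) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.kind == "exon")

    @property
    def introns(self) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.kind == "intron")


@dataclass(frozen=True)
class KdrSite:
    """A named kdr mutation site (e.g. V410L) anchored to a codon locus.

    ``codon_states`` maps catalog codons to residue symbols.  Sites whose
    mutant codon is not documented in the source literature are carried as
    translate-only sites: any non-catalog codon is translated with the
    standard genetic code and flagged.
    """

    site_name: str
    residue_number: int
    codon_states: Mapping[str, str]
    susceptible_codons: frozenset[str]
    resistance_residues: Mapping[str, str]  # residue symbol -> mutation name
    location: tuple[str, int, int] | None  # (region, start, end); None = standalone
    annotation_only: bool = False

    @property
    def standalone(self) -> bool:
        return self.location is None


@dataclass(frozen=True, order=True)
class Mutation:
    """One resistance mutation, ordered by residue number then symbol."""

    residue: int
    symbol: str

    @property
    def name(self) -> str:
        return f"{self.residue}{self.symbol}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class KdrAlleleLabel:
    """Canonical label for a set of resistance mutations on one chromosome."""

    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(set(self.mutations)))
        object.__setattr__(self, "mutations", ordered)

    @property
    def display(self) -> str:
        if not self.mutations:
            return "susceptible"
        return "+".join(m.name for m in self.mutations)

    @property
    def is_susceptible(self) -> bool:
        return not self.mutations

    def __str__(self) -> str:
        return self.display

    def __len__(self) -> int:
        return len(self.mutations)

    def mutation_names(self) -> frozenset[str]:
        return frozenset(m.name for m in self.mutations)

    @classmethod
    def parse(cls, text: str) -> "KdrAlleleLabel":
        text = text.strip()
        if text in ("", "susceptible"):
            return cls(())
        muts = []
        for part in text.split("+"):
            part = part.strip()
            digits = "".join(ch for ch in part if ch.isdigit())
            symbol = part[len(digits):]
            if not digits or not symbol:
                raise InputError(f"cannot parse allele label component {part!r}")
            muts.append(Mutation(int(digits), symbol))
        return cls(tuple(muts))


SUSCEPTIBLE = KdrAlleleLabel(())


@dataclass(frozen=True)
class Locus:
    """A codon locus shared by one or more named kdr sites (e.g. 1016 G/I)."""

    key: str
    residue: int
    codon_states: Mapping[str, str]
    susceptible_codons: frozenset[str]
    resistance_residues: Mapping[str, str]
    location: tuple[str, int, int] | None
    annotation_only: bool

    @property
    def standalone(self) -> bool:
        return self.location is None

    @property
    def susceptible_residue(self) -> str:
        return translate_codon(next(iter(self.susceptible_codons)))


@dataclass(frozen=True)
class VsscCatalog:
    """Versioned catalog of regions, codon loci and named kdr sites."""

    version: str
    regions: Mapping[str, RegionSpec]
    loci: Mapping[str, Locus]
    sites: Mapping[str, KdrSite]
    intron_groups: Mapping[str, int] = field(default_factory=dict)

    def region(self, name: str) -> RegionSpec:
        try:
            return self.regions[name]
        except KeyError:
            raise ConfigError(f"unknown region {name!r}") from None

    def site(self, name: str) -> KdrSite:
        try:
            return self.sites[name]
        except KeyError:
            raise ConfigError(f"unknown kdr site {name!r}") from None

    def locus(self, key: int | str) -> Locus:
        try:
            return self.loci[str(key)]
        except KeyError:
            raise ConfigError(f"unknown kdr locus {key!r}") from None

    def region_loci(self, region: str) -> tuple[Locus, ...]:
        """Codon loci lying inside one region alignment, left to right."""
        hits = [l for l in self.loci.values() if l.location and l.location[0] == region]
        return tuple(sorted(hits, key=lambda l: l.location[1]))

    @property
    def pattern_width(self) -> int:
        """Width of the concatenated pattern coordinate system."""
        return sum(r.width for r in self.regions.values()) + 6

    def concat_offsets(self) -> dict[str, int]:
        """Start column of each component on the concatenated pattern."""
        e68, e2021, e3132 = (self.regions[n].width for n in ("E6-8", "E20-21", "E31-32"))
        return {
            "E6-8": 0,
            "codon410": e68,
            "E20-21": e68 + 3,
            "codon1534": e68 + 3 + e2021,
            "E31-32": e68 + 3 + e2021 + 3,
        }


def _build_catalog(raw: dict) -> VsscCatalog:
    regions = {}
    for rname, rd in raw["regions"].items():
        feats = tuple(Feature(f["name"], f["kind"], f["start"], f["end"]) for f in rd["features"])
        regions[rname] = RegionSpec(rname, feats, rd["width"], rd["nominal_length"])
    loci = {}
    for key, ld in raw["loci"].items():
        loc = ld["location"]
        location = None if loc == "standalone" else (loc["region"], loc["start"], loc["end"])
        loci[key] = Locus(
            key=key,
            residue=ld["residue"],
            codon_states=dict(ld["codon_states"]),
            susceptible_codons=frozenset(ld["susceptible_codons"]),
            resistance_residues=dict(ld["resistance_residues"]),
            location=location,
            annotation_only=ld.get("annotation_only", False),
        )
    sites = {}
    for sname, sd in raw["sites"].items():
        locus = loci[sd["locus"]]
        sites[sname] = KdrSite(
            site_name=sname,
            residue_number=locus.residue,
            codon_states=locus.codon_states,
            susceptible_codons=locus.susceptible_codons,
            resistance_residues=locus.resistance_residues,
            location=locus.location,
            annotation_only=locus.annotation_only,
        )
    groups = {k: int(v) for k, v in raw.get("intron_groups", {}).get("groups", {}).items()}
    return VsscCatalog(raw["version"], regions, loci, sites, groups)


def load_catalog(path: str | None = None) -> VsscCatalog:
    """Load the codon/region catalog (packaged default, or a user JSON file)."""
    if path is None:
        text = resources.files("kdrevo.data").joinpath("vssc_catalog.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return _build_catalog(json.loads(text))


_DEFAULT: VsscCatalog | None = None


def default_catalog() -> VsscCatalog:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_catalog()
    return _DEFAULT


def codon_to_residue(site: KdrSite | Locus, codon: str) -> str:
    """Map a codon at a kdr site to its residue symbol.

    Catalog codons use the catalog mapping; anything else is translated with
    the standard genetic code and flagged with :class:`NonCatalogCodonWarning`
    so novel variants are surfaced rather than silently misclassified.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= DNA_BASES:
        raise InputError(f"kdr-site codon must be 3 unambiguous DNA bases, got {codon!r}")
    if codon in site.codon_states:
        return site.codon_states[codon]
    residue = translate_codon(codon)
    name = site.site_name if isinstance(site, KdrSite) else f"locus {site.key}"
    warnings.warn(
        f"codon {codon} at {name} is not in the catalog; translated to {residue}",
        NonCatalogCodonWarning,
        stacklevel=2,
    )
    return residue


def classify_kdr_allele(
    codon_states: Mapping[int | str, str],
    catalog: VsscCatalog | None = None,
) -> KdrAlleleLabel:
    """Derive the resistance-allele label from per-locus codon states.

    ``codon_states`` maps residue numbers (or string keys) to codons, e.g.
    ``{410: "TTA", 989: "TCC", 1016: "ATA", 1534: "TGC"}`` ->
    ``410L+1016I+1534C``.  Loci 410, 989, 1016 and 1534 are required.
    Annotation-only loci (Q1835R) never contribute to the label.
    """
    catalog = catalog or default_catalog()
    provided = {str(k): v for k, v in codon_states.items()}
    missing = [k for k in REQUIRED_LOCI if k not in provided]
    if missing:
        raise IncompleteGenotypeError(f"missing required loci: {', '.join(missing)}")
    muts: list[Mutation] = []
    for key, codon in provided.items():
        locus = catalog.locus(key)
        if locus.annotation_only:
            continue
        residue = codon_to_residue_locus(locus, codon)
        if residue in locus.resistance_residues:
            muts.append(Mutation(locus.residue, residue))
    return KdrAlleleLabel(tuple(muts))


def codon_to_residue_locus(locus: Locus, codon: str) -> str:
    """Locus-level variant of :func:`codon_to_residue` (same semantics)."""
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= DNA_BASES:
        raise InputError(f"kdr-site codon must be 3 unambiguous DNA bases, got {codon!r}")
    if codon in locus.codon_states:
        return locus.codon_states[codon]
    residue = translate_codon(codon)
    warnings.warn(
        f"codon {codon} at locus {locus.key} is not in the catalog; translated to {residue}",
        NonCatalogCodonWarning,
        stacklevel=2,
    )
    return residue


def annotations_from_codons(
    codon_states: Mapping[int | str, str], catalog: VsscCatalog | None = None
) -> frozenset[str]:
    """Mutation names at annotation-only loci (e.g. Q1835R), kept off the label."""
    catalog = catalog or default_catalog()
    out = set()
    for key, codon in codon_states.items():
        locus = catalog.locus(key)
        if not locus.annotation_only:
            continue
        residue = codon_to_residue_locus(locus, codon)
        if residue in locus.resistance_residues:
            out.add(f"{locus.residue}{residue}")
    return frozenset(out)
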