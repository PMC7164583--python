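"""Orchestration and file I/O: raw inputs -> haplotype catalogs -> pattern
registry -> allele frequencies, variation summaries, parsimony network and
evolutionary-scenario report.

Input formats: one multi-FASTA per region (record ids ``individual|region``),
ASPCR band calls and collection metadata as TSV.  All output tables are TSV
with documented columns; the network is exported as GraphML and DOT.  All
file coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .domain import (
    FailedReactionError,
    InputError,
    KdrAlleleLabel,
    VsscCatalog,
    default_catalog,
)
from .genotyping import (
    DiploidRegionGenotype,
    HaplotypeCatalog,
    build_haplotype_catalog,
    phase_heterozygote,
    score_aspcr,
    aspcr_codon_pair,
    validate_inferred_haplotypes,
)
from .inference import ScenarioCall, classify_scenarios
from .network import (
    ParsimonyNetwork,
    build_network,
    minimum_origins,
    to_dot,
    to_graphml,
)
from .patterns import (
    IndividualGenotype,
    PatternRegistry,
    assemble_patterns,
    compute_allele_frequencies,
    intron_lengths,
    summarize_variation,
)
from .simulate import SimulatedDataset

log = logging.getLogger("kdrevo")

REGIONS = ("E6-8", "E20-21", "E31-32")
ASPCR_COLUMNS = ("individual", "population", "continent", "site", "band_S", "band_R")
METADATA_COLUMNS = ("individual", "population", "continent")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, recorded in the run log."""

    region_fastas: Mapping[str, str | Path]
    aspcr_path: str | Path
    metadata_path: str | Path
    output_dir: str | Path | None = None
    catalog_path: str | None = None
    parsimony_threshold: float = 0.95
    count_indels: bool = True
    population_scoped_phasing: bool = True
    include_susceptible: bool = True

    def flags(self) -> dict:
        return {
            "parsimony_threshold": self.parsimony_threshold,
            "count_indels": self.count_indels,
            "population_scoped_phasing": self.population_scoped_phasing,
            "include_susceptible": self.include_susceptible,
        }


@dataclass
class PipelineResult:
    catalogs: dict[str, HaplotypeCatalog]
    genotypes: dict[str, list[DiploidRegionGenotype]]
    registry: PatternRegistry
    assignments: list
    frequencies: pd.DataFrame
    variation: dict[str, pd.DataFrame]
    intron_lengths: dict[str, pd.DataFrame]
    network: ParsimonyNetwork
    origins: dict[str, int]
    scenarios: list[ScenarioCall]
    warnings: list[str] = field(default_factory=list)

    def pattern_sequences(self) -> dict[str, str]:
        return {p.p_id: p.concatenated_sequence for p in self.registry}

    def pattern_alleles(self) -> dict[str, KdrAlleleLabel]:
        return {p.p_id: p.allele for p in self.registry}


# ---------------------------------------------------------------------------
# readers / writers


def read_region_fasta(path: str | Path, region: str) -> list[tuple[str, str]]:
    """Read one region's multi-FASTA; ids are ``individual|region``."""
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if "|" in rid:
            indiv, rregion = rid.split("|", 1)
            if rregion != region:
                raise InputError(f"{path}: record {rid} is not for region {region}")
        else:
            indiv = rid
        if indiv in seen:
            raise InputError(f"{path}: duplicate individual id {indiv!r}")
        seen.add(indiv)
        out.append((indiv, str(rec.seq).upper()))
    if not out:
        log.warning("%s: empty FASTA", path)
    return out


def write_region_fasta(records: Sequence[tuple[str, str]], region: str, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=f"{indiv}|{region}", description="") for indiv, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset in the exact formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for region, records in dataset.sequences.items():
        p = outdir / f"{region.replace('-', '_')}.fasta"
        write_region_fasta(records, region, p)
        paths[region] = p
    paths["aspcr"] = outdir / "aspcr.tsv"
    dataset.aspcr.to_csv(paths["aspcr"], sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.tsv"
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# stages


def genotype_region(
    records: Sequence[tuple[str, str]],
    region_name: str,
    populations: Mapping[str, str],
    catalog: VsscCatalog | None = None,
    population_scoped: bool = True,
) -> tuple[HaplotypeCatalog, list[DiploidRegionGenotype]]:
    """Catalog direct haplotypes, then phase the ambiguous individuals."""
    catalog = catalog or default_catalog()
    region = catalog.region(region_name)
    hap_catalog = build_haplotype_catalog(records, region, populations)
    genotypes: dict[str, DiploidRegionGenotype] = {}
    for indiv, seq in records:
        hap = hap_catalog.lookup(seq)
        if hap is not None:
            genotypes[indiv] = DiploidRegionGenotype(
                indiv, region_name, (hap.haplotype_id, hap.haplotype_id), "direct"
            )
    for indiv, seq in hap_catalog.ambiguous:
        pop = populations.get(indiv)
        res = phase_heterozygote(seq, hap_catalog, pop, population_scoped)
        if res.status == "resolved":
            pair = res.pair
        elif res.status == "new_inferred":
            new = hap_catalog.add(res.proposed_sequence, provenance="inferred")
            pair = tuple(sorted((res.known_member, new.haplotype_id)))
        else:
            genotypes[indiv] = DiploidRegionGenotype(
                indiv, region_name, None, "unresolved", raw_sequence=seq, reason=res.reason
            )
            continue
        for hid in set(pair):
            hap_catalog.support[hid].add(indiv)
            if pop is not None:
                hap_catalog.populations[hid].add(pop)
        genotypes[indiv] = DiploidRegionGenotype(indiv, region_name, pair, "phased")
    ordered = [genotypes[i] for i, _ in records]
    hap_catalog, ordered = validate_inferred_haplotypes(hap_catalog, ordered)
    return hap_catalog, ordered


def aspcr_genotypes(
    aspcr: pd.DataFrame, catalog: VsscCatalog
) -> dict[str, dict[str, tuple[str, str] | None]]:
    """Per-individual codon pairs at the two standalone loci from band calls."""
    out: dict[str, dict[str, tuple[str, str] | None]] = {}
    site_locus = {"V410L": "410", "F1534C": "1534"}
    for _, row in aspcr.iterrows():
        indiv = row["individual"]
        site = row["site"]
        locus = catalog.locus(site_locus[site])
        try:
            geno = score_aspcr(bool(int(row["band_S"])), bool(int(row["band_R"])))
            pair = aspcr_codon_pair(locus, geno)
        except FailedReactionError:
            pair = None
        out.setdefault(indiv, {})[site_locus[site]] = pair
    return out


def analyze(
    sequences: Mapping[str, Sequence[tuple[str, str]]],
    aspcr: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    catalog: VsscCatalog | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    catalog = catalog or default_catalog()
    config = config or PipelineConfig({}, "", "")
    if metadata["individual"].duplicated().any():
        raise InputError("duplicate individual ids in metadata")
    populations = dict(zip(metadata["individual"], metadata["population"]))
    continents = dict(zip(metadata["population"], metadata["continent"]))
    warnings_log: list[str] = []

    catalogs: dict[str, HaplotypeCatalog] = {}
    genotypes: dict[str, list[DiploidRegionGenotype]] = {}
    for region in REGIONS:
        if region not in sequences:
            raise InputError(f"missing sequences for region {region}")
        cat, genos = genotype_region(
            sequences[region], region, populations, catalog,
            config.population_scoped_phasing,
        )
        catalogs[region] = cat
        genotypes[region] = genos
        for g in genos:
            if not g.resolved:
                warnings_log.append(f"{g.individual_id}/{region}: unresolved ({g.reason})")

    codons = aspcr_genotypes(aspcr, catalog)
    geno_by_region = {r: {g.individual_id: g for g in genotypes[r]} for r in REGIONS}
    indiv_genotypes: list[IndividualGenotype] = []
    for _, row in metadata.iterrows():
        indiv = row["individual"]
        region_pairs = {}
        for r in REGIONS:
            g = geno_by_region[r].get(indiv)
            region_pairs[r] = g.pair if g is not None else None
        site_pairs = codons.get(indiv, {})
        indiv_genotypes.append(
            IndividualGenotype(
                indiv,
                row["population"],
                row["continent"],
                region_pairs,
                site_pairs.get("410"),
                site_pairs.get("1534"),
            )
        )
    registry, assignments = assemble_patterns(indiv_genotypes, catalogs)
    for a in assignments:
        if a.status != "resolved":
            warnings_log.append(f"{a.individual_id}: excluded from patterns ({a.reason})")

    frequencies = compute_allele_frequencies(
        registry, assignments, continents, config.include_susceptible
    )
    variation = {r: summarize_variation(catalogs[r]) for r in REGIONS}
    lengths = {r: intron_lengths(catalogs[r]) for r in REGIONS}

    counts = {p.p_id: p.count for p in registry}
    attributes = {
        p.p_id: {
            "allele": str(p.allele),
            "continent": _majority_continent(p, continents),
        }
        for p in registry
    }
    network = build_network(
        {p.p_id: p.concatenated_sequence for p in registry},
        counts,
        threshold=config.parsimony_threshold,
        count_indels=config.count_indels,
        attributes=attributes,
    )
    alleles = {p.p_id: p.allele for p in registry}
    origins: dict[str, int] = {}
    for mutation in sorted({m.name for a in alleles.values() for m in a.mutations}):
        states = {
            pid: ("derived" if mutation in a.mutation_names() else "ancestral")
            for pid, a in alleles.items()
        }
        origins[mutation] = minimum_origins(network, states, "derived")

    scenarios = classify_scenarios(
        {p.p_id: p.concatenated_sequence for p in registry}, alleles
    )
    return PipelineResult(
        catalogs,
        genotypes,
        registry,
        assignments,
        frequencies,
        variation,
        lengths,
        network,
        origins,
        scenarios,
        warnings_log,
    )


def _majority_continent(pattern, continents: Mapping[str, str]) -> str:
    tally: dict[str, int] = {}
    for (_, pop), c in pattern.observed_in.items():
        cont = continents.get(pop, "")
        tally[cont] = tally.get(cont, 0) + c
    if not tally:
        return ""
    return sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


# ---------------------------------------------------------------------------
# end-to-end run with file I/O


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read inputs, run :func:`analyze`, and write the artifact bundle."""
    sequences = {}
    for region in REGIONS:
        path = config.region_fastas.get(region)
        if path is None or not Path(path).exists():
            raise InputError(f"missing input FASTA for region {region}")
        sequences[region] = read_region_fasta(path, region)
    aspcr = read_table(config.aspcr_path, ASPCR_COLUMNS)
    metadata = read_table(config.metadata_path, METADATA_COLUMNS)
    catalog = default_catalog() if config.catalog_path is None else None
    result = analyze(sequences, aspcr, metadata, config, catalog)
    if config.output_dir is not None:
        write_bundle(result, config, Path(config.output_dir))
    return result


def write_bundle(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.frequencies.to_csv(outdir / "allele_frequencies.tsv", sep="\t", index=False)
    pd.concat(result.variation.values()).to_csv(
        outdir / "variation_summary.tsv", sep="\t", index=False
    )
    pd.concat(result.intron_lengths.values()).to_csv(
        outdir / "intron_lengths.tsv", sep="\t", index=False
    )
    registry_rows = []
    for p in result.registry:
        registry_rows.append(
            {
                "p_id": p.p_id,
                "e68_haplotype": p.components.e68,
                "codon_410": p.components.codon410,
                "e2021_haplotype": p.components.e2021,
                "codon_1534": p.components.codon1534,
                "e3132_haplotype": p.components.e3132,
                "allele": str(p.allele),
                "annotations": "+".join(sorted(p.annotations)),
                "chromosomes": p.count,
                "populations": ",".join(sorted(p.populations())),
            }
        )
    pd.DataFrame(registry_rows).to_csv(outdir / "pattern_registry.tsv", sep="\t", index=False)

    geno_rows = []
    for region, genos in result.genotypes.items():
        for g in genos:
            geno_rows.append(
                {
                    "individual": g.individual_id,
                    "region": region,
                    "haplotype_1": g.pair[0] if g.pair else "",
                    "haplotype_2": g.pair[1] if g.pair else "",
                    "source": g.source,
                    "reason": g.reason,
                }
            )
    pd.DataFrame(geno_rows).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)

    to_graphml(result.network, str(outdir / "network.graphml"))
    to_dot(result.network, str(outdir / "network.dot"))

    scen_rows = [
        {
            "allele": s.allele,
            "verdict": s.verdict,
            "sequential_evidence": ";".join(s.sequential_evidence),
            "n_recombination_candidates": len(s.recombination_candidates),
        }
        for s in result.scenarios
    ]
    pd.DataFrame(scen_rows).to_csv(outdir / "scenarios.tsv", sep="\t", index=False)
    candidates = [
        {
            "allele": s.allele,
            "child": c.child,
            "parent_left": c.parent_left,
            "parent_right": c.parent_right,
            "breakpoint_start": c.breakpoint[0],
            "breakpoint_end": c.breakpoint[1],
            "informative_left": len(c.informative_left),
            "informative_right": len(c.informative_right),
        }
        for s in result.scenarios
        for c in s.recombination_candidates
    ]
    with open(outdir / "recombination_candidates.json", "w") as fh:
        json.dump(candidates, fh, indent=1)

    run_log = {
        "version": __version__,
        "flags": config.flags(),
        "connection_limit": result.network.connection_limit,
        "n_patterns": len(result.registry),
        "n_haplotypes": {r: len(c.haplotypes) for r, c in result.catalogs.items()},
        "minimum_origins": result.origins,
        "warnings": result.warnings,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1)
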