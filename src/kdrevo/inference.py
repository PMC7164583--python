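"""Did a multi-mutation kdr allele arise by sequential mutation, by a single
crossover between existing alleles, or is the data consistent with either?

Recombination evidence: a pattern is a *perfect mosaic* of two sampled
parent patterns under exactly one breakpoint — it matches the left parent at
every informative site (column where the parents differ) left of the
breakpoint and the right parent at every informative site right of it, with
no private differences.  Only single crossovers are modelled; anything
needing two breakpoints surfaces as "no candidate".

Sequential evidence: a sampled pattern exists whose resistance-mutation set
is a proper subset of the focal allele and whose step distance to the focal
pattern equals the number of mutations gained — every step on the path is a
kdr codon change, i.e. the allele can be reached by pure mutation
accumulation on an existing background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .domain import AlignmentError, KdrAlleleLabel
from .network import INTERMEDIATE, SAMPLED, ParsimonyNetwork, mutational_steps


@dataclass(frozen=True)
class RecombinationCandidate:
    """A child pattern explained as left-parent + right-parent with one breakpoint.

    ``breakpoint`` is the half-open interval of concatenated-pattern columns
    in which the crossover may have occurred (maximal compatible interval:
    just after the last left-informative site through the first
    right-informative site).
    """

    child: str
    parent_left: str
    parent_right: str
    breakpoint: tuple[int, int]
    informative_left: tuple[int, ...]
    informative_right: tuple[int, ...]


def detect_single_crossover(
    child_id: str,
    child_seq: str,
    parents: Mapping[str, str],
    min_informative: int = 1,
    max_mismatch: int = 0,
) -> list[RecombinationCandidate]:
    """Enumerate single-crossover explanations of ``child_seq``.

    All ordered parent pairs are scanned; a candidate requires a perfect
    mosaic (``max_mismatch`` defaults to 0 because pattern sequences are
    short and low-diversity) with at least ``min_informative`` informative
    sites on each side of the breakpoint.  Swapping the parents yields the
    mirrored candidate, so both orientations appear when both are valid.
    """
    child_seq = child_seq.upper()
    names = [p for p in parents if p != child_id]
    out: list[RecombinationCandidate] = []
    for left in names:
        for right in names:
            if left == right:
                continue
            cand = _scan_pair(
                child_id,
                child_seq,
                left,
                parents[left].upper(),
                right,
                parents[right].upper(),
                min_informative,
                max_mismatch,
            )
            if cand is not None:
                out.append(cand)
    return out


def _scan_pair(
    child_id: str,
    child: str,
    left_id: str,
    left: str,
    right_id: str,
    right: str,
    min_informative: int,
    max_mismatch: int,
) -> RecombinationCandidate | None:
    if not (len(child) == len(left) == len(right)):
        raise AlignmentError("child and parents must share the pattern coordinate system")
    match_left_only: list[int] = []
    match_right_only: list[int] = []
    mismatches = 0
    for col, (c, a, b) in enumerate(zip(child, left, right)):
        if a == b:
            if c != a:
                mismatches += 1  # private difference: not explainable by this pair
        elif c == a:
            match_left_only.append(col)
        elif c == b:
            match_right_only.append(col)
        else:
            mismatches += 1  # informative site matching neither parent
        if mismatches > max_mismatch:
            return None
    if len(match_left_only) < min_informative or len(match_right_only) < min_informative:
        return None
    if match_left_only[-1] > match_right_only[0]:
        return None  # sides interleave: needs more than one breakpoint
    lo = match_left_only[-1] + 1
    hi = match_right_only[0] + 1
    return RecombinationCandidate(
        child_id,
        left_id,
        right_id,
        (lo, hi),
        tuple(match_left_only),
        tuple(match_right_only),
    )


# ---------------------------------------------------------------------------
# mutation paths on the network


@dataclass(frozen=True)
class MutationPath:
    """A shortest network path from a focal pattern down to a smaller allele."""

    start: str
    end: str
    nodes: tuple[str, ...]
    steps: int
    gains: frozenset[str]  # mutation names gained along start <- end

    @property
    def pure_mutation(self) -> bool:
        """True when every step on the path is a kdr codon change."""
        return self.steps == len(self.gains)


def mutation_paths(
    network: ParsimonyNetwork,
    allele: KdrAlleleLabel | str,
    alleles: Mapping[str, KdrAlleleLabel],
) -> list[MutationPath]:
    """Shortest paths from each pattern carrying ``allele`` to the nearest
    sampled pattern with a strictly smaller (subset) mutation set.

    Paths may pass through inferred intermediates (whose states are unknown)
    but not through sampled patterns whose mutation set is not a subset of
    the focal allele — sequential accumulation never loses a mutation.
    Returns an empty list when the allele is absent from the network.
    """
    target = allele if isinstance(allele, KdrAlleleLabel) else KdrAlleleLabel.parse(str(allele))
    carriers = [n for n, a in alleles.items() if a == target and n in network.graph]
    if not carriers:
        return []
    focal_set = target.mutation_names()

    def passable(node: str) -> bool:
        data = network.graph.nodes[node]
        if data["kind"] == INTERMEDIATE:
            return True
        return alleles[node].mutation_names() <= focal_set

    sub = network.graph.subgraph([n for n in network.graph if passable(n)])
    out: list[MutationPath] = []
    for start in carriers:
        if start not in sub:
            continue
        lengths, paths = nx.single_source_dijkstra(sub, start)
        best: list[MutationPath] = []
        best_len = None
        for node, dist in sorted(lengths.items(), key=lambda kv: (kv[1], kv[0])):
            if node == start or network.graph.nodes[node]["kind"] != SAMPLED:
                continue
            if not alleles[node].mutation_names() < focal_set:
                continue
            if best_len is not None and dist > best_len:
                break
            best_len = dist
            gains = focal_set - alleles[node].mutation_names()
            best.append(
                MutationPath(start, node, tuple(paths[node]), int(dist), frozenset(gains))
            )
        out.extend(best)
    return out


# ---------------------------------------------------------------------------
# scenario classification


@dataclass
class ScenarioCall:
    """Verdict on how one multi-mutation allele arose."""

    allele: str
    verdict: str  # "sequential" | "recombination" | "either" | "unresolved"
    sequential_evidence: tuple[str, ...] = ()  # "child<-ancestor(+gains)" strings
    recombination_candidates: tuple[RecombinationCandidate, ...] = ()


def classify_scenarios(
    sequences: Mapping[str, str],
    alleles: Mapping[str, KdrAlleleLabel],
    min_informative: int = 1,
    max_mismatch: int = 0,
) -> list[ScenarioCall]:
    """Classify every multi-mutation allele among the sampled patterns.

    Sequential evidence uses the step matrix directly: a sampled ancestor
    with a proper-subset allele at a step distance equal to the number of
    mutations gained.  Recombination evidence restricts crossover candidates
    to parent pairs whose mutation sets are proper subsets of the child's —
    a parent already carrying the full allele explains nothing about its
    origin.  Verdicts: sequential / recombination / either / unresolved.
    Results are invariant to pattern input order (patterns are iterated in
    sorted-id order).
    """
    multi = sorted(
        {str(a) for a in alleles.values() if len(a) >= 2}
    )
    calls: list[ScenarioCall] = []
    ids = sorted(sequences)
    for allele_str in multi:
        allele = KdrAlleleLabel.parse(allele_str)
        focal_set = allele.mutation_names()
        carriers = [n for n in ids if alleles[n] == allele]

        seq_evidence: list[str] = []
        for child in carriers:
            for anc in ids:
                anc_set = alleles[anc].mutation_names()
                if not anc_set < focal_set:
                    continue
                gains = focal_set - anc_set
                steps = mutational_steps(sequences[child], sequences[anc])
                if steps == len(gains):
                    seq_evidence.append(f"{child}<-{anc}(+{'+'.join(sorted(gains))})")

        rec_candidates: list[RecombinationCandidate] = []
        subset_parents = {
            n: sequences[n] for n in ids if alleles[n].mutation_names() < focal_set
        }
        for child in carriers:
            rec_candidates.extend(
                detect_single_crossover(
                    child, sequences[child], subset_parents, min_informative, max_mismatch
                )
            )

        if seq_evidence and rec_candidates:
            verdict = "either"
        elif seq_evidence:
            verdict = "sequential"
        elif rec_candidates:
            verdict = "recombination"
        else:
            verdict = "unresolved"
        calls.append(
            ScenarioCall(allele_str, verdict, tuple(seq_evidence), tuple(rec_candidates))
        )
    return calls
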