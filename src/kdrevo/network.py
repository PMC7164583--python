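"""Statistical-parsimony genealogy network over pattern sequences.

Distances between patterns are mutational steps: substituted columns plus
indel events (a maximal gap run present in exactly one of the two sequences
counts as one step, matching how indel events are counted in the variation
summary).  Pattern pairs are connected in increasing step order, TCS-style;
a d-step connection is realized as a chain of d-1 inferred (unsampled)
intermediate nodes, and pairs whose distance exceeds the statistical-
parsimony connection limit stay in separate components.

The connection limit is the largest step count whose probability of being
free of homoplasy exceeds the chosen threshold (default 0.95).  The
probability estimator is isolated in :func:`parsimony_probability` so it can
be swapped; see docs/methods.md for the model used here.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .domain import GAP, AlignmentError, ConfigError


# ---------------------------------------------------------------------------
# mutational step distance


def mutational_steps(seq1: str, seq2: str, count_indels: bool = True) -> int:
    """Mutational steps between two sequences on one alignment architecture.

    Substitutions: columns where both sequences have a base and the bases
    differ.  Indel events: maximal runs of columns gapped in exactly one of
    the two sequences (the gapped side must not switch within a run).
    Columns gapped in both sequences are shared history and count nothing.
    Set ``count_indels=False`` for a substitutions-only distance.
    """
    if len(seq1) != len(seq2):
        raise AlignmentError(f"length mismatch: {len(seq1)} vs {len(seq2)}")
    seq1 = seq1.upper()
    seq2 = seq2.upper()
    subs = 0
    indel_events = 0
    current = 0  # 0 none, 1 gap-in-seq1, 2 gap-in-seq2
    for a, b in zip(seq1, seq2):
        ga, gb = a == GAP, b == GAP
        if ga and gb:
            continue  # shared gap: neutral, does not break a run
        if ga:
            if current != 1:
                indel_events += 1
                current = 1
        elif gb:
            if current != 2:
                indel_events += 1
                current = 2
        else:
            current = 0
            if a != b:
                subs += 1
    return subs + (indel_events if count_indels else 0)


def step_matrix(
    sequences: Mapping[str, str], count_indels: bool = True
) -> tuple[list[str], np.ndarray]:
    """Symmetric integer step matrix over the registered patterns (sorted ids)."""
    ids = sorted(sequences, key=_natural_key)
    n = len(ids)
    mat = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        d = mutational_steps(sequences[ids[i]], sequences[ids[j]], count_indels)
        mat[i, j] = mat[j, i] = d
    return ids, mat


def _natural_key(s: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]


# ---------------------------------------------------------------------------
# statistical parsimony connection limit


def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that a ``steps``-step connection is free of homoplasy.

    Model: mutation events fall independently and uniformly over the
    ``seq_length`` sites; a connection of j steps is non-homoplasious when
    all j events hit distinct sites, i.e.

        P(j) = prod_{i=1}^{j-1} (1 - i / L).

    P(1) = 1: a single step can never be homoplasious on its own.  This is
    the estimator behind :func:`parsimony_connection_limit`; it is isolated
    here so an alternative (e.g. a coalescent-calibrated one) can be swapped
    in without touching the network construction.
    """
    if seq_length < 1:
        raise ConfigError("sequence length must be >= 1")
    if steps < 1:
        return 1.0
    p = 1.0
    for i in range(1, steps):
        p *= 1.0 - i / seq_length
    return max(p, 0.0)


def parsimony_connection_limit(seq_length: int, threshold: float = 0.95) -> int:
    """Largest step count whose probability of parsimony exceeds ``threshold``.

    Single-step connections are always allowed, so the limit is floored at 1
    (an extreme threshold close to 1 yields exactly 1).
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError("threshold must lie strictly between 0 and 1")
    if seq_length < 1:
        raise ConfigError("sequence length must be >= 1")
    j = 1
    while j < seq_length and parsimony_probability(j + 1, seq_length) > threshold:
        j += 1
    return j


# ---------------------------------------------------------------------------
# network construction


SAMPLED = "sampled"
INTERMEDIATE = "intermediate"


@dataclass
class ParsimonyNetwork:
    """TCS-style genealogy network: sampled patterns plus inferred intermediates."""

    graph: nx.Graph
    connection_limit: int
    ids: list[str] = field(default_factory=list)

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == SAMPLED]

    @property
    def intermediate_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == INTERMEDIATE]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_network(
    sequences: Mapping[str, str],
    counts: Mapping[str, int] | None = None,
    limit: int | None = None,
    threshold: float = 0.95,
    count_indels: bool = True,
    attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> ParsimonyNetwork:
    """Build the statistical-parsimony network over pattern sequences.

    Pattern pairs are visited in increasing step order (ties broken by
    P-number order, a documented determinism rule with no biological claim);
    a pair is connected when it would join two separate components and its
    distance does not exceed the connection limit.  A d-step connection adds
    d-1 inferred intermediate nodes.
    """
    if not sequences:
        raise ConfigError("need at least one pattern")
    counts = counts or {}
    attributes = attributes or {}
    ids, mat = step_matrix(sequences, count_indels)
    if limit is None:
        limit = parsimony_connection_limit(len(next(iter(sequences.values()))), threshold)

    g = nx.Graph()
    for pid in ids:
        g.add_node(pid, kind=SAMPLED, count=int(counts.get(pid, 0)), **attributes.get(pid, {}))

    pairs = sorted(
        (
            (int(mat[i, j]), ids[i], ids[j])
            for i, j in itertools.combinations(range(len(ids)), 2)
            if 0 < mat[i, j] <= limit
        ),
        key=lambda t: (t[0], _natural_key(t[1]), _natural_key(t[2])),
    )
    comp = {pid: pid for pid in ids}

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for d, a, b in pairs:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        comp[ra] = rb
        if d == 1:
            g.add_edge(a, b)
        else:
            chain = [a]
            for k in range(1, d):
                node = f"{a}~{b}~{k}"
                g.add_node(node, kind=INTERMEDIATE, count=0)
                comp[node] = rb
                chain.append(node)
            chain.append(b)
            for u, v in zip(chain, chain[1:]):
                g.add_edge(u, v)
    return ParsimonyNetwork(g, limit, ids)


# ---------------------------------------------------------------------------
# minimum origins of a derived character state


def minimum_origins(
    network: ParsimonyNetwork | nx.Graph,
    states: Mapping[str, str],
    derived_state: str,
) -> int:
    """Minimum number of independent origins of ``derived_state`` on the network.

    Sampled nodes carry fixed states; intermediate (inferred) nodes are free.
    An origin is one gain of the derived state (losses are free), so for a
    full labelling the gain count is the number of connected components of
    the derived-labelled subgraph.  Marking an intermediate derived can only
    merge derived components (or add an unforced extra origin), hence the
    minimum is attained by letting every intermediate carry the derived
    state and counting the components of the subgraph induced by derived
    sampled nodes plus all intermediates that contain at least one sampled
    derived node.  This closed form equals the exhaustive minimum over all
    intermediate assignments (verified against brute force in the tests).
    """
    g = network.graph if isinstance(network, ParsimonyNetwork) else network
    derived_sampled = {n for n, s in states.items() if s == derived_state}
    if not derived_sampled:
        return 0
    free = {n for n, d in g.nodes(data=True) if d.get("kind") == INTERMEDIATE}
    free -= set(states)  # an intermediate with an asserted state is not free
    sub = g.subgraph(derived_sampled | free)
    return sum(1 for c in nx.connected_components(sub) if c & derived_sampled)


# ---------------------------------------------------------------------------
# export


def to_graphml(network: ParsimonyNetwork, path: str) -> None:
    g = nx.Graph()
    for n, d in network.graph.nodes(data=True):
        g.add_node(n, **{k: _graphml_safe(v) for k, v in d.items()})
    g.add_edges_from(network.graph.edges())
    nx.write_graphml(g, path)


_CONTINENT_COLORS = {"Asia": "yellow", "America": "blue", "Africa": "green"}


def to_dot(network: ParsimonyNetwork, path: str) -> None:
    """Write a plain Graphviz DOT file (no pydot dependency)."""
    lines = ["graph parsimony_network {", "  node [shape=circle];"]
    for n, d in network.graph.nodes(data=True):
        attrs = []
        if d["kind"] == INTERMEDIATE:
            attrs.append('shape="point"')
        else:
            label = str(d.get("allele", "")) or n
            attrs.append(f'label="{n}\\n{label}"')
            attrs.append(f'width={0.4 + 0.08 * d.get("count", 0):.2f}')
            color = _CONTINENT_COLORS.get(str(d.get("continent", "")), "")
            if color:
                attrs.append(f'fillcolor="{color}" style="filled"')
        lines.append(f'  "{n}" [{", ".join(attrs)}];')
    for u, v in network.graph.edges():
        lines.append(f'  "{u}" -- "{v}";')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _graphml_safe(v):
    if isinstance(v, (str, int, float, bool)):
        return v
    return str(v)
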