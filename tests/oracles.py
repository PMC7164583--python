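"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its definition by direct enumeration
or exact arithmetic, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def steps_oracle(s1: str, s2: str, count_indels: bool = True) -> int:
    """Column-scan mutational distance: substitutions plus one-sided gap runs."""
    assert len(s1) == len(s2)
    subs = 0
    events = 0
    prev = None  # which side was gapped in the previous non-shared-gap column
    for a, b in zip(s1.upper(), s2.upper()):
        if a == "-" and b == "-":
            continue
        if a == "-":
            side = "left"
        elif b == "-":
            side = "right"
        else:
            side = None
            if a != b:
                subs += 1
        if side is not None and side != prev:
            events += 1
        prev = side
    return subs + (events if count_indels else 0)


def parsimony_probability_oracle(steps: int, length: int) -> Fraction:
    """Exact probability that `steps` uniform mutation events hit distinct sites."""
    p = Fraction(1)
    for i in range(1, steps):
        p *= Fraction(length - i, length)
    return p


def connection_limit_oracle(length: int, threshold: Fraction | float) -> int:
    """Largest j with P(j) > threshold, floored at 1 (single steps always pass)."""
    thr = Fraction(threshold).limit_denominator(10**9)
    j = 1
    while j < length and parsimony_probability_oracle(j + 1, length) > thr:
        j += 1
    return j


def minimum_origins_oracle(
    edges: list[tuple[str, str]],
    fixed_states: dict[str, str],
    free_nodes: list[str],
    derived: str = "derived",
) -> int:
    """Exhaustive minimum over all assignments of the free (intermediate) nodes
    of the number of connected components of the derived-labelled subgraph."""
    nodes = sorted({n for e in edges for n in e} | set(fixed_states) | set(free_nodes))
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    fixed_derived = {n for n, s in fixed_states.items() if s == derived}
    if not fixed_derived:
        return 0
    best = None
    for mask in itertools.product([False, True], repeat=len(free_nodes)):
        derived_set = set(fixed_derived)
        derived_set.update(n for n, m in zip(free_nodes, mask) if m)
        # count components of the derived-induced subgraph by BFS
        seen: set[str] = set()
        comps = 0
        for start in sorted(derived_set):
            if start in seen:
                continue
            comps += 1
            stack = [start]
            seen.add(start)
            while stack:
                cur = stack.pop()
                for nb in adj[cur]:
                    if nb in derived_set and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        if best is None or comps < best:
            best = comps
    return best


def iupac_expansion_oracle(code: str) -> set[str]:
    """Full IUPAC nucleotide ambiguity expansion, written out by hand."""
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    return set(table[code.upper()])


def phase_pairs_oracle(ambiguous: str, haplotypes: dict[str, str]) -> list[tuple[str, str]]:
    """All unordered catalog pairs whose site-wise union reproduces the trace."""
    out = []
    ids = sorted(haplotypes)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            ok = True
            for obs, x, y in zip(ambiguous.upper(), haplotypes[a], haplotypes[b]):
                if x == y:
                    expect = x
                elif "-" in (x, y):
                    ok = False
                    break
                else:
                    expect = _code(frozenset((x, y)))
                if obs != expect:
                    ok = False
                    break
            if ok:
                out.append((a, b))
    return out


def _code(bases: frozenset[str]) -> str:
    rev = {
        frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
        frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    }
    return rev[bases]


def crossover_scan_oracle(
    child: str, left: str, right: str, min_informative: int = 1
) -> tuple[int, int] | None:
    """Try every breakpoint explicitly; return the maximal valid interval."""
    n = len(child)
    valid = []
    for bp in range(n + 1):
        ok = True
        informative_left = informative_right = 0
        for col in range(n):
            parent = left if col < bp else right
            if child[col] != parent[col]:
                ok = False
                break
            if left[col] != right[col]:
                if col < bp:
                    informative_left += 1
                else:
                    informative_right += 1
        if ok and informative_left >= min_informative and informative_right >= min_informative:
            valid.append(bp)
    if not valid:
        return None
    assert valid == list(range(valid[0], valid[-1] + 1)), "breakpoints must be contiguous"
    return (valid[0], valid[-1] + 1)
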