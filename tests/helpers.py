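"""Independent brute-force oracles and fixture builders shared across tests.

Everything here is deliberately naive -- enumeration, exact rational
arithmetic, quadratic pair counting -- so it cannot share a failure mode
with the vectorised implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np

from lcrscape.annotate import LCRegion
from lcrscape.entropy import STANDARD_AA, ProteinRecord
from lcrscape.network import PPINetwork


def random_protein(rng, length: int, pid: str = "P1", alphabet: str = STANDARD_AA) -> ProteinRecord:
    codes = rng.integers(0, len(alphabet), size=length)
    return ProteinRecord(id=pid, sequence="".join(alphabet[c] for c in codes))


def random_proteome(rng, n: int, len_lo: int, len_hi: int, alphabet: str = STANDARD_AA):
    return [
        random_protein(rng, int(rng.integers(len_lo, len_hi + 1)), f"P{i:04d}", alphabet)
        for i in range(n)
    ]


def exhaustive_resolution(candidates: list[LCRegion]) -> list[LCRegion]:
    """Best disjoint subset by exhaustive enumeration over all subsets.

    Among all *maximal* pairwise-disjoint subsets, returns the one whose
    sorted key sequence (Z ascending, longer first, smaller start first)
    is lexicographically smallest -- the objective the greedy resolver
    optimises.  Only feasible for ~10 candidates.
    """
    n = len(candidates)
    assert n <= 12, "exhaustive oracle limited to small instances"

    def disjoint(subset):
        return all(
            not a.overlaps(b) for a, b in combinations(subset, 2)
        )

    def key(region):
        return (region.Z, -region.length, region.start)

    feasible = []
    for mask in range(1, 1 << n):
        subset = [candidates[i] for i in range(n) if mask >> i & 1]
        if disjoint(subset):
            feasible.append((mask, subset))
    best = None
    best_key = None
    for mask, subset in feasible:
        maximal = all(
            mask >> i & 1 or not disjoint(subset + [candidates[i]])
            for i in range(n)
        )
        if not maximal:
            continue
        k = sorted(key(r) for r in subset)
        if best_key is None or k < best_key:
            best, best_key = subset, k
    assert best is not None
    return sorted(best, key=lambda r: r.start)


def random_candidates(rng, n: int, pid: str = "PX") -> list[LCRegion]:
    """Random overlapping candidate regions with deliberate Z/length ties."""
    out = []
    seen = set()
    while len(out) < n:
        start = int(rng.integers(1, 80))
        length = int(rng.integers(5, 30))
        z = float(np.round(rng.normal(-3, 1.5), 1))  # coarse grid induces ties
        sig = (start, length, z)
        if sig in seen:
            continue
        seen.add(sig)
        out.append(
            LCRegion(protein_id=pid, start=start, end=start + length - 1, H=1.0, Z=z)
        )
    return out


def graph_with_degrees(degrees: dict[str, int]) -> PPINetwork:
    """A graph in which each named node has exactly the requested degree.

    Each node is wired to its own set of fresh stub nodes, so named-node
    degrees are independent of each other.
    """
    g = nx.Graph()
    stub = 0
    for node, deg in degrees.items():
        g.add_node(node)
        for _ in range(deg):
            g.add_edge(node, f"_stub{stub}")
            stub += 1
    return PPINetwork(name="fixture", graph=g)


def brute_force_u(a, b) -> float:
    """Mann-Whitney U of sample ``a``: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), rational arithmetic."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(n, K) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return total
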