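"""PPI network loading and connectivity analyses for LCR protein sets.

Networks are undirected, deduplicated, self-loop-free graphs over protein
identifiers, read from tab-delimited edge lists (BioGrid-tab-like, with a
configurable interaction-type column so genetic interactions can be
stripped).  The analyses mirror the standard connectivity questions asked
of LCR proteins: rank-based degree comparisons between protein groups,
ordinary least squares of degree on LCR length, and a simple
observed-vs-expected enrichment of LCR proteins among network nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Interaction-type labels accepted as physical (BioGrid experimental-system-type).
DEFAULT_PHYSICAL_TYPES = frozenset({"physical"})


@dataclass
class PPINetwork:
    """An undirected physical-interaction graph over protein identifiers."""

    name: str
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def degrees(self, ids: Iterable[str] | None = None) -> dict[str, int]:
        """Degrees of the requested nodes (all nodes when ``ids`` is None).

        Identifiers absent from the network are silently dropped: a protein
        not reported in a dataset has no degree there, rather than degree 0.
        """
        if ids is None:
            return dict(self.graph.degree)
        return {n: self.graph.degree[n] for n in ids if n in self.graph}


def from_edge_records(
    name: str,
    records: Iterable[tuple],
    *,
    physical_only: bool = False,
    physical_types: frozenset[str] = DEFAULT_PHYSICAL_TYPES,
) -> PPINetwork:
    """Build a network from ``(id_a, id_b[, type])`` tuples in memory."""
    g = nx.Graph()
    n_dropped_type = n_self = 0
    for rec in records:
        a, b = str(rec[0]), str(rec[1])
        if physical_only:
            etype = str(rec[2]) if len(rec) > 2 else ""
            if etype not in physical_types:
                n_dropped_type += 1
                continue
        if a == b:
            n_self += 1
            continue
        g.add_edge(a, b)
    if n_dropped_type or n_self:
        logger.info(
            "%s: dropped %d non-physical rows, %d self-loops",
            name,
            n_dropped_type,
            n_self,
        )
    if g.number_of_edges() == 0:
        raise ValueError(f"network {name!r} has zero edges after filtering")
    return PPINetwork(name=name, graph=g)


def read_network(
    path,
    *,
    name: str | None = None,
    physical_only: bool = False,
    id_cols: tuple[int, int] = (0, 1),
    type_col: int | None = 2,
    physical_types: frozenset[str] = DEFAULT_PHYSICAL_TYPES,
    delimiter: str = "\t",
    synonyms: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Read an undirected, deduplicated network from a tab-delimited edge list.

    Rows are symmetrised and deduplicated; self-loops are dropped.  With
    ``physical_only`` set, rows whose ``type_col`` value is not in the
    ``physical_types`` whitelist are removed (dropped and kept counts are
    logged).  Malformed rows are logged and skipped.  An optional synonym
    map translates identifiers on the fly; unmatched ids pass through
    unchanged.
    """
    records: list[tuple] = []
    n_malformed = 0
    need = max(id_cols) + 1
    if physical_only and type_col is not None:
        need = max(need, type_col + 1)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < need:
                n_malformed += 1
                continue
            a, b = fields[id_cols[0]].strip(), fields[id_cols[1]].strip()
            if not a or not b:
                n_malformed += 1
                continue
            if synonyms is not None:
                a = synonyms.get(a, a)
                b = synonyms.get(b, b)
            if type_col is not None and len(fields) > type_col:
                records.append((a, b, fields[type_col].strip()))
            else:
                records.append((a, b))
    if n_malformed:
        logger.warning("%s: skipped %d malformed rows", path, n_malformed)
    net_name = name if name is not None else str(path)
    return from_edge_records(
        net_name, records, physical_only=physical_only, physical_types=physical_types
    )


@dataclass
class DegreeComparison:
    """Mann-Whitney U comparison of the degree distributions of two groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    U: float
    p: float
    alternative: str
    method: str


def compare_degrees(
    network: PPINetwork,
    group_a: Iterable[str],
    group_b: Iterable[str],
    *,
    alternative: str = "two-sided",
    label_a: str = "A",
    label_b: str = "B",
    exact_max_n: int = 50,
) -> DegreeComparison:
    """Mann-Whitney U on the degrees of two disjoint protein groups.

    Only group members present in the network are compared (intersection
    semantics).  The exact null distribution is used when both samples
    have at most ``exact_max_n`` members and the pooled degrees are free
    of ties; otherwise the tie-corrected normal approximation applies.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("degree comparison groups must be disjoint")
    da = np.array([network.graph.degree[n] for n in sorted(set_a) if n in network.graph])
    db = np.array([network.graph.degree[n] for n in sorted(set_b) if n in network.graph])
    if da.size == 0:
        raise ValueError(
            f"group {label_a!r} has no members in network {network.name!r}"
        )
    if db.size == 0:
        raise ValueError(
            f"group {label_b!r} has no members in network {network.name!r}"
        )
    pooled = np.concatenate([da, db])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (da.size <= exact_max_n and db.size <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(da, db, alternative=alternative, method=method)
    return DegreeComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(da.size),
        n_b=int(db.size),
        U=float(res.statistic),
        p=float(res.pvalue),
        alternative=alternative,
        method=method,
    )


@dataclass
class LengthDegreeRegression:
    """OLS of protein degree on LCR length for one positional subset."""

    label: str
    n: int
    slope: float
    intercept: float
    r2: float
    p: float
    stderr: float


def length_degree_regression(
    lengths: Sequence[float],
    degrees: Sequence[float],
    *,
    label: str = "",
) -> LengthDegreeRegression:
    """Ordinary least squares of degree on LCR length (two-sided slope p)."""
    x = np.asarray(lengths, dtype=np.float64)
    y = np.asarray(degrees, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("lengths and degrees must align")
    if x.size < 3:
        raise ValueError(f"regression needs n >= 3, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in LCR lengths; slope undefined")
    res = sps.linregress(x, y)
    return LengthDegreeRegression(
        label=label,
        n=int(x.size),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        stderr=float(res.stderr),
    )


def network_lcr_enrichment(
    network: PPINetwork,
    lcr_ids: Iterable[str],
    proteome_ids: Iterable[str],
) -> float:
    """``(Observed - Expected) / Expected`` LCR-protein count among nodes.

    Observed is the number of network nodes carrying an LCR; Expected is
    the node count scaled by the proteome-wide LCR fraction.  Nodes absent
    from the supplied proteome trigger a warning (the expectation then
    refers to the proteome's fraction regardless).
    """
    lcr = set(lcr_ids)
    proteome = set(proteome_ids)
    nodes = network.nodes
    outside = nodes - proteome
    if outside:
        logger.warning(
            "%s: %d network nodes absent from the supplied proteome",
            network.name,
            len(outside),
        )
    if not proteome:
        raise ValueError("empty proteome id set")
    expected = len(nodes) * len(lcr & proteome) / len(proteome)
    if expected == 0:
        raise ValueError("expected LCR node count is zero; enrichment undefined")
    observed = len(nodes & lcr)
    return (observed - expected) / expected
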