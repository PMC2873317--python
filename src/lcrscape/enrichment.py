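"""GO-term over-representation with Fisher's exact test and BH correction.

Study sets (e.g. all single-LCR proteins, or the terminal / central
subsets) are compared against a background gene universe.  For each term
the one-sided over-representation p-value is the hypergeometric upper
tail P(X >= k) with k study genes annotated, K background genes
annotated, study size n and background size N -- identical to the
one-sided Fisher exact test on the 2x2 contingency table.  P-values are
transformed to q-values with the Benjamini-Hochberg step-up procedure,
applied within each ontology branch (P / F / C) by default.

No GO-DAG ancestor propagation is performed: annotations are taken as
given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BRANCHES = ("P", "F", "C")
DEFAULT_Q_THRESHOLD = 0.1


@dataclass
class AnnotationTable:
    """Gene -> GO-term annotations with per-term branch and definition."""

    term_genes: dict[str, set[str]]
    term_branch: dict[str, str]
    term_def: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_genes.items():
            if not genes:
                raise ValueError(f"term {term} has an empty gene set")
            if term not in self.term_branch:
                raise ValueError(f"term {term} has no ontology branch assigned")

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_genes)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return out


def read_annotations(path, fmt: str = "auto") -> AnnotationTable:
    """Read gene -> term annotations from GAF 2.x or a plain TSV.

    The TSV layout is ``gene<TAB>term[<TAB>branch[<TAB>definition]]``
    (branch defaults to "P" when absent).  GAF rows with a ``NOT``
    qualifier are dropped, and duplicate gene-term pairs collapse to a
    single membership.  ``fmt`` is "gaf", "tsv" or "auto" (sniffed from a
    ``!gaf-version`` header).
    """
    if fmt not in {"auto", "gaf", "tsv"}:
        raise ValueError(f"unknown annotation format {fmt!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if fmt == "auto":
        fmt = "gaf" if any(l.startswith("!gaf-version") for l in lines[:5]) else "tsv"

    term_genes: dict[str, set[str]] = {}
    term_branch: dict[str, str] = {}
    term_def: dict[str, str] = {}
    if fmt == "gaf":
        for line in lines:
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                logger.warning("skipping short GAF row: %r", line[:80])
                continue
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            gene, term, aspect = fields[1], fields[4], fields[8]
            term_genes.setdefault(term, set()).add(gene)
            term_branch[term] = aspect
    else:
        for line in lines:
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                logger.warning("skipping short annotation row: %r", line[:80])
                continue
            gene, term = fields[0].strip(), fields[1].strip()
            term_genes.setdefault(term, set()).add(gene)
            if len(fields) >= 3 and fields[2].strip():
                term_branch[term] = fields[2].strip()
            else:
                term_branch.setdefault(term, "P")
            if len(fields) >= 4 and fields[3].strip():
                term_def[term] = fields[3].strip()
    if not term_genes:
        raise ValueError(f"no annotations parsed from {path}")
    return AnnotationTable(term_genes=term_genes, term_branch=term_branch, term_def=term_def)


@dataclass
class EnrichmentRow:
    """One term's contingency counts and (adjusted) significance."""

    term: str
    branch: str
    k: int  # study genes with the term
    n: int  # study size
    K: int  # background genes with the term
    N: int  # background size
    p: float
    q: float | None = None
    definition: str = ""


def fisher_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationTable,
) -> list[EnrichmentRow]:
    """One-sided over-representation p-value per term (q not yet assigned).

    ``p = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  Terms with no
    study gene report p = 1.  The study set must be contained in the
    background; offenders are listed in the raised error.
    """
    study_set = set(study)
    background_set = set(background)
    if not study_set:
        raise ValueError("study set is empty")
    stray = study_set - background_set
    if stray:
        raise ValueError(
            "study genes missing from background: " + ", ".join(sorted(stray)[:10])
        )
    N = len(background_set)
    n = len(study_set)
    rows: list[EnrichmentRow] = []
    for term in annotations.terms:
        genes = annotations.term_genes[term] & background_set
        K = len(genes)
        k = len(genes & study_set)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            EnrichmentRow(
                term=term,
                branch=annotations.term_branch[term],
                k=k,
                n=n,
                K=K,
                N=N,
                p=min(p, 1.0),
                definition=annotations.term_def.get(term, ""),
            )
        )
    return rows


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_rows(rows: Sequence[EnrichmentRow], *, per_branch: bool = True) -> list[EnrichmentRow]:
    """Assign q-values, correcting within each ontology branch by default.

    With ``per_branch=False`` a single pooled correction over all terms is
    applied instead.  Row order is preserved.
    """
    rows = list(rows)
    if per_branch:
        groups: dict[str, list[int]] = {}
        for i, row in enumerate(rows):
            groups.setdefault(row.branch, []).append(i)
    else:
        groups = {"all": list(range(len(rows)))}
    for idx in groups.values():
        q = bh_adjust([rows[i].p for i in idx])
        for i, qv in zip(idx, q):
            rows[i].q = float(qv)
    return rows


def enrichment_report(
    rows: Sequence[EnrichmentRow], q_threshold: float = DEFAULT_Q_THRESHOLD
) -> pd.DataFrame:
    """Rows with q < threshold, sorted by branch then p-value."""
    kept = [r for r in rows if r.q is not None and r.q < q_threshold]
    kept.sort(key=lambda r: (r.branch, r.p, r.term))
    return pd.DataFrame(
        [
            {
                "branch": r.branch,
                "term": r.term,
                "definition": r.definition,
                "genes": r.k,
                "background": r.K,
                "p": r.p,
                "q": r.q,
            }
            for r in kept
        ],
        columns=["branch", "term", "definition", "genes", "background", "p", "q"],
    )


def go_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationTable,
    *,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    per_branch: bool = True,
) -> tuple[list[EnrichmentRow], pd.DataFrame]:
    """Convenience driver: Fisher p-values, BH q-values, filtered report."""
    rows = fisher_enrichment(study, background, annotations)
    rows = adjust_rows(rows, per_branch=per_branch)
    return rows, enrichment_report(rows, q_threshold)
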