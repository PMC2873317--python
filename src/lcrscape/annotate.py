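"""From flagged windows to a non-redundant per-protein LCR annotation.

Detection emits every window whose entropy falls below its length-class
threshold; overlapping candidates are then resolved greedily, keeping the
region with the most extreme standardised Z-score, so each protein ends up
with a set of pairwise-disjoint low-complexity regions.  Each retained
region is given positional metrics (normalised centre, folded position)
and a terminal / central / intermediate class based on its distance from
the sequence extremities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import (
    CalibrationTable,
    ProteinRecord,
    ProteomeScan,
    DEFAULT_ALPHA,
    DEFAULT_W_MAX,
    DEFAULT_W_MIN,
    build_calibration,
)

logger = logging.getLogger(__name__)

#: Maximum residues between a terminal LCR and a sequence extremity.
DEFAULT_T_CUT = 25
#: Minimum residues between a central LCR and both sequence extremities.
DEFAULT_C_CUT = 50

POSITION_CLASSES = ("terminal", "central", "intermediate")


@dataclass
class LCRegion:
    """A detected low-complexity region (1-based inclusive coordinates)."""

    protein_id: str
    start: int
    end: int
    H: float
    Z: float
    centre_norm: float | None = None
    folded: float | None = None
    pos_class: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "LCRegion") -> bool:
        """True if the two regions share at least one residue."""
        return self.start <= other.end and other.start <= self.end


def _greedy_key(region: LCRegion, literal_z: bool):
    z = -region.Z if literal_z else region.Z
    return (z, -region.length, region.start)


def resolve_overlaps(
    candidates: Sequence[LCRegion], *, literal_z: bool = False
) -> list[LCRegion]:
    """Reduce overlapping candidates of one protein to disjoint regions.

    Greedy selection: repeatedly retain the candidate with the most extreme
    (most negative) Z-score and discard every candidate overlapping it,
    until none remain.  Ties on Z are broken in favour of the longer
    region, then the smaller start, making the procedure deterministic.
    With ``literal_z`` the literal reading "highest Z-score wins" (most
    positive Z first) is used instead.

    Returns the retained regions sorted by start coordinate.
    """
    if not candidates:
        return []
    pids = {c.protein_id for c in candidates}
    if len(pids) != 1:
        raise ValueError(f"candidates span multiple proteins: {sorted(pids)}")
    order = sorted(candidates, key=lambda c: _greedy_key(c, literal_z))
    kept: list[LCRegion] = []
    for cand in order:
        if all(not cand.overlaps(k) for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda c: c.start)


def position_metrics(region: LCRegion, protein_length: int) -> tuple[float, float]:
    """Normalised centre position and its folded counterpart.

    ``centre_norm`` is the region's centre coordinate divided by the
    protein length (in (0, 1)); ``folded = min(x, 1 - x)`` maps both
    termini onto a single centre-to-extremity scale in [0, 0.5], with 0 at
    an extremity and 0.5 at the exact sequence centre.
    """
    if region.end > protein_length:
        raise ValueError(
            f"region {region.start}..{region.end} exceeds protein length {protein_length}"
        )
    centre = ((region.start + region.end) / 2.0) / protein_length
    return centre, min(centre, 1.0 - centre)


def classify_position(
    region: LCRegion,
    protein_length: int,
    t_cut: int = DEFAULT_T_CUT,
    c_cut: int = DEFAULT_C_CUT,
) -> str:
    """Terminal / central / intermediate classification of one region.

    Margins count residues outside the region: N-margin ``start - 1``,
    C-margin ``L - end``.  A region is *terminal* when either margin is at
    most ``t_cut`` (default 25 aa), *central* when both margins are at
    least ``c_cut`` (default 50 aa), and *intermediate* in the deliberate
    buffer zone between the two cut-offs.
    """
    if region.end > protein_length:
        raise ValueError("region exceeds protein bounds")
    n_margin = region.start - 1
    c_margin = protein_length - region.end
    if n_margin <= t_cut or c_margin <= t_cut:
        return "terminal"
    if n_margin >= c_cut and c_margin >= c_cut:
        return "central"
    return "intermediate"


def annotate_region(
    region: LCRegion,
    protein_length: int,
    t_cut: int = DEFAULT_T_CUT,
    c_cut: int = DEFAULT_C_CUT,
) -> LCRegion:
    """Return a copy of ``region`` with positional metrics and class set."""
    centre, folded = position_metrics(region, protein_length)
    return replace(
        region,
        centre_norm=centre,
        folded=folded,
        pos_class=classify_position(region, protein_length, t_cut, c_cut),
    )


def detect_lcrs(
    proteome: Sequence[ProteinRecord],
    cal: CalibrationTable,
    *,
    windows: Iterable[int] | None = None,
    scan: ProteomeScan | None = None,
    skip_ambiguous: bool = False,
) -> list[LCRegion]:
    """Emit every window whose entropy is strictly below its ``t_w``.

    Candidates carry their Z-score; window lengths that are uncalibrated
    (or degenerate, sigma = 0) are skipped with a warning.  The output is
    unresolved -- heavy overlap between candidates is expected.
    """
    ws = sorted({int(w) for w in windows}) if windows is not None else cal.calibrated_windows()
    if scan is None:
        scan = ProteomeScan(proteome, ws, skip_ambiguous=skip_ambiguous)
    ids = scan.ids
    out: list[LCRegion] = []
    for w in ws:
        if not cal.is_calibrated(w):
            logger.warning("skipping uncalibrated window length %d", w)
            continue
        st = cal.stats[w]
        if st.sigma <= 0.0:
            logger.warning("skipping degenerate calibration at w=%d (sigma=0)", w)
            continue
        h, pidx, start = scan.entropies(w)
        mask = h < st.t
        if not mask.any():
            continue
        z = (h[mask] - st.mu) / st.sigma
        for hv, zv, p, s in zip(
            h[mask].tolist(), z.tolist(), pidx[mask].tolist(), start[mask].tolist()
        ):
            out.append(LCRegion(ids[p], s, s + w - 1, hv, zv))
    return out


@dataclass
class ProteomeAnnotation:
    """Resolved LCR annotation over a proteome.

    ``regions`` maps protein id -> disjoint regions (only proteins with at
    least one region appear); ``protein_lengths`` covers the full proteome
    so proteins without LCRs remain known.
    """

    regions: dict[str, list[LCRegion]]
    protein_lengths: dict[str, int]

    @property
    def n_proteins(self) -> int:
        return len(self.protein_lengths)

    @property
    def n_with_lcr(self) -> int:
        return sum(1 for regs in self.regions.values() if regs)

    @property
    def n_single_lcr(self) -> int:
        return sum(1 for regs in self.regions.values() if len(regs) == 1)

    def all_regions(self) -> list[LCRegion]:
        return [r for pid in sorted(self.regions) for r in self.regions[pid]]

    def ids_with_lcr(self) -> set[str]:
        return {pid for pid, regs in self.regions.items() if regs}

    def ids_without_lcr(self) -> set[str]:
        return set(self.protein_lengths) - self.ids_with_lcr()

    def ids_by_class(self, pos_class: str) -> set[str]:
        """Proteins whose (first) region carries the given positional class."""
        if pos_class not in POSITION_CLASSES:
            raise ValueError(f"unknown positional class {pos_class!r}")
        return {
            pid
            for pid, regs in self.regions.items()
            if regs and regs[0].pos_class == pos_class
        }

    def single_lcr_filter(self) -> "ProteomeAnnotation":
        """Sub-annotation of proteins carrying exactly one resolved LCR."""
        return ProteomeAnnotation(
            regions={
                pid: list(regs)
                for pid, regs in self.regions.items()
                if len(regs) == 1
            },
            protein_lengths=dict(self.protein_lengths),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for region in self.all_regions():
            rows.append(
                {
                    "protein_id": region.protein_id,
                    "start": region.start,
                    "end": region.end,
                    "length": region.length,
                    "H": region.H,
                    "Z": region.Z,
                    "centre_norm": region.centre_norm,
                    "folded": region.folded,
                    "pos_class": region.pos_class,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "protein_id",
                "start",
                "end",
                "length",
                "H",
                "Z",
                "centre_norm",
                "folded",
                "pos_class",
            ],
        )

    def write_tsv(self, path) -> None:
        """Tab-separated interval export, 0-based half-open coordinates."""
        df = self.to_dataframe()
        df["start0"] = df["start"] - 1
        df["end_excl"] = df["end"]
        cols = [
            "protein_id",
            "start0",
            "end_excl",
            "length",
            "H",
            "Z",
            "centre_norm",
            "folded",
            "pos_class",
        ]
        df[cols].to_csv(path, sep="\t", index=False)


def single_lcr_filter(annotation: ProteomeAnnotation) -> ProteomeAnnotation:
    """Functional alias for :meth:`ProteomeAnnotation.single_lcr_filter`."""
    return annotation.single_lcr_filter()


def annotate_proteome(
    proteome: Sequence[ProteinRecord],
    cal: CalibrationTable | None = None,
    *,
    w_min: int = DEFAULT_W_MIN,
    w_max: int = DEFAULT_W_MAX,
    alpha: float = DEFAULT_ALPHA,
    windows: Iterable[int] | None = None,
    t_cut: int = DEFAULT_T_CUT,
    c_cut: int = DEFAULT_C_CUT,
    literal_z: bool = False,
    skip_ambiguous: bool = False,
) -> ProteomeAnnotation:
    """Full annotation pass: scan, (optionally) calibrate, detect, resolve.

    When ``cal`` is None the calibration corpus is the proteome itself and
    the scan is shared between calibration and detection, so each window
    length is computed exactly once.
    """
    ws = sorted({int(w) for w in windows}) if windows is not None else list(
        range(w_min, w_max + 1)
    )
    scan = ProteomeScan(
        proteome, ws, skip_ambiguous=skip_ambiguous, cache=cal is None
    )
    if cal is None:
        cal = build_calibration(proteome, alpha=alpha, windows=ws, scan=scan)
    candidates = detect_lcrs(proteome, cal, windows=ws, scan=scan)
    by_protein: dict[str, list[LCRegion]] = {}
    for cand in candidates:
        by_protein.setdefault(cand.protein_id, []).append(cand)
    lengths = {rec.id: rec.length for rec in proteome}
    regions: dict[str, list[LCRegion]] = {}
    for pid, cands in by_protein.items():
        resolved = resolve_overlaps(cands, literal_z=literal_z)
        regions[pid] = [
            annotate_region(r, lengths[pid], t_cut, c_cut) for r in resolved
        ]
    return ProteomeAnnotation(regions=regions, protein_lengths=lengths)
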