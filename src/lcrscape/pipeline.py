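"""End-to-end orchestration: calibrate, detect, position-test, network, enrich.

:func:`analyse` is the in-memory core used by the command line, the test
suite and the acceptance script alike: it takes a proteome, any number of
interaction networks and an optional annotation table, and produces a
single JSON-serialisable report containing every statistic the analysis
tabulates -- LCR counts, the positional KS test, per-network degree
comparisons and length-degree regressions, network LCR enrichment, and
GO-term enrichment for the whole single-LCR set and its terminal /
central subsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__
from .annotate import (
    DEFAULT_C_CUT,
    DEFAULT_T_CUT,
    ProteomeAnnotation,
    annotate_proteome,
)
from .enrichment import DEFAULT_Q_THRESHOLD, AnnotationTable, go_enrichment
from .entropy import (
    DEFAULT_ALPHA,
    DEFAULT_W_MAX,
    DEFAULT_W_MIN,
    CalibrationTable,
    ProteinRecord,
)
from .network import (
    PPINetwork,
    compare_degrees,
    length_degree_regression,
    network_lcr_enrichment,
)
from .positional import DEFAULT_N_REPS, build_position_null, positional_test

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A run configuration names missing inputs or inconsistent parameters."""


@dataclass
class RunConfig:
    """Paths, parameters and flags for one reproducible pipeline run.

    Parameter defaults are the analysis constants used throughout the
    package: window lengths 16-300 aa, calibration tail mass 0.5%,
    terminal cut 25 aa, central cut 50 aa, 1000 null re-insertions.
    """

    fasta: str | None = None
    calibration: str | None = None
    edges: list[str] = field(default_factory=list)
    annotations: str | None = None
    synonyms: str | None = None
    w_min: int = DEFAULT_W_MIN
    w_max: int = DEFAULT_W_MAX
    alpha: float = DEFAULT_ALPHA
    t_cut: int = DEFAULT_T_CUT
    c_cut: int = DEFAULT_C_CUT
    n_reps: int = DEFAULT_N_REPS
    q_threshold: float = DEFAULT_Q_THRESHOLD
    seed: int = 0
    physical_only: bool = False
    folded_ks: bool = True
    literal_z: bool = False
    skip_ambiguous: bool = False

    def validate(self) -> None:
        if self.fasta is None:
            raise ConfigError("a proteome FASTA path is required")
        if not (1 <= self.w_min <= self.w_max):
            raise ConfigError("require 1 <= w_min <= w_max")
        if not (0.0 < self.alpha < 0.5):
            raise ConfigError("alpha must lie in (0, 0.5)")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        for path in [self.fasta, self.calibration, self.annotations, self.synonyms, *self.edges]:
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _safe(fn, *args, **kwargs):
    """Run one report entry, degrading to an {'error': ...} record."""
    try:
        return _jsonable(fn(*args, **kwargs))
    except ValueError as exc:
        return {"error": str(exc)}


def analyse(
    proteome: Sequence[ProteinRecord],
    networks: Mapping[str, PPINetwork],
    annotations: AnnotationTable | None = None,
    *,
    calibration: CalibrationTable | None = None,
    w_min: int = DEFAULT_W_MIN,
    w_max: int = DEFAULT_W_MAX,
    alpha: float = DEFAULT_ALPHA,
    windows: Iterable[int] | None = None,
    t_cut: int = DEFAULT_T_CUT,
    c_cut: int = DEFAULT_C_CUT,
    n_reps: int = DEFAULT_N_REPS,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    seed: int = 0,
    folded_ks: bool = True,
    literal_z: bool = False,
    skip_ambiguous: bool = False,
) -> dict:
    """Run every analysis stage in order and return the report dict.

    The positional test and all group analyses operate on the single-LCR
    sub-annotation; the non-LCR comparison group contains proteins with no
    detected region at all (multi-LCR proteins belong to neither group).
    """
    annotation = annotate_proteome(
        proteome,
        calibration,
        w_min=w_min,
        w_max=w_max,
        alpha=alpha,
        windows=windows,
        t_cut=t_cut,
        c_cut=c_cut,
        literal_z=literal_z,
        skip_ambiguous=skip_ambiguous,
    )
    single = annotation.single_lcr_filter()
    lcr_ids = sorted(single.ids_with_lcr())
    non_lcr_ids = sorted(annotation.ids_without_lcr())
    terminal_ids = sorted(single.ids_by_class("terminal"))
    central_ids = sorted(single.ids_by_class("central"))
    intermediate_ids = sorted(single.ids_by_class("intermediate"))
    single_regions = {pid: single.regions[pid][0] for pid in lcr_ids}

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "seed": int(seed),
            "parameters": {
                "w_min": w_min,
                "w_max": w_max,
                "alpha": alpha,
                "windows": sorted({int(w) for w in windows}) if windows is not None else None,
                "t_cut": t_cut,
                "c_cut": c_cut,
                "n_reps": n_reps,
                "q_threshold": q_threshold,
                "folded_ks": folded_ks,
                "literal_z": literal_z,
            },
        },
        "counts": {
            "proteins_total": annotation.n_proteins,
            "proteins_with_lcr": annotation.n_with_lcr,
            "proteins_single_lcr": annotation.n_single_lcr,
            "terminal": len(terminal_ids),
            "central": len(central_ids),
            "intermediate": len(intermediate_ids),
        },
    }

    # --- positional bias against the re-insertion null -------------------
    rng = np.random.default_rng(seed)
    if lcr_ids:
        shapes = [
            (annotation.protein_lengths[pid], single_regions[pid].length)
            for pid in lcr_ids
        ]
        observed = [single_regions[pid].centre_norm for pid in lcr_ids]
        null = build_position_null(shapes, n_reps=n_reps, rng=rng)
        report["positional"] = _safe(
            positional_test, observed, null, folded=folded_ks
        )
        if isinstance(report["positional"], dict) and "error" not in report["positional"]:
            report["positional"]["n_reps"] = n_reps
    else:
        report["positional"] = {"error": "no single-LCR proteins detected"}

    # --- per-network connectivity analyses --------------------------------
    proteome_ids = sorted(annotation.protein_lengths)
    report["networks"] = {}
    for net_name in sorted(networks):
        net = networks[net_name]
        entry: dict = {"nodes": net.n_nodes, "edges": net.n_edges}
        entry["degree_comparisons"] = {
            "lcr_vs_nonlcr": _safe(
                compare_degrees, net, lcr_ids, non_lcr_ids,
                label_a="single-LCR", label_b="non-LCR",
            ),
            "terminal_vs_central": _safe(
                compare_degrees, net, terminal_ids, central_ids,
                label_a="terminal", label_b="central",
            ),
            "terminal_vs_nonlcr": _safe(
                compare_degrees, net, terminal_ids, non_lcr_ids,
                label_a="terminal", label_b="non-LCR",
            ),
            "central_vs_nonlcr": _safe(
                compare_degrees, net, central_ids, non_lcr_ids,
                label_a="central", label_b="non-LCR",
            ),
        }

        def _regression(ids: list[str], label: str):
            present = [pid for pid in ids if pid in net.graph]
            lengths = [single_regions[pid].length for pid in present]
            degrees = [net.graph.degree[pid] for pid in present]
            return length_degree_regression(lengths, degrees, label=label)

        entry["regressions"] = {
            "terminal": _safe(_regression, terminal_ids, "terminal"),
            "central": _safe(_regression, central_ids, "central"),
        }
        entry["lcr_enrichment"] = _safe(
            network_lcr_enrichment, net, lcr_ids, proteome_ids
        )
        report["networks"][net_name] = entry

    # --- GO-term over-representation --------------------------------------
    if annotations is not None:
        background = proteome_ids
        report["go"] = {}
        for label, study in (
            ("all_lcr", lcr_ids),
            ("terminal", terminal_ids),
            ("central", central_ids),
        ):
            if not study:
                report["go"][label] = {"error": "empty study set"}
                continue
            rows, rep = go_enrichment(
                study, background, annotations, q_threshold=q_threshold
            )
            report["go"][label] = {
                "n_study": len(study),
                "n_significant": int(len(rep)),
                "significant": rep.to_dict(orient="records"),
                "rows": [_jsonable(r) for r in rows],
            }
    return report


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline from file inputs per ``config``.

    Any stage failure aborts with the stage name attached to the raised
    exception; a partial report is not fabricated.
    """
    from .io import read_fasta, read_synonym_map
    from .enrichment import read_annotations
    from .network import read_network

    config.validate()
    stage = "load"
    try:
        proteome = read_fasta(config.fasta)
        synonyms = read_synonym_map(config.synonyms) if config.synonyms else None
        networks = {}
        for path in config.edges:
            net = read_network(
                path,
                name=Path(path).stem,
                physical_only=config.physical_only,
                synonyms=synonyms,
            )
            networks[net.name] = net
        annotations = (
            read_annotations(config.annotations) if config.annotations else None
        )
        calibration = (
            CalibrationTable.from_tsv(config.calibration)
            if config.calibration
            else None
        )
        stage = "analyse"
        report = analyse(
            proteome,
            networks,
            annotations,
            calibration=calibration,
            w_min=config.w_min,
            w_max=config.w_max,
            alpha=config.alpha,
            t_cut=config.t_cut,
            c_cut=config.c_cut,
            n_reps=config.n_reps,
            q_threshold=config.q_threshold,
            seed=config.seed,
            folded_ks=config.folded_ks,
            literal_z=config.literal_z,
            skip_ambiguous=config.skip_ambiguous,
        )
    except ConfigError:
        raise
    except Exception as exc:  # annotate the failing stage for the caller
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    cfg_json = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    report["provenance"]["config"] = _jsonable(dataclasses.asdict(config))
    report["provenance"]["config_sha256"] = hashlib.sha256(
        cfg_json.encode()
    ).hexdigest()
    return report
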