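"""Stage orchestration: markers -> msap -> deg -> additivity.

Each stage reads its validated inputs, runs the corresponding module, writes
its per-item and summary outputs under the output directory, and contributes
one entry to the run report. Any stage failure raises :class:`StageError`
carrying the stage name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, additivity, expression, io, markers, msap
from .errors import PolyhybError, StageError
from .expression import ExpressionSet

logger = logging.getLogger(__name__)

STAGES = ("markers", "msap", "deg", "additivity")

__all__ = ["STAGES", "RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """Consolidated record of one pipeline run."""

    version: str
    config: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, summary: dict) -> None:
        if any(s["stage"] == name for s in self.stages):
            raise PolyhybError(f"stage {name} already reported")
        self.stages.append({"stage": name, "summary": summary})

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _marker_stage(config: io.RolesConfig, path, outdir: Path, report: RunReport) -> None:
    matrix = io.read_marker_table(path)
    summary: dict = {}
    classes, class_summary = markers.classify_fragments(
        matrix, config.hybrid, config.maternal, config.paternal
    )
    io.write_tsv(classes.to_frame(), outdir / "marker_classes_hybrid.tsv", "fragment_id")
    io.write_tsv(class_summary, outdir / "marker_class_summary_hybrid.tsv", "fragment_class")
    summary["hybrid_classes"] = {
        "counts": {k: int(class_summary.loc[k, "count"]) for k in markers.FRAGMENT_CLASSES},
        "percent": {k: float(class_summary.loc[k, "percent"]) for k in markers.FRAGMENT_CLASSES},
        "total": int(class_summary.loc["total", "count"]),
    }
    tallies = {}
    for allo in config.allopolyploids:
        records, tally = markers.classify_alterations(
            matrix, allo, config.maternal, config.paternal, config.hybrid
        )
        io.write_tsv(records, outdir / f"marker_alterations_{allo}.tsv", "fragment_id")
        tallies[allo] = tally
    if tallies:
        combined = markers.alteration_summary(tallies, warn=report.warnings.append)
        io.write_tsv(combined, outdir / "marker_alteration_summary.tsv", "alteration")
        summary["alterations"] = {
            allo: {
                "counts": {t: int(tally.loc[t, "count"]) for t in markers.ALTERATION_TYPES},
                "percent": {t: float(combined.loc[t, f"{allo}_percent"]) for t in markers.ALTERATION_TYPES},
                "subtotal": int(combined.loc["subtotal", f"{allo}_count"]),
            }
            for allo, tally in tallies.items()
        }
    report.add_stage("markers", summary)


def _msap_stage(config: io.RolesConfig, path, outdir: Path, report: RunReport) -> None:
    table = io.read_msap_table(path)
    lines = [config.hybrid, *config.allopolyploids]
    states = msap.call_states(table, lines)
    io.write_tsv(states, outdir / "msap_states.tsv", "site_id")
    summary: dict = {"levels": {}}
    for line in lines:
        summary["levels"][line] = msap.methylation_level(states[line])
    level_table = pd.DataFrame(summary["levels"]).T
    io.write_tsv(level_table, outdir / "msap_levels.tsv", "line")
    if config.allopolyploids:
        counts = {
            allo: msap.transition_counts(states, config.hybrid, allo)
            for allo in config.allopolyploids
        }
        transitions = msap.transition_summary(counts)
        io.write_tsv(transitions, outdir / "msap_transitions.tsv", "category")
        summary["transitions"] = {
            name: {"mean": float(row["mean"]), "se": None if pd.isna(row["se"]) else float(row["se"]), "direction": row["direction"]}
            for name, row in transitions.iterrows()
        }
    report.add_stage("msap", summary)


def _load_expression(inputs: dict) -> ExpressionSet:
    counts = io.read_counts(inputs["counts"])
    lengths = io.read_series(inputs["lengths"], "gene_id", "length_bp")
    libsizes = io.read_series(inputs["libsizes"], "sample", "library_size")
    return ExpressionSet(counts=counts, lengths=lengths, library_sizes=libsizes)


def _deg_stage(config: io.RolesConfig, inputs: dict, outdir: Path, report: RunReport) -> dict:
    expr = _load_expression(inputs)
    if "matches" in inputs and inputs["matches"] is not None:
        matches = io.read_blast_tabular(inputs["matches"])
        retained = expression.filter_homologs(
            matches,
            max_evalue=config.homolog_max_evalue,
            min_align_length=config.homolog_min_align_length,
            min_identity=config.homolog_min_identity,
        )
        io.write_tsv(retained, outdir / "homologs_retained.tsv")
    derived_lines = [
        line
        for line in (config.hybrid, *config.allopolyploids)
        if line in expr.counts.columns
    ]
    summary: dict = {}
    tables: dict = {}
    for derived in derived_lines:
        for parent in (config.maternal, config.paternal):
            deg_table, totals = expression.call_degs(
                expr,
                parent,
                derived,
                epsilon=config.epsilon,
                p_threshold=config.p_threshold,
            )
            key = f"{derived}_vs_{parent}"
            io.write_tsv(deg_table, outdir / f"deg_{key}.tsv", "gene_id")
            summary[key] = totals
            tables[key] = deg_table
    report.add_stage("deg", summary)
    return {"expr": expr, "tables": tables, "derived_lines": derived_lines}


def _additivity_stage(
    config: io.RolesConfig, deg_state: dict, outdir: Path, report: RunReport
) -> None:
    expr: ExpressionSet = deg_state["expr"]
    fpkm = expr.fpkm
    summary: dict = {}
    for derived in deg_state["derived_lines"]:
        flags = pd.DataFrame(
            {
                "maternal": fpkm[config.maternal] > config.detection_fpkm,
                "paternal": fpkm[config.paternal] > config.detection_fpkm,
                "derived": fpkm[derived] > config.detection_fpkm,
            }
        )
        categories, venn_counts = additivity.partition_expressed(flags)
        deg_mat = deg_state["tables"][f"{derived}_vs_{config.maternal}"]
        deg_pat = deg_state["tables"][f"{derived}_vs_{config.paternal}"]
        shared = deg_mat.index.intersection(deg_pat.index)
        calls = additivity.classify_additivity(
            fpkm.loc[shared, derived],
            fpkm.loc[shared, config.maternal],
            fpkm.loc[shared, config.paternal],
            deg_mat.loc[shared, "status"] != "not_de",
            deg_pat.loc[shared, "status"] != "not_de",
            epsilon=config.epsilon,
        )
        patterns, pattern_counts = additivity.assign_patterns(deg_mat, deg_pat)
        io.write_tsv(
            calls.join(patterns), outdir / f"additivity_{derived}.tsv", "gene_id"
        )
        summary[derived] = {
            "venn": {k: int(v) for k, v in venn_counts.items()},
            "additivity": additivity.additivity_summary(calls),
            "patterns": pattern_counts,
        }
    report.add_stage("additivity", summary)


def run_pipeline(
    config: io.RolesConfig,
    inputs: dict,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> RunReport:
    """Run the requested stages in canonical order and write all outputs.

    ``inputs`` maps input names (``markers``, ``msap``, ``counts``,
    ``lengths``, ``libsizes``, optionally ``matches``) to file paths. The
    ``additivity`` stage requires the ``deg`` stage. Fully deterministic
    given the same config and inputs.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PolyhybError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    if "additivity" in ordered and "deg" not in ordered:
        raise PolyhybError("the additivity stage requires the deg stage")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=vars(config).copy())

    deg_state = None
    for stage in ordered:
        logger.info("running stage %s", stage)
        try:
            if stage == "markers":
                _marker_stage(config, inputs["markers"], outdir, report)
            elif stage == "msap":
                _msap_stage(config, inputs["msap"], outdir, report)
            elif stage == "deg":
                deg_state = _deg_stage(config, inputs, outdir, report)
            elif stage == "additivity":
                _additivity_stage(config, deg_state, outdir, report)
        except KeyError as exc:
            raise StageError(stage, f"missing input {exc}") from exc
        except PolyhybError as exc:
            if isinstance(exc, StageError):
                raise
            raise StageError(stage, str(exc)) from exc
    io.write_json(report.to_dict(), outdir / "run_report.json")
    return report
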