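"""End-to-end benchmarking experiments: sweeps over read length, error rate
or transcriptome complexity.

Each sweep value runs the same chain — build or load the reference
transcriptome, simulate paired reads, hand them to the assembler hook (or a
built-in stub), align the assembly back to the reference, evaluate — and
contributes one row of the four metrics to the experiment report.  Every
per-value directory carries a manifest with the config hash and seeds, and a
finished value is not recomputed when the experiment is re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import assemblers
from .align import align_all
from .evaluate import DEFAULT_MIN_LENGTH, EvalMetrics, evaluate, EvalCounts
from .simulate import SimulationConfig, assign_expression, simulate, write_fastq
from .transcriptome import (
    TranscriptSet,
    load_reference_transcripts,
    synthesize_transcriptome,
)

EXPERIMENT_KINDS = ("read_length_sweep", "error_sweep", "complexity_sweep")

SWEEP_COLUMN = {
    "read_length_sweep": "Read Length",
    "error_sweep": "Error Rate",
    "complexity_sweep": "Isoforms Per Gene",
}
METRIC_COLUMNS = (
    "Full-length Percentage",
    "False Positive Rate",
    "Nucleotide Sensitivity",
    "Nucleotide Specificity",
)


@dataclass
class SynthesisSpec:
    """How to build a synthetic reference when no FASTA is given.

    ``exon_length`` fixes every exon to that many bp; when None the default
    log-normal exon-length sampler is used.
    """

    n_genes: int = 100
    isoform_range: tuple[int, int] = (1, 2)
    exon_count_range: tuple[int, int] = (4, 12)
    exon_length: int | None = None


@dataclass
class ExperimentConfig:
    experiment_kind: str
    sweep_values: list[Any]
    sim: SimulationConfig
    reference_fasta: str | None = None
    synthesis: SynthesisSpec | None = None
    assembler: Any = None  # callable hook, "stub:..." spec, or shell template
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.experiment_kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind: {self.experiment_kind}")
        if not self.sweep_values:
            raise ValueError("sweep_values must be non-empty")
        if self.experiment_kind == "read_length_sweep":
            bad = [v for v in self.sweep_values if not (1 <= int(v) <= self.sim.insert_size)]
            if bad:
                raise ValueError(f"read lengths must lie in [1, insert_size]: {bad}")
        elif self.experiment_kind == "error_sweep":
            bad = [v for v in self.sweep_values if not (0.0 <= float(v) <= 1.0)]
            if bad:
                raise ValueError(f"error rates must lie in [0, 1]: {bad}")
        else:
            for v in self.sweep_values:
                lo, hi = v
                if lo < 1 or hi < lo:
                    raise ValueError(f"invalid isoform range {v}")
        if self.reference_fasta is None and self.synthesis is None:
            self.synthesis = SynthesisSpec()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = SimulationConfig(**raw["sim"])
        synthesis = None
        if "synthesis" in raw and raw["synthesis"] is not None:
            syn = dict(raw["synthesis"])
            if "isoform_range" in syn:
                syn["isoform_range"] = tuple(syn["isoform_range"])
            if "exon_count_range" in syn:
                syn["exon_count_range"] = tuple(syn["exon_count_range"])
            synthesis = SynthesisSpec(**syn)
        sweep = raw["sweep_values"]
        if raw["experiment_kind"] == "complexity_sweep":
            sweep = [tuple(v) for v in sweep]
        return cls(
            experiment_kind=raw["experiment_kind"],
            sweep_values=sweep,
            sim=sim,
            reference_fasta=raw.get("reference_fasta"),
            synthesis=synthesis,
            assembler=raw.get("assembler"),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        payload = {
            "experiment_kind": self.experiment_kind,
            "sweep_values": [list(v) if isinstance(v, tuple) else v for v in self.sweep_values],
            "sim": dataclasses.asdict(self.sim),
            "reference_fasta": self.reference_fasta,
            "synthesis": dataclasses.asdict(self.synthesis) if self.synthesis else None,
            "assembler": self.assembler if isinstance(self.assembler, str) else repr(self.assembler),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class ReportRow:
    sweep_value: Any
    metrics: EvalMetrics | None
    status: str = "ok"  # "ok", "simulated" (no assembler), "assembler_failed"
    config_hash: str = ""
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class ExperimentReport:
    experiment_kind: str
    rows: list[ReportRow]
    threshold: Any = None


# ---------------------------------------------------------------------------
# running experiments
# ---------------------------------------------------------------------------


def _sim_for_value(config: ExperimentConfig, value: Any) -> SimulationConfig:
    sim = dataclasses.replace(config.sim)
    if config.experiment_kind == "read_length_sweep":
        sim.read_length = int(value)
    elif config.experiment_kind == "error_sweep":
        sim.error_rate = float(value)
    return sim


def _reference_for_value(config: ExperimentConfig, value: Any) -> TranscriptSet:
    if config.reference_fasta is not None:
        return load_reference_transcripts(config.reference_fasta)
    spec = config.synthesis
    isoform_range = (
        tuple(value) if config.experiment_kind == "complexity_sweep" else spec.isoform_range
    )
    _, _, tx = synthesize_transcriptome(
        spec.n_genes,
        isoform_range,
        seed=config.seed,
        exon_count_range=spec.exon_count_range,
        exon_length_sampler=spec.exon_length,
    )
    return tx


def _value_tag(value: Any) -> str:
    if isinstance(value, tuple):
        return f"{value[0]}-{value[1]}"
    return str(value).replace(".", "p")


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full sweep; one report row per sweep value.

    A failing external assembler yields an ``assembler_failed`` row and the
    sweep continues.  With no assembler hook the pipeline stops after
    simulation for each value (status ``simulated``).
    """
    out_root = Path(config.output_dir) if config.output_dir else None
    chash = config.config_hash()
    hook = assemblers.resolve_assembler(config.assembler)
    rows: list[ReportRow] = []
    for value in config.sweep_values:
        vdir = out_root / f"value_{_value_tag(value)}" if out_root else None
        if vdir is not None:
            cached = _load_cached_row(vdir, chash, value)
            if cached is not None:
                rows.append(cached)
                continue
            vdir.mkdir(parents=True, exist_ok=True)
        sim_cfg = _sim_for_value(config, value)
        reference = _reference_for_value(config, value)
        profile = assign_expression(reference, sim_cfg)
        result = simulate(reference, profile, sim_cfg)
        reads1 = reads2 = None
        if vdir is not None:
            reads1, reads2 = vdir / "reads_1.fastq", vdir / "reads_2.fastq"
            write_fastq(result.pairs, reads1, reads2, vdir / "truth.tsv")
            reference.to_fasta(vdir / "reference.fasta")
        provenance = {
            "n_reference": len(reference),
            "n_pairs": len(result.pairs),
            "n_skipped_transcripts": len(result.skipped),
            "seed": config.seed,
            "sim": dataclasses.asdict(sim_cfg),
        }
        if hook is None:
            row = ReportRow(value, None, status="simulated", config_hash=chash, provenance=provenance)
        else:
            try:
                assembly = hook(reference, reads1, reads2, vdir or Path("."))
            except assemblers.ExternalAssemblerError as exc:
                provenance["assembler_error"] = str(exc)
                row = ReportRow(
                    value, None, status="assembler_failed", config_hash=chash, provenance=provenance
                )
            else:
                alignments = align_all(assembly, reference)
                metrics = evaluate(assembly, reference, alignments)
                provenance["n_assembled_raw"] = len(assembly)
                row = ReportRow(value, metrics, status="ok", config_hash=chash, provenance=provenance)
        rows.append(row)
        if vdir is not None:
            _save_row(vdir, row)
    report = ExperimentReport(experiment_kind=config.experiment_kind, rows=rows)
    if config.experiment_kind == "read_length_sweep" and all(
        r.status == "ok" for r in rows
    ) and len(rows) >= 2:
        report.threshold = detect_threshold(report)
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)
        write_report(report, out_root / "report.tsv")
        with open(out_root / "manifest.json", "w") as fh:
            json.dump({"config_hash": chash, "seed": config.seed}, fh, indent=2)
    return report


def _row_payload(row: ReportRow) -> dict:
    d = {
        "sweep_value": list(row.sweep_value) if isinstance(row.sweep_value, tuple) else row.sweep_value,
        "status": row.status,
        "config_hash": row.config_hash,
        "provenance": row.provenance,
        "metrics": None,
    }
    if row.metrics is not None:
        d["metrics"] = {
            "full_length_pct": row.metrics.full_length_pct,
            "false_positive_pct": row.metrics.false_positive_pct,
            "nt_sensitivity_pct": row.metrics.nt_sensitivity_pct,
            "nt_specificity_pct": row.metrics.nt_specificity_pct,
            "counts": dataclasses.asdict(row.metrics.counts),
            "specificity_undefined": row.metrics.specificity_undefined,
        }
    return d


def _save_row(vdir: Path, row: ReportRow) -> None:
    with open(vdir / "metrics.json", "w") as fh:
        json.dump(_row_payload(row), fh, indent=2)


def _load_cached_row(vdir: Path, chash: str, value: Any) -> ReportRow | None:
    path = vdir / "metrics.json"
    if not path.exists():
        return None
    with open(path) as fh:
        d = json.load(fh)
    if d.get("config_hash") != chash:
        return None
    metrics = None
    if d["metrics"] is not None:
        m = d["metrics"]
        metrics = EvalMetrics(
            full_length_pct=m["full_length_pct"],
            false_positive_pct=m["false_positive_pct"],
            nt_sensitivity_pct=m["nt_sensitivity_pct"],
            nt_specificity_pct=m["nt_specificity_pct"],
            counts=EvalCounts(**m["counts"]),
            specificity_undefined=m["specificity_undefined"],
        )
    return ReportRow(
        sweep_value=value,
        metrics=metrics,
        status=d["status"],
        config_hash=d["config_hash"],
        provenance=d.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# threshold detection
# ---------------------------------------------------------------------------


def detect_threshold(report: ExperimentReport, tol_pct: float = 1.0):
    """Find the read length beyond which assembly quality plateaus.

    The plateau criteria: relative to the candidate value, every longer read
    length gains at most ``tol_pct`` in full-length percentage, does not
    decrease the false positive rate, and gains at most ``tol_pct`` in
    nucleotide sensitivity.  (A small specificity decrease is tolerated and
    not gated.)  Returns the smallest such value, or None when quality is
    still improving at the longest read length tried.
    """
    if report.experiment_kind != "read_length_sweep":
        raise ValueError("threshold detection applies to read-length sweeps only")
    rows = [r for r in report.rows if r.metrics is not None]
    if len(rows) < 2:
        raise ValueError("need at least two metric rows to detect a plateau")
    rows = sorted(rows, key=lambda r: r.sweep_value)
    for i, cand in enumerate(rows[:-1]):
        m0 = cand.metrics
        plateau = True
        for later in rows[i + 1 :]:
            m1 = later.metrics
            if (
                m1.full_length_pct - m0.full_length_pct > tol_pct
                or m1.false_positive_pct < m0.false_positive_pct
                or m1.nt_sensitivity_pct - m0.nt_sensitivity_pct > tol_pct
            ):
                plateau = False
                break
        if plateau:
            return cand.sweep_value
    return None


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------


def report_frame(report: ExperimentReport) -> pd.DataFrame:
    sweep_col = SWEEP_COLUMN[report.experiment_kind]
    records = []
    for row in report.rows:
        rec: dict[str, Any] = {
            sweep_col: (
                f"{row.sweep_value[0]}~{row.sweep_value[1]}"
                if isinstance(row.sweep_value, tuple)
                else row.sweep_value
            )
        }
        if row.metrics is not None:
            rec.update(zip(METRIC_COLUMNS, row.metrics.as_tuple()))
        else:
            rec.update({c: float("nan") for c in METRIC_COLUMNS})
        rec["Status"] = row.status
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=[sweep_col, *METRIC_COLUMNS, "Status"])


def write_report(report: ExperimentReport, path: str | Path) -> None:
    """TSV report with the conventional column layout; one decimal on percentages."""
    df = report_frame(report)
    df.to_csv(path, sep="\t", index=False, float_format="%.1f")


def read_report(path: str | Path, experiment_kind: str) -> ExperimentReport:
    """Load a written report back into an (alignment-free) ExperimentReport."""
    df = pd.read_csv(path, sep="\t")
    sweep_col = SWEEP_COLUMN[experiment_kind]
    rows = []
    for _, rec in df.iterrows():
        value = rec[sweep_col]
        if isinstance(value, str) and "~" in value:
            lo, hi = value.split("~")
            value = (int(lo), int(hi))
        metrics = None
        if rec["Status"] == "ok":
            metrics = EvalMetrics(
                full_length_pct=float(rec["Full-length Percentage"]),
                false_positive_pct=float(rec["False Positive Rate"]),
                nt_sensitivity_pct=float(rec["Nucleotide Sensitivity"]),
                nt_specificity_pct=float(rec["Nucleotide Specificity"]),
                counts=EvalCounts(0, 0, 0, 0, 0, 0, 0, 0),
            )
        rows.append(ReportRow(sweep_value=value, metrics=metrics, status=rec["Status"]))
    return ExperimentReport(experiment_kind=experiment_kind, rows=rows)


def make_metrics_row(
    sweep_value: Any,
    full_length_pct: float,
    false_positive_pct: float,
    nt_sensitivity_pct: float,
    nt_specificity_pct: float,
) -> ReportRow:
    """Construct a metrics row directly (e.g. from published tables)."""
    return ReportRow(
        sweep_value=sweep_value,
        metrics=EvalMetrics(
            full_length_pct=full_length_pct,
            false_positive_pct=false_positive_pct,
            nt_sensitivity_pct=nt_sensitivity_pct,
            nt_specificity_pct=nt_specificity_pct,
            counts=EvalCounts(0, 0, 0, 0, 0, 0, 0, 0),
        ),
    )
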