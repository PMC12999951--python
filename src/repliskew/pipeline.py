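"""Per-replicon analysis orchestration and batch aggregation."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_io
from .div_fit import DEFAULT_MAX_COARSE, fit_div
from .genome_io import Replicon, Topology, build_position_labels
from .skew_core import (
    DEFAULT_WINDOW_SIZE,
    SKEW_CLASSES,
    cumulative_profile,
    gsb_profile,
    windowed_skew,
    write_profiles_tsv,
)
from .skew_index import DEFAULT_SKEWI_WINDOW, skew_index
from .stats_correlate import (
    PCC_STATISTICS,
    ClassSummary,
    CorrelationSet,
    aggregate_class,
    compare_groups,
    pearson,
    summaries_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything that parametrizes a run; hashed into every output record."""

    schema_version: int = 1
    window_size: int = DEFAULT_WINDOW_SIZE
    skewi_window: int = DEFAULT_SKEWI_WINDOW
    feature_type: str = "CDS"
    annotation_format: str = "gff3"
    sequence_format: str = "fasta"
    gene_oriented: bool = False
    default_topology: str = "circular"
    max_coarse: int = DEFAULT_MAX_COARSE
    force_linear: bool = False

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class GenomeRecord:
    replicon_id: str
    length: int
    class_label: str
    config_hash: str
    window_size: int
    skewi_window: int
    skewi: float | None = None
    skewi_qc_pass: bool | None = None
    skewi_qc_reason: str | None = None
    div: float | None = None
    ori_bp: int | None = None
    ter_bp: int | None = None
    slope_lead: float | None = None
    slope_lag: float | None = None
    drift: float | None = None
    rms_residual: float | None = None
    div_note: str | None = None
    pcc_total: float | None = None
    pcc_codon1: float | None = None
    pcc_codon2: float | None = None
    pcc_codon3: float | None = None
    pcc_noncoding: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def correlation_set(self) -> CorrelationSet:
        return CorrelationSet(
            self.replicon_id,
            self.class_label,
            self.pcc_total,
            self.pcc_codon1,
            self.pcc_codon2,
            self.pcc_codon3,
            self.pcc_noncoding,
        )


def analyze_replicon_obj(
    replicon: Replicon,
    features: genome_io.FeatureTable | None,
    config: AnalysisConfig = AnalysisConfig(),
    class_label: str = "other",
    curves_out: str | Path | None = None,
) -> GenomeRecord:
    """Run the full per-replicon analysis on in-memory objects.

    An unannotated replicon yields a total-skew-only record (sub-skews and
    PCCs missing).  Module errors propagate with the stage name prefixed.
    """
    record = GenomeRecord(
        replicon_id=replicon.id,
        length=replicon.length,
        class_label=class_label,
        config_hash=config.hash(),
        window_size=config.window_size,
        skewi_window=config.skewi_window,
    )

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name}: {exc}") from exc

    labels = None
    if features is not None and len(features) > 0:
        labels = _stage("genome_io", lambda: build_position_labels(replicon, features))

    classes = SKEW_CLASSES if labels is not None else ("total",)
    profiles = {}
    cumulatives = {}
    for cls in classes:
        prof = _stage(
            "skew_core",
            lambda c=cls: windowed_skew(
                replicon, labels, c, config.window_size, gene_oriented=config.gene_oriented
            ),
        )
        profiles[cls] = prof
        cumulatives[cls] = cumulative_profile(prof)

    if curves_out is not None:
        write_profiles_tsv(curves_out, cumulatives, profiles)

    if replicon.length >= 2 * config.skewi_window:
        si = _stage("skew_index", lambda: skew_index(replicon, config.skewi_window))
        record.skewi = si.skewi
        record.skewi_qc_pass = si.qc_pass
        record.skewi_qc_reason = si.qc_reason

    if cumulatives["total"].n_windows >= 8:
        df = _stage(
            "div_fit",
            lambda: fit_div(
                cumulatives["total"],
                topology=replicon.topology,
                force_linear=config.force_linear,
                max_coarse=config.max_coarse,
            ),
        )
        record.div = df.div
        record.ori_bp = df.ori_bp
        record.ter_bp = df.ter_bp
        record.slope_lead = df.slope_lead
        record.slope_lag = df.slope_lag
        record.drift = df.drift
        record.rms_residual = df.rms_residual
        record.div_note = df.note

    if labels is not None and cumulatives["total"].n_windows >= 3:
        gsb = gsb_profile(labels, config.window_size).cumulative.astype(float)
        for cls in SKEW_CLASSES:
            cum = cumulatives[cls].cumulative
            if np.ptp(cum) == 0 or np.ptp(gsb) == 0:
                continue
            setattr(record, f"pcc_{cls}", _stage("stats_correlate", lambda c=cum: pearson(gsb, c)))
    return record


def analyze_replicon(
    fasta: str | Path,
    annotation: str | Path | None,
    config: AnalysisConfig = AnalysisConfig(),
    class_label: str = "other",
    curves_out: str | Path | None = None,
) -> list[GenomeRecord]:
    """File-level entry point: one GenomeRecord per replicon in the FASTA."""
    replicons = genome_io.read_replicons(
        fasta, config.sequence_format, Topology(config.default_topology)
    )
    table = None
    if annotation is not None:
        lengths = {r.id: r.length for r in replicons}
        table = genome_io.read_features(
            annotation, config.annotation_format, config.feature_type, lengths
        )
    records = []
    for rep in replicons:
        feats = table.for_replicon(rep.id) if table is not None else None
        out = None
        if curves_out is not None:
            out = Path(curves_out)
            if len(replicons) > 1:
                out = out.with_name(f"{out.stem}.{rep.id}{out.suffix}")
        records.append(analyze_replicon_obj(rep, feats, config, class_label, out))
    return records


def batch_run(
    manifest: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[list[GenomeRecord], list[ClassSummary], list[dict]]:
    """Analyze every manifest row (fasta, annotation, class_label); aggregate.

    Per-genome failures are logged and skipped, never silently dropped; if
    every row fails, raises.
    """
    required = {"fasta", "annotation", "class_label"}
    if manifest.empty:
        raise ValueError("empty manifest")
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    records: list[GenomeRecord] = []
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        annot = row["annotation"]
        if isinstance(annot, float) or annot in ("", None, "."):
            annot = None
        try:
            records.extend(
                analyze_replicon(row["fasta"], annot, config, str(row["class_label"]))
            )
        except Exception as exc:
            logger.error("row %s failed: %s", row["fasta"], exc)
            failures.append({"fasta": str(row["fasta"]), "error": str(exc)})
    if not records:
        raise RuntimeError(f"all {len(failures)} manifest rows failed")
    summaries = summarize_records(records)
    return records, summaries, failures


def summarize_records(records: list[GenomeRecord]) -> list[ClassSummary]:
    summaries = []
    by_class: dict[str, list[CorrelationSet]] = {}
    for rec in records:
        by_class.setdefault(rec.class_label, []).append(rec.correlation_set())
    for label, sets in sorted(by_class.items()):
        for stat in PCC_STATISTICS:
            if any(s.get(stat) is not None for s in sets):
                summaries.append(aggregate_class(sets, stat))
    return summaries


def records_to_frame(records: list[GenomeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def compare_classes(
    records: list[GenomeRecord], field_name: str, method: str
) -> "object":
    """Group comparison of one numeric record field across class labels."""
    groups: dict[str, list[float]] = {}
    for rec in records:
        v = getattr(rec, field_name)
        if v is not None:
            groups.setdefault(rec.class_label, []).append(v)
    return compare_groups({k: np.array(v) for k, v in groups.items()}, method)
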