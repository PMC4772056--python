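"""Batch orchestration and report export.

Reproduces the automated workflow: discover every dataset under a root
directory, run the processing chain and composition analysis on each, and
export the per-sample table (MUFA, PUFA, SFA, IV, F/H) as comma-separated
values or a fixed-width text file.  A failing sample never aborts the
batch; its row records the failure reason.
"""

from __future__ import annotations

import csv
import datetime
import io
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bruker import discover_datasets, read_dataset
from .composition import FACResult, analyze_sample
from .config import AnalysisConfig
from .integration import default_regions
from .processing import process

__all__ = ["SampleRow", "BatchReport", "run_batch", "export", "parse_csv"]

CSV_COLUMNS = ["sample", "mufa_pct", "pufa_pct", "sfa_pct", "iv", "fh_ratio", "flags"]


@dataclass
class SampleRow:
    label: str
    path: str
    result: FACResult | None
    status: str  # "ok" or "failed: <reason>"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class BatchReport:
    rows: list[SampleRow]
    config: AnalysisConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_ok(self) -> int:
        return sum(r.ok for r in self.rows)

    @property
    def exit_code(self) -> int:
        """0: all analysed (or nothing to do); 2: partial; 3: all failed."""
        if not self.rows or self.n_ok == len(self.rows):
            return 0
        return 3 if self.n_ok == 0 else 2


def run_batch(root: str | Path, config: AnalysisConfig | None = None) -> BatchReport:
    """Process and analyse every dataset below *root*.

    Per dataset: read -> transform -> (auto-phase) -> baseline ->
    (TMS reference) -> quality -> integrate -> composition.  Errors are
    captured per sample.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"unreadable root directory: {root}")
    config = config or AnalysisConfig()
    rows: list[SampleRow] = []
    for path in discover_datasets(root):
        label = path.name
        try:
            fid = read_dataset(path)
            label = fid.sample_label or label
            regions = default_regions(
                field_mhz=fid.params.spectrometer_frequency,
                temperature=fid.params.temperature,
                water_halfwidth=config.water_exclusion_halfwidth,
                water_delta_30c=config.water_delta_30c,
                water_slope=config.water_slope,
                windows=config.windows,
            )
            spectrum, quality = process(
                fid,
                zero_fill_to=config.zero_fill_to,
                do_auto_phase=config.auto_phase,
                do_auto_reference=config.auto_reference,
                baseline_lam=config.baseline_lam,
                baseline_p=config.baseline_p,
                snr_min=config.snr_min,
            )
            result = analyze_sample(
                spectrum,
                regions,
                quality,
                tail_correction=config.tail_correction,
                eq2_uses_h=config.eq2_uses_h,
                j_includes_sn2=config.j_includes_sn2,
                fh_band=config.fh_band,
                sample_label=label,
            )
            rows.append(SampleRow(label, str(path), result, "ok"))
        except Exception as exc:  # per-sample failure, batch continues
            rows.append(SampleRow(label, str(path), None, f"failed: {exc}"))
    metadata = {
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "config_digest": config.digest,
        "version": __version__,
        "root": str(root),
    }
    return BatchReport(rows=rows, config=config, metadata=metadata)


def _format_row(row: SampleRow) -> list[str]:
    if row.result is None:
        return [row.label, "", "", "", "", "", row.status]
    r = row.result
    return [
        row.label,
        f"{r.mufa:.2f}",
        f"{r.pufa:.2f}",
        f"{r.sfa:.2f}",
        f"{r.iv:.2f}",
        f"{r.fh_ratio:.2f}",
        ";".join(r.qc_flags),
    ]


def _comment_header(report: BatchReport) -> list[str]:
    m = report.metadata
    lines = [
        f"# oilnmr {m.get('version', '')} fatty acid composition report",
        f"# generated: {m.get('timestamp', '')}",
        f"# config: {m.get('config_digest', '')}",
    ]
    for name, (lo, hi) in sorted(report.config.windows.items()):
        lines.append(f"# region {name}: {lo:.2f}-{hi:.2f} ppm")
    return lines


def export(report: BatchReport, format: str, path: str | Path) -> Path:
    """Write the report as ``csv`` or fixed-width ``txt``.

    Both carry the same columns; run metadata lives in ``#`` comment lines
    so the data rows are byte-identical across reruns of the same inputs.
    """
    path = Path(path)
    header = _comment_header(report)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for row in report.rows:
            writer.writerow(_format_row(row))
        text = "\n".join(header) + "\n" + buf.getvalue()
    elif format == "txt":
        table = [CSV_COLUMNS] + [_format_row(r) for r in report.rows]
        widths = [max(len(r[i]) for r in table) for i in range(len(CSV_COLUMNS))]
        lines = [
            "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip()
            for r in table
        ]
        text = "\n".join(header + lines) + "\n"
    else:
        raise ValueError(f"unknown export format {format!r}")
    path.write_text(text)
    return path


def parse_csv(path: str | Path) -> list[dict[str, str]]:
    """Read back an exported csv, skipping comment lines."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")
    ]
    return list(csv.DictReader(io.StringIO("\n".join(lines))))
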