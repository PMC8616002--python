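"""Input/output plumbing: FASTA ingestion, run configuration, result bundles.

Outputs mirror a downloadable result bundle as a plain directory:

* ``summary.csv`` — one row per sequence with verdict, crossings, extrema
* ``profiles/<id>.csv`` — the per-pH series (or per-residue profile in
  single-pH mode)
* ``results.json`` — a single document mirroring both, with the full run
  configuration in its header block
* ``skipped.tsv`` — records rejected during parsing/validation
* optional per-sequence plots and an optional ZIP of the whole directory

Floats are written with 6 decimal places and field order is fixed, so
re-runs are byte-identical once the optional timestamp is disabled.
"""

from __future__ import annotations

import csv
import datetime
import io
import json
import logging
import re
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import yaml
from Bio import SeqIO

from .physchem import (
    LipophilicityScale,
    PKaSet,
    ProteinRecord,
    SequenceError,
)
from .scan import PhProfile, TransitionReport, ScanSummary
from .scoring import BoundaryParams

logger = logging.getLogger("disphscan")

FLOAT_FMT = "%.6f"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


@dataclass
class RunConfig:
    """Everything that determines a run; serialized into every output header."""

    fasta: str = ""
    outdir: str = ""
    ph_min: float = 0.0
    ph_max: float = 14.0
    step: float = 0.5
    window: int = 51
    ci: float = 0.02
    single_ph: float | None = None
    boundary_c1: float = 2.785
    boundary_c2: float = 1.151
    pka_file: str | None = None
    scale_file: str | None = None
    include_termini: bool = False
    plots: bool = False
    zip_bundle: bool = False
    timestamp: bool = True
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = set(cls().to_dict())
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def boundary(self) -> BoundaryParams:
        return BoundaryParams(c1=self.boundary_c1, c2=self.boundary_c2)

    def pkas(self) -> PKaSet:
        return PKaSet.from_csv(self.pka_file) if self.pka_file else PKaSet.emboss()

    def scale(self) -> LipophilicityScale:
        if self.scale_file:
            return LipophilicityScale.from_csv(self.scale_file)
        return LipophilicityScale.kyte_doolittle_normalized()


@dataclass(frozen=True)
class SkippedRecord:
    identifier: str
    reason: str


def parse_fasta(
    source: str | Path | TextIO,
) -> tuple[list[ProteinRecord], list[SkippedRecord]]:
    """Parse multi-FASTA input into validated records.

    Accepts a path, raw FASTA text, or an open text handle; tolerates
    wrapped lines and CRLF endings. Duplicate identifiers get a numeric
    suffix (``x``, ``x_2``, ...) with a warning. Invalid records (empty
    sequence, gap characters, unknown letters) are collected in the skipped
    list rather than aborting the run.
    """
    if isinstance(source, (str, Path)):
        looks_like_text = isinstance(source, str) and (
            "\n" in source or source.lstrip().startswith(">")
        )
        if looks_like_text:
            handle: TextIO = io.StringIO(source)
        else:
            p = Path(source)
            if not p.exists():
                raise FileNotFoundError(f"FASTA input not found: {source}")
            handle = open(p)
    else:
        handle = source

    records: list[ProteinRecord] = []
    skipped: list[SkippedRecord] = []
    seen: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            identifier = rec.id or "<unnamed>"
            n = seen.get(identifier, 0) + 1
            seen[identifier] = n
            if n > 1:
                logger.warning(
                    "duplicate identifier %r renamed to %r", identifier,
                    f"{identifier}_{n}",
                )
                identifier = f"{identifier}_{n}"
            description = rec.description
            if description.startswith(rec.id):
                description = description[len(rec.id):].strip()
            try:
                records.append(
                    ProteinRecord(
                        identifier=identifier,
                        sequence=str(rec.seq),
                        description=description,
                    )
                )
            except SequenceError as exc:
                skipped.append(SkippedRecord(identifier, str(exc)))
    finally:
        if handle is not source:
            handle.close()
    if not records and not skipped:
        raise ValueError("no parsable FASTA records in input")
    return records, skipped


SUMMARY_COLUMNS = [
    "identifier",
    "verdict",
    "n_transitions",
    "transition_phs",
    "directions",
    "ph_classes",
    "max_score",
    "max_score_ph",
    "min_score",
    "min_score_ph",
]

SINGLE_PH_COLUMNS = ["identifier", "disph_score", "state",
                     "mean_hydrophobicity", "ncpr"]


def _summary_row(report: TransitionReport) -> list[str]:
    return [
        report.identifier,
        report.verdict,
        str(len(report.transitions)),
        ";".join(_fmt(t.ph) for t in report.transitions),
        ";".join(t.direction for t in report.transitions),
        ";".join(t.ph_class for t in report.transitions),
        _fmt(report.max_score),
        _fmt(report.max_score_ph),
        _fmt(report.min_score),
        _fmt(report.min_score_ph),
    ]


def _safe_name(identifier: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", identifier)


def _report_json(report: TransitionReport) -> dict:
    return {
        "identifier": report.identifier,
        "verdict": report.verdict,
        "transitions": [
            {
                "ph": round(t.ph, 6),
                "direction": t.direction,
                "ph_class": t.ph_class,
            }
            for t in report.transitions
        ],
        "max_score": round(report.max_score, 6),
        "max_score_ph": round(report.max_score_ph, 6),
        "min_score": round(report.min_score, 6),
        "min_score_ph": round(report.min_score_ph, 6),
    }


def _profile_json(profile: PhProfile) -> list[dict]:
    return [
        {
            "ph": round(p.ph, 6),
            "mean_hydrophobicity": round(p.mean_hydrophobicity, 6),
            "ncpr": round(p.ncpr, 6),
            "score": round(p.score, 6),
            "state": p.state,
        }
        for p in profile.points
    ]


def _summary_json(summary: ScanSummary | None) -> dict | None:
    if summary is None:
        return None
    return {k: (round(v, 6) if isinstance(v, float) else v)
            for k, v in asdict(summary).items()}


def write_results(
    reports: list[TransitionReport],
    profiles: list[PhProfile],
    config: RunConfig,
    outdir: str | Path,
    skipped: list[SkippedRecord] | None = None,
    summary: ScanSummary | None = None,
    residue_profiles: dict[str, "np.ndarray"] | None = None,
    records: list[ProteinRecord] | None = None,
) -> Path:
    """Write the result bundle; returns the output directory path.

    ``residue_profiles`` (identifier -> per-position score array) is only
    supplied in single-pH mode and produces per-residue CSVs/plots instead
    of per-pH series; ``records`` supplies the residue letters for those
    CSVs.
    """
    import numpy as np  # noqa: F401  (type reference above)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_test"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable") from exc

    single_mode = config.single_ph is not None
    profile_by_id = {p.identifier: p for p in profiles}
    sequence_by_id = {r.identifier: r.sequence for r in (records or [])}

    # --- summary.csv ---
    with open(out / "summary.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        if single_mode:
            writer.writerow(SINGLE_PH_COLUMNS)
            for report in reports:
                point = profile_by_id[report.identifier].points[0]
                writer.writerow([
                    report.identifier,
                    _fmt(point.score),
                    point.state,
                    _fmt(point.mean_hydrophobicity),
                    _fmt(point.ncpr),
                ])
        else:
            writer.writerow(SUMMARY_COLUMNS)
            for report in reports:
                writer.writerow(_summary_row(report))

    # --- per-sequence profiles ---
    profile_dir = out / "profiles"
    profile_dir.mkdir(exist_ok=True)
    for profile in profiles:
        path = profile_dir / f"{_safe_name(profile.identifier)}.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            if single_mode and residue_profiles is not None:
                writer.writerow(["position", "residue", "disph_score"])
                seq_scores = residue_profiles[profile.identifier]
                sequence = sequence_by_id.get(profile.identifier, "")
                for i, score in enumerate(seq_scores, start=1):
                    aa = sequence[i - 1] if sequence else ""
                    writer.writerow([str(i), aa, _fmt(score)])
            else:
                writer.writerow(["ph", "mean_hydrophobicity", "ncpr",
                                 "disph_score", "state"])
                for p in profile.points:
                    writer.writerow([
                        _fmt(p.ph), _fmt(p.mean_hydrophobicity),
                        _fmt(p.ncpr), _fmt(p.score), p.state,
                    ])

    # --- skipped.tsv ---
    skipped = skipped or []
    with open(out / "skipped.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["identifier", "reason"])
        for s in skipped:
            writer.writerow([s.identifier, s.reason])

    # --- results.json ---
    doc: dict = {"config": config.to_dict()}
    if config.timestamp:
        doc["generated"] = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    doc["summary"] = _summary_json(summary)
    doc["skipped"] = [asdict(s) for s in skipped]
    doc["sequences"] = [
        {
            **_report_json(report),
            "profile": _profile_json(profile_by_id[report.identifier]),
        }
        for report in reports
    ]
    with open(out / "results.json", "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")

    # --- plots ---
    if config.plots:
        _write_plots(out, reports, profiles, residue_profiles, single_mode)

    if config.zip_bundle:
        archive = shutil.make_archive(str(out), "zip", root_dir=out)
        logger.info("wrote ZIP bundle %s", archive)
    return out


def _write_plots(out, reports, profiles, residue_profiles, single_mode):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out / "plots"
    plot_dir.mkdir(exist_ok=True)
    for profile in profiles:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        if single_mode and residue_profiles is not None:
            scores = residue_profiles[profile.identifier]
            ax.plot(range(1, len(scores) + 1), scores, lw=1.0)
            ax.set_xlabel("residue position")
        else:
            ax.plot(profile.phs(), profile.scores(), marker="o", ms=3, lw=1.0)
            ax.set_xlabel("pH")
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("DispH score")
        ax.set_title(profile.identifier, fontsize=9)
        fig.tight_layout()
        fig.savefig(plot_dir / f"{_safe_name(profile.identifier)}.png", dpi=110)
        plt.close(fig)
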