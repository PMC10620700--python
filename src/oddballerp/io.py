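"""On-disk formats: session CSV/TSV dialect, feature tables, YAML config,
and the JSON/Markdown report.

A session is stored as two text files sharing a base path:

``<base>_eeg.csv``
    Header comment lines ``# subject_id=...`` and ``# sample_rate_hz=...``
    followed by a CSV with columns ``fp1_uv, fp2_uv`` (one row per sample).
``<base>_events.tsv``
    Tab-separated with columns ``onset_ms, event_type, detail``; stimulus
    rows carry their tone frequency (Hz) in ``detail``, press rows leave it
    empty.  Event times are written at full precision, so the event log
    round-trips exactly; samples round-trip to the written precision
    (``%.6f`` µV, far below noise).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError
from .simulate import (
    ResponseEvent,
    SessionRecording,
    StimulusEvent,
    STANDARD_TONE_HZ,
    TARGET_TONE_HZ,
)

EVENTS_COLUMNS = ("onset_ms", "event_type", "detail")


def session_paths(base) -> tuple[Path, Path]:
    base = Path(base)
    return base.parent / f"{base.name}_eeg.csv", base.parent / f"{base.name}_events.tsv"


def write_session(recording: SessionRecording, base) -> tuple[Path, Path]:
    """Write one session to ``<base>_eeg.csv`` + ``<base>_events.tsv``."""
    eeg_path, events_path = session_paths(base)
    eeg_path.parent.mkdir(parents=True, exist_ok=True)
    with open(eeg_path, "w") as fh:
        fh.write(f"# subject_id={recording.subject_id}\n")
        fh.write(f"# sample_rate_hz={recording.sample_rate:g}\n")
        fh.write("fp1_uv,fp2_uv\n")
        for a, b in zip(recording.fp1, recording.fp2):
            fh.write(f"{a:.6f},{b:.6f}\n")

    rows = [
        {"onset_ms": s.onset_ms, "event_type": s.kind,
         "detail": f"{s.tone_frequency_hz:g}"}
        for s in recording.stimuli
    ] + [
        {"onset_ms": r.press_time_ms, "event_type": "press", "detail": ""}
        for r in recording.responses
    ]
    events = pd.DataFrame(rows, columns=list(EVENTS_COLUMNS))
    events = events.sort_values("onset_ms", kind="stable")
    events.to_csv(events_path, sep="\t", index=False)  # full float precision
    return eeg_path, events_path


def read_session(base) -> SessionRecording:
    """Read a session written by :func:`write_session`."""
    eeg_path, events_path = session_paths(base)
    if not eeg_path.exists():
        raise FormatError(f"missing EEG file {eeg_path}")
    if not events_path.exists():
        raise FormatError(f"missing events file {events_path}")

    meta = {}
    with open(eeg_path) as fh:
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    try:
        sample_rate = float(meta["sample_rate_hz"])
        subject_id = meta["subject_id"]
    except KeyError as exc:
        raise FormatError(f"EEG header missing field {exc} in {eeg_path}") from exc
    eeg = pd.read_csv(eeg_path, comment="#")
    for col in ("fp1_uv", "fp2_uv"):
        if col not in eeg.columns:
            raise FormatError(f"EEG file {eeg_path} missing column {col!r}")

    events = pd.read_csv(events_path, sep="\t", dtype={"detail": str},
                         float_precision="round_trip")
    for col in EVENTS_COLUMNS:
        if col not in events.columns:
            raise FormatError(f"events file {events_path} missing column {col!r}")

    stimuli, responses = [], []
    for _, row in events.iterrows():
        kind = row["event_type"]
        if kind == "press":
            responses.append(ResponseEvent(float(row["onset_ms"])))
        elif kind in ("standard", "target"):
            tone = TARGET_TONE_HZ if kind == "target" else STANDARD_TONE_HZ
            stimuli.append(StimulusEvent(float(row["onset_ms"]), kind, tone))
        else:
            raise FormatError(
                f"events file {events_path}: unknown event_type {kind!r}"
            )
    stimuli.sort(key=lambda s: s.onset_ms)
    responses.sort(key=lambda r: r.press_time_ms)
    return SessionRecording(
        subject_id=subject_id,
        sample_rate=sample_rate,
        fp1=eeg["fp1_uv"].to_numpy(dtype=float),
        fp2=eeg["fp2_uv"].to_numpy(dtype=float),
        stimuli=stimuli,
        responses=responses,
    )


# ---------------------------------------------------------------------------
# feature tables & config
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load a YAML pipeline/calibration config (empty file -> {})."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping at top level")
    return cfg


def dump_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

#: Minimal structural schema of the JSON report (field -> required type).
REPORT_SCHEMA = {
    "n_cn": int,
    "n_mci": int,
    "alpha": float,
    "demographics": list,
    "feature_tests": list,
    "logistic": list,
    "correlations": dict,
}


def validate_report(report: dict) -> None:
    """Raise :class:`FormatError` unless the report matches the schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise FormatError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise FormatError(
                f"report key {key!r} must be {typ.__name__}, "
                f"got {type(report[key]).__name__}"
            )


def render_markdown(results) -> str:
    """Markdown report with the mean (SD) / t / star layout."""
    lines = ["# Oddball ERP cohort report", ""]
    lines.append(f"Included subjects: CN={results.n_cn}, MCI={results.n_mci}; "
                 f"alpha={results.alpha}")
    lines.append("")
    lines.append("## Demographics and neuropsychological scores")
    lines.append("")
    lines.append("| Variable | CN mean (SD) | MCI mean (SD) | statistic | p | |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in results.demographics.iterrows():
        if r["test"] == "chi2":
            cn = mci = ""
        else:
            cn = f"{r['cn_mean']:.2f} ({r['cn_sd']:.2f})"
            mci = f"{r['mci_mean']:.2f} ({r['mci_sd']:.2f})"
        lines.append(f"| {r['variable']} | {cn} | {mci} | "
                     f"{r['statistic']:.3f} | {r['p']:.3g} | {r['sig']} |")
    lines.append("")
    lines.append("## ERP and behavioral measures")
    lines.append("")
    lines.append("| Feature | CN mean (SD) | MCI mean (SD) | t | p | |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in results.feature_tests.iterrows():
        lines.append(
            f"| {r['feature']} | {r['cn_mean']:.2f} ({r['cn_sd']:.2f}) | "
            f"{r['mci_mean']:.2f} ({r['mci_sd']:.2f}) | "
            f"{r['t']:.2f} | {r['p']:.3g} | {r['sig']} |"
        )
    lines.append("")
    lines.append("## Odds ratios (per SD) from nested logistic models")
    lines.append("")
    lines.append("| Feature | Model | OR (95% CI) | p | |")
    lines.append("|---|---|---|---|---|")
    for _, r in results.logistic.iterrows():
        lines.append(
            f"| {r['feature']} | {int(r['model'])} | "
            f"{r['odds_ratio']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f}) | "
            f"{r['p']:.3g} | {r['sig']} |"
        )
    lines.append("")
    return "\n".join(lines)


def write_report(results, out_dir, ledger: dict | None = None) -> dict[str, Path]:
    """Write the JSON report, Markdown report, per-table CSVs, and the
    correlation matrices; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    report = results.to_dict()
    validate_report(report)
    paths["report_json"] = out / "report.json"
    paths["report_json"].write_text(json.dumps(report, indent=2, default=float))
    paths["report_md"] = out / "report.md"
    paths["report_md"].write_text(render_markdown(results))
    paths["demographics_csv"] = write_table(results.demographics, out / "demographics.csv")
    paths["features_csv"] = write_table(results.feature_tests, out / "feature_tests.csv")
    paths["logistic_csv"] = write_table(results.logistic, out / "logistic.csv")
    for g, kinds in results.correlations.items():
        for kind, mat in kinds.items():
            p = out / f"correlation_{g.lower()}_{kind}.csv"
            mat.to_csv(p)
            paths[f"correlation_{g}_{kind}"] = p
    if ledger is not None:
        paths["exclusions_json"] = out / "exclusions.json"
        paths["exclusions_json"].write_text(json.dumps(ledger, indent=2, default=str))
    return paths
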