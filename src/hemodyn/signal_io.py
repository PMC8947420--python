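"""Readers and writers for signal CSVs, cohort manifests and result tables.

All interchange is plain CSV (comma separator, dot decimal, mandatory header
row) with times in seconds, zero-based from recording start.  Cohort
manifests are YAML files listing, per subject and posture, the file of each
channel and — for synthetic cohorts — the ground-truth autoregulation grade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SignalFormatError, ParameterError
from .signals import UniformSignal

log = logging.getLogger("hemodyn")

#: relative tolerance on time-step uniformity when reading CSV signals
TIME_UNIFORMITY_RTOL = 1e-6


def read_signal_csv(
    path: str | Path,
    value_column: str,
    time_column: str = "time_s",
    units: str = "",
) -> UniformSignal:
    """Read one channel of an evenly sampled recording from CSV.

    The sampling interval is inferred from the median time difference; the
    time column must be strictly increasing and uniform to within
    ``1e-6 * dt``.  Non-finite sample values are rejected with the offending
    row index, since downstream stages assume finite input.
    """
    df = pd.read_csv(path)
    for col in (time_column, value_column):
        if col not in df.columns:
            raise SignalFormatError(f"{path}: missing column {col!r}")
    t = df[time_column].to_numpy(dtype=float)
    x = df[value_column].to_numpy(dtype=float)
    if t.size < 2:
        raise SignalFormatError(f"{path}: need at least two samples")
    diffs = np.diff(t)
    if np.any(diffs <= 0):
        idx = int(np.argmax(diffs <= 0))
        raise SignalFormatError(f"{path}: time not strictly increasing at row {idx + 1}")
    dt = float(np.median(diffs))
    if np.max(np.abs(diffs - dt)) > TIME_UNIFORMITY_RTOL * dt:
        idx = int(np.argmax(np.abs(diffs - dt)))
        raise SignalFormatError(
            f"{path}: non-uniform sampling at row {idx + 1} "
            f"(dt={diffs[idx]:.6g}, expected {dt:.6g})"
        )
    bad = ~np.isfinite(x)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise SignalFormatError(f"{path}: non-finite sample at row {idx}")
    return UniformSignal(values=x, dt=dt, units=units, t0=float(t[0]))


def write_signal_csv(
    path: str | Path,
    signals: dict[str, UniformSignal],
    time_column: str = "time_s",
) -> None:
    """Write one or more channels sharing a grid to a single CSV file."""
    first = next(iter(signals.values()))
    for name, sig in signals.items():
        if sig.n != first.n or abs(sig.dt - first.dt) > TIME_UNIFORMITY_RTOL * first.dt:
            raise SignalFormatError(f"channel {name!r} does not share the common grid")
    data = {time_column: first.times()}
    data.update({name: sig.values for name, sig in signals.items()})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


RESULT_COLUMNS = ("subject", "posture", "metric", "value")


def write_results_table(rows, path: str | Path) -> None:
    """Write (subject, posture, metric, value) rows as a deterministic CSV.

    Rows are sorted by (subject, posture, metric); duplicate keys are a
    validation error because they would silently overwrite each other in
    downstream pivots.
    """
    df = pd.DataFrame(list(rows), columns=list(RESULT_COLUMNS))
    if df.duplicated(subset=["subject", "posture", "metric"]).any():
        dup = df[df.duplicated(subset=["subject", "posture", "metric"])].iloc[0]
        raise ParameterError(
            f"duplicate result row ({dup['subject']}, {dup['posture']}, {dup['metric']})"
        )
    df = df.sort_values(["subject", "posture", "metric"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise SignalFormatError(f"{path}: missing result columns {sorted(missing)}")
    return df


@dataclass
class RecordingManifest:
    """Location of the raw channels of one (subject, posture) recording."""

    subject_id: str
    posture: str
    bp_file: str
    bfv_files: list[str]
    hemisphere: str = "merged"
    true_ari: int | None = None
    heart_rate_hz: float | None = None

    def __post_init__(self) -> None:
        if self.posture not in ("lay", "sit", "stand"):
            raise ParameterError(f"unknown posture {self.posture!r}")
        if not (1 <= len(self.bfv_files) <= 2):
            raise ParameterError("each recording needs one or two BFV files")


@dataclass
class CohortManifest:
    """A set of recordings plus the directory they live in."""

    root: str
    recordings: list[RecordingManifest] = field(default_factory=list)

    def resolve(self, rel: str) -> Path:
        return Path(self.root) / rel

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.recordings:
            seen.setdefault(rec.subject_id, None)
        return list(seen)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    payload = {
        "root": manifest.root,
        "recordings": [
            {
                "subject_id": r.subject_id,
                "posture": r.posture,
                "bp_file": r.bp_file,
                "bfv_files": list(r.bfv_files),
                "hemisphere": r.hemisphere,
                "true_ari": r.true_ari,
                "heart_rate_hz": r.heart_rate_hz,
            }
            for r in manifest.recordings
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_manifest(path: str | Path) -> CohortManifest:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "recordings" not in payload:
        raise SignalFormatError(f"{path}: not a cohort manifest")
    recs = [RecordingManifest(**entry) for entry in payload["recordings"]]
    return CohortManifest(root=payload.get("root", str(Path(path).parent)), recordings=recs)


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Configure timestamped, stage-tagged logging for pipeline runs."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
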