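"""Reading/writing ROI time-series matrices, study manifests and result tables.

Matrices are delimited numeric text, one row per volume (time point) and one
column per ROI.  The manifest is a CSV with header ``participant,session,file``
mapping each matrix file to its (participant, session) cell; the design must
be rectangular (every participant has the same number of sessions).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DesignError, FormatError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "method",
    "K",
    "observable",
    "nd",
    "p_value",
    "sig_05",
    "sig_001",
    "sig_bonf",
]


@dataclass
class RoiTimeSeries:
    """One session's T x N signal matrix plus its identity in the study."""

    participant_id: str
    session_id: str
    data: np.ndarray
    t_r: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("time-series data must be a 2-D matrix")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise FormatError(
                f"need at least 2 volumes and 2 ROIs, got T={t}, N={n}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("time-series data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class StudyManifest:
    """Rectangular (participant x session) -> file mapping."""

    entries: list[tuple[str, str, Path]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for pid, sid, _ in self.entries:
            key = (pid, sid)
            if key in seen:
                raise DesignError(f"duplicate (participant, session) pair {key}")
            seen.add(key)
        counts = {}
        for pid, _, _ in self.entries:
            counts[pid] = counts.get(pid, 0) + 1
        if counts and len(set(counts.values())) != 1:
            raise DesignError(
                "non-rectangular design: session counts per participant "
                f"are {counts}; every participant needs the same number"
            )

    @property
    def participants(self) -> list[str]:
        out = []
        for pid, _, _ in self.entries:
            if pid not in out:
                out.append(pid)
        return out

    def sessions(self, participant_id: str) -> list[tuple[str, Path]]:
        return [
            (sid, path)
            for pid, sid, path in self.entries
            if pid == participant_id
        ]

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_sessions(self) -> int:
        if not self.entries:
            return 0
        return len(self.sessions(self.participants[0]))


def _sniff_delimiter(sample_line: str) -> str | None:
    """Return ',' or '\\t', or None for generic whitespace splitting."""
    if "," in sample_line:
        return ","
    if "\t" in sample_line:
        return "\t"
    return None


def load_session(
    path, participant_id: str = "", session_id: str = "", t_r: float | None = None
) -> RoiTimeSeries:
    """Load one session's matrix from delimited text (csv/tsv/whitespace)."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        delim = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if delim is None and not rows:
                delim = _sniff_delimiter(line)
            cells = line.split(delim) if delim else line.split()
            parsed = []
            for colno, cell in enumerate(cells, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, "
                        f"column {colno}"
                    ) from None
            if rows and len(parsed) != len(rows[0]):
                raise FormatError(
                    f"{path}: ragged row {lineno} has {len(parsed)} cells, "
                    f"expected {len(rows[0])}"
                )
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    data = np.array(rows, dtype=float)
    logger.debug("loaded %s: T=%d, N=%d", path, *data.shape)
    return RoiTimeSeries(
        participant_id=participant_id,
        session_id=session_id,
        data=data,
        t_r=t_r,
    )


def load_manifest(path) -> StudyManifest:
    """Load the study manifest CSV with columns participant, session, file.

    File paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse manifest: {exc}") from exc
    required = {"participant", "session", "file"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    base = path.parent
    entries = [
        (str(row.participant), str(row.session), base / str(row.file))
        for row in table.itertuples()
    ]
    return StudyManifest(entries=entries)


def write_session(ts: RoiTimeSeries, path) -> None:
    """Write a session matrix as CSV (full float precision, round-trips)."""
    np.savetxt(path, ts.data, delimiter=",", fmt="%.17g")


def write_manifest(manifest: StudyManifest, path) -> None:
    path = Path(path)
    base = path.parent
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant", "session", "file"])
        for pid, sid, fpath in manifest.entries:
            fpath = Path(fpath)
            try:
                rel = fpath.relative_to(base)
            except ValueError:
                rel = fpath
            writer.writerow([pid, sid, str(rel)])


def write_results(records: list[dict], path) -> None:
    """Write the results table (method x K x observable -> ND, p-value)."""
    table = pd.DataFrame(records, columns=RESULT_COLUMNS)
    table.to_csv(path, index=False)


def read_results(path) -> list[dict]:
    table = pd.read_csv(
        path,
        dtype={
            "method": str,
            "K": int,
            "observable": str,
            "nd": float,
            "p_value": float,
            "sig_05": bool,
            "sig_001": bool,
            "sig_bonf": bool,
        },
    )
    return table.to_dict(orient="records")
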