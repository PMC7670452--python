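"""Reading and writing the published dataset's folder layout.

Layout: one folder per subject (``s1`` ... ``s12``) with subfolders
``forearm`` (array 1), ``biceps`` (array 2), ``triceps`` (array 3) and
``torque``. Signal files are plain ascii named ``<task>_<effort>.txt``
(e.g. ``flexion_30.txt``), one row per time sample, one column per channel,
whitespace- or tab-delimited with an optional header line (the deposited
dialect is not printed anywhere, so the reader sniffs delimiter and header
and round-trip tests pin the writer's dialect down). Metadata files at the
root: ``ReferencePoints.txt``, ``nchannels.txt``, ``forearm.txt`` and
``SubjectsDescription.txt`` (tab-delimited, one row per subject).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ElectrodeGrid, default_grids
from .recording import MultiChannelRecording

__all__ = ["SubjectMetadata", "read_signal_file", "write_signal_file",
           "read_subject", "write_subject", "read_metadata", "write_metadata",
           "FILENAME_PATTERN"]

ARRAY_FOLDERS = {1: "forearm", 2: "biceps", 3: "triceps"}
FILENAME_PATTERN = r"(?P<task>[a-z]+)_(?P<effort>\d+)\.txt"
FOREARM_MUSCLES = ("brachioradialis", "anconeus", "pronator_teres")


@dataclass
class SubjectMetadata:
    """Per-subject anthropometry, array reference offsets and channel counts.

    ``reference_points``: array id -> (x_cm, y_cm) offset from the anatomical
    origin to the upper-left electrode. ``nchannels``: array id -> recorded
    channel count. ``forearm_ranges``: muscle -> (first, last) inclusive
    channel interval on array 1. ``anthropometry``: array id ->
    (circumference_cm, length_cm), plus the population descriptors.
    """
    subject: str
    reference_points: dict = field(default_factory=dict)
    nchannels: dict = field(default_factory=dict)
    forearm_ranges: dict = field(default_factory=dict)
    anthropometry: dict = field(default_factory=dict)
    description: dict = field(default_factory=dict)

    def __post_init__(self):
        for a, (circ, length) in self.anthropometry.items():
            if circ <= 0 or length <= 0:
                raise ValueError(
                    f"array {a}: circumference and length must be positive")
        for muscle, (first, last) in self.forearm_ranges.items():
            if first < 0 or last < first:
                raise ValueError(f"invalid channel range for {muscle}")

    def muscle_channel_count(self, muscle: str) -> int:
        first, last = self.forearm_ranges[muscle]
        return last - first + 1  # inclusive interval


def write_signal_file(path, signals: np.ndarray, fmt: str = "%.10g",
                      delimiter: str = "\t") -> None:
    """One row per time sample, one column per channel, no header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(signals).T, fmt=fmt, delimiter=delimiter)


def read_signal_file(path) -> np.ndarray:
    """Read an ascii signal matrix as channels x samples.

    Auto-detects the delimiter (any whitespace, tab or comma) and skips a
    single non-numeric header line if present. Raises with the line number
    on a non-numeric token, and on an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected signal file at {path}")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ValueError(f"{path} is empty")

    def parse(ln):
        return [tok for tok in re.split(r"[,\s]+", ln) if tok]

    start = 0
    try:
        [float(t) for t in parse(lines[0])]
    except ValueError:
        start = 1
        if len(lines) == 1:
            raise ValueError(f"{path} contains only a header line") from None
    rows = []
    width = None
    for i, ln in enumerate(lines[start:], start=start + 1):
        toks = parse(ln)
        try:
            row = [float(t) for t in toks]
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric token on line {i}") from err
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(f"{path}: ragged row on line {i}")
        rows.append(row)
    return np.asarray(rows).T  # channels x samples


def signal_filename(task: str, effort: float) -> str:
    return f"{task}_{int(effort)}.txt"


def write_subject(root, subject: str, rec, *, fs: float | None = None) -> None:
    """Write one synthetic trial in the dataset folder dialect.

    ``rec`` is a SyntheticRecording (or anything with .recordings/.torque
    and truth task/effort).
    """
    root = Path(root)
    task = rec.truth["task"]
    effort = rec.truth["effort"]
    fname = signal_filename(task, effort)
    for r in rec.recordings:
        folder = ARRAY_FOLDERS[r.grid.array_id]
        write_signal_file(root / subject / folder / fname, r.signals)
    write_signal_file(root / subject / "torque" / fname, rec.torque)


def read_subject(root, subject: str, task: str, effort: float, *,
                 grids: list[ElectrodeGrid] | None = None,
                 metadata: dict | None = None,
                 filename_pattern: str = FILENAME_PATTERN):
    """Read one trial: per-array MultiChannelRecording dict plus torque.

    The channel count of each file is cross-checked against the
    ``nchannels`` metadata when available; on mismatch a warning is raised
    and the file's own channel count wins (explicit reconciliation policy:
    trust the data, flag the metadata).
    """
    root = Path(root)
    if grids is None:
        grids = default_grids()
    fname = signal_filename(task, effort)
    for folder in list(ARRAY_FOLDERS.values()) + ["torque"]:
        d = root / subject / folder
        if not d.is_dir():
            raise FileNotFoundError(f"expected subfolder {d}")
    recordings = {}
    for grid in grids:
        folder = ARRAY_FOLDERS[grid.array_id]
        sig = read_signal_file(root / subject / folder / fname)
        expected = None
        if metadata is not None and subject in metadata:
            expected = metadata[subject].nchannels.get(grid.array_id)
        if expected is not None and sig.shape[0] != expected:
            warnings.warn(
                f"{subject}/{folder}/{fname}: nchannels metadata says "
                f"{expected} channels but the file has {sig.shape[0]}; "
                "using the file's channel count", stacklevel=2)
        if sig.shape[0] != grid.n_channels:
            raise ValueError(
                f"{subject}/{folder}/{fname}: {sig.shape[0]} channels do not "
                f"fit the declared {grid.shape} grid")
        recordings[grid.array_id] = MultiChannelRecording(
            signals=sig, fs=2048.0, grid=grid, subject=subject,
            task=task, effort=effort)
        recordings[grid.array_id].validate_finite()
    torque = read_signal_file(root / subject / "torque" / fname)
    return recordings, torque


# -- metadata tables ---------------------------------------------------------

def write_metadata(root, metas: list[SubjectMetadata]) -> None:
    """Write the four tab-delimited metadata tables."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rp, nc, fa, sd = [], [], [], []
    for m in metas:
        row = {"subject": m.subject}
        for a in (1, 2, 3):
            x, y = m.reference_points.get(a, (np.nan, np.nan))
            row[f"array{a}_x"] = x
            row[f"array{a}_y"] = y
        rp.append(row)
        nc.append({"subject": m.subject,
                   **{f"array{a}": m.nchannels.get(a, 0) for a in (1, 2, 3)}})
        row = {"subject": m.subject}
        for muscle in FOREARM_MUSCLES:
            first, last = m.forearm_ranges.get(muscle, (0, -1))
            row[f"{muscle}_first"] = first
            row[f"{muscle}_last"] = last
        fa.append(row)
        row = {"subject": m.subject, **m.description}
        for a in (1, 2, 3):
            circ, length = m.anthropometry.get(a, (np.nan, np.nan))
            row[f"array{a}_circumference_cm"] = circ
            row[f"array{a}_length_cm"] = length
        sd.append(row)
    pd.DataFrame(rp).to_csv(root / "ReferencePoints.txt", sep="\t", index=False)
    pd.DataFrame(nc).to_csv(root / "nchannels.txt", sep="\t", index=False)
    pd.DataFrame(fa).to_csv(root / "forearm.txt", sep="\t", index=False)
    pd.DataFrame(sd).to_csv(root / "SubjectsDescription.txt", sep="\t",
                            index=False)


def read_metadata(root) -> dict:
    """Read the metadata tables into one SubjectMetadata per subject."""
    root = Path(root)
    tables = {}
    for name in ("ReferencePoints", "nchannels", "forearm",
                 "SubjectsDescription"):
        path = root / f"{name}.txt"
        if not path.exists():
            raise FileNotFoundError(f"expected metadata file {path}")
        try:
            tables[name] = pd.read_csv(path, sep="\t").set_index("subject")
        except Exception as err:
            raise ValueError(f"malformed metadata table {path}: {err}") from err
    out = {}
    for subject in tables["nchannels"].index:
        rp = tables["ReferencePoints"].loc[subject]
        nc = tables["nchannels"].loc[subject]
        fa = tables["forearm"].loc[subject]
        sd = tables["SubjectsDescription"].loc[subject]
        forearm_ranges = {}
        for muscle in FOREARM_MUSCLES:
            first = int(fa[f"{muscle}_first"])
            last = int(fa[f"{muscle}_last"])
            if last >= first >= 0:
                forearm_ranges[muscle] = (first, last)
        anthropometry = {}
        for a in (1, 2, 3):
            circ = float(sd[f"array{a}_circumference_cm"])
            length = float(sd[f"array{a}_length_cm"])
            if np.isfinite(circ) and np.isfinite(length):
                anthropometry[a] = (circ, length)
        description = {k: sd[k] for k in sd.index
                       if not k.startswith("array")}
        out[str(subject)] = SubjectMetadata(
            subject=str(subject),
            reference_points={a: (float(rp[f"array{a}_x"]),
                                  float(rp[f"array{a}_y"])) for a in (1, 2, 3)},
            nchannels={a: int(nc[f"array{a}"]) for a in (1, 2, 3)},
            forearm_ranges=forearm_ranges,
            anthropometry=anthropometry,
            description=description)
    return out
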