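"""Readers for the two public single-channel EEG corpora and task assembly.

Bonn corpus: five sets (A/B from healthy subjects with eyes open/closed;
C hippocampal formation and D epileptogenic zone during seizure-free
intervals; E during seizure activity), 100 plain-text recordings per set,
one sample value per line, 4097 samples per recording.  Files are named
either with the set letter (A001.txt) or the original Z/O/N/F/S prefixes.

UCI epileptic-seizure-recognition table: CSV with 178 feature columns
X1..X178 plus an integer label y in 1..5, one 1-second chunk per row;
class 1 is seizure, classes 2-5 are non-seizure states, so the standard
task is binary (1 vs rest).

Tasks on the Bonn sets are written as hyphenated group strings, e.g.
"A-E" (two classes) or "AB-CD-E" (three classes: healthy vs interictal vs
seizure).  Each recording is windowed into non-overlapping fixed-length
segments; the recording id is kept on every window so cross-validation can
split group-aware.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BONN_LENGTH = 4097
UCI_LENGTH = 178
#: original Bonn file prefixes for each set letter
SET_ALIASES = {"A": "Z", "B": "O", "C": "N", "D": "F", "E": "S"}


class FormatError(ValueError):
    """A data file does not match the expected on-disk layout."""


@dataclass
class SignalRecord:
    """One labeled single-channel EEG segment or recording."""

    samples: np.ndarray
    source_set: str
    recording_id: str
    label: int = -1


@dataclass(frozen=True)
class TaskSpec:
    """Ordered class groups parsed from a hyphenated task name."""

    groups: tuple[tuple[str, ...], ...]

    @classmethod
    def parse(cls, name: str) -> "TaskSpec":
        parts = name.upper().split("-")
        groups = tuple(tuple(part) for part in parts)
        seen: set[str] = set()
        for group in groups:
            if not group:
                raise ValueError(f"empty class group in task {name!r}")
            for letter in group:
                if letter not in SET_ALIASES:
                    raise ValueError(f"unknown Bonn set {letter!r} in task {name!r}")
                if letter in seen:
                    raise ValueError(f"set {letter!r} appears in two groups of task {name!r}")
                seen.add(letter)
        return cls(groups)

    def render(self) -> str:
        return "-".join("".join(g) for g in self.groups)

    @property
    def n_classes(self) -> int:
        return len(self.groups)

    @property
    def sets(self) -> tuple[str, ...]:
        return tuple(letter for group in self.groups for letter in group)


@dataclass
class Dataset:
    """Uniform-length labeled segments with source-recording ids."""

    X: np.ndarray  # [n, length]
    y: np.ndarray  # [n] integer class labels
    record_ids: np.ndarray  # [n] source recording id per segment

    def __len__(self) -> int:
        return len(self.X)

    @property
    def pairs(self):
        return list(zip(self.X, self.y))


def _read_signal_file(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as err:
                raise FormatError(f"{path}: non-numeric value on line {lineno}: {line!r}") from err
    if len(values) != BONN_LENGTH:
        raise FormatError(f"{path}: expected {BONN_LENGTH} samples, found {len(values)}")
    return np.asarray(values)


def _discover_set_files(directory: Path, set_letter: str) -> list[Path]:
    letter = set_letter.upper()
    alias = SET_ALIASES[letter]
    for sub in (letter, alias, letter.lower(), alias.lower()):
        subdir = directory / sub
        if subdir.is_dir():
            return sorted(p for p in subdir.iterdir() if p.suffix.lower() in (".txt", ""))
    pattern = re.compile(rf"^({letter}|{alias})\d+", re.IGNORECASE)
    return sorted(p for p in directory.iterdir()
                  if p.is_file() and pattern.match(p.name))


def read_bonn_set(directory, set_letter: str) -> list[SignalRecord]:
    """Read all recordings of one Bonn set from a directory of text files."""
    directory = Path(directory)
    letter = set_letter.upper()
    if letter not in SET_ALIASES:
        raise ValueError(f"unknown Bonn set {set_letter!r}")
    files = _discover_set_files(directory, letter)
    if not files:
        raise FormatError(f"no files for set {letter} under {directory}")
    return [SignalRecord(_read_signal_file(p), letter, p.stem) for p in files]


def read_uci_csv(path) -> list[SignalRecord]:
    """Read the UCI-style CSV; label is 1 for seizure (y==1) else 0."""
    df = pd.read_csv(path)
    feature_cols = [f"X{i}" for i in range(1, UCI_LENGTH + 1)]
    missing = [c for c in feature_cols + ["y"] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing[:3]}{'...' if len(missing) > 3 else ''}")
    id_col = next((c for c in df.columns if c not in feature_cols and c != "y"), None)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        raw_id = str(rowd[id_col]) if id_col is not None else str(i)
        # ids like "X21.V1.791" share the trailing token across chunks of one subject
        rec_id = raw_id.rsplit(".", 1)[-1] if "." in raw_id else raw_id
        label = 1 if int(rowd["y"]) == 1 else 0
        records.append(SignalRecord(np.array([float(rowd[c]) for c in feature_cols]),
                                    "UCI", rec_id, label))
    return records


def _normalize(window: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return window
    if mode == "zscore":
        sd = window.std()
        return (window - window.mean()) / (sd if sd > 1e-12 else 1.0)
    if mode == "minmax":
        lo, hi = window.min(), window.max()
        span = hi - lo
        return (window - lo) / (span if span > 1e-12 else 1.0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def make_task(records_by_set: dict[str, list[SignalRecord]], task: TaskSpec | str,
              window_len: int = UCI_LENGTH, normalize: str = "zscore") -> Dataset:
    """Window the referenced Bonn sets into a labeled segment dataset.

    Each recording contributes floor(4097 / window_len) non-overlapping
    windows; windows never cross recording boundaries.  The class label of a
    window is the index of the task group its set belongs to.
    """
    if isinstance(task, str):
        task = TaskSpec.parse(task)
    for letter in task.sets:
        if letter not in records_by_set:
            raise ValueError(f"task needs set {letter!r} which was not loaded")
    segments, labels, rec_ids = [], [], []
    for class_idx, group in enumerate(task.groups):
        for letter in group:
            for record in records_by_set[letter]:
                n_windows = len(record.samples) // window_len
                if n_windows < 1:
                    raise ValueError(
                        f"window length {window_len} exceeds recording length "
                        f"{len(record.samples)}")
                for w in range(n_windows):
                    window = record.samples[w * window_len:(w + 1) * window_len]
                    segments.append(_normalize(window.astype(float), normalize))
                    labels.append(class_idx)
                    rec_ids.append(f"{letter}:{record.recording_id}")
    return Dataset(np.asarray(segments), np.asarray(labels, dtype=int),
                   np.asarray(rec_ids))


def records_to_dataset(records: list[SignalRecord], normalize: str = "zscore") -> Dataset:
    """Uniform-length records (e.g. UCI rows) straight to a Dataset."""
    lengths = {len(r.samples) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have mixed lengths: {sorted(lengths)}")
    X = np.stack([_normalize(r.samples.astype(float), normalize) for r in records])
    y = np.asarray([r.label for r in records], dtype=int)
    ids = np.asarray([r.recording_id for r in records])
    return Dataset(X, y, ids)
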