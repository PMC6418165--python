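"""On-disk trial format: time-stamped stylus samples plus metadata.

A trial file is a plain CSV with columns exactly
``subject_id,group,session,block,trial,t,x,y`` (t in s, x/y in cm, one
row per 160 Hz sample).  A JSON sidecar ``<name>.meta.json`` carries the
target layout and the nominal sample rate, so a trial file is
self-contained.  The original experiment stored data in an acquisition
tool's proprietary format; this dialect replaces it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .layout import TargetLayout, default_layout

__all__ = [
    "GROUPS",
    "SESSIONS",
    "TrialRecord",
    "TrialSet",
    "read_trials",
    "write_trials",
]

GROUPS = ("OG", "SOG", "RMCG", "DPTCG")
SESSIONS = ("pre", "train", "post", "day2", "mirror", "scaled")

COLUMNS = ["subject_id", "group", "session", "block", "trial", "t", "x", "y"]


@dataclass
class TrialRecord:
    """One recorded trial: identity plus the raw (t, x, y) samples."""

    subject_id: str
    group: str
    session: str
    block: int
    trial: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate_hz: float = 160.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(f"{self.key()}: unknown group {self.group!r}")
        if self.session not in SESSIONS:
            raise ValidationError(f"{self.key()}: unknown session {self.session!r}")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError(f"{self.key()}: t/x/y length mismatch")
        if len(self.t) < 2:
            raise ValidationError(f"{self.key()}: needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"{self.key()}: timestamps must be strictly increasing"
            )
        if self.sample_rate_hz <= 0:
            raise ValidationError(f"{self.key()}: sample rate must be positive")

    def key(self) -> str:
        return (
            f"trial(subject={self.subject_id}, session={self.session}, "
            f"block={self.block}, trial={self.trial})"
        )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class TrialSet:
    """A bag of trials sharing one target layout."""

    trials: list[TrialRecord]
    layout: TargetLayout = field(default_factory=default_layout)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        if not self.trials:
            return pd.DataFrame(columns=COLUMNS)
        parts = []
        for tr in self.trials:
            parts.append(
                pd.DataFrame(
                    {
                        "subject_id": tr.subject_id,
                        "group": tr.group,
                        "session": tr.session,
                        "block": tr.block,
                        "trial": tr.trial,
                        "t": tr.t,
                        "x": tr.x,
                        "y": tr.y,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)[COLUMNS]


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_trials(tset: TrialSet, path) -> Path:
    """Write a TrialSet as CSV + JSON sidecar; returns the CSV path.

    Floats are written with full repr precision so that
    ``read_trials(write_trials(tset))`` reproduces every sample exactly.
    """
    path = Path(path)
    tset.to_frame().to_csv(path, index=False)
    sample_rate = tset.trials[0].sample_rate_hz if tset.trials else 160.0
    meta = {
        "layout": tset.layout.to_dict(),
        "sample_rate_hz": sample_rate,
        "provenance": tset.provenance,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trials(path) -> TrialSet:
    """Parse a trial CSV (plus its ``.meta.json`` sidecar if present).

    Raises :class:`FormatError` for missing columns or non-numeric
    samples (reported with 1-based file line numbers) and
    :class:`ValidationError`, naming the trial, when timestamps within a
    trial are not strictly increasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    bad_lines = []
    for col in ("t", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        # +2: header line plus 1-based indexing
        bad_lines.extend((df.index[vals.isna() & df[col].notna()] + 2).tolist())
        df[col] = vals
    bad_lines.extend((df.index[df[["t", "x", "y"]].isna().any(axis=1)] + 2).tolist())
    if bad_lines:
        raise FormatError(
            f"{path}: malformed sample rows at line(s) {sorted(set(bad_lines))}"
        )

    meta_path = _meta_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        layout = TargetLayout.from_dict(meta["layout"])
        sample_rate = float(meta.get("sample_rate_hz", 160.0))
        provenance = meta.get("provenance", "")
    else:
        layout, sample_rate, provenance = default_layout(), 160.0, ""

    trials = []
    if len(df):
        for key, g in df.groupby(
            ["subject_id", "group", "session", "block", "trial"], sort=False
        ):
            subject_id, group, session, block, trial = key
            trials.append(
                TrialRecord(
                    subject_id=str(subject_id),
                    group=str(group),
                    session=str(session),
                    block=int(block),
                    trial=int(trial),
                    t=g["t"].to_numpy(),
                    x=g["x"].to_numpy(),
                    y=g["y"].to_numpy(),
                    sample_rate_hz=sample_rate,
                )
            )
    return TrialSet(trials=trials, layout=layout, provenance=provenance)
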