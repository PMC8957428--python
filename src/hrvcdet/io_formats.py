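"""Reading, writing and validation of RR-interval series and grouped feature tables.

No science lives here: these are the containers and file formats the rest of
the package consumes.  RR intervals are always in milliseconds; seconds appear
only in the derived ``beat_times``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "FeatureTable",
    "ArtifactReport",
    "read_rr",
    "write_rr",
    "filter_artifacts",
    "read_feature_table",
    "write_feature_table",
    "read_config",
]

#: Conventional physiological bounds for a plausible NN interval (ms) and the
#: maximal fractional beat-to-beat jump tolerated by the artifact filter.
DEFAULT_MIN_MS = 300.0
DEFAULT_MAX_MS = 2000.0
DEFAULT_MAX_REL_JUMP = 0.2


@dataclass(frozen=True)
class RRSeries:
    """An ordered series of NN (normal-to-normal) intervals for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the athlete/subject.
    stage : str
        Training-stage label (e.g. ``"early"``, ``"middle"``, ``"late"``).
    intervals : ndarray of float
        NN intervals in milliseconds, in recording order.  All strictly
        positive; at least two intervals.
    """

    subject_id: str
    stage: str
    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1 or iv.size < 2:
            raise ValueError("RRSeries needs at least 2 intervals")
        if not np.all(np.isfinite(iv)):
            raise ValueError("RRSeries intervals must be finite")
        if np.any(iv <= 0):
            bad = int(np.argmax(iv <= 0))
            raise ValueError(f"non-positive RR interval at position {bad}: {iv[bad]}")
        object.__setattr__(self, "intervals", iv)

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative beat onset times in seconds: ``beat_times[k] = sum(intervals[:k+1]) / 1000``."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds."""
        return float(self.intervals.sum() / 1000.0)

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class FeatureTable:
    """Grouped numeric feature table: one row per subject, one class label per row."""

    subject_ids: tuple
    class_labels: tuple
    X: np.ndarray  # shape (N, M)
    feature_names: tuple

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (rows x features)")
        n, m = X.shape
        if len(self.subject_ids) != n or len(self.class_labels) != n:
            raise ValueError("subject_ids/class_labels length must match row count")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must match column count")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "class_labels", tuple(str(c) for c in self.class_labels))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> tuple:
        seen = []
        for c in self.class_labels:
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "class", list(self.class_labels))
        df.insert(0, "subject", list(self.subject_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        if "subject" not in df.columns or "class" not in df.columns:
            raise ValueError("feature table needs 'subject' and 'class' columns")
        feats = [c for c in df.columns if c not in ("subject", "class")]
        if not feats:
            raise ValueError("feature table has no feature columns")
        try:
            X = df[feats].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric feature cell: {exc}") from exc
        return cls(
            subject_ids=tuple(df["subject"].astype(str)),
            class_labels=tuple(df["class"].astype(str)),
            X=X,
            feature_names=tuple(feats),
        )


@dataclass(frozen=True)
class ArtifactReport:
    """Positions (indices into the original series) removed by the artifact filter."""

    removed_indices: tuple
    reasons: tuple  # parallel to removed_indices: "bounds" or "jump"

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)


def read_rr(path, subject_id: str = "", stage: str = "") -> RRSeries:
    """Read an RR series from a plain-text file (one interval in ms per line)
    or a CSV with an ``interval_ms`` column (optionally ``subject``/``stage``
    columns used to select rows when ``subject_id``/``stage`` are given).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if "," in first:
        df = pd.read_csv(io.StringIO(text))
        if "interval_ms" not in df.columns:
            raise ValueError(f"{path}: CSV RR file needs an 'interval_ms' column")
        if subject_id and "subject" in df.columns:
            df = df[df["subject"].astype(str) == subject_id]
        if stage and "stage" in df.columns:
            df = df[df["stage"].astype(str) == stage]
        if df.empty:
            raise ValueError(f"{path}: no intervals")
        vals = df["interval_ms"].astype(float).to_numpy()
        if not subject_id and "subject" in df.columns:
            subject_id = str(df["subject"].iloc[0])
        if not stage and "stage" in df.columns:
            stage = str(df["stage"].iloc[0])
    else:
        vals_list = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            s = line.strip()
            if not s:
                continue
            try:
                v = float(s)
            except ValueError:
                raise ValueError(f"{path}: non-numeric interval on line {lineno}: {s!r}") from None
            if v <= 0:
                raise ValueError(f"{path}: non-positive interval on line {lineno}: {s!r}")
            vals_list.append(v)
        if not vals_list:
            raise ValueError(f"{path}: no intervals")
        vals = np.array(vals_list)
    return RRSeries(subject_id=subject_id or path.stem, stage=stage or "unknown", intervals=vals)


def write_rr(rr: RRSeries, path) -> None:
    """Write an RR series as plain text, one interval per line, LF-terminated.

    Uses repr-precision formatting so read_rr(write_rr(x)) round-trips exactly.
    """
    lines = [np.format_float_positional(v, trim="-") for v in rr.intervals]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def filter_artifacts(
    rr: RRSeries,
    min_ms: float = DEFAULT_MIN_MS,
    max_ms: float = DEFAULT_MAX_MS,
    max_rel_jump: float = DEFAULT_MAX_REL_JUMP,
) -> tuple:
    """Remove implausible beats: intervals outside ``[min_ms, max_ms]`` or
    differing from the previous *retained* interval by more than
    ``max_rel_jump`` (fractional).  Returns ``(clean_series, report)``.
    """
    if not (min_ms < max_ms):
        raise ValueError("min_ms must be < max_ms")
    if not (0 < max_rel_jump <= 1):
        raise ValueError("max_rel_jump must be in (0, 1]")
    kept = []
    removed = []
    reasons = []
    prev = None
    for i, v in enumerate(rr.intervals):
        if v < min_ms or v > max_ms:
            removed.append(i)
            reasons.append("bounds")
            continue
        if prev is not None and abs(v - prev) / prev > max_rel_jump:
            removed.append(i)
            reasons.append("jump")
            continue
        kept.append(v)
        prev = v
    if len(kept) < 2:
        raise ValueError("artifact filter removed (nearly) all beats")
    clean = RRSeries(subject_id=rr.subject_id, stage=rr.stage, intervals=np.array(kept))
    return clean, ArtifactReport(removed_indices=tuple(removed), reasons=tuple(reasons))


def read_feature_table(path) -> FeatureTable:
    """Read a feature table CSV (columns: subject, class, then M numeric features)."""
    df = pd.read_csv(path)
    return FeatureTable.from_frame(df)


def write_feature_table(table: FeatureTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_config(path) -> dict:
    """Parse a flat key=value config file.  Blank lines and '#' comments ignored.

    Values are returned as strings; callers coerce.
    """
    cfg = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if "=" not in s:
            raise ValueError(f"{path}: malformed config line {lineno}: {s!r}")
        key, _, val = s.partition("=")
        cfg[key.strip()] = val.strip()
    return cfg
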