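"""Plain-text I/O for spike-time tables, labels, feature tables and metrics.

All interchange formats are deliberately boring: comma-separated text with a
mandatory header for tabular data, JSON for metric documents.  Timestamps are
seconds as decimal numbers; the half-open window convention ``[t0, t1)`` is
used everywhere, so a spike exactly at treatment time belongs to the
treatment window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SPIKE_COLUMNS = ["well_id", "unit_id", "timestamp_s"]
LABEL_COLUMNS = ["well_id", "unit_id", "delta_mfr_hz", "kde_density", "label"]
FEATURE_COLUMNS = ["well_id", "unit_id", "mfr_hz", "isicv", "sync_median", "sync_skewness"]

NOCICEPTOR = "nociceptor"
NON_NOCICEPTOR = "non-nociceptor"
UNLABELED = "unlabeled"


class SpikeTableFormatError(ValueError):
    """The file is not a valid spike/label/feature table (e.g. missing columns)."""


class SpikeTableParseError(ValueError):
    """A row failed to parse or violated an invariant; the message names it."""


@dataclass(frozen=True)
class SpikeTrain:
    """One sorted unit's spike times within a well.

    ``timestamps`` are seconds, strictly increasing (each spike is one
    threshold crossing; duplicates are forbidden) and non-negative.
    """

    well_id: str
    unit_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if ts.size and ts[0] < 0:
            raise ValueError(
                f"unit {self.well_id}/{self.unit_id}: negative timestamp {ts[0]}"
            )
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            raise ValueError(
                f"unit {self.well_id}/{self.unit_id}: timestamps must be "
                "strictly increasing with no duplicates"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    def in_window(self, t0: float, t1: float) -> np.ndarray:
        """Spike times falling in the half-open interval [t0, t1)."""
        ts = self.timestamps
        return ts[(ts >= t0) & (ts < t1)]


@dataclass(frozen=True)
class SessionLayout:
    """Recording layout: condition plus the window boundaries t0 < t1 < t2.

    Baseline is [t0, t1), treatment (or pseudo-treatment, for untreated
    cultures) is [t1, t2).
    """

    condition: str
    t0: float = 0.0
    t1: float = 300.0
    t2: float = 600.0

    def __post_init__(self) -> None:
        if self.condition not in ("treated", "untreated"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not (self.t0 < self.t1 < self.t2):
            raise ValueError("layout requires t0 < t1 < t2")


@dataclass
class RecordingSession:
    """A condition's spike trains grouped by well, with its window layout.

    The baseline window ends exactly where the treatment window begins.
    """

    condition: str
    baseline_window: tuple[float, float]
    treatment_window: tuple[float, float]
    trains: list[SpikeTrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_window[1] != self.treatment_window[0]:
            raise ValueError("baseline window must end where treatment window begins")
        if not (self.baseline_window[0] < self.baseline_window[1] < self.treatment_window[1]):
            raise ValueError("windows must be non-degenerate and ordered")
        t0, t2 = self.baseline_window[0], self.treatment_window[1]
        for tr in self.trains:
            ts = tr.timestamps
            if ts.size and (ts[0] < t0 or ts[-1] >= t2):
                raise ValueError(
                    f"unit {tr.well_id}/{tr.unit_id} has spikes outside [{t0}, {t2})"
                )

    @property
    def wells(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trains:
            seen.setdefault(tr.well_id, None)
        return list(seen)

    def by_well(self) -> dict[str, list[SpikeTrain]]:
        out: dict[str, list[SpikeTrain]] = {}
        for tr in self.trains:
            out.setdefault(tr.well_id, []).append(tr)
        return out

    @property
    def n_units(self) -> int:
        return len(self.trains)


def read_spike_table(
    path: str | Path,
    layout: SessionLayout,
    out_of_range: str = "strict",
) -> RecordingSession:
    """Read a CSV spike table (columns well_id, unit_id, timestamp_s).

    Rows with timestamps outside the recording interval ``[t0, t2)`` raise
    an error in ``strict`` mode (default) or are dropped with a logged
    warning in ``drop`` mode.  Row numbers in error messages are 1-based
    data-row indices (the header is row 0).
    """
    if out_of_range not in ("strict", "drop"):
        raise ValueError("out_of_range must be 'strict' or 'drop'")
    df = pd.read_csv(path, dtype={"well_id": str, "unit_id": str})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise SpikeTableFormatError(f"{path}: missing columns {missing}")

    ts = pd.to_numeric(df["timestamp_s"], errors="coerce")
    bad = ts.isna() & df["timestamp_s"].notna()
    if df["timestamp_s"].isna().any():
        row = int(df.index[df["timestamp_s"].isna()][0]) + 1
        raise SpikeTableParseError(f"{path}: empty timestamp at row {row}")
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise SpikeTableParseError(
            f"{path}: non-numeric timestamp {df['timestamp_s'][row - 1]!r} at row {row}"
        )
    if (ts < 0).any():
        row = int(df.index[ts < 0][0]) + 1
        raise SpikeTableParseError(f"{path}: negative timestamp at row {row}")

    in_range = (ts >= layout.t0) & (ts < layout.t2)
    if not in_range.all():
        row = int(df.index[~in_range][0]) + 1
        if out_of_range == "strict":
            raise SpikeTableParseError(
                f"{path}: timestamp {ts[row - 1]} at row {row} outside recording "
                f"interval [{layout.t0}, {layout.t2})"
            )
        n_drop = int((~in_range).sum())
        log.warning("%s: dropping %d out-of-range row(s), first at row %d", path, n_drop, row)
        df = df[in_range]
        ts = ts[in_range]

    if df.empty:
        log.warning("%s: spike table contains no rows", path)

    trains = []
    df = df.assign(timestamp_s=ts)
    for (well, unit), grp in df.groupby(["well_id", "unit_id"], sort=True):
        times = np.sort(grp["timestamp_s"].to_numpy(dtype=float))
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise SpikeTableParseError(
                f"{path}: duplicate timestamp in unit {well}/{unit}"
            )
        trains.append(SpikeTrain(str(well), str(unit), times))
    return RecordingSession(
        condition=layout.condition,
        baseline_window=(layout.t0, layout.t1),
        treatment_window=(layout.t1, layout.t2),
        trains=trains,
    )


def write_spike_table(session: RecordingSession, path: str | Path) -> None:
    rows = [
        (tr.well_id, tr.unit_id, t)
        for tr in session.trains
        for t in tr.timestamps
    ]
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    """Write per-unit label records.

    Expects columns well_id, unit_id, delta_mfr_hz, kde_density and a boolean
    ``label`` column (True = nociceptor); labels are serialized as explicit
    strings so the file is self-describing.
    """
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise SpikeTableFormatError(f"label records missing columns {missing}")
    out = labels[LABEL_COLUMNS].copy()
    out["label"] = np.where(out["label"].astype(bool), NOCICEPTOR, NON_NOCICEPTOR)
    out.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well_id": str, "unit_id": str})
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise SpikeTableFormatError(f"{path}: missing columns {missing}")
    bad = ~df["label"].isin([NOCICEPTOR, NON_NOCICEPTOR])
    if bad.any():
        raise SpikeTableParseError(
            f"{path}: unknown label value {df['label'][bad].iloc[0]!r}"
        )
    df["label"] = df["label"] == NOCICEPTOR
    return df


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write the four-feature baseline phenotype table, with label if present."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise SpikeTableFormatError(f"feature records missing columns {missing}")
    cols = list(FEATURE_COLUMNS)
    out = features[cols].copy()
    if "label" in features.columns:
        out["label"] = np.where(
            features["label"].astype(bool), NOCICEPTOR, NON_NOCICEPTOR
        )
    out.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature table; a missing label column yields an explicit
    ``"unlabeled"`` marker column rather than a silent default."""
    df = pd.read_csv(path, dtype={"well_id": str, "unit_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SpikeTableFormatError(f"{path}: missing columns {missing}")
    if "label" in df.columns:
        bad = ~df["label"].isin([NOCICEPTOR, NON_NOCICEPTOR])
        if bad.any():
            raise SpikeTableParseError(
                f"{path}: unknown label value {df['label'][bad].iloc[0]!r}"
            )
        df["label"] = df["label"] == NOCICEPTOR
    else:
        df["label"] = UNLABELED
    return df


def write_metrics(metrics: dict, path: str | Path) -> None:
    """Write a metrics document as JSON (floats round-trip exactly)."""
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_metrics(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
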