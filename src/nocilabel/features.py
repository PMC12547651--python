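"""Baseline phenotype features: MFR, ISI CV, and pairwise spike synchronization.

Each unit's functional phenotype is summarized over the entire baseline
window (never the 30-s response bins) by four numbers:

* mean firing rate (Hz);
* ISI coefficient of variation (SD/mean of consecutive inter-spike
  intervals; 0 for clock-like firing, ≈1 for Poisson firing);
* the median and the adjusted Fisher–Pearson skewness (G1) of the unit's
  pairwise spike-synchronization values against every other active unit in
  the same well (pairs never cross wells).

Spike synchronization is the adaptive-coincidence measure: each spike is
matched to its nearest counterpart in the other train, the coincidence
window τ is half the minimum of the four adjacent ISIs (its own
preceding/following and its counterpart's preceding/following), and the
measure is the fraction of spikes of both trains whose nearest counterpart
lies strictly within τ — a bounded [0,1], parameter- and timescale-free
similarity.  At the window edges, the distance to the window boundary
serves as the surrogate adjacent ISI (auxiliary-spike convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import RecordingSession, SpikeTrain

__all__ = [
    "FeatureUndefinedError",
    "mean_firing_rate",
    "isi_cv",
    "spike_synchronization",
    "pairwise_synchrony_stats",
    "adjusted_skewness",
    "build_feature_table",
]

MIN_SPIKES_FOR_ISICV = 3  # two ISIs are the minimum for a sample SD
MIN_VALID_PAIRS = 3


class FeatureUndefinedError(ValueError):
    """A feature's precondition is not met for this unit (too few spikes
    or too few valid pairs); callers exclude the unit rather than impute."""


def mean_firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in the half-open window divided by window length, Hz."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window length must be > 0")
    return train.in_window(t0, t1).size / (t1 - t0)


def isi_cv(train: SpikeTrain, window: tuple[float, float], ddof: int = 1) -> float:
    """Coefficient of variation of consecutive inter-spike intervals.

    Uses the sample (n−1) SD by default; requires at least 3 spikes in the
    window (2 ISIs), else raises FeatureUndefinedError.
    """
    ts = train.in_window(*window)
    if ts.size < MIN_SPIKES_FOR_ISICV:
        raise FeatureUndefinedError(
            f"unit {train.well_id}/{train.unit_id}: insufficient ISIs "
            f"({ts.size} spike(s) in window)"
        )
    isis = np.diff(ts)
    return float(np.std(isis, ddof=ddof) / np.mean(isis))


def _adjacent_isis(ts: np.ndarray, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    """Preceding and following ISI for each spike, with the distance to the
    window edge as surrogate ISI for the first/last spike."""
    prev = np.empty(ts.size)
    nxt = np.empty(ts.size)
    prev[0] = ts[0] - t0
    nxt[-1] = t1 - ts[-1]
    if ts.size > 1:
        d = np.diff(ts)
        prev[1:] = d
        nxt[:-1] = d
    return prev, nxt


def _coincidences(
    a: np.ndarray,
    b: np.ndarray,
    prev_a: np.ndarray,
    nxt_a: np.ndarray,
    prev_b: np.ndarray,
    nxt_b: np.ndarray,
) -> int:
    """Number of spikes of `a` whose nearest spike of `b` is strictly within
    the adaptive coincidence window."""
    idx = np.searchsorted(b, a)
    left = np.clip(idx - 1, 0, b.size - 1)
    right = np.clip(idx, 0, b.size - 1)
    d_left = np.abs(a - b[left])
    d_right = np.abs(a - b[right])
    use_right = d_right < d_left
    j = np.where(use_right, right, left)
    d = np.where(use_right, d_right, d_left)
    tau = 0.5 * np.minimum.reduce([prev_a, nxt_a, prev_b[j], nxt_b[j]])
    return int(np.count_nonzero(d < tau))


def spike_synchronization(
    train_a: SpikeTrain | np.ndarray,
    train_b: SpikeTrain | np.ndarray,
    window: tuple[float, float],
) -> float:
    """Adaptive-coincidence spike synchronization of two trains in [t0, t1).

    Returns the mean coincidence indicator over all spikes of both trains,
    bounded in [0, 1]; 1 for identical trains.  Undefined (raises) when
    either train has no spike in the window.
    """
    t0, t1 = window
    a = train_a.in_window(t0, t1) if isinstance(train_a, SpikeTrain) else np.asarray(train_a, float)
    b = train_b.in_window(t0, t1) if isinstance(train_b, SpikeTrain) else np.asarray(train_b, float)
    if a.size == 0 or b.size == 0:
        raise FeatureUndefinedError("spike synchronization undefined for empty train")
    prev_a, nxt_a = _adjacent_isis(a, t0, t1)
    prev_b, nxt_b = _adjacent_isis(b, t0, t1)
    n_coinc = _coincidences(a, b, prev_a, nxt_a, prev_b, nxt_b)
    n_coinc += _coincidences(b, a, prev_b, nxt_b, prev_a, nxt_a)
    return n_coinc / (a.size + b.size)


def adjusted_skewness(values: np.ndarray) -> float:
    """Adjusted Fisher–Pearson skewness G1 = [sqrt(n(n−1))/(n−2)]·m3/m2^1.5;
    zero-variance samples return 0 by convention."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.ptp(v) == 0 or np.isclose(np.var(v), 0.0):
        return 0.0
    return float(stats.skew(v, bias=False))


def pairwise_synchrony_stats(
    unit: SpikeTrain,
    co_resident: list[SpikeTrain],
    window: tuple[float, float],
) -> tuple[float, float]:
    """Median and G1 skewness of the unit's pairwise synchronization values
    against every other active unit in its well.

    Pairs with an empty counterpart train are excluded; at least 3 valid
    pairs are required, else FeatureUndefinedError.
    """
    if unit.in_window(*window).size == 0:
        raise FeatureUndefinedError(
            f"unit {unit.well_id}/{unit.unit_id}: no baseline spikes"
        )
    values = []
    for other in co_resident:
        if other.well_id != unit.well_id:
            raise ValueError("pairwise synchrony never crosses wells")
        if other.unit_id == unit.unit_id:
            continue
        if other.in_window(*window).size == 0:
            continue
        values.append(spike_synchronization(unit, other, window))
    if len(values) < MIN_VALID_PAIRS:
        raise FeatureUndefinedError(
            f"unit {unit.well_id}/{unit.unit_id}: only {len(values)} valid "
            f"pair(s), need {MIN_VALID_PAIRS}"
        )
    vals = np.asarray(values)
    return float(np.median(vals)), adjusted_skewness(vals)


def build_feature_table(
    session: RecordingSession,
    labels: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline feature vectors for every retained unit of a session.

    Units failing a feature precondition (too few spikes for the ISI CV,
    too few valid within-well pairs) are excluded — never imputed — and
    listed in the returned exclusion report with a reason.  When ``labels``
    is given (columns well_id, unit_id, label) it is joined on the unit key;
    labeled units missing from the session's retained set raise an error
    listing them.

    Returns (features, exclusions).
    """
    window = session.baseline_window
    by_well = session.by_well()
    rows, excluded = [], []
    for well_id, trains in by_well.items():
        for tr in trains:
            try:
                mfr = mean_firing_rate(tr, window)
                cv = isi_cv(tr, window)
                med, skw = pairwise_synchrony_stats(tr, trains, window)
            except FeatureUndefinedError as err:
                reason = str(err).split(": ", 1)[-1]
                excluded.append(
                    {"well_id": well_id, "unit_id": tr.unit_id, "reason": reason}
                )
                continue
            rows.append(
                {
                    "well_id": well_id,
                    "unit_id": tr.unit_id,
                    "mfr_hz": mfr,
                    "isicv": cv,
                    "sync_median": med,
                    "sync_skewness": skw,
                }
            )
    features = pd.DataFrame(
        rows,
        columns=["well_id", "unit_id", "mfr_hz", "isicv", "sync_median", "sync_skewness"],
    )
    exclusions = pd.DataFrame(excluded, columns=["well_id", "unit_id", "reason"])
    if labels is not None:
        lab = labels[["well_id", "unit_id", "label"]]
        merged = features.merge(lab, on=["well_id", "unit_id"], how="left", validate="1:1")
        unmatched = merged["label"].isna()
        if unmatched.any():
            keys = merged.loc[unmatched, ["well_id", "unit_id"]].to_records(index=False)
            raise ValueError(f"units without a label: {list(map(tuple, keys))}")
        features = merged
    return features, exclusions
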