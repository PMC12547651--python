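"""Synthetic multi-well MEA sessions with known ground-truth subtypes.

The generator emulates the statistical structure of heterogeneous sensory
neuron co-cultures used for pharmacological responder labeling:

* each unit is a gamma-renewal spike train with a subtype-drawn baseline
  rate (log-normal) and gamma ISI shape ``k`` (``k < 1`` gives irregular
  firing, ISI CV > 1);
* within-well synchrony is planted by the mother-process (single
  interaction process) construction: every well has a shared homogeneous
  Poisson "mother" train, and each unit copies its spikes with a per-unit
  probability, jittering copies by a Gaussian SD, then merges them with an
  independent renewal component;
* in a treated session, ground-truth responders multiply their total rate
  by ``response_gain`` from the treatment time (plus a uniform onset
  latency) onward; untreated sessions have no rate change and carry only
  non-responder ground truth.

Responders are parameterized to fire faster, more irregularly and more
synchronously than non-responders at baseline; non-responders participate
in the mother process only sparsely (a small fraction of high-participation
units), which makes their pairwise-synchrony distributions right-skewed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RecordingSession, SpikeTrain, write_spike_table

__all__ = [
    "SubtypeParams",
    "SyntheticConfig",
    "generate_session",
    "generate_study",
]


@dataclass(frozen=True)
class SubtypeParams:
    """Baseline statistics of one functional subtype.

    rate_log_median: median of the log-normal baseline firing rate, Hz.
    rate_log_sd: SD of log-rate (dimensionless).
    isi_shape: gamma renewal shape k; ISI CV = 1/sqrt(k).
    p_sync: probability a unit copies each mother-process spike.
    p_sync_high / high_frac: a fraction of units is drawn with the elevated
        copy probability instead (sparse high-sync participation).
    jitter_sd: Gaussian jitter of copied spikes, seconds.
    """

    rate_log_median: float
    rate_log_sd: float
    isi_shape: float
    p_sync: float
    p_sync_high: float = 0.0
    high_frac: float = 0.0
    jitter_sd: float = 0.005


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale configuration; defaults mirror a 14-well agonist arm of
    roughly 620 single units with ~37% planted responders."""

    n_wells_treated: int = 14
    n_wells_untreated: int = 14
    units_per_well: tuple[int, int] = (30, 60)
    responder_fraction: float = 0.3682
    responder: SubtypeParams = field(
        default_factory=lambda: SubtypeParams(
            rate_log_median=1.8, rate_log_sd=0.3, isi_shape=0.4, p_sync=0.9
        )
    )
    non_responder: SubtypeParams = field(
        default_factory=lambda: SubtypeParams(
            rate_log_median=0.7,
            rate_log_sd=0.8,
            isi_shape=2.0,
            p_sync=0.2,
            p_sync_high=0.6,
            high_frac=0.1,
        )
    )
    response_gain: float = 4.0
    response_latency_jitter: float = 5.0
    mother_rate: float = 1.2
    baseline_duration: float = 300.0
    treatment_duration: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.response_gain <= 0:
            raise ValueError("response_gain must be > 0")
        if self.baseline_duration <= 0 or self.treatment_duration <= 0:
            raise ValueError("durations must be > 0")
        lo, hi = self._unit_range()
        if lo < 1 or hi < lo:
            raise ValueError("units_per_well must be a positive count or range")
        if self.n_wells_treated < 1 or self.n_wells_untreated < 1:
            raise ValueError("need at least one well per condition")
        if self.response_latency_jitter < 0 or self.mother_rate < 0:
            raise ValueError("latency jitter and mother rate must be >= 0")

    def _unit_range(self) -> tuple[int, int]:
        if isinstance(self.units_per_well, int):
            return self.units_per_well, self.units_per_well
        lo, hi = self.units_per_well
        return int(lo), int(hi)

    def windows(self) -> tuple[float, float, float]:
        t1 = self.baseline_duration
        return 0.0, t1, t1 + self.treatment_duration


def _renewal_train(
    rng: np.random.Generator, rate: float, shape: float, t0: float, t1: float
) -> np.ndarray:
    """Ordinary gamma-renewal process on [t0, t1): ISIs ~ Gamma(k, 1/(k*rate)),
    so the mean ISI is 1/rate and the ISI CV is 1/sqrt(k)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    dur = t1 - t0
    scale = 1.0 / (shape * rate)
    out: list[np.ndarray] = []
    t = t0
    while True:
        expected = max(16, int((t1 - t) * rate * 1.5) + 16)
        isis = rng.gamma(shape, scale, size=expected)
        times = t + np.cumsum(isis)
        if times[-1] >= t1:
            out.append(times[times < t1])
            break
        out.append(times)
        t = times[-1]
    return np.concatenate(out)


def _unit_spikes(
    rng: np.random.Generator,
    *,
    rate: float,
    shape: float,
    p_sync: float,
    jitter_sd: float,
    mother: np.ndarray,
    mother_rate: float,
    t0: float,
    t1: float,
    t2: float,
    gain: float,
    onset: float | None,
) -> np.ndarray:
    """Merge an independent renewal component with jittered mother copies.

    The independent rate is set so the unit's *total* expected rate equals
    ``rate`` before onset and ``rate * gain`` after; the mother contribution
    (p_sync * mother_rate) is the shared part of both.
    """
    shared_rate = p_sync * mother_rate
    base_ind = max(rate - shared_rate, 0.05 * rate)
    pieces = []
    if onset is None or gain == 1.0:
        pieces.append(_renewal_train(rng, base_ind, shape, t0, t2))
    else:
        post_ind = max(rate * gain - shared_rate, 0.05 * rate * gain)
        pieces.append(_renewal_train(rng, base_ind, shape, t0, onset))
        pieces.append(_renewal_train(rng, post_ind, shape, onset, t2))
    if mother.size and p_sync > 0:
        copies = mother[rng.random(mother.size) < p_sync]
        if jitter_sd > 0:
            copies = copies + rng.normal(0.0, jitter_sd, size=copies.size)
        copies = copies[(copies >= t0) & (copies < t2)]
        pieces.append(copies)
    spikes = np.sort(np.concatenate(pieces))
    return np.unique(spikes)  # exact duplicates forbidden by the data model


def generate_session(
    config: SyntheticConfig,
    condition: str,
    rng: np.random.Generator | None = None,
    well_prefix: str | None = None,
) -> tuple[RecordingSession, pd.DataFrame]:
    """Generate one condition's session and its ground-truth table.

    Returns the session plus a DataFrame with one row per unit:
    well_id, unit_id, is_responder, baseline_rate_hz, isi_shape, p_sync.
    For ``condition="untreated"`` no rate change is applied and every
    ground-truth label is non-responder (the subtype mixture is still drawn,
    so the pseudo-treatment null matches the treated baseline marginal).
    """
    config.validate()
    if condition not in ("treated", "untreated"):
        raise ValueError(f"unknown condition {condition!r}")
    if rng is None:
        rng = np.random.default_rng([config.seed, 0 if condition == "treated" else 1])
    t0, t1, t2 = config.windows()
    n_wells = (
        config.n_wells_treated if condition == "treated" else config.n_wells_untreated
    )
    prefix = well_prefix or ("T" if condition == "treated" else "U")
    lo, hi = config._unit_range()

    trains: list[SpikeTrain] = []
    truth_rows = []
    for w in range(n_wells):
        well_id = f"{prefix}{w + 1:02d}"
        n_units = int(rng.integers(lo, hi + 1))
        mother = _renewal_train(rng, config.mother_rate, 1.0, t0, t2)
        for u in range(n_units):
            is_resp = bool(rng.random() < config.responder_fraction)
            params = config.responder if is_resp else config.non_responder
            rate = params.rate_log_median * np.exp(
                rng.normal(0.0, params.rate_log_sd)
            )
            p_sync = params.p_sync
            if params.high_frac > 0 and rng.random() < params.high_frac:
                p_sync = params.p_sync_high
            responds = is_resp and condition == "treated"
            onset = (
                t1 + rng.uniform(0.0, config.response_latency_jitter)
                if responds
                else None
            )
            spikes = _unit_spikes(
                rng,
                rate=rate,
                shape=params.isi_shape,
                p_sync=p_sync,
                jitter_sd=params.jitter_sd,
                mother=mother,
                mother_rate=config.mother_rate,
                t0=t0,
                t1=t1,
                t2=t2,
                gain=config.response_gain if responds else 1.0,
                onset=onset,
            )
            unit_id = f"u{u + 1:03d}"
            trains.append(SpikeTrain(well_id, unit_id, spikes))
            truth_rows.append(
                {
                    "well_id": well_id,
                    "unit_id": unit_id,
                    "is_responder": is_resp and condition == "treated",
                    "baseline_rate_hz": rate,
                    "isi_shape": params.isi_shape,
                    "p_sync": p_sync,
                }
            )
    session = RecordingSession(
        condition=condition,
        baseline_window=(t0, t1),
        treatment_window=(t1, t2),
        trains=trains,
    )
    return session, pd.DataFrame(truth_rows)


def generate_study(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[RecordingSession, RecordingSession, pd.DataFrame]:
    """Generate the treated and untreated arms plus the combined truth table.

    When ``out_dir`` is given, writes treated.csv, untreated.csv and
    truth.csv there.  Fixing ``config.seed`` fixes all output bit-for-bit.
    """
    config.validate()
    treated, truth_t = generate_session(config, "treated")
    untreated, truth_u = generate_session(config, "untreated")
    truth = pd.concat([truth_t, truth_u], ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spike_table(treated, out / "treated.csv")
        write_spike_table(untreated, out / "untreated.csv")
        truth.to_csv(out / "truth.csv", index=False)
    return treated, untreated, truth


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a flat mapping (e.g. parsed YAML);
    subtype blocks may be nested mappings."""
    kwargs = dict(d)
    for key in ("responder", "non_responder"):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = SubtypeParams(**kwargs[key])
    if "units_per_well" in kwargs and isinstance(kwargs["units_per_well"], list):
        kwargs["units_per_well"] = tuple(kwargs["units_per_well"])
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SyntheticConfig(**kwargs)
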