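"""Sleep-deprivation bookkeeping and rebound metrics.

An :class:`SDExperiment` pairs one or more basal (undisturbed) days with a
sleep-deprivation (SD) day on the same epoch grid; basal metrics are the
arithmetic mean over basal days.  The same machinery serves pharmacological
designs (e.g. saline day as "basal", drug day as "sd_day") — only the day
labels change.

Rebound metrics:

* cumulative sleep loss: running sum of (SD - basal) sleep minutes per bin;
* rebound ratio: SD / basal of a metric within a window (default ZT12-24);
* paired delta: SD - basal within a window (default ZT12-15);
* rebound onset: hour where the smoothed cumulative-loss curve bottoms out
  and starts recovering (no standard definition exists; this package uses
  the minimum of the smoothed curve, flagged as a package convention);
* delta-power rebound: percentage change of the NREM delta fraction
  (default window ZT6-12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sleepmap.hypnogram import (
    Hypnogram,
    TWO_STATE,
    Window,
    collapse_three_to_two,
    count_transitions,
    state_duration,
    transition_probability,
)
from sleepmap.spectral import (
    DELTA,
    Band,
    Recording,
    SpectralConfig,
    band_fraction_percent,
    flag_artifact_epochs,
    state_psd_percent,
)


class UndefinedMetricError(ValueError):
    """Raised when a ratio would divide by a zero basal metric."""


def _two_state(hyp: Hypnogram) -> Hypnogram:
    return hyp if hyp.alphabet == TWO_STATE else collapse_three_to_two(hyp)


@dataclass
class SDExperiment:
    """Paired basal-day and deprivation-day hypnograms.

    Each day is a full-day hypnogram starting at its own ZT0; all days must
    share the epoch length and timebase.  ``basal`` may hold several days
    (averaged in every metric).  Optional recordings plus three-state
    hypnograms enable the spectral rebound metric.
    """

    basal: list[Hypnogram]
    sd_day: Hypnogram
    deprivation_start: float = 0.0
    deprivation_end: float = 6.0
    basal_recordings: list[Recording] = field(default_factory=list)
    sd_recording: Recording | None = None
    basal_hyp3: list[Hypnogram] = field(default_factory=list)
    sd_hyp3: Hypnogram | None = None

    def __post_init__(self) -> None:
        if not self.basal:
            raise ValueError("at least one basal day is required")
        days = [*self.basal, self.sd_day]
        eps = {d.epoch_length for d in days}
        if len(eps) != 1:
            raise ValueError("all days must share epoch_length")
        tbs = {d.timebase for d in days}
        if len(tbs) != 1:
            raise ValueError("all days must share timebase")
        n = {d.n_epochs for d in days}
        if len(n) != 1:
            raise ValueError("all days must share the epoch grid")
        if not (0 <= self.deprivation_start < self.deprivation_end <= 24):
            raise ValueError("deprivation window must lie inside the SD day")

    @property
    def epoch_length(self) -> float:
        return self.sd_day.epoch_length


def _metric_value(hyp: Hypnogram, win: Window, metric: str, degenerate: str = "one") -> float:
    hyp2 = _two_state(hyp)
    if metric == "duration":
        return state_duration(hyp2, win, "S")
    counts = count_transitions(hyp2, win)
    if metric == "p_ws":
        return transition_probability(counts, "W", degenerate=degenerate)
    if metric == "p_sw":
        return transition_probability(counts, "S", degenerate=degenerate)
    raise ValueError("metric must be 'duration', 'p_ws' or 'p_sw'")


def day_metric(
    exp: SDExperiment, day: str, zt_start: float, zt_end: float, metric: str
) -> float:
    """Metric on one day type; basal values are averaged across basal days."""
    if day == "sd":
        win = exp.sd_day.zt_window(zt_start, zt_end)
        return _metric_value(exp.sd_day, win, metric)
    if day == "basal":
        vals = [
            _metric_value(h, h.zt_window(zt_start, zt_end), metric) for h in exp.basal
        ]
        return float(np.mean(vals))
    raise ValueError("day must be 'sd' or 'basal'")


def cumulative_difference(
    exp: SDExperiment, resolution_minutes: float = 60.0
) -> pd.Series:
    """Cumulative sleep loss (SD - basal) over the 24-h day, in minutes.

    Indexed by bin end hour (ZT); the value at ZT24 equals total SD-day
    sleep minus mean total basal sleep.
    """
    step = resolution_minutes / 60.0
    edges = np.arange(0.0, 24.0 + 1e-9, step)
    diffs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sd = state_duration(_two_state(exp.sd_day), exp.sd_day.zt_window(lo, hi), "S")
        basal = float(
            np.mean(
                [
                    state_duration(_two_state(h), h.zt_window(lo, hi), "S")
                    for h in exp.basal
                ]
            )
        )
        diffs.append(sd - basal)
    return pd.Series(np.cumsum(diffs), index=edges[1:], name="cumulative_sleep_loss_min")


def rebound_ratio(
    exp: SDExperiment,
    zt_start: float = 12.0,
    zt_end: float = 24.0,
    metric: str = "duration",
) -> float:
    """SD-day metric divided by mean basal metric within [zt_start, zt_end)."""
    basal = day_metric(exp, "basal", zt_start, zt_end, metric)
    if not np.isfinite(basal) or basal == 0:
        raise UndefinedMetricError(
            f"basal {metric} in ZT{zt_start}-{zt_end} is zero or undefined"
        )
    return day_metric(exp, "sd", zt_start, zt_end, metric) / basal


def paired_delta(
    exp: SDExperiment,
    zt_start: float = 12.0,
    zt_end: float = 15.0,
    metric: str = "duration",
) -> float:
    """SD-day metric minus mean basal metric within [zt_start, zt_end)."""
    return day_metric(exp, "sd", zt_start, zt_end, metric) - day_metric(
        exp, "basal", zt_start, zt_end, metric
    )


def rebound_onset(
    exp: SDExperiment,
    resolution_minutes: float = 60.0,
    smooth_hours: float = 1.0,
    sustain_hours: float = 1.0,
) -> float:
    """Hour at which recovery of the cumulative-loss curve begins.

    The cumulative (SD - basal) series is smoothed with a centered moving
    average of ``smooth_hours``; the onset is the hour (at or after
    deprivation end) where the smoothed series attains its minimum and is
    nondecreasing for at least ``sustain_hours`` afterwards.  NaN when no
    such hour exists (no rebound).
    """
    series = cumulative_difference(exp, resolution_minutes)
    step = resolution_minutes / 60.0
    k = max(1, int(round(smooth_hours / step)))
    smoothed = series.rolling(k, center=True, min_periods=1).mean()
    hours = smoothed.index.to_numpy()
    values = smoothed.to_numpy()
    eligible = np.where(hours >= exp.deprivation_end - 1e-9)[0]
    if eligible.size == 0:
        return float("nan")
    n_sustain = max(1, int(round(sustain_hours / step)))
    order = eligible[np.argsort(values[eligible], kind="stable")]
    for i in order:
        seg = values[i : i + n_sustain + 1]
        if seg.size < 2:
            continue  # minimum at the very end: recovery not observable
        if np.all(np.diff(seg) >= -1e-9):
            return float(hours[i])
    return float("nan")


def delta_rebound_percent(
    exp: SDExperiment,
    zt_start: float = 6.0,
    zt_end: float = 12.0,
    band: Band = DELTA,
    state: str = "N",
    config: SpectralConfig = SpectralConfig(),
    exclude_artifacts: bool = True,
) -> float:
    """Percentage change of the NREM band fraction on the SD day vs basal.

    ``100 * (fraction_SD - fraction_basal) / fraction_basal`` over the
    window, computed from unmasked epochs of ``state``.  NaN when either
    day has no eligible epoch in the window.
    """
    if exp.sd_recording is None or exp.sd_hyp3 is None or not exp.basal_recordings:
        raise ValueError("delta_rebound_percent requires recordings and staged days")

    def fraction(rec: Recording, hyp: Hypnogram) -> float:
        mask = flag_artifact_epochs(rec, hyp) if exclude_artifacts else None
        win = hyp.zt_window(zt_start, zt_end)
        result = state_psd_percent(rec, hyp, state, win, mask, config)
        return band_fraction_percent(result, band)

    sd = fraction(exp.sd_recording, exp.sd_hyp3)
    basal_vals = [
        fraction(rec, hyp) for rec, hyp in zip(exp.basal_recordings, exp.basal_hyp3)
    ]
    basal = float(np.nanmean(basal_vals)) if basal_vals else float("nan")
    if not np.isfinite(sd) or not np.isfinite(basal) or basal == 0:
        return float("nan")
    return 100.0 * (sd - basal) / basal
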