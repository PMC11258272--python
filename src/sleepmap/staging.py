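"""Rule-based three-state vigilance staging of 8-s epochs from EEG/EMG features.

The rules implement the standard manual-scoring criteria for mouse
polysomnography: wakefulness is low-amplitude EEG with high-amplitude EMG;
NREM sleep is high-amplitude EEG dominated by the 0.5-4 Hz delta band with
low EMG; REM sleep is low-amplitude EEG dominated by the 6-10 Hz theta band
with EMG atonia.  The criteria are qualitative — every numeric cutoff here
is a package decision, data-driven by default because absolute amplitudes
are rig-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sleepmap.hypnogram import Hypnogram
from sleepmap.spectral import (
    DELTA,
    THETA,
    Recording,
    SpectralConfig,
    all_epoch_psd,
    band_mask,
    epoch_rms,
)


@dataclass(frozen=True)
class StagerThresholds:
    """Scalar cutoffs for the staging rules.

    ``emg_high``: EMG RMS at/above which an epoch is wake.
    ``emg_atonia``: EMG RMS at/below which atonia is assumed (REM gate).
    ``eeg_high_amplitude``: EEG RMS at/above which the EEG counts as
    high-amplitude (NREM gate).
    ``delta_dominance``: minimum delta fraction of total power for NREM.
    ``theta_dominance``: minimum theta/delta power ratio for REM.
    """

    emg_high: float
    emg_atonia: float
    eeg_high_amplitude: float
    delta_dominance: float = 0.4
    theta_dominance: float = 1.5

    def __post_init__(self) -> None:
        if self.emg_atonia > self.emg_high:
            raise ValueError("emg_atonia must not exceed emg_high")


#: Absolute fallback cutoffs used when the features are degenerate (constant).
FALLBACK_THRESHOLDS = StagerThresholds(
    emg_high=10.0, emg_atonia=2.0, eeg_high_amplitude=30.0
)


def extract_features(
    rec: Recording,
    epoch_length: float = 8.0,
    config: SpectralConfig = SpectralConfig(),
) -> pd.DataFrame:
    """Per-epoch staging features.

    Columns: eeg_rms, emg_rms, delta_fraction, theta_fraction,
    theta_delta_ratio.  Fractions are of total power in the configured
    analysis band; the ratio is theta power / delta power (inf when delta
    power is zero but theta is not).
    """
    freqs, psd = all_epoch_psd(rec, epoch_length, config)
    tot = band_mask(freqs, config.total_band(rec.fs))
    total = psd[:, tot].sum(axis=1)
    delta = psd[:, band_mask(freqs, DELTA)].sum(axis=1)
    theta = psd[:, band_mask(freqs, THETA)].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_fraction = np.where(total > 0, delta / total, 0.0)
        theta_fraction = np.where(total > 0, theta / total, 0.0)
        theta_delta_ratio = np.where(
            delta > 0, theta / delta, np.where(theta > 0, np.inf, 0.0)
        )
    eeg_rms, emg_rms = epoch_rms(rec, epoch_length)
    return pd.DataFrame(
        {
            "eeg_rms": eeg_rms,
            "emg_rms": emg_rms,
            "delta_fraction": delta_fraction,
            "theta_fraction": theta_fraction,
            "theta_delta_ratio": theta_delta_ratio,
        }
    )


def _two_means_split(values: np.ndarray) -> tuple[float, float]:
    """Exact 1-D two-class split minimizing within-class variance (Otsu).

    Returns the means of the low and high class at the optimal split.
    Deterministic; assumes at least two distinct values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    csum = np.cumsum(x)
    total = csum[-1]
    ks = np.arange(1, n)
    mean_lo = csum[:-1] / ks
    mean_hi = (total - csum[:-1]) / (n - ks)
    # maximize between-class variance = w_lo * w_hi * (mu_hi - mu_lo)^2
    between = ks * (n - ks) * (mean_hi - mean_lo) ** 2
    k = int(np.argmax(between))
    return float(mean_lo[k]), float(mean_hi[k])


def fit_thresholds(
    features: pd.DataFrame,
    fallback: StagerThresholds = FALLBACK_THRESHOLDS,
    delta_dominance: float = 0.4,
    theta_dominance: float = 1.5,
) -> StagerThresholds:
    """Data-driven cutoffs from a feature table.

    ``emg_high`` is the geometric midpoint of a two-class split of
    log(EMG RMS) (scale-equivariant: rescaling the signal rescales the
    threshold); ``emg_atonia`` is the 10th percentile of EMG RMS;
    ``eeg_high_amplitude`` is the median EEG RMS.  With fewer than 100
    epochs or degenerate (constant) features the configured absolute
    fallbacks are used and a warning is emitted.
    """
    if len(features) < 100:
        warnings.warn("fewer than 100 epochs; data-driven thresholds are unreliable")
    emg = features["emg_rms"].to_numpy(dtype=float)
    eeg = features["eeg_rms"].to_numpy(dtype=float)
    degenerate = (
        emg.size < 2
        or np.ptp(emg) <= 1e-12 * max(1.0, np.abs(emg).max())
        or np.any(emg <= 0)
    )
    if degenerate:
        warnings.warn("degenerate EMG feature; falling back to absolute cutoffs")
        return replace(
            fallback, delta_dominance=delta_dominance, theta_dominance=theta_dominance
        )
    lo, hi = _two_means_split(np.log(emg))
    emg_high = float(np.exp(0.5 * (lo + hi)))
    emg_atonia = float(np.quantile(emg, 0.10))
    emg_atonia = min(emg_atonia, emg_high)
    return StagerThresholds(
        emg_high=emg_high,
        emg_atonia=emg_atonia,
        eeg_high_amplitude=float(np.median(eeg)),
        delta_dominance=delta_dominance,
        theta_dominance=theta_dominance,
    )


def stage_epochs(
    features: pd.DataFrame,
    thresholds: StagerThresholds,
    epoch_length: float = 8.0,
    start_hour: float = 0.0,
    smooth: bool = False,
    subject_id: str | None = None,
) -> Hypnogram:
    """Classify every epoch into W/N/R by fixed rule precedence.

    Rules, in order: (1) EMG RMS >= emg_high -> W (low-amplitude EEG with
    high-amplitude EMG); else (2) EEG RMS >= eeg_high_amplitude and delta
    fraction >= delta_dominance -> N (high-amplitude, delta-dominant EEG
    with low EMG); else (3) theta/delta ratio >= theta_dominance and EMG
    RMS <= emg_atonia -> R (theta-dominant EEG with atonia); else (4) W.
    EMG dominance goes first because it is the least ambiguous cue.

    ``smooth=True`` applies an optional 3-epoch majority filter (off by
    default; the scoring criteria describe no smoothing rule).
    """
    emg = features["emg_rms"].to_numpy(dtype=float)
    eeg = features["eeg_rms"].to_numpy(dtype=float)
    delta = features["delta_fraction"].to_numpy(dtype=float)
    ratio = features["theta_delta_ratio"].to_numpy(dtype=float)
    stages = np.full(len(features), "W", dtype="<U1")
    awake = emg >= thresholds.emg_high
    nrem = ~awake & (eeg >= thresholds.eeg_high_amplitude) & (delta >= thresholds.delta_dominance)
    rem = (
        ~awake
        & ~nrem
        & (ratio >= thresholds.theta_dominance)
        & (emg <= thresholds.emg_atonia)
    )
    stages[nrem] = "N"
    stages[rem] = "R"
    if smooth:
        stages = _majority3(stages)
    return Hypnogram(
        stages=stages,
        epoch_length=epoch_length,
        start_hour=start_hour,
        subject_id=subject_id,
        alphabet=("W", "N", "R"),
    )


def _majority3(stages: np.ndarray) -> np.ndarray:
    out = stages.copy()
    for i in range(1, len(stages) - 1):
        a, b, c = stages[i - 1], stages[i], stages[i + 1]
        if a == c and b != a:
            out[i] = a
    return out


def stage_recording(
    rec: Recording,
    epoch_length: float = 8.0,
    start_hour: float = 0.0,
    thresholds: StagerThresholds | None = None,
    config: SpectralConfig = SpectralConfig(),
    smooth: bool = False,
    subject_id: str | None = None,
) -> Hypnogram:
    """Convenience pipeline: features -> (fitted) thresholds -> hypnogram."""
    features = extract_features(rec, epoch_length, config)
    if thresholds is None:
        thresholds = fit_thresholds(features)
    return stage_epochs(
        features,
        thresholds,
        epoch_length=epoch_length,
        start_hour=start_hour,
        smooth=smooth,
        subject_id=subject_id,
    )
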