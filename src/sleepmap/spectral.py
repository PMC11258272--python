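"""Per-epoch Welch power spectra, artifact exclusion and normalized band power.

Each 8-s epoch gets a Welch averaged-periodogram PSD (default 2-s Hann
segments, 50% overlap, i.e. 0.5 Hz bins — fine enough to resolve the
0.5-1 Hz slow-oscillation band while still averaging 7 segments).  Spectra
are averaged over all unmasked epochs of one vigilance state and expressed
as a percentage of total power over the analysis band (default 0.5 Hz to
Nyquist; DC is excluded because its offset is amplifier-dependent).

Band edges are half-open [lo, hi) on bin centers so that delta (0.5-4 Hz)
and the slow oscillation (0.5-1 Hz) partition cleanly at their shared
0.5 Hz edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from sleepmap.hypnogram import ARTIFACT, Hypnogram, Window


@dataclass(frozen=True)
class Band:
    """Frequency band [lo_hz, hi_hz), half-open on bin centers."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo_hz < self.hi_hz:
            raise ValueError("band requires 0 <= lo < hi")


DELTA = Band("delta", 0.5, 4.0)
SO = Band("so", 0.5, 1.0)
THETA = Band("theta", 6.0, 10.0)


@dataclass
class Recording:
    """EEG + EMG traces sampled on a common clock, aligned to an epoch grid."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float = 128.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D and equally long")

    @property
    def n_samples(self) -> int:
        return int(self.eeg.size)

    def samples_per_epoch(self, epoch_length: float = 8.0) -> int:
        n = self.fs * epoch_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch length must cover an integer number of samples")
        return int(round(n))

    def n_epochs(self, epoch_length: float = 8.0) -> int:
        return self.n_samples // self.samples_per_epoch(epoch_length)

    def check_alignment(self, hyp: Hypnogram) -> None:
        spe = self.samples_per_epoch(hyp.epoch_length)
        if self.n_samples != spe * hyp.n_epochs:
            raise ValueError(
                f"recording has {self.n_samples} samples but hypnogram implies "
                f"{spe * hyp.n_epochs}"
            )


@dataclass(frozen=True)
class SpectralConfig:
    """Welch configuration inside one epoch.

    ``segment_seconds``/``overlap`` control the averaged periodogram;
    ``total_lo_hz``/``total_hi_hz`` define the "total power" band used for
    percentage normalization (``total_hi_hz=None`` means Nyquist).
    """

    segment_seconds: float = 2.0
    overlap: float = 0.5
    window: str = "hann"
    total_lo_hz: float = 0.5
    total_hi_hz: float | None = None

    def total_band(self, fs: float) -> Band:
        hi = fs / 2.0 if self.total_hi_hz is None else self.total_hi_hz
        return Band("total", self.total_lo_hz, hi)


@dataclass
class PSDResult:
    """State-averaged spectrum as percentage of total power.

    ``power_percent`` sums to 100 over the total band (NaN-filled when no
    eligible epoch existed; then ``n_epochs_used`` is 0).
    """

    freqs: np.ndarray
    power_percent: np.ndarray
    state: str
    n_epochs_used: int


def band_mask(freqs: np.ndarray, band: Band) -> np.ndarray:
    return (freqs >= band.lo_hz - 1e-9) & (freqs < band.hi_hz - 1e-9)


def all_epoch_psd(
    rec: Recording,
    epoch_length: float = 8.0,
    config: SpectralConfig = SpectralConfig(),
    channel: str = "eeg",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of every epoch at once; returns (freqs, psd[n_epochs, n_bins]).

    Density scaling, constant detrend: summing psd * df over all bins
    reproduces the epoch's time-domain variance up to window effects.
    """
    x = rec.eeg if channel == "eeg" else rec.emg
    spe = rec.samples_per_epoch(epoch_length)
    n_ep = rec.n_epochs(epoch_length)
    seg = x[: n_ep * spe].reshape(n_ep, spe)
    nperseg = int(round(config.segment_seconds * rec.fs))
    noverlap = int(round(nperseg * config.overlap))
    freqs, psd = sps.welch(
        seg,
        fs=rec.fs,
        window=config.window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def epoch_psd(
    rec: Recording,
    epoch_index: int,
    epoch_length: float = 8.0,
    config: SpectralConfig = SpectralConfig(),
    channel: str = "eeg",
) -> tuple[np.ndarray, np.ndarray]:
    """Raw Welch spectrum of a single epoch."""
    if not 0 <= epoch_index < rec.n_epochs(epoch_length):
        raise IndexError(f"epoch {epoch_index} out of range")
    freqs, psd = all_epoch_psd(rec, epoch_length, config, channel)
    return freqs, psd[epoch_index]


def epoch_rms(rec: Recording, epoch_length: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch RMS of the EEG and EMG channels."""
    spe = rec.samples_per_epoch(epoch_length)
    n_ep = rec.n_epochs(epoch_length)
    out = []
    for x in (rec.eeg, rec.emg):
        seg = x[: n_ep * spe].reshape(n_ep, spe)
        out.append(np.sqrt(np.mean(seg**2, axis=1)))
    return out[0], out[1]


def flag_artifact_epochs(
    rec: Recording,
    hyp: Hypnogram,
    n_mads: float = 6.0,
) -> np.ndarray:
    """Boolean mask of artifact epochs (True = exclude).

    An epoch is flagged when its EEG or EMG RMS exceeds
    median + ``n_mads`` x MAD (normal-scaled), computed per vigilance state
    so that state-specific amplitude differences are not themselves flagged.
    X epochs are always flagged.
    """
    rec.check_alignment(hyp)
    eeg_rms, emg_rms = epoch_rms(rec, hyp.epoch_length)
    flags = hyp.stages == ARTIFACT
    for state in hyp.alphabet:
        sel = hyp.stages == state
        if not np.any(sel):
            continue
        for values in (eeg_rms, emg_rms):
            med = np.median(values[sel])
            mad = spstats.median_abs_deviation(values[sel], scale="normal")
            flags |= sel & (values > med + n_mads * mad)
    return flags


def _eligible(
    rec: Recording,
    hyp: Hypnogram,
    state: str,
    win: Window | None,
    mask: np.ndarray | None,
) -> np.ndarray:
    rec.check_alignment(hyp)
    sl = hyp.window_slice(win)
    sel = np.zeros(hyp.n_epochs, dtype=bool)
    sel[sl] = True
    sel &= hyp.stages == state
    if mask is not None:
        sel &= ~np.asarray(mask, dtype=bool)
    return sel


def state_psd_percent(
    rec: Recording,
    hyp: Hypnogram,
    state: str,
    win: Window | None = None,
    mask: np.ndarray | None = None,
    config: SpectralConfig = SpectralConfig(),
) -> PSDResult:
    """Mean spectrum over unmasked epochs of ``state``, normalized to 100%.

    Normalization restricts to the configured total band; with no eligible
    epoch the spectrum is NaN and ``n_epochs_used`` is 0.
    """
    sel = _eligible(rec, hyp, state, win, mask)
    freqs, psd = all_epoch_psd(rec, hyp.epoch_length, config)
    tot = band_mask(freqs, config.total_band(rec.fs))
    freqs_out = freqs[tot]
    if not np.any(sel):
        return PSDResult(freqs_out, np.full(freqs_out.size, np.nan), state, 0)
    mean_psd = psd[sel].mean(axis=0)[tot]
    total = mean_psd.sum()
    percent = 100.0 * mean_psd / total if total > 0 else np.zeros_like(mean_psd)
    return PSDResult(freqs_out, percent, state, int(sel.sum()))


def band_fraction_percent(result: PSDResult, band: Band) -> float:
    """Percentage of a PSDResult's total power inside ``band``."""
    if result.n_epochs_used == 0:
        return float("nan")
    return float(result.power_percent[band_mask(result.freqs, band)].sum())


def band_fraction(
    rec: Recording,
    hyp: Hypnogram,
    band: Band = DELTA,
    state: str = "N",
    resolution: str = "hour",
    win: Window | None = None,
    mask: np.ndarray | None = None,
    config: SpectralConfig = SpectralConfig(),
) -> pd.Series:
    """Per-bin percentage of ``band`` power over total power during ``state``.

    ``resolution`` is "hour" or "day"; bins with no eligible epoch get NaN
    (a sentinel, not zero).  The series is indexed by bin start hour
    (absolute hours).
    """
    if resolution not in ("hour", "day"):
        raise ValueError("resolution must be 'hour' or 'day'")
    step = 1.0 if resolution == "hour" else 24.0
    window = win if win is not None else hyp.full_window()
    base = _eligible(rec, hyp, state, window, mask)
    freqs, psd = all_epoch_psd(rec, hyp.epoch_length, config)
    tot = band_mask(freqs, config.total_band(rec.fs))
    in_band = band_mask(freqs[tot], band)
    hours = hyp.epoch_start_hours()
    starts = np.arange(window.start_hour, window.end_hour - 1e-9, step)
    values = {}
    for s in starts:
        end = min(s + step, window.end_hour)
        sel = base & (hours >= s - 1e-9) & (hours < end - 1e-9)
        if not np.any(sel):
            values[float(s)] = float("nan")
            continue
        mean_psd = psd[sel].mean(axis=0)[tot]
        total = mean_psd.sum()
        values[float(s)] = float("nan") if total <= 0 else float(
            100.0 * mean_psd[in_band].sum() / total
        )
    return pd.Series(values, name=f"{band.name}_percent")
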