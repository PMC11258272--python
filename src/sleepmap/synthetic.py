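"""Seeded generators with known ground truth for every pipeline stage.

The generators invert the package's estimators: hypnograms come from
first-order Markov chains whose transition parameters are exactly the
quantities P_WS / P_SW estimate; EEG/EMG recordings are built from
state-specific spectral recipes whose band fractions have closed forms;
cell maps plant a known double-positive fraction at a known radius on a
Poisson background whose chance-colocalization rate is
``1 - exp(-lambda * (4/3) pi r^3)``.

Every ``simulate_*`` function returns ``(object, manifest)`` where the
manifest is a JSON-serializable dict of the planted ground truth, so
recovery tests are self-describing.

Default parameters are the package's reference study conditions: a 12:12
light/dark cycle with consolidated dark-phase wake (low P_WS, high P_SW in
the dark; the reverse in the light), 8-s epochs, 128 Hz EEG/EMG, and mouse-
like state occupancies (~49% wake, ~45% NREM, ~6% REM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from sleepmap.hypnogram import (
    THREE_STATE,
    TWO_STATE,
    Hypnogram,
)
from sleepmap.spectral import Recording

EPOCHS_PER_DAY = int(24 * 3600 / 8)  # 10800 at 8-s epochs


# ---------------------------------------------------------------------------
# two-state sleep/wake chains


@dataclass(frozen=True)
class MarkovSleepParams:
    """Per-epoch transition probabilities of the two-state sleep/wake chain.

    ``p_ws_*`` is the probability that a wake epoch is followed by sleep,
    ``p_sw_*`` the reverse, split by light (ZT0-12) and dark (ZT12-24)
    phase.  Defaults model an adult mouse: sleep-dominated light phase and
    consolidated dark-phase wakefulness.
    """

    p_ws_light: float = 0.08
    p_sw_light: float = 0.04
    p_ws_dark: float = 0.05
    p_sw_dark: float = 0.08
    epoch_length: float = 8.0
    n_days: int = 1
    start_state: str = "W"

    def rates_at(self, zt_hour: float) -> tuple[float, float]:
        if zt_hour % 24.0 < 12.0:
            return self.p_ws_light, self.p_sw_light
        return self.p_ws_dark, self.p_sw_dark


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_hypnogram(
    params: MarkovSleepParams = MarkovSleepParams(),
    seed: int | np.random.Generator = 0,
    subject_id: str | None = None,
) -> tuple[Hypnogram, dict]:
    """Sample a two-state sleep/wake chain over ``params.n_days`` days.

    The state at epoch t+1 is drawn from the transition probabilities in
    force at epoch t's zeitgeber hour.  Reproducible under the seed.
    """
    rng = _as_rng(seed)
    epochs_per_hour = 3600.0 / params.epoch_length
    n = int(round(params.n_days * 24 * epochs_per_hour))
    u = rng.random(n)
    stages = np.empty(n, dtype="<U1")
    state = params.start_state
    for i in range(n):
        stages[i] = state
        p_ws, p_sw = params.rates_at(i / epochs_per_hour)
        if state == "W":
            state = "S" if u[i] < p_ws else "W"
        else:
            state = "W" if u[i] < p_sw else "S"
    hyp = Hypnogram(
        stages=stages,
        epoch_length=params.epoch_length,
        start_hour=0.0,
        subject_id=subject_id,
        alphabet=TWO_STATE,
    )
    manifest = {
        "generator": "markov_two_state",
        "p_ws_light": params.p_ws_light,
        "p_sw_light": params.p_sw_light,
        "p_ws_dark": params.p_ws_dark,
        "p_sw_dark": params.p_sw_dark,
        "n_days": params.n_days,
        "epoch_length": params.epoch_length,
    }
    return hyp, manifest


#: Default three-state transition matrix (rows/cols in W, N, R order).
#: Stationary occupancy ~ (0.49, 0.45, 0.06); direct wake-to-REM entries are
#: nearly absent, and REM bouts last ~1 min.
DEFAULT_THREE_STATE_MATRIX = np.array(
    [
        [0.948, 0.050, 0.002],
        [0.040, 0.942, 0.018],
        [0.120, 0.020, 0.860],
    ]
)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix (eigen method)."""
    w, v = np.linalg.eig(np.asarray(matrix, dtype=float).T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_three_state(
    matrix: np.ndarray = DEFAULT_THREE_STATE_MATRIX,
    n_epochs: int = EPOCHS_PER_DAY,
    seed: int | np.random.Generator = 0,
    epoch_length: float = 8.0,
    start_state: str = "W",
    subject_id: str | None = None,
) -> tuple[Hypnogram, dict]:
    """Sample a {W,N,R} chain from a row-stochastic 3x3 matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3) or not np.allclose(matrix.sum(axis=1), 1.0):
        raise ValueError("matrix must be 3x3 row-stochastic")
    rng = _as_rng(seed)
    labels = np.array(THREE_STATE)
    cum = np.cumsum(matrix, axis=1)
    u = rng.random(n_epochs)
    stages = np.empty(n_epochs, dtype="<U1")
    state = int(np.where(labels == start_state)[0][0])
    for i in range(n_epochs):
        stages[i] = labels[state]
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 2)
    hyp = Hypnogram(
        stages=stages,
        epoch_length=epoch_length,
        start_hour=0.0,
        subject_id=subject_id,
        alphabet=THREE_STATE,
    )
    manifest = {
        "generator": "markov_three_state",
        "matrix": matrix.tolist(),
        "stationary": stationary_distribution(matrix).tolist(),
        "n_epochs": n_epochs,
    }
    return hyp, manifest


# ---------------------------------------------------------------------------
# sleep deprivation


@dataclass(frozen=True)
class ReboundScenario:
    """Sleep-deprivation day and its homeostatic after-effect.

    During the deprivation window each scheduled transition into sleep (and
    each attempt to stay asleep) is blocked with probability
    ``deprivation_success``, which models enforced wakefulness at the epoch
    level and keeps the chain semantics intact.  After the window the
    transition rates are modulated with an exponentially decaying rebound::

        p_ws(t) = p_ws * (1 + (k_ws - 1) * exp(-t / tau))
        p_sw(t) = p_sw * (1 - (1 - k_sw) * exp(-t / tau))

    with t hours since deprivation end.  ``k_ws >= 1`` transiently promotes
    falling asleep and ``k_sw <= 1`` consolidates sleep, the rebound
    signature (increased P_WS, decreased P_SW).
    """

    deprivation_start: float = 0.0
    deprivation_end: float = 6.0
    deprivation_success: float = 1.0
    k_ws: float = 2.0
    k_sw: float = 0.5
    tau_hours: float = 6.0

    def __post_init__(self) -> None:
        if not (self.k_ws > 0 and self.k_sw > 0 and self.tau_hours > 0):
            raise ValueError("multipliers and decay constant must be positive")
        if not 0 <= self.deprivation_success <= 1:
            raise ValueError("deprivation_success must be in [0, 1]")


def simulate_sd_experiment(
    base: MarkovSleepParams = MarkovSleepParams(),
    scen: ReboundScenario = ReboundScenario(),
    n_basal_days: int = 3,
    seed: int | np.random.Generator = 0,
    subject_id: str | None = None,
):
    """Basal days plus one sleep-deprivation day from the same base chain.

    Returns ``(SDExperiment, manifest)``.  Basal days are independent
    samples of the base chain; the SD day applies the deprivation block and
    the rebound modulation of ``scen``.
    """
    from sleepmap.homeostasis import SDExperiment  # local import avoids a cycle

    rng = _as_rng(seed)
    streams = rng.spawn(n_basal_days + 1)
    basal = [
        simulate_hypnogram(replace(base, n_days=1), streams[i], subject_id)[0]
        for i in range(n_basal_days)
    ]

    epochs_per_hour = 3600.0 / base.epoch_length
    n = int(round(24 * epochs_per_hour))
    sd_rng = streams[-1]
    u = sd_rng.random(n)
    u_block = sd_rng.random(n)
    stages = np.empty(n, dtype="<U1")
    state = base.start_state
    for i in range(n):
        zt = i / epochs_per_hour
        in_dep = scen.deprivation_start <= zt < scen.deprivation_end
        if in_dep and state == "S" and u_block[i] < scen.deprivation_success:
            state = "W"  # enforced awakening of a sleeping epoch
        stages[i] = state
        p_ws, p_sw = base.rates_at(zt)
        if zt >= scen.deprivation_end:
            decay = math.exp(-(zt - scen.deprivation_end) / scen.tau_hours)
            p_ws = min(1.0, p_ws * (1.0 + (scen.k_ws - 1.0) * decay))
            p_sw = min(1.0, p_sw * (1.0 - (1.0 - scen.k_sw) * decay))
        if state == "W":
            state = "S" if u[i] < p_ws else "W"
        else:
            state = "W" if u[i] < p_sw else "S"
    sd_day = Hypnogram(
        stages=stages,
        epoch_length=base.epoch_length,
        start_hour=0.0,
        subject_id=subject_id,
        alphabet=TWO_STATE,
    )
    exp = SDExperiment(
        basal=basal,
        sd_day=sd_day,
        deprivation_start=scen.deprivation_start,
        deprivation_end=scen.deprivation_end,
    )
    manifest = {
        "generator": "sd_experiment",
        "base": {
            "p_ws_light": base.p_ws_light,
            "p_sw_light": base.p_sw_light,
            "p_ws_dark": base.p_ws_dark,
            "p_sw_dark": base.p_sw_dark,
        },
        "n_basal_days": n_basal_days,
        "deprivation": [scen.deprivation_start, scen.deprivation_end],
        "deprivation_success": scen.deprivation_success,
        "k_ws": scen.k_ws,
        "k_sw": scen.k_sw,
        "tau_hours": scen.tau_hours,
    }
    return exp, manifest


# ---------------------------------------------------------------------------
# EEG/EMG synthesis


@dataclass(frozen=True)
class StateRecipe:
    """Spectral recipe of one vigilance state (amplitudes in arbitrary uV).

    The EEG is a delta-band sinusoid plus a theta-band sinusoid plus a
    1/f^alpha broadband background; the EMG is white noise at
    ``emg_level`` RMS.
    """

    delta_amp: float
    theta_amp: float
    broadband_amp: float
    emg_level: float


@dataclass(frozen=True)
class EEGSynthesisParams:
    """Per-state recipes plus global synthesis settings.

    ``amplitude_jitter_sigma`` applies one multiplicative lognormal factor
    per epoch to all EEG components (and an independent one to the EMG), so
    within-epoch band *fractions* stay at their recipe values while
    absolute amplitudes vary between epochs, as in real recordings.
    """

    fs: float = 128.0
    delta_freq: float = 2.0
    theta_freq: float = 7.0
    background_exponent: float = 1.0
    background_lo_hz: float = 0.5
    amplitude_jitter_sigma: float = 0.35
    recipes: dict = field(
        default_factory=lambda: {
            "W": StateRecipe(delta_amp=5.0, theta_amp=10.0, broadband_amp=15.0, emg_level=20.0),
            "N": StateRecipe(delta_amp=55.0, theta_amp=5.0, broadband_amp=15.0, emg_level=5.0),
            "R": StateRecipe(delta_amp=3.0, theta_amp=35.0, broadband_amp=10.0, emg_level=1.5),
        }
    )


def _background_band_weight(
    params: EEGSynthesisParams, lo: float, hi: float
) -> float:
    """Fraction of the broadband background's power inside [lo, hi).

    The background has density proportional to f^-alpha on
    [background_lo_hz, fs/2]; the weight is the normalized integral.
    """
    alpha = params.background_exponent
    f1, f2 = params.background_lo_hz, params.fs / 2.0
    lo = max(lo, f1)
    hi = min(hi, f2)
    if hi <= lo:
        return 0.0

    def integral(a: float, b: float) -> float:
        if abs(alpha - 1.0) < 1e-12:
            return math.log(b / a)
        return (b ** (1 - alpha) - a ** (1 - alpha)) / (1 - alpha)

    return integral(lo, hi) / integral(f1, f2)


def analytic_band_fraction(
    params: EEGSynthesisParams,
    state: str,
    band_lo: float,
    band_hi: float,
    total_lo: float = 0.5,
    total_hi: float | None = None,
) -> float:
    """Closed-form expected fraction of EEG power in [band_lo, band_hi).

    Sinusoids contribute amp^2/2 at their single frequency; the broadband
    background contributes its amplitude squared spread as f^-alpha.  The
    per-epoch amplitude jitter cancels from the ratio.
    """
    total_hi = params.fs / 2.0 if total_hi is None else total_hi
    r = params.recipes[state]

    def tone(amp: float, freq: float, lo: float, hi: float) -> float:
        return amp**2 / 2.0 if lo <= freq < hi else 0.0

    def power(lo: float, hi: float) -> float:
        return (
            tone(r.delta_amp, params.delta_freq, lo, hi)
            + tone(r.theta_amp, params.theta_freq, lo, hi)
            + r.broadband_amp**2 * _background_band_weight(params, lo, hi)
        )

    total = power(total_lo, total_hi)
    return power(band_lo, band_hi) / total if total > 0 else float("nan")


def _shaped_noise(
    n: int, fs: float, alpha: float, lo_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance gaussian noise with density ~ f^-alpha above lo_hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros(freqs.size)
    sel = freqs >= lo_hz
    shape[sel] = freqs[sel] ** (-alpha / 2.0)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(spec, n=n)
    std = x.std()
    return x / std if std > 0 else x


def simulate_recording(
    hyp3: Hypnogram,
    params: EEGSynthesisParams = EEGSynthesisParams(),
    seed: int | np.random.Generator = 0,
) -> tuple[Recording, dict]:
    """Synthesize an EEG/EMG recording consistent with a staged hypnogram.

    Oscillatory components keep a globally continuous phase (so there is no
    spectral splatter at epoch boundaries); amplitudes switch with the
    state on the epoch grid.
    """
    rng = _as_rng(seed)
    spe = int(round(params.fs * hyp3.epoch_length))
    n = spe * hyp3.n_epochs
    t = np.arange(n) / params.fs

    states = hyp3.stages
    recipes = params.recipes

    def per_epoch(attr: str) -> np.ndarray:
        return np.array([getattr(recipes.get(s, StateRecipe(0, 0, 0, 0)), attr) for s in states])

    jit_eeg = np.exp(params.amplitude_jitter_sigma * rng.standard_normal(hyp3.n_epochs))
    jit_emg = np.exp(params.amplitude_jitter_sigma * rng.standard_normal(hyp3.n_epochs))

    a_delta = np.repeat(per_epoch("delta_amp") * jit_eeg, spe)
    a_theta = np.repeat(per_epoch("theta_amp") * jit_eeg, spe)
    a_bb = np.repeat(per_epoch("broadband_amp") * jit_eeg, spe)
    a_emg = np.repeat(per_epoch("emg_level") * jit_emg, spe)

    background = _shaped_noise(
        n, params.fs, params.background_exponent, params.background_lo_hz, rng
    )
    phase_d = rng.uniform(0, 2 * np.pi)
    phase_t = rng.uniform(0, 2 * np.pi)
    eeg = (
        a_delta * np.sin(2 * np.pi * params.delta_freq * t + phase_d)
        + a_theta * np.sin(2 * np.pi * params.theta_freq * t + phase_t)
        + a_bb * background
    )
    emg = a_emg * rng.standard_normal(n)
    rec = Recording(eeg=eeg, emg=emg, fs=params.fs)
    manifest = {
        "generator": "eeg_emg_recording",
        "fs": params.fs,
        "delta_freq": params.delta_freq,
        "theta_freq": params.theta_freq,
        "background_exponent": params.background_exponent,
        "amplitude_jitter_sigma": params.amplitude_jitter_sigma,
        "recipes": {
            s: vars(r) for s, r in recipes.items()
        },
        "analytic_delta_fraction": {
            s: analytic_band_fraction(params, s, 0.5, 4.0) for s in recipes
        },
        "analytic_theta_fraction": {
            s: analytic_band_fraction(params, s, 6.0, 10.0) for s in recipes
        },
    }
    return rec, manifest


# ---------------------------------------------------------------------------
# cell maps


@dataclass(frozen=True)
class RegionSpec:
    """One atlas region modelled as a cube of the stated volume."""

    acronym: str
    volume_mm3: float
    densities: dict  # channel -> cells per mm^3


@dataclass(frozen=True)
class CellMapScenario:
    """Paired point clouds with a planted double-positive fraction.

    Channel-B cells are a homogeneous Poisson process per region at the
    stated density.  A ``coloc_fraction`` of channel-A cells is planted
    uniformly inside a sphere of ``jitter_um`` around a random B cell; the
    remainder is uniform in the region.  ``density_multipliers`` scales a
    region's densities (used to plant group effects).
    """

    regions: Sequence[RegionSpec] = (
        RegionSpec("ISO", 8.0, {"cFos": 800.0, "PV": 600.0}),
    )
    coloc_channels: tuple[str, str] | None = ("cFos", "PV")
    coloc_fraction: float = 0.0
    jitter_um: float = 8.0
    density_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.jitter_um < 0:
            raise ValueError("jitter_um must be nonnegative")


def chance_coloc_rate(density_per_mm3: float, radius_um: float) -> float:
    """Chance double-positive rate under a Poisson reference channel.

    Probability that at least one reference cell of intensity
    ``density_per_mm3`` falls within ``radius_um`` of a random point:
    ``1 - exp(-lambda * (4/3) pi r^3)`` with lambda in cells/um^3.
    """
    lam = density_per_mm3 * 1e-9
    return 1.0 - math.exp(-lam * (4.0 / 3.0) * math.pi * radius_um**3)


def simulate_cell_map(
    scen: CellMapScenario = CellMapScenario(),
    seed: int | np.random.Generator = 0,
    brain_id: str = "brain0",
    group: str = "S",
):
    """One synthetic brain: ``(BrainCellTable, manifest)``.

    Regions are laid out as disjoint cubes along the x axis with a 100 um
    gap, so region labels are exact by construction.
    """
    from sleepmap.cellmap import BrainCellTable, Ontology

    rng = _as_rng(seed)
    rows = []
    offset = 0.0
    truth = {"regions": {}}
    ontology_rows = [{"acronym": "root", "parent": "", "volume_mm3": 0.0}]
    for region in scen.regions:
        side = (region.volume_mm3 * 1e9) ** (1.0 / 3.0)  # um
        mult = scen.density_multipliers.get(region.acronym, 1.0)
        coords: dict[str, np.ndarray] = {}
        for channel, density in region.densities.items():
            lam = density * mult * region.volume_mm3
            n_cells = int(rng.poisson(lam))
            xyz = rng.uniform(0.0, side, size=(n_cells, 3))
            xyz[:, 0] += offset
            coords[channel] = xyz
        # plant double positives
        if scen.coloc_channels is not None and scen.coloc_fraction > 0:
            a, b = scen.coloc_channels
            if a in coords and b in coords and len(coords[b]) > 0:
                n_a = len(coords[a])
                n_plant = int(round(scen.coloc_fraction * n_a))
                anchors = coords[b][rng.integers(0, len(coords[b]), n_plant)]
                # uniform in a sphere of radius jitter_um
                direction = rng.standard_normal((n_plant, 3))
                direction /= np.linalg.norm(direction, axis=1, keepdims=True)
                radii = scen.jitter_um * rng.random(n_plant) ** (1.0 / 3.0)
                planted = anchors + direction * radii[:, None]
                lo = np.array([offset, 0.0, 0.0])
                hi = lo + side
                planted = np.clip(planted, lo, hi)  # projection shrinks distances
                coords[a] = np.vstack([planted, coords[a][n_plant:]])
        for channel, xyz in coords.items():
            rows.append(
                pd.DataFrame(
                    {
                        "x_um": xyz[:, 0],
                        "y_um": xyz[:, 1],
                        "z_um": xyz[:, 2],
                        "intensity": 1.0,
                        "channel": channel,
                        "region": region.acronym,
                    }
                )
            )
        truth["regions"][region.acronym] = {
            "volume_mm3": region.volume_mm3,
            "densities": {
                ch: d * mult for ch, d in region.densities.items()
            },
        }
        ontology_rows.append(
            {
                "acronym": region.acronym,
                "parent": "root",
                "volume_mm3": region.volume_mm3,
            }
        )
        offset += side + 100.0

    columns = ["x_um", "y_um", "z_um", "intensity", "channel", "region"]
    if rows:
        cells = pd.concat(rows, ignore_index=True)[columns]
    else:
        cells = pd.DataFrame(columns=columns)
    ontology = Ontology(pd.DataFrame(ontology_rows))
    table = BrainCellTable(cells=cells, brain_id=brain_id, group=group, ontology=ontology)
    truth.update(
        {
            "generator": "cell_map",
            "coloc_channels": list(scen.coloc_channels) if scen.coloc_channels else None,
            "coloc_fraction": scen.coloc_fraction,
            "jitter_um": scen.jitter_um,
        }
    )
    return table, truth


def simulate_cell_map_group(
    scen: CellMapScenario = CellMapScenario(),
    n_brains: int = 6,
    seed: int | np.random.Generator = 0,
    group: str = "S",
):
    """Independent brains from one scenario: ``(list[BrainCellTable], manifest)``."""
    rng = _as_rng(seed)
    streams = rng.spawn(n_brains)
    tables = []
    manifest = None
    for i, sub in enumerate(streams):
        table, manifest = simulate_cell_map(
            scen, sub, brain_id=f"{group}{i}", group=group
        )
        tables.append(table)
    manifest = dict(manifest or {})
    manifest["n_brains"] = n_brains
    return tables, manifest
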