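"""Staged epoch sequences and their transition / duration / episode statistics.

A hypnogram is a gap-free sequence of fixed-length epochs (default 8 s), each
labelled with a vigilance state.  Two alphabets are supported: the two-state
respiration alphabet {W, S} (wake / sleep) and the three-state EEG/EMG
alphabet {W, N, R} (wake / NREM / REM).  The reserved label X marks
missing or artifact epochs; X epochs contribute to no duration, void both
adjacent transition pairs, and terminate episodes.

Transition probabilities follow the convention of per-window counts of
adjacent-epoch transitions::

    P_WS = N_WS / (N_WS + N_WW)        P_SW = N_SW / (N_SW + N_SS)

where N_XY counts adjacent epoch pairs going from state X to state Y.  When a
row of counts is empty (e.g. an all-sleep window leaves no wake pairs), the
away-from-state probability is treated as 1 by convention; a strict mode
returns NaN instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TWO_STATE: tuple[str, ...] = ("W", "S")
THREE_STATE: tuple[str, ...] = ("W", "N", "R")
ARTIFACT = "X"

_SECONDS_PER_HOUR = 3600.0


class WindowRangeError(ValueError):
    """Raised when a window is not fully covered by the hypnogram."""


@dataclass(frozen=True)
class Window:
    """Half-open interval [start_hour, end_hour) in absolute hours.

    Absolute hours count from ZT0 (lights-on) of day 0, so a window on day 1
    has hours offset by 24.  ``Window.zt`` builds a window from zeitgeber
    hours plus a day index.
    """

    start_hour: float
    end_hour: float

    def __post_init__(self) -> None:
        if not self.end_hour > self.start_hour:
            raise ValueError("window end must be strictly after start")

    @classmethod
    def zt(cls, start: float, end: float, day: int = 0) -> "Window":
        return cls(day * 24.0 + start, day * 24.0 + end)

    @property
    def duration_hours(self) -> float:
        return self.end_hour - self.start_hour


@dataclass
class Hypnogram:
    """Gap-free sequence of staged epochs on a zeitgeber timebase.

    Parameters
    ----------
    stages:
        Sequence of labels from one alphabet ({W,S} or {W,N,R}) plus X.
    epoch_length:
        Epoch duration in seconds (default 8).
    start_hour:
        Absolute hour of the first epoch (day * 24 + zeitgeber hour).
    timebase:
        "ZT" for light/dark entrained time, "CT" for circadian time in
        constant darkness.  Purely a bookkeeping flag; binning is identical.
    """

    stages: np.ndarray
    epoch_length: float = 8.0
    start_hour: float = 0.0
    timebase: str = "ZT"
    subject_id: str | None = None
    alphabet: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U1")
        if self.stages.size < 1:
            raise ValueError("hypnogram needs at least one epoch")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.timebase not in ("ZT", "CT"):
            raise ValueError("timebase must be 'ZT' or 'CT'")
        if not self.alphabet:
            present = set(self.stages.tolist()) - {ARTIFACT}
            if present <= set(TWO_STATE):
                self.alphabet = TWO_STATE
            elif present <= set(THREE_STATE):
                self.alphabet = THREE_STATE
            else:
                raise ValueError(f"labels {sorted(present)} fit no known alphabet")
        else:
            self.alphabet = tuple(self.alphabet)
            bad = set(self.stages.tolist()) - set(self.alphabet) - {ARTIFACT}
            if bad:
                raise ValueError(f"labels {sorted(bad)} outside declared alphabet")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def epochs_per_hour(self) -> float:
        return _SECONDS_PER_HOUR / self.epoch_length

    @property
    def duration_hours(self) -> float:
        return self.n_epochs / self.epochs_per_hour

    @property
    def end_hour(self) -> float:
        return self.start_hour + self.duration_hours

    def epoch_start_hours(self) -> np.ndarray:
        """Absolute hour at which each epoch starts."""
        return self.start_hour + np.arange(self.n_epochs) / self.epochs_per_hour

    def zt_hours(self) -> np.ndarray:
        """Zeitgeber hour in [0, 24) at which each epoch starts."""
        return np.mod(self.epoch_start_hours(), 24.0)

    def full_window(self) -> Window:
        return Window(self.start_hour, self.end_hour)

    def window_slice(self, win: Window | None) -> slice:
        """Epoch index slice covered by ``win`` (epochs whose start lies in it).

        Raises :class:`WindowRangeError` when the window extends beyond the
        hypnogram.
        """
        if win is None:
            return slice(0, self.n_epochs)
        eps = 1e-9
        if win.start_hour < self.start_hour - eps or win.end_hour > self.end_hour + eps:
            raise WindowRangeError(
                f"window [{win.start_hour}, {win.end_hour}) outside hypnogram "
                f"[{self.start_hour}, {self.end_hour})"
            )
        first = int(np.ceil((win.start_hour - self.start_hour) * self.epochs_per_hour - eps))
        last = int(np.ceil((win.end_hour - self.start_hour) * self.epochs_per_hour - eps))
        return slice(max(first, 0), min(last, self.n_epochs))

    def zt_window(self, start: float, end: float) -> Window:
        """Window at zeitgeber hours [start, end) on this hypnogram's own day."""
        day = int(np.floor(self.start_hour / 24.0 + 1e-9))
        return Window.zt(start, end, day=day)


@dataclass
class TransitionCounts:
    """Adjacent-epoch transition counts N_XY within a window.

    ``matrix[i, j]`` counts transitions from ``labels[i]`` to ``labels[j]``;
    pairs touching an X epoch are excluded.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    n_pairs: int

    def count(self, from_state: str, to_state: str) -> int:
        i = self.labels.index(from_state)
        j = self.labels.index(to_state)
        return int(self.matrix[i, j])


def count_transitions(hyp: Hypnogram, win: Window | None = None) -> TransitionCounts:
    """Count every ordered adjacent-epoch pair fully inside ``win``.

    Pairs straddling the window boundary are not counted, so counts are
    additive over a partition of the recording into windows.  Pairs with an X
    member are dropped; a window with no usable pair is a valid result with
    ``n_pairs = 0``.
    """
    sl = hyp.window_slice(win)
    seq = hyp.stages[sl]
    labels = hyp.alphabet
    k = len(labels)
    matrix = np.zeros((k, k), dtype=np.int64)
    if seq.size >= 2:
        index = {lab: i for i, lab in enumerate(labels)}
        a = seq[:-1]
        b = seq[1:]
        ok = (a != ARTIFACT) & (b != ARTIFACT)
        ia = np.array([index[s] for s in a[ok]], dtype=np.intp)
        ib = np.array([index[s] for s in b[ok]], dtype=np.intp)
        np.add.at(matrix, (ia, ib), 1)
    return TransitionCounts(labels=labels, matrix=matrix, n_pairs=int(matrix.sum()))


def transition_probability(
    counts: TransitionCounts,
    from_state: str,
    to_state: str | None = None,
    degenerate: str = "one",
):
    """Destination probabilities out of ``from_state``.

    For the two-state alphabet with ``to_state`` omitted this is exactly
    P_WS = N_WS/(N_WS+N_WW) (from W) or P_SW = N_SW/(N_SW+N_SS) (from S),
    returned as a float.  For three states with ``to_state`` omitted the full
    row of destination probabilities is returned as a dict (including the
    diagonal self-transition).

    When the row of counts is empty the away-from-state probability is
    treated as 1 (``degenerate="one"``, the default convention) or returned
    as NaN (``degenerate="nan"``, strict mode).
    """
    if from_state not in counts.labels:
        raise ValueError(f"unknown from_state {from_state!r}")
    if degenerate not in ("one", "nan"):
        raise ValueError("degenerate must be 'one' or 'nan'")
    i = counts.labels.index(from_state)
    row = counts.matrix[i].astype(float)
    total = row.sum()

    def _prob(j: int) -> float:
        if total == 0:
            if degenerate == "nan":
                return float("nan")
            return 1.0 if counts.labels[j] != from_state else 0.0
        return float(row[j] / total)

    if to_state is not None:
        if to_state not in counts.labels:
            raise ValueError(f"unknown to_state {to_state!r}")
        return _prob(counts.labels.index(to_state))
    if len(counts.labels) == 2:
        j = 1 - i
        return _prob(j)
    return {lab: _prob(j) for j, lab in enumerate(counts.labels)}


def p_ws(hyp: Hypnogram, win: Window | None = None, degenerate: str = "one") -> float:
    """Wake-to-sleep transition probability in a window (two-state alphabet)."""
    return transition_probability(count_transitions(hyp, win), "W", degenerate=degenerate)


def p_sw(hyp: Hypnogram, win: Window | None = None, degenerate: str = "one") -> float:
    """Sleep-to-wake transition probability in a window (two-state alphabet)."""
    hyp2 = hyp if hyp.alphabet == TWO_STATE else collapse_three_to_two(hyp)
    return transition_probability(count_transitions(hyp2, win), "S", degenerate=degenerate)


def state_duration(hyp: Hypnogram, win: Window | None, state: str) -> float:
    """Minutes spent in ``state`` within ``win`` (epoch count x epoch length)."""
    sl = hyp.window_slice(win)
    n = int(np.count_nonzero(hyp.stages[sl] == state))
    return n * hyp.epoch_length / 60.0


@dataclass
class EpisodeTable:
    """Maximal same-state runs (bouts) within a window.

    ``table`` columns: state, start_epoch, length_epochs, censored_left,
    censored_right.  A run is censored on a side when its true boundary is
    unobservable there — it touches the window edge or abuts an X epoch.
    """

    table: pd.DataFrame
    epoch_length: float

    def mean_duration_minutes(self, state: str) -> float:
        """Arithmetic mean bout duration in minutes; NaN when no bouts exist.

        Censored bouts are included (flagged in the table), which keeps the
        approximate duality mean-bout-length ~ 1/P(leave state).
        """
        lengths = self.table.loc[self.table["state"] == state, "length_epochs"]
        if lengths.empty:
            return float("nan")
        return float(lengths.mean() * self.epoch_length / 60.0)

    def mean_length_epochs(self, state: str) -> float:
        lengths = self.table.loc[self.table["state"] == state, "length_epochs"]
        if lengths.empty:
            return float("nan")
        return float(lengths.mean())


def episodes(hyp: Hypnogram, win: Window | None = None) -> EpisodeTable:
    """Maximal runs per state inside ``win``; X breaks runs and joins none."""
    sl = hyp.window_slice(win)
    seq = hyp.stages[sl]
    records = []
    n = seq.size
    i = 0
    while i < n:
        if seq[i] == ARTIFACT:
            i += 1
            continue
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        records.append(
            {
                "state": seq[i],
                "start_epoch": sl.start + i,
                "length_epochs": j - i + 1,
                "censored_left": i == 0 or seq[i - 1] == ARTIFACT,
                "censored_right": j == n - 1 or seq[j + 1] == ARTIFACT,
            }
        )
        i = j + 1
    table = pd.DataFrame.from_records(
        records,
        columns=["state", "start_epoch", "length_epochs", "censored_left", "censored_right"],
    )
    return EpisodeTable(table=table, epoch_length=hyp.epoch_length)


def collapse_three_to_two(hyp3: Hypnogram) -> Hypnogram:
    """Map a {W,N,R} hypnogram onto {W,S}: N and R both become S.

    Lets EEG-derived and respiration-derived records share the two-state
    transition statistics; metadata is preserved.
    """
    if hyp3.alphabet != THREE_STATE:
        raise ValueError("collapse_three_to_two requires the {W,N,R} alphabet")
    stages = hyp3.stages.copy()
    stages[np.isin(stages, ("N", "R"))] = "S"
    return replace(hyp3, stages=stages, alphabet=TWO_STATE)
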