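"""Auditory receptive fields and best frequency from a tone schedule.

A tuning session presents pure tones on a frequency x sound-level grid
(typically half-octave-spaced frequencies at a few sound pressure levels,
each combination repeated ~10 times, 1 s tones with a 3 s intertrial
interval).  A cell's receptive field is the mean dF/F0 during the tone
presentation, averaged across repeats, organized by (frequency, level);
its best frequency (BF) is the frequency of the maximal entry at any
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "StimulusSchedule",
    "ReceptiveField",
    "half_octave_ladder",
    "assign_trials",
    "update_receptive_field",
    "best_frequency",
    "build_tone_schedule",
]

DEFAULT_LEVELS_DB = (50.0, 60.0, 70.0)
DEFAULT_DURATION_S = 1.0
DEFAULT_INTERTRIAL_S = 3.0


def half_octave_ladder(f_start_hz: float, n_steps: int) -> np.ndarray:
    """Half-octave-spaced frequencies: f_k = f_start * 2**(k/2), k = 0..n-1."""
    if f_start_hz <= 0:
        raise ValueError("f_start_hz must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return f_start_hz * 2.0 ** (np.arange(n_steps) / 2.0)


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    duration_s: float
    frequency_hz: float
    level_db: float


@dataclass
class StimulusSchedule:
    events: list[StimulusEvent]
    frequencies_hz: list[float]
    levels_db: list[float]
    intertrial_s: float = DEFAULT_INTERTRIAL_S

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.onset_s)
        for a, b in zip(ev[:-1], ev[1:]):
            if a.onset_s + a.duration_s > b.onset_s:
                raise ValueError(
                    f"overlapping stimulus events at {a.onset_s} s and {b.onset_s} s"
                )
        grid_f = set(self.frequencies_hz)
        grid_l = set(self.levels_db)
        for e in ev:
            if e.frequency_hz not in grid_f or e.level_db not in grid_l:
                raise ValueError(
                    f"event ({e.frequency_hz} Hz, {e.level_db} dB) not on the grid"
                )
        self.events = ev

    @classmethod
    def from_csv(cls, path) -> "StimulusSchedule":
        df = pd.read_csv(path)
        events = [
            StimulusEvent(
                float(r.onset_s),
                float(getattr(r, "duration_s", DEFAULT_DURATION_S)),
                float(r.frequency_hz),
                float(r.level_db),
            )
            for r in df.itertuples(index=False)
        ]
        freqs = sorted({e.frequency_hz for e in events})
        levels = sorted({e.level_db for e in events})
        return cls(events=events, frequencies_hz=freqs, levels_db=levels)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "onset_s": e.onset_s,
                    "duration_s": e.duration_s,
                    "frequency_hz": e.frequency_hz,
                    "level_db": e.level_db,
                }
                for e in self.events
            ]
        ).to_csv(path, index=False)


def build_tone_schedule(
    frequencies_hz,
    levels_db=DEFAULT_LEVELS_DB,
    n_repeats: int = 10,
    duration_s: float = DEFAULT_DURATION_S,
    intertrial_s: float = DEFAULT_INTERTRIAL_S,
    start_s: float = 1.0,
    seed: int | None = None,
) -> StimulusSchedule:
    """Build a repeated, optionally shuffled, tone-grid schedule.

    Trials are spaced ``duration_s + intertrial_s`` apart (1 s tone, 3 s
    intertrial interval by default).
    """
    combos = [(f, l) for _ in range(n_repeats) for f in frequencies_hz for l in levels_db]
    if seed is not None:
        rng = np.random.default_rng(seed)
        combos = [combos[i] for i in rng.permutation(len(combos))]
    events = [
        StimulusEvent(start_s + i * (duration_s + intertrial_s), duration_s, f, l)
        for i, (f, l) in enumerate(combos)
    ]
    return StimulusSchedule(
        events=events,
        frequencies_hz=sorted(set(frequencies_hz)),
        levels_db=sorted(set(levels_db)),
        intertrial_s=intertrial_s,
    )


def assign_trials(
    schedule: StimulusSchedule, frame_rate: float, n_frames: int
) -> list[tuple[StimulusEvent, np.ndarray]]:
    """Frame window per event: frames with onset <= time < onset + duration.

    An event whose window is not yet fully acquired is omitted (pending).
    A tone shorter than one frame still claims the single covering frame.
    """
    out = []
    for e in schedule.events:
        first = int(np.ceil(e.onset_s * frame_rate - 1e-9))
        last = int(np.ceil((e.onset_s + e.duration_s) * frame_rate - 1e-9))  # exclusive
        if last <= first:
            last = first + 1
        if last > n_frames:
            continue  # pending: stream has not covered the event yet
        out.append((e, np.arange(first, last)))
    return out


@dataclass
class ReceptiveField:
    """Running mean dF/F0 response per (frequency, level), for one cell."""

    cell_id: int
    frequencies_hz: list[float]
    levels_db: list[float]
    mean_response: np.ndarray = field(default=None)  # (n_freq, n_level)
    n_trials: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        shape = (len(self.frequencies_hz), len(self.levels_db))
        if self.mean_response is None:
            self.mean_response = np.zeros(shape)
        if self.n_trials is None:
            self.n_trials = np.zeros(shape, dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.mean_response,
            index=pd.Index(self.frequencies_hz, name="frequency_hz"),
            columns=pd.Index(self.levels_db, name="level_db"),
        )
        return df.mask(self.n_trials == 0)


def update_receptive_field(
    rf: ReceptiveField,
    dff_trace: np.ndarray,
    event: StimulusEvent,
    frames: np.ndarray,
) -> ReceptiveField:
    """Fold one completed trial into the running mean for its grid cell.

    The trial response is the mean dF/F0 over the presentation window; a
    window with no finite sample is skipped.
    """
    vals = np.asarray(dff_trace, dtype=np.float64)[frames]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return rf
    resp = float(vals.mean())
    fi = rf.frequencies_hz.index(event.frequency_hz)
    li = rf.levels_db.index(event.level_db)
    n = rf.n_trials[fi, li]
    rf.mean_response[fi, li] = (rf.mean_response[fi, li] * n + resp) / (n + 1)
    rf.n_trials[fi, li] = n + 1
    return rf


def best_frequency(rf: ReceptiveField) -> float | None:
    """Frequency of the maximal receptive-field entry at any sound level.

    Ties break toward the lower frequency; returns None when no grid cell
    has a completed trial yet.
    """
    filled = rf.n_trials > 0
    if not filled.any():
        return None
    resp = np.where(filled, rf.mean_response, -np.inf)
    best_per_freq = resp.max(axis=1)
    fi = int(np.argmax(best_per_freq))  # argmax takes the first (lowest) on ties
    return float(rf.frequencies_hz[fi])
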