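"""Stimulus spike patterns: frozen Poisson templates with per-trial jitter.

A stimulus is a fixed ("frozen") pattern of homogeneous Poisson spike trains
-- by default 80 afferents at 6 Hz over a 500 ms decision period.  On each
presentation the template's spike times are independently jittered by a
zero-mean Gaussian, which is the only source of sensory variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusPattern",
    "generate_pattern",
    "jitter_pattern",
    "pattern_to_raster",
    "save_pattern_txt",
    "load_pattern_txt",
]

DEFAULT_N_TRAINS = 80
DEFAULT_DURATION = 500.0  # ms
DEFAULT_RATE = 6.0  # Hz
DEFAULT_JITTER_SD = 2.0  # ms


@dataclass
class StimulusPattern:
    """A frozen multi-afferent spike pattern.

    trains : list of 1-d float arrays of spike times (ms), each sorted and in
        [0, duration).
    duration : pattern duration T (ms).
    label : stimulus identity.
    """

    trains: list
    duration: float
    label: object = None

    def __post_init__(self) -> None:
        clean = []
        for times in self.trains:
            t = np.sort(np.asarray(times, dtype=float))
            if t.size and (t[0] < 0 or t[-1] >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            clean.append(t)
        self.trains = clean

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))


def generate_pattern(
    n_trains: int = DEFAULT_N_TRAINS,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
    rng: np.random.Generator | None = None,
    label=None,
) -> StimulusPattern:
    """Draw a frozen pattern of homogeneous Poisson trains.

    ``rate`` is in Hz and ``duration`` in ms; the expected total spike count
    is ``n_trains * rate * duration / 1000``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng() if rng is None else rng
    mean = rate * duration / 1000.0
    trains = []
    for _ in range(n_trains):
        n = rng.poisson(mean)
        trains.append(np.sort(rng.uniform(0.0, duration, size=n)))
    return StimulusPattern(trains=trains, duration=duration, label=label)


def _reflect(times: np.ndarray, duration: float) -> np.ndarray:
    """Reflect spike times into [0, duration) (preserves counts)."""
    period = 2.0 * duration
    t = np.mod(times, period)
    t = np.where(t >= duration, period - t, t)
    # the fold can land exactly on `duration`; nudge inside
    return np.clip(t, 0.0, np.nextafter(duration, 0.0))


def jitter_pattern(
    pattern: StimulusPattern,
    jitter_sd: float = DEFAULT_JITTER_SD,
    rng: np.random.Generator | None = None,
) -> StimulusPattern:
    """One presentation instance: Gaussian-jittered copy of the template.

    Each spike time is displaced independently by N(0, jitter_sd^2) and
    reflected back into [0, T); spike counts are preserved and trains are
    re-sorted.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if jitter_sd == 0:
        return StimulusPattern([t.copy() for t in pattern.trains], pattern.duration, pattern.label)
    rng = np.random.default_rng() if rng is None else rng
    trains = []
    for t in pattern.trains:
        jittered = t + rng.normal(0.0, jitter_sd, size=t.size)
        trains.append(np.sort(_reflect(jittered, pattern.duration)))
    return StimulusPattern(trains=trains, duration=pattern.duration, label=pattern.label)


def pattern_to_raster(pattern: StimulusPattern, dt: float) -> np.ndarray:
    """Bin a pattern into a boolean (n_trains, n_steps) raster."""
    n_steps = int(round(pattern.duration / dt))
    raster = np.zeros((pattern.n_trains, n_steps), dtype=np.uint8)
    for i, times in enumerate(pattern.trains):
        bins = np.floor(times / dt).astype(int)
        raster[i, np.clip(bins, 0, n_steps - 1)] = 1
    return raster


def save_pattern_txt(pattern: StimulusPattern, path) -> None:
    """Write a pattern as two-column text: afferent index, spike time (ms)."""
    with open(path, "w") as fh:
        fh.write(f"# n_trains={pattern.n_trains} duration_ms={pattern.duration}\n")
        for i, times in enumerate(pattern.trains):
            for t in times:
                fh.write(f"{i}\t{t:.6f}\n")


def load_pattern_txt(path) -> StimulusPattern:
    """Read a pattern written by :func:`save_pattern_txt`."""
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        n_trains = int(meta["n_trains"])
        duration = float(meta["duration_ms"])
        trains = [[] for _ in range(n_trains)]
        for line in fh:
            idx, t = line.split()
            trains[int(idx)].append(float(t))
    return StimulusPattern([np.asarray(t) for t in trains], duration)
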