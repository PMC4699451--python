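"""Spike-sequence data model and plain-text readers/writers.

A *spike sequence* is an ordered set of event times on an observation
interval (0, T]; it is the common currency between the Langevin simulator,
the synthetic-train generator and the renewal statistics.  Interspike times
and windowed spike counts are the two equivalent representations of the
underlying point process that the analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeSequence",
    "CountSeries",
    "interspike_times",
    "spike_counts",
    "read_spikes",
    "write_spikes",
]


@dataclass(frozen=True)
class SpikeSequence:
    """Ordered event times (seconds) on the observation interval (0, T].

    Parameters
    ----------
    times : array-like
        Strictly increasing event times, each in (0, T].
    duration : float
        Length T of the observation interval, seconds.
    label : str, optional
        Free-text provenance tag.
    """

    times: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if times[0] <= 0:
                raise ValueError("event times must be strictly positive")
            if np.any(np.diff(times) <= 0):
                bad = int(np.argmax(np.diff(times) <= 0)) + 1
                raise ValueError(
                    f"event times must be strictly increasing (violation at index {bad})"
                )
            if times[-1] > self.duration + 1e-12:
                raise ValueError("event times must lie within (0, duration]")

    @property
    def n(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class CountSeries:
    """Spike counts in consecutive fixed-width windows.

    ``counts[j]`` is the number of events in ``[j*window, (j+1)*window)``;
    a trailing partial window is discarded so that all counts are
    identically distributed under a stationary process.  ``tail`` records
    the number of events falling in the discarded remainder.
    """

    window: float
    counts: np.ndarray
    tail: int = 0

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if self.window <= 0:
            raise ValueError("window must be positive")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")


def interspike_times(seq: SpikeSequence) -> np.ndarray:
    """Consecutive event-time differences δt_i = t_{i+1} - t_i (seconds).

    Requires at least two events; returns an array of length N - 1 whose
    entries are all positive and telescope to ``times[-1] - times[0]``.
    """
    if seq.n < 2:
        raise ValueError("insufficient events: need at least 2 spikes")
    return np.diff(seq.times)


def spike_counts(seq: SpikeSequence, window: float) -> CountSeries:
    """Count events in M = floor(T / window) full windows of width ``window``.

    Events at a window edge belong to the right window (half-open binning);
    events in the trailing partial window are reported in ``tail`` and not
    counted.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window >= seq.duration:
        raise ValueError("window exceeds duration")
    m = int(np.floor(seq.duration / window))
    edges = np.arange(m + 1) * window
    counts, _ = np.histogram(seq.times, bins=edges)
    tail = seq.n - int(counts.sum())
    return CountSeries(window=window, counts=counts, tail=tail)


def read_spikes(path, duration: float | None = None) -> SpikeSequence:
    """Read a spike sequence from a single-column text/CSV file.

    One numeric time (seconds) per line; ``#``-prefixed comment lines are
    allowed and a ``# duration=<T>`` header, when present, supplies the
    observation-interval length.  Without a duration the last event time is
    used.  Non-monotone or non-positive times raise a validation error
    naming the offending line.
    """
    times = []
    file_duration = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("duration"):
                    file_duration = float(body.split("=", 1)[1])
                continue
            if lineno == 1 and not _is_number(line.split(",")[0]):
                continue  # single-column CSV header
            value = float(line.split(",")[0])
            if value <= 0:
                raise ValueError(f"{path}: non-positive event time on line {lineno}")
            if times and value <= times[-1]:
                raise ValueError(f"{path}: non-monotone event time on line {lineno}")
            times.append(value)
    if duration is None:
        duration = file_duration
    if duration is None:
        if not times:
            raise ValueError(f"{path}: empty spike file and no duration supplied")
        duration = times[-1]
    return SpikeSequence(times=np.asarray(times), duration=duration)


def write_spikes(seq: SpikeSequence, path) -> None:
    """Write one event time per line with a ``# duration=<T>`` header.

    The ``%.17g`` format makes read_spikes(write_spikes(x)) reproduce the
    times bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"# duration={float(seq.duration)!r}\n")
        for t in seq.times:
            fh.write(f"{float(t)!r}\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
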