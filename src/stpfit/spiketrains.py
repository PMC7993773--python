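"""Presynaptic spike trains and stimulation protocols.

A spike train is the independent variable of every short-term plasticity
model in this package: an ordered sequence of stimulation times in seconds.
Protocols are described either directly (regular trains, bursts with a test
pulse, seeded Poisson trains) or as a :class:`ProtocolSpec`, an ordered list
of ``(pulse_count, frequency)`` segments such as "5 pulses at 100 Hz followed
by one pulse at 20 Hz".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "ProtocolSpec",
    "regular_train",
    "compound_train",
    "poisson_train",
    "burst_plus_test",
    "load_spike_times",
    "save_spike_times",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of presynaptic spike times.

    Parameters
    ----------
    times : array-like of float
        Strictly increasing spike times in seconds, all non-negative.
    duration : float, optional
        Observation window in seconds; defaults to the last spike time.
    label : str, optional
        Free-text protocol label.
    """

    times: np.ndarray
    duration: float = None  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        if times.size and np.any(times < 0):
            raise ValueError("spike times must be non-negative")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", times)
        last = float(times[-1]) if times.size else 0.0
        duration = last if self.duration is None else float(self.duration)
        if duration < last:
            raise ValueError("duration must cover the last spike time")
        object.__setattr__(self, "duration", duration)

    def __len__(self) -> int:
        return self.times.size

    @property
    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)


@dataclass(frozen=True)
class ProtocolSpec:
    """A stimulation protocol as ordered (pulse_count, frequency) segments."""

    segments: tuple[tuple[int, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        segments = tuple((int(n), float(f)) for n, f in self.segments)
        if not segments:
            raise ValueError("protocol needs at least one segment")
        for n, f in segments:
            if n < 1:
                raise ValueError("pulse counts must be >= 1")
            if f <= 0:
                raise ValueError("frequencies must be positive")
        object.__setattr__(self, "segments", segments)

    @classmethod
    def from_config(cls, segments: Iterable[Sequence[float]], label: str = "") -> "ProtocolSpec":
        return cls(tuple((int(n), float(f)) for n, f in segments), label=label)


def regular_train(frequency: float, n_pulses: int, t0: float = 0.0, label: str = "") -> SpikeTrain:
    """Regular stimulation: ``n_pulses`` spikes at ``frequency`` Hz from ``t0``."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    times = t0 + np.arange(n_pulses) / frequency
    label = label or f"{n_pulses}x{frequency:g}Hz"
    return SpikeTrain(times, label=label)


def compound_train(spec: ProtocolSpec, t0: float = 0.0) -> SpikeTrain:
    """Concatenate the segments of a protocol into one spike train.

    The first spike of segment ``k+1`` follows the last spike of segment ``k``
    by the inter-spike interval of segment ``k+1`` — the "recovery pulse"
    convention of short-term plasticity protocols.
    """
    times: list[float] = []
    t = t0
    for i, (n, f) in enumerate(spec.segments):
        start = t if i == 0 else t + 1.0 / f
        seg = start + np.arange(n) / f
        times.extend(seg.tolist())
        t = seg[-1]
    label = spec.label or "+".join(f"{n}x{f:g}Hz" for n, f in spec.segments)
    return SpikeTrain(np.asarray(times), label=label)


def poisson_train(rate: float, n_spikes: int, seed, t0: float = 0.0) -> SpikeTrain:
    """Homogeneous Poisson train with ``n_spikes`` spikes at mean rate ``rate`` Hz.

    Inter-spike intervals are i.i.d. exponential with mean ``1/rate``;
    reproducible for a fixed ``seed`` (any ``numpy.random`` seed or Generator).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    rng = np.random.default_rng(seed)
    isis = rng.exponential(scale=1.0 / rate, size=n_spikes)
    times = t0 + np.cumsum(isis)
    return SpikeTrain(times, label=f"poisson{rate:g}Hz_n{n_spikes}")


def burst_plus_test(burst_n: int, burst_freq: float, delay: float) -> SpikeTrain:
    """A burst of ``burst_n`` spikes at ``burst_freq`` Hz plus one test spike.

    The test spike is placed ``delay`` seconds after the last burst spike;
    used to probe slow (post-burst) facilitation.
    """
    if delay <= 0:
        raise ValueError("delay must be positive")
    burst = regular_train(burst_freq, burst_n)
    times = np.append(burst.times, burst.times[-1] + delay)
    return SpikeTrain(times, label=f"burst{burst_n}x{burst_freq:g}Hz+test{delay:g}s")


def load_spike_times(path) -> SpikeTrain:
    """Read a plain-text spike-time file (one time in seconds per line).

    Lines beginning with ``#`` are treated as comments.
    """
    times = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        times.append(float(line))
    return SpikeTrain(np.asarray(times), label=Path(path).stem)


def save_spike_times(train: SpikeTrain, path) -> None:
    lines = [f"# spike times (s), label={train.label}"]
    lines += [f"{t:.9f}" for t in train.times]
    Path(path).write_text("\n".join(lines) + "\n")
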