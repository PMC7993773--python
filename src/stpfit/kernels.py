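"""Causal basis functions, kernels, and spike-train filtering.

An efficacy (or variance) kernel is a linear combination of causal basis
functions plus a constant baseline.  Convolved with a presynaptic spike train
it yields the "potential" that a sigmoidal readout turns into per-spike
synaptic efficacies.  Filtering is event-driven and exact: for exponential
bases the convolution at spike times is computed by a per-spike recursive
decay, never on a time grid.  Dense-grid evaluation exists for visualization
and for oracle tests only.

Causality is strict: a basis contributes only at times strictly after a
spike (``h(0)`` counts as 0), so the first pulse of any train always sees the
baseline alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .spiketrains import SpikeTrain

__all__ = [
    "ExponentialBasis",
    "GaussianBasis",
    "Kernel",
    "FilteredTrain",
    "evaluate_basis",
    "filter_at_spikes",
    "design_matrix",
    "convolve_on_grid",
]


@dataclass(frozen=True)
class ExponentialBasis:
    """Integral-normalized exponential decay ``h(t) = exp(-t/tau)/tau`` for t > 0."""

    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        mask = t > 0
        out[mask] = np.exp(-t[mask] / self.tau) / self.tau
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"type": "exp", "tau": self.tau}


@dataclass(frozen=True)
class GaussianBasis:
    """Normalized Gaussian density centred at ``mu`` (s), truncated to t > 0.

    The truncated mass at t <= 0 is not renormalized; for the delayed-
    facilitation kernels used here (``mu`` a few SDs above zero) it is
    negligible.
    """

    mu: float
    sd: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sd <= 0:
            raise ValueError("mu and sd must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        mask = t > 0
        z = (t[mask] - self.mu) / self.sd
        out[mask] = np.exp(-0.5 * z * z) / (self.sd * np.sqrt(2.0 * np.pi))
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"type": "gauss", "mu": self.mu, "sd": self.sd}


Basis = Union[ExponentialBasis, GaussianBasis]


def evaluate_basis(basis: Basis, t) -> float:
    """Value of a causal basis density at time ``t`` (0 for t <= 0)."""
    return basis(t)


def basis_from_dict(d: dict) -> Basis:
    kind = d["type"]
    if kind == "exp":
        return ExponentialBasis(float(d["tau"]))
    if kind == "gauss":
        return GaussianBasis(float(d["mu"]), float(d["sd"]))
    raise ValueError(f"unknown basis type {kind!r}")


@dataclass(frozen=True)
class Kernel:
    """A causal kernel: linear combination of bases plus a baseline coefficient.

    ``k(t) = sum_l amplitudes[l] * bases[l](t)`` for t > 0 and exactly 0 for
    t <= 0.  The baseline is the coefficient of the constant basis and is kept
    outside the kernel proper.
    """

    bases: tuple[Basis, ...]
    amplitudes: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        bases = tuple(self.bases)
        amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        if len(bases) != amplitudes.size:
            raise ValueError("one amplitude per basis required")
        object.__setattr__(self, "bases", bases)
        object.__setattr__(self, "amplitudes", amplitudes)

    @classmethod
    def exponential(cls, taus: Sequence[float], amplitudes: Sequence[float],
                    baseline: float = 0.0) -> "Kernel":
        return cls(tuple(ExponentialBasis(t) for t in taus), np.asarray(amplitudes),
                   baseline)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, b in zip(self.amplitudes, self.bases):
            out += a * b(t)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "bases": [b.to_dict() for b in self.bases],
            "amplitudes": [float(a) for a in self.amplitudes],
            "baseline": float(self.baseline),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Kernel":
        return cls(tuple(basis_from_dict(b) for b in d["bases"]),
                   np.asarray(d["amplitudes"], dtype=float),
                   float(d.get("baseline", 0.0)))


@dataclass(frozen=True)
class FilteredTrain:
    """A spike train filtered through a set of bases, sampled just before spikes.

    ``design_matrix`` has one constant row (all ones, the baseline regressor)
    followed by one row per basis; column ``j`` holds the strictly causal
    convolution values at spike ``j`` and therefore depends only on spikes
    ``i < j``.
    """

    spike_times: np.ndarray
    design_matrix: np.ndarray


def design_matrix(bases: Sequence[Basis], train: SpikeTrain) -> np.ndarray:
    """Strictly causal basis filtering at spike times.

    Returns an array of shape ``(1 + len(bases), n_spikes)``: row 0 is the
    constant regressor, row ``1 + l`` entry ``j`` is
    ``sum_{i<j} h_l(t_j - t_i)``.  Exponential rows are computed by the exact
    recursion ``z_{j+1} = (z_j + 1/tau) * exp(-dt_j/tau)``.
    """
    t = train.times
    n = t.size
    X = np.empty((1 + len(bases), n))
    X[0] = 1.0
    dts = np.diff(t)
    for l, basis in enumerate(bases, start=1):
        if isinstance(basis, ExponentialBasis):
            decay = np.exp(-dts / basis.tau)
            z = np.empty(n)
            z[0] = 0.0
            for j in range(1, n):
                z[j] = (z[j - 1] + 1.0 / basis.tau) * decay[j - 1]
            X[l] = z
        else:
            # generic causal basis: explicit pairwise evaluation
            diff = t[:, None] - t[None, :]  # (j, i) -> t_j - t_i
            vals = basis(np.where(diff > 0, diff, -1.0))
            vals[diff <= 0] = 0.0
            X[l] = vals.sum(axis=1)
    return X


def filter_at_spikes(bases: Sequence[Basis], train: SpikeTrain) -> FilteredTrain:
    """Event-driven filtering of a spike train; see :func:`design_matrix`."""
    return FilteredTrain(train.times.copy(), design_matrix(bases, train))


def convolve_on_grid(kernel: Kernel, train: SpikeTrain, dt: float,
                     t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense trace of ``(k * S)(t) + baseline`` on a uniform grid.

    Intended for plots and for convergence tests against the event-driven
    evaluation; converges to :func:`filter_at_spikes` values at spike times as
    ``dt -> 0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    trace = np.full(grid.size, float(kernel.baseline))
    for ts in train.times:
        if ts > t_end:
            break
        trace += kernel(grid - ts)
    return grid, trace
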