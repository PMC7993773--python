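"""The spike-response model of short-term plasticity (SRP).

The deterministic model assigns to the j-th presynaptic spike a synaptic
efficacy

    mu_j = f(k_mu * S(t_j) + b_mu) / f(b_mu),

a sigmoidal readout ``f`` (the logistic function) of the strictly causal
convolution of the efficacy kernel ``k_mu`` with the spike train, normalized
so that the first pulse of any train has efficacy exactly 1.  The stochastic
extension draws per-trial amplitudes from a gamma distribution whose mean is
``mu_j`` and whose standard deviation follows its own linear-nonlinear
cascade,

    sigma_j = sigma_0 * f(k_sigma * S(t_j) + b_sigma),

which lets trial-to-trial variability rise or fall along a train
independently of the mean (heteroskedasticity).  Two reduced variance modes
recover generalized-linear-model structure: ``proportional``
(sigma = sigma_0 * mu, constant CV) and ``constant`` (sigma = sigma_0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .kernels import Kernel, design_matrix
from .spiketrains import SpikeTrain

__all__ = [
    "SRPParameters",
    "EfficacyTrain",
    "PSCShape",
    "mean_efficacies",
    "sd_efficacies",
    "sample_efficacies",
    "efficacy_train",
    "psc_trace",
    "n_free_parameters",
]

VARIANCE_MODES = ("kernel", "proportional", "constant")


@dataclass(frozen=True)
class SRPParameters:
    """Parameters of one SRP synapse.

    ``mu_kernel`` holds the efficacy-kernel amplitudes and baseline b_mu;
    ``sigma_kernel`` the variance-kernel amplitudes and baseline b_sigma
    (ignored in the ``proportional`` and ``constant`` variance modes);
    ``sigma_scale`` is the positive scale factor sigma_0.
    """

    mu_kernel: Kernel
    sigma_kernel: Optional[Kernel] = None
    sigma_scale: float = 1.0
    variance_mode: str = "kernel"

    def __post_init__(self) -> None:
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be positive")
        if self.variance_mode not in VARIANCE_MODES:
            raise ValueError(f"variance_mode must be one of {VARIANCE_MODES}")
        if self.variance_mode == "kernel" and self.sigma_kernel is None:
            raise ValueError("variance_mode='kernel' requires a sigma_kernel")

    def to_dict(self) -> dict:
        d = {
            "mu_kernel": self.mu_kernel.to_dict(),
            "sigma_scale": float(self.sigma_scale),
            "variance_mode": self.variance_mode,
        }
        if self.sigma_kernel is not None:
            d["sigma_kernel"] = self.sigma_kernel.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SRPParameters":
        return cls(
            mu_kernel=Kernel.from_dict(d["mu_kernel"]),
            sigma_kernel=(Kernel.from_dict(d["sigma_kernel"])
                          if "sigma_kernel" in d else None),
            sigma_scale=float(d.get("sigma_scale", 1.0)),
            variance_mode=d.get("variance_mode", "kernel"),
        )


@dataclass(frozen=True)
class EfficacyTrain:
    """Per-spike efficacy statistics (and optional samples) for one train."""

    spike_times: np.ndarray
    efficacies: np.ndarray          # mu_j, first-pulse-normalized
    sds: np.ndarray                 # sigma_j
    samples: Optional[np.ndarray] = None  # (n_trials, n_spikes) gamma draws


def _potential(kernel: Kernel, train: SpikeTrain) -> np.ndarray:
    """Potential efficacy k*S + b sampled just before each spike."""
    X = design_matrix(kernel.bases, train)
    theta = np.concatenate(([kernel.baseline], kernel.amplitudes))
    return theta @ X


def mean_efficacies(params: SRPParameters, train: SpikeTrain) -> np.ndarray:
    """Deterministic per-spike efficacies ``f(k_mu*S + b_mu) / f(b_mu)``.

    Strict causality of the kernel makes the convolution vanish at the first
    spike, so ``mu_1 == 1`` exactly for any parameters.
    """
    v = _potential(params.mu_kernel, train)
    return expit(v) / expit(params.mu_kernel.baseline)


def sd_efficacies(params: SRPParameters, train: SpikeTrain,
                  mus: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-spike amplitude standard deviations sigma_j.

    ``kernel`` mode: sigma_0 * f(k_sigma*S + b_sigma); ``proportional``:
    sigma_0 * mu_j; ``constant``: sigma_0 for every spike.
    """
    n = len(train)
    if params.variance_mode == "constant":
        return np.full(n, params.sigma_scale)
    if params.variance_mode == "proportional":
        if mus is None:
            mus = mean_efficacies(params, train)
        return params.sigma_scale * mus
    v = _potential(params.sigma_kernel, train)
    return params.sigma_scale * expit(v)


def sample_efficacies(params: SRPParameters, train: SpikeTrain,
                      n_trials: int, seed=None) -> np.ndarray:
    """Draw gamma-distributed amplitudes, shape mu^2/sigma^2, scale sigma^2/mu.

    Returns an ``(n_trials, n_spikes)`` matrix of independent draws — the
    model assumes successive responses are statistically independent given
    the spike train.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    mus = mean_efficacies(params, train)
    sds = sd_efficacies(params, train, mus)
    shape = (mus / sds) ** 2
    scale = sds**2 / mus
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, scale, size=(n_trials, mus.size))


def efficacy_train(params: SRPParameters, train: SpikeTrain,
                   n_trials: int = 0, seed=None) -> EfficacyTrain:
    """Bundle mean, SD, and optionally sampled efficacies for a train."""
    mus = mean_efficacies(params, train)
    sds = sd_efficacies(params, train, mus)
    samples = sample_efficacies(params, train, n_trials, seed) if n_trials else None
    return EfficacyTrain(train.times.copy(), mus, sds, samples)


@dataclass(frozen=True)
class PSCShape:
    """Stereotypical post-synaptic current time course, peak-normalized.

    A difference of exponentials ``e^{-t/decay} - e^{-t/rise}`` scaled so the
    single maximum equals 1; zero for t <= 0.  Presentation-layer only — all
    fitting operates on amplitude tables, never on synthesized traces.
    """

    rise: float = 0.002
    decay: float = 0.020

    def __post_init__(self) -> None:
        if self.rise <= 0 or self.decay <= self.rise:
            raise ValueError("need 0 < rise < decay")

    @property
    def t_peak(self) -> float:
        r, d = self.rise, self.decay
        return r * d / (d - r) * np.log(d / r)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        mask = t > 0
        tm = t[mask]
        raw = np.exp(-tm / self.decay) - np.exp(-tm / self.rise)
        peak = np.exp(-self.t_peak / self.decay) - np.exp(-self.t_peak / self.rise)
        out[mask] = raw / peak
        return out if out.ndim else float(out)


def psc_trace(eff: EfficacyTrain, shape: PSCShape, dt: float,
              t_end: float, trial: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a current trace: superposition of PSC shapes scaled per spike.

    Uses sampled amplitudes (``eff.samples[trial]``) when present, otherwise
    the mean efficacies.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    weights = eff.samples[trial] if eff.samples is not None else eff.efficacies
    grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    trace = np.zeros(grid.size)
    for w, ts in zip(weights, eff.spike_times):
        if ts > t_end:
            break
        trace += w * shape(grid - ts)
    return grid, trace


def n_free_parameters(params: SRPParameters, standardized: bool = True) -> int:
    """Number of free parameters of the SRP likelihood.

    Counts the efficacy-kernel amplitudes and baseline, plus (in ``kernel``
    variance mode) the variance-kernel amplitudes and baseline.  In
    ``standardized`` mode the scale sigma_0 is fixed by amplitude
    standardization and not counted; otherwise it adds one.  With three bases
    per kernel and both baselines this gives 8 standardized parameters.
    """
    n = 1 + len(params.mu_kernel.amplitudes)
    if params.variance_mode == "kernel":
        n += 1 + len(params.sigma_kernel.amplitudes)
    if not standardized:
        n += 1
    return n
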