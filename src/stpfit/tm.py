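"""Classic and extended Tsodyks-Markram (TM) synapse models.

The TM model tracks two state variables per synapse: R, the recovered
fraction of releasable resources, and u, the utilized efficacy (release
probability).  The normalized amplitude of the n-th response is
``mu_n = R_n * u_n`` evaluated with the pre-jump (left-limit) values; each
spike then depletes R by the released fraction and bumps u by the
facilitation jump, and both relax exponentially between spikes
(timescales tau_R and tau_u, resting values 1 and U).

The classic facilitation jump is ``f*(1 - u)``; it shrinks as u grows, so
classic-TM facilitation is always sublinear.  The extended variant uses
``u*f*(1 - u)``, which grows with u below 0.5 and saturates above — for a
small baseline U this produces the supralinear facilitation seen at
physiological calcium.

Between spikes the dynamics are linear, so the exact integrated maps

    R_{n+1} = 1 - [1 - R_n (1 - u_n)] exp(-dt/tau_R)
    u_{n+1} = U + [u_n + jump(u_n) - U] exp(-dt/tau_u)

are used for all efficacy computations; the explicit ODE integrator exists
as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiketrains import SpikeTrain

__all__ = [
    "TMParameters",
    "tm_efficacies",
    "tm_ode_integrate",
    "classic_jump",
    "extended_jump",
]


@dataclass(frozen=True)
class TMParameters:
    """Four-parameter TM model: baseline U, jump constant f, timescales tau_u, tau_R."""

    U: float
    f: float
    tau_u: float
    tau_R: float
    variant: str = "classic"

    def __post_init__(self) -> None:
        if not 0 < self.U < 1:
            raise ValueError("U must lie in (0, 1)")
        if not 0 < self.f < 1:
            raise ValueError("f must lie in (0, 1)")
        if self.tau_u <= 0 or self.tau_R <= 0:
            raise ValueError("timescales must be positive")
        if self.variant not in ("classic", "extended"):
            raise ValueError("variant must be 'classic' or 'extended'")

    def to_dict(self) -> dict:
        return {"U": self.U, "f": self.f, "tau_u": self.tau_u,
                "tau_R": self.tau_R, "variant": self.variant}

    @classmethod
    def from_dict(cls, d: dict) -> "TMParameters":
        return cls(float(d["U"]), float(d["f"]), float(d["tau_u"]),
                   float(d["tau_R"]), d.get("variant", "classic"))


def classic_jump(u, f):
    """Classic spike-triggered facilitation increment ``f*(1-u)``."""
    return f * (1.0 - u)


def extended_jump(u, f):
    """Extended increment ``u*f*(1-u)``; maximal at u = 0.5, zero at 0 and 1."""
    return u * f * (1.0 - u)


def tm_efficacies(params: TMParameters, train: SpikeTrain) -> np.ndarray:
    """Per-spike efficacies mu_n = R_n * u_n via the exact integrated maps.

    Initial state is the resting one (R_0 = 1, u_0 = U: no previous
    activation), release uses pre-jump u, and depletion at each spike uses
    the same pre-jump value.
    """
    return _tm_maps(params, train.isis)[0]


def _tm_maps(params: TMParameters, isis: np.ndarray):
    """Vectorized-over-parameters TM recursion; scalars broadcast fine."""
    U, f = params.U, params.f
    jump = extended_jump if params.variant == "extended" else classic_jump
    n = isis.size + 1
    R = np.ones_like(np.asarray(U, dtype=float))
    u = np.asarray(U, dtype=float).copy()
    mus = []
    Rs, us = [], []
    for k in range(n):
        mus.append(R * u)
        Rs.append(R)
        us.append(u)
        if k == n - 1:
            break
        dt = isis[k]
        u_plus = u + jump(u, f)
        R = 1.0 - (1.0 - R * (1.0 - u)) * np.exp(-dt / params.tau_R)
        u = U + (u_plus - U) * np.exp(-dt / params.tau_u)
    return np.array(mus), np.array(Rs), np.array(us)


def tm_state_sequences(params: TMParameters, train: SpikeTrain):
    """Pre-jump (R_n, u_n) at every spike, alongside mu_n = R_n u_n."""
    mus, Rs, us = _tm_maps(params, train.isis)
    return mus, Rs, us


def tm_efficacies_grid(U, f, tau_u, tau_R, variant: str,
                       train: SpikeTrain) -> np.ndarray:
    """TM efficacies for arrays of parameters sharing one spike train.

    All four parameter arrays must broadcast to a common shape; the returned
    array has shape ``(n_spikes,) + broadcast_shape``.  Used by the MSE grid
    search, where one pass per spike covers the whole parameter grid.
    """
    U, f, tau_u, tau_R = np.broadcast_arrays(
        np.asarray(U, float), np.asarray(f, float),
        np.asarray(tau_u, float), np.asarray(tau_R, float))
    jump = extended_jump if variant == "extended" else classic_jump
    R = np.ones_like(U)
    u = U.copy()
    out = np.empty((len(train),) + U.shape)
    isis = train.isis
    for k in range(len(train)):
        out[k] = R * u
        if k == len(train) - 1:
            break
        dt = isis[k]
        u_plus = u + jump(u, f)
        R = 1.0 - (1.0 - R * (1.0 - u)) * np.exp(-dt / tau_R)
        u = U + (u_plus - U) * np.exp(-dt / tau_u)
    return out


def tm_ode_integrate(params: TMParameters, train: SpikeTrain, dt: float,
                     t_end: float | None = None):
    """Explicit fixed-step integration of the TM ODEs with spike jumps.

    Jumps are applied at spike times to the left-limit values: release and
    depletion use u(t-), R(t-).  Serves as the independent oracle for
    :func:`tm_efficacies`.  Returns ``(t, R, u, mus)`` with ``mus`` the
    pre-jump R*u at each spike.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end is None:
        t_end = train.duration
    n_steps = int(round(t_end / dt)) + 1
    t = np.arange(n_steps) * dt
    R = np.empty(n_steps)
    u = np.empty(n_steps)
    R[0], u[0] = 1.0, params.U
    jump = extended_jump if params.variant == "extended" else classic_jump
    spike_idx = np.round(train.times / dt).astype(int)
    spike_set = {}
    for i, si in enumerate(spike_idx):
        spike_set[si] = i
    mus = np.zeros(len(train))
    for k in range(n_steps):
        if k in spike_set:
            mus[spike_set[k]] = R[k] * u[k]
        if k == n_steps - 1:
            break
        dR = (1.0 - R[k]) / params.tau_R
        du = (params.U - u[k]) / params.tau_u
        R_next = R[k] + dt * dR
        u_next = u[k] + dt * du
        if k in spike_set:
            # spike-triggered jumps on the left limits
            R_next -= R[k] * u[k]
            u_next += jump(u[k], params.f)
        R[k + 1], u[k + 1] = R_next, u_next
    return t, R, u, mus
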