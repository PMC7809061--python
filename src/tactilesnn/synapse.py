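"""Difference-of-exponentials AMPA/GABA synaptic currents.

Each presynaptic spike at t* feeds a two-stage linear cascade after an axonal
latency tau_L = 1 ms:

    tau_r dx/dt = -x + W delta(t - t* - tau_L)
    tau_d dI/dt = -I + x

Base time constants (AMPA: tau_d 0.4 ms, tau_r 2 ms; GABA: tau_d 0.25 ms,
tau_r 5 ms) are multiplied by a common scale factor of 7.  A spike increments
x by W; the resulting current is the double exponential

    I(t) = W * (exp(-t/tau_r) - exp(-t/tau_d)) * tau_r / (tau_r - tau_d)

for t measured from spike arrival.  Because the cascade is linear, the
response to a spike train is the superposition of single-spike responses,
and population drive can be computed by filtering the (delayed) spike-count
matrix once per postsynaptic layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afferents import _euler_lowpass  # same forward-Euler one-pole


@dataclass(frozen=True)
class SynapseKinetics:
    """AMPA/GABA cascade time constants (ms), before the global scale."""

    tau_d_ampa: float = 0.4
    tau_r_ampa: float = 2.0
    tau_d_gaba: float = 0.25
    tau_r_gaba: float = 5.0
    scale: float = 7.0
    tau_latency_ms: float = 1.0

    @property
    def ampa(self) -> tuple[float, float]:
        """Effective (tau_r, tau_d) for excitatory synapses."""
        return self.tau_r_ampa * self.scale, self.tau_d_ampa * self.scale

    @property
    def gaba(self) -> tuple[float, float]:
        return self.tau_r_gaba * self.scale, self.tau_d_gaba * self.scale


DEFAULT_KINETICS = SynapseKinetics()


def _delay_steps(kinetics: SynapseKinetics, dt_ms: float) -> int:
    return int(round(kinetics.tau_latency_ms / dt_ms))


def synaptic_current(
    spikes: np.ndarray,
    W: np.ndarray,
    tau_r: float,
    tau_d: float,
    dt_ms: float,
    latency_ms: float = 1.0,
) -> np.ndarray:
    """Postsynaptic current matrix from a presynaptic spike matrix.

    Parameters
    ----------
    spikes:
        Boolean/int matrix (n_steps, n_pre).
    W:
        Weight matrix (n_post, n_pre); a spike of unit j increments x of
        every postsynaptic target i by W[i, j] at t* + latency.

    Returns
    -------
    I : (n_steps, n_post) current traces (non-negative for W >= 0).
    """
    if W.ndim != 2 or W.shape[1] != spikes.shape[1]:
        raise ValueError("weight matrix shape does not match presynaptic count")
    if np.any(W < 0):
        # inhibition is modelled with positive magnitudes and an explicit sign
        raise ValueError("synaptic weights must be non-negative")
    lag = int(round(latency_ms / dt_ms))
    drive = np.asarray(spikes, dtype=float) @ W.T  # (n_steps, n_post)
    # the Euler one-pole already consumes its input with a one-step delay,
    # so shifting by lag-1 delivers each spike to x exactly at t* + latency
    shift = max(lag - 1, 0)
    if shift:
        drive = np.vstack([np.zeros((shift, drive.shape[1])), drive[:-shift]])
    # spike increments x by W: impulse of area W*tau_r into the one-pole
    x = _euler_lowpass(drive * (tau_r / dt_ms), tau_r, dt_ms)
    return _euler_lowpass(x, tau_d, dt_ms)


def double_exponential(t_ms: np.ndarray, W: float, tau_r: float, tau_d: float) -> np.ndarray:
    """Closed-form single-spike PSC (t measured from spike arrival)."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    if tau_r == tau_d:
        out[pos] = W * t[pos] / tau_r * np.exp(-t[pos] / tau_r)
    else:
        out[pos] = (
            W * tau_r / (tau_r - tau_d) * (np.exp(-t[pos] / tau_r) - np.exp(-t[pos] / tau_d))
        )
    return out


class ExpCascade:
    """Stateful per-step synapse bank for recurrent (in-loop) connections."""

    def __init__(self, n_post: int, tau_r: float, tau_d: float, dt_ms: float):
        self.x = np.zeros(n_post)
        self.I = np.zeros(n_post)
        self.ar = dt_ms / tau_r
        self.ad = dt_ms / tau_d

    def step(self, increment: np.ndarray | float = 0.0) -> np.ndarray:
        """Advance one Euler step; ``increment`` adds directly to x."""
        self.I = self.I + self.ad * (self.x - self.I)
        self.x = self.x * (1.0 - self.ar)
        self.x += increment
        return self.I
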