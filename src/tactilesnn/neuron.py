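"""Izhikevich spiking neurons, integrated with forward Euler (dt = 0.1 ms).

dv/dt = 0.04 v^2 + 5 v + 140 - u + I
du/dt = a (b v - u)
on v >= 30 mV:  v <- c, u <- u + d

Afferents use the regular-spiking parameter set (a=0.02, b=0.2, c=-65, d=8);
central neurons (cuneate and cortical) use a=0.1, b=0.2, c=-65, d=6.
Intrinsic noise is a per-step Gaussian increment to v, scaled by sqrt(dt),
producing sparse background activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

V_PEAK = 30.0  # mV, spike cut-off
V_FLOOR = -120.0  # numerical clamp; well below any trajectory of interest


@dataclass(frozen=True)
class IzhikevichParams:
    a: float
    b: float
    c: float
    d: float

    def rest_state(self) -> tuple[float, float]:
        """Stable fixed point of the noise-free, input-free dynamics.

        Solves 0.04 v^2 + 5 v + 140 - b v = 0 (with u = b v) and returns the
        lower (stable) root; for b = 0.2 this is (v, u) = (-70, -14).
        """
        disc = (5.0 - self.b) ** 2 - 4 * 0.04 * 140.0
        v = (-(5.0 - self.b) - np.sqrt(disc)) / (2 * 0.04)
        return float(v), float(self.b * v)


#: regular-spiking primary afferents
AFFERENT_PARAMS = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: cuneate and cortical neurons
CENTRAL_PARAMS = IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=6.0)


def simulate_izhikevich(
    I: np.ndarray,
    params: IzhikevichParams,
    dt_ms: float = 0.1,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    record_v: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Drive a population of Izhikevich neurons with a current matrix.

    Parameters
    ----------
    I:
        Input current, shape (n_steps, n_units) or (n_steps,) for one unit.
    noise_sd:
        SD of the intrinsic membrane-potential fluctuation (mV per sqrt(ms)).

    Returns
    -------
    spikes:
        Boolean matrix (n_steps, n_units); True where the unit fired.
    v_trace:
        Membrane potential (with resets applied, never above 30 mV) if
        ``record_v``, else None.
    """
    I = np.asarray(I, dtype=float)
    if I.ndim == 1:
        I = I[:, None]
    n_steps, n_units = I.shape
    v0, u0 = params.rest_state()
    v = np.full(n_units, v0)
    u = np.full(n_units, u0)
    spikes = np.zeros((n_steps, n_units), dtype=bool)
    v_trace = np.empty((n_steps, n_units)) if record_v else None

    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        noise = rng.normal(0.0, noise_sd * np.sqrt(dt_ms), size=(n_steps, n_units))
    else:
        noise = None

    a, b, c, d = params.a, params.b, params.c, params.d
    overflowed = False
    for t in range(n_steps):
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I[t]
        v = v + dt_ms * dv
        u = u + dt_ms * a * (b * v - u)
        if noise is not None:
            v += noise[t]
        if not overflowed and not np.all(np.isfinite(v)):
            overflowed = True
            log.warning("membrane potential overflow; clamping and resetting")
            v = np.nan_to_num(v, nan=c, posinf=V_PEAK, neginf=V_FLOOR)
        np.clip(v, V_FLOOR, None, out=v)
        fired = v >= V_PEAK
        if fired.any():
            spikes[t] = fired
            v[fired] = c
            u[fired] += d
        if record_v:
            v_trace[t] = v
    return spikes, v_trace


def spike_times(spikes: np.ndarray, dt_ms: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """(unit_ids, times_ms) event lists from a boolean spike matrix."""
    t_idx, units = np.nonzero(spikes)
    return units, t_idx * dt_ms
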