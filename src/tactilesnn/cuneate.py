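"""Cuneate nucleus: projection neurons (PN) with feedforward lateral inhibition.

The CN layer has 100 PNs on a 10x10 lattice aligned with the SA-I centres and
100 interneurons (IN), one per PN.  Primary afferents make AMPA synapses onto
both subpopulations: PN p is driven by its co-located SA-I afferent and the
nearest RA-I afferents; IN p is driven by the *neighbouring* afferents (the
k = 4 nearest same-type neighbours of PN p's drivers), and makes a GABA
synapse onto PN p — so a skin contact that excites a PN also recruits, via
its neighbours, inhibition onto that same PN (feedforward lateral
inhibition, or surround suppression).  ``inhibition_level`` scales the
IN->PN weight multiplicatively (1 = full inhibition, 0.25 = the partial-
inhibition condition).  Each subpopulation additionally has weak random
recurrent connections (probability 0.2, a few percent of the feedforward
weight so the excitatory loop stays far from its runaway regime; PN->PN
excitatory, IN->IN inhibitory).

All neurons are Izhikevich units with the central parameter set
(a=0.1, b=0.2, c=-65, d=6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .afferents import AfferentPopulation
from .neuron import CENTRAL_PARAMS, IzhikevichParams, simulate_izhikevich
from .synapse import ExpCascade, SynapseKinetics, synaptic_current

N_PN = 100
N_IN = 100
#: afferent -> CN excitatory weight (calibration constant)
W_EX = 16.0
#: IN -> PN inhibitory weight at full inhibition
W_INH = 4.0
#: recurrent weights as a fraction of the feedforward weight
RECURRENT_FRACTION = 0.02
RECURRENT_P = 0.2
#: lateral-inhibition neighbourhood (nearest same-type neighbours per driver)
K_NEIGHBORS = 4
#: RA-I drivers per PN (nearest centres)
K_RA_DRIVERS = 2


@dataclass
class CNNetwork:
    """Connectivity and parameters of the cuneate layer."""

    sa_pop: AfferentPopulation
    ra_pop: AfferentPopulation
    exc_pn: np.ndarray  # (N_PN, n_afferents)
    exc_in: np.ndarray  # (N_IN, n_afferents)
    inh_in_to_pn: np.ndarray  # (N_PN, N_IN), full-inhibition weights
    rec_pn: np.ndarray  # (N_PN, N_PN) excitatory
    rec_in: np.ndarray  # (N_IN, N_IN) inhibitory (positive magnitudes)
    inhibition_level: float = 1.0
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    params: IzhikevichParams = field(default_factory=lambda: CENTRAL_PARAMS)

    @property
    def n_afferents(self) -> int:
        return self.exc_pn.shape[1]

    def afferent_skin_footprint(self) -> np.ndarray:
        """(N_PN, n_sites) map from skin to PN channels.

        Each PN's footprint is the innervation-weight sum of its driving
        afferents; used by the cortical layer to place receptive fields in
        skin space.
        """
        W_aff = sparse.vstack(
            [self.sa_pop.weight_matrix(), self.ra_pop.weight_matrix()]
        ).toarray()
        drivers = (self.exc_pn > 0).astype(float)
        return drivers @ W_aff


def _nearest(centers: np.ndarray, point: np.ndarray, k: int, exclude: set[int]) -> np.ndarray:
    d = np.hypot(centers[:, 0] - point[0], centers[:, 1] - point[1])
    order = np.argsort(d, kind="stable")
    picked = [i for i in order if i not in exclude]
    return np.array(picked[:k], dtype=int)


def build_cn(
    sa_pop: AfferentPopulation,
    ra_pop: AfferentPopulation,
    inhibition_level: float = 1.0,
    w_ex: float = W_EX,
    w_inh: float = W_INH,
    k_neighbors: int = K_NEIGHBORS,
    rng: np.random.Generator | int | None = None,
) -> CNNetwork:
    """Wire the cuneate layer from the two afferent populations."""
    if len(sa_pop) != N_PN:
        raise ValueError("PN lattice expects a 100-unit SA-I population")
    rng = np.random.default_rng(rng)
    n_aff = len(sa_pop) + len(ra_pop)
    sa_centers = sa_pop.centers_rowcol
    ra_centers = ra_pop.centers_rowcol
    n_sa = len(sa_pop)

    exc_pn = np.zeros((N_PN, n_aff))
    exc_in = np.zeros((N_IN, n_aff))
    for p in range(N_PN):
        # drivers: co-located SA afferent + nearest RA centres
        exc_pn[p, p] = w_ex
        ra_drivers = _nearest(ra_centers, sa_centers[p], K_RA_DRIVERS, set())
        exc_pn[p, n_sa + ra_drivers] = w_ex
        # neighbours of the drivers excite the IN paired with this PN
        sa_nb = _nearest(sa_centers, sa_centers[p], k_neighbors, {p})
        exc_in[p, sa_nb] = w_ex
        ra_nb = _nearest(ra_centers, sa_centers[p], k_neighbors + K_RA_DRIVERS,
                         set(ra_drivers.tolist()))[:k_neighbors]
        exc_in[p, n_sa + ra_nb] = w_ex

    inh = np.zeros((N_PN, N_IN))
    np.fill_diagonal(inh, w_inh)

    w_rec = RECURRENT_FRACTION
    rec_pn = (rng.random((N_PN, N_PN)) < RECURRENT_P) * (w_rec * w_ex)
    np.fill_diagonal(rec_pn, 0.0)
    rec_in = (rng.random((N_IN, N_IN)) < RECURRENT_P) * (w_rec * w_inh)
    np.fill_diagonal(rec_in, 0.0)

    return CNNetwork(sa_pop, ra_pop, exc_pn, exc_in, inh, rec_pn, rec_in,
                     inhibition_level=inhibition_level)


def simulate_with_recurrence(
    I_ff: np.ndarray,
    W_rec: np.ndarray,
    tau_r: float,
    tau_d: float,
    sign: float,
    params: IzhikevichParams,
    dt_ms: float,
    latency_ms: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Izhikevich population with one recurrent synapse type, stepped in-loop.

    ``sign`` is +1 for excitatory recurrence, -1 for inhibitory.  Recurrent
    spikes are delivered after ``latency_ms``.  Returns the boolean spike
    matrix.  Feedforward currents must already be summed into ``I_ff``.
    """
    n_steps, n = I_ff.shape
    lag = max(int(round(latency_ms / dt_ms)), 1)
    syn = ExpCascade(n, tau_r, tau_d, dt_ms)
    pending = np.zeros((lag, n))  # ring buffer of delayed x-increments
    v0, u0 = params.rest_state()
    v = np.full(n, v0)
    u = np.full(n, u0)
    spikes = np.zeros((n_steps, n), dtype=bool)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        noise = rng.normal(0.0, noise_sd * np.sqrt(dt_ms), size=(n_steps, n))
    else:
        noise = None
    a, b, c, d = params.a, params.b, params.c, params.d
    for t in range(n_steps):
        I_rec = syn.step(pending[t % lag])
        pending[t % lag] = 0.0
        I = I_ff[t] + sign * I_rec
        v = v + dt_ms * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u = u + dt_ms * a * (b * v - u)
        if noise is not None:
            v += noise[t]
        np.clip(v, -120.0, None, out=v)
        fired = v >= 30.0
        if fired.any():
            spikes[t] = fired
            v[fired] = c
            u[fired] += d
            pending[t % lag] += W_rec @ fired  # read back at step t + lag
    return spikes


@dataclass
class CNResponse:
    pn_spikes: np.ndarray
    in_spikes: np.ndarray
    dt_ms: float
    pn_current: np.ndarray | None = None  # net synaptic input per PN


def cn_response(
    network: CNNetwork,
    afferent_spikes: np.ndarray,
    dt_ms: float = 0.1,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    keep_currents: bool = False,
) -> CNResponse:
    """Drive the cuneate layer with a (n_steps, 296) afferent spike matrix.

    The afferent channel order is SA-I units first (0..99) then RA-I
    (100..295), matching :func:`build_cn`.
    """
    if afferent_spikes.shape[1] != network.n_afferents:
        raise ValueError("afferent spike matrix does not match network size")
    rng = np.random.default_rng(rng)
    kin = network.kinetics
    tau_rA, tau_dA = kin.ampa
    tau_rG, tau_dG = kin.gaba
    lat = kin.tau_latency_ms

    # interneurons: afferent AMPA + IN->IN recurrent GABA
    I_in_ff = synaptic_current(afferent_spikes, network.exc_in, tau_rA, tau_dA, dt_ms, lat)
    in_spikes = simulate_with_recurrence(
        I_in_ff, network.rec_in, tau_rG, tau_dG, -1.0, network.params, dt_ms, lat,
        noise_sd, rng,
    )
    # projection neurons: afferent AMPA - IN GABA + PN->PN recurrent AMPA
    I_pn_ex = synaptic_current(afferent_spikes, network.exc_pn, tau_rA, tau_dA, dt_ms, lat)
    W_gaba = network.inh_in_to_pn * network.inhibition_level
    I_pn_inh = synaptic_current(in_spikes, W_gaba, tau_rG, tau_dG, dt_ms, lat)
    I_pn = I_pn_ex - I_pn_inh
    pn_spikes = simulate_with_recurrence(
        I_pn, network.rec_pn, tau_rA, tau_dA, +1.0, network.params, dt_ms, lat,
        noise_sd, rng,
    )
    return CNResponse(pn_spikes, in_spikes, dt_ms,
                      pn_current=I_pn if keep_currents else None)
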