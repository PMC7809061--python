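"""Somatosensory area 3b: orientation-tuned pyramidal neurons.

The cortical layer has 16 orientation groups (5..80 deg in 5-deg steps) of
10 pyramidal neurons (PY) each, with a matched cortical interneuron (c-IN)
per PY: 160 + 160 = 320 spiking neurons.  Each PY has a receptive field with
two adjacent skin sub-regions, both elongated along its preferred
orientation: an excitatory band, and an inhibitory band displaced
perpendicular to the orientation.  The excitatory band drives the PY
directly through the PN channels of the cuneate layer; the inhibitory band
drives the paired c-IN, which makes a GABA synapse onto the PY.  The ten PYs
of a group place their receptive fields at different skin locations (a
lattice of y-offsets over the central region), so the group responds to its
orientation wherever the edge lands.

Weights are constructed once from oriented edge templates mapped through
each PN's skin footprint, L1-normalized per neuron, and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cuneate import CNNetwork
from .neuron import CENTRAL_PARAMS, IzhikevichParams, simulate_izhikevich
from .stimulus import edge_template
from .synapse import SynapseKinetics, synaptic_current
from .grid import MM_TO_NORM

#: the 16 orientation classes, degrees
ORIENTATIONS_DEG = tuple(range(5, 85, 5))
#: receptive-field y-offsets per group, mm (lattice over the central region)
DEFAULT_LOCATIONS_MM = tuple(np.round(np.linspace(-1.8, 1.8, 10), 4))
#: cortical receptive-field band width, normalized units
RF_WIDTH = 0.1
#: perpendicular displacement of the inhibitory band (one template width, 2w)
INH_OFFSET = 2 * RF_WIDTH
#: total excitatory weight per PY over PN channels (calibration constant)
G_EX = 80.0
#: total PN->c-IN weight per c-IN
G_CIN = 80.0
#: c-IN -> PY inhibitory weight
W_CIN = 30.0


class ConfigurationError(ValueError):
    pass


@dataclass
class CorticalNetwork:
    orientations_deg: tuple[float, ...]
    locations_mm: tuple[float, ...]
    w_exc: np.ndarray  # (n_py, n_pn) PN -> PY
    w_cin: np.ndarray  # (n_py, n_pn) PN -> paired c-IN
    w_inh: np.ndarray  # (n_py, n_py) c-IN -> PY (diagonal)
    group_of: np.ndarray  # (n_py,) orientation-group index
    rf_exc_skin: np.ndarray  # (n_py, n_sites) skin-space excitatory template
    rf_inh_skin: np.ndarray  # (n_py, n_sites) skin-space inhibitory template
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    params: IzhikevichParams = field(default_factory=lambda: CENTRAL_PARAMS)

    @property
    def n_py(self) -> int:
        return self.w_exc.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.orientations_deg)

    def group_label(self, g: int) -> float:
        return self.orientations_deg[g]


def build_cortical_rfs(
    cn: CNNetwork,
    orientations_deg: tuple[float, ...] = ORIENTATIONS_DEG,
    locations_mm: tuple[float, ...] = DEFAULT_LOCATIONS_MM,
    rf_width: float = RF_WIDTH,
    g_ex: float = G_EX,
    g_cin: float = G_CIN,
    w_cin: float = W_CIN,
    rng: np.random.Generator | int | None = None,
) -> CorticalNetwork:
    """Construct the 160-PY / 160-c-IN network over the PN channels.

    Construction is deterministic given the cuneate network; ``rng`` is
    accepted for API symmetry with the other builders.
    """
    if len(orientations_deg) < 16:
        raise ConfigurationError("the cortical layer expects at least 16 orientations")
    grid = cn.sa_pop.grid
    footprint = cn.afferent_skin_footprint()  # (n_pn, n_sites)
    n_py = len(orientations_deg) * len(locations_mm)
    n_pn = footprint.shape[0]

    w_exc = np.zeros((n_py, n_pn))
    w_cin_mat = np.zeros((n_py, n_pn))
    rf_exc = np.zeros((n_py, grid.n_sites))
    rf_inh = np.zeros((n_py, grid.n_sites))
    group_of = np.zeros(n_py, dtype=int)

    i = 0
    for g, theta in enumerate(orientations_deg):
        th = np.deg2rad(theta)
        perp = (np.sin(th), np.cos(th))
        for loc in locations_mm:
            cy = loc * MM_TO_NORM
            exc = edge_template(theta, rf_width, grid, center=(0.0, cy)).values
            inh = edge_template(
                theta, rf_width, grid,
                center=(INH_OFFSET * perp[0], cy + INH_OFFSET * perp[1]),
            ).values
            we = footprint @ exc
            wi = footprint @ inh
            w_exc[i] = g_ex * we / we.sum()
            w_cin_mat[i] = g_cin * wi / wi.sum()
            rf_exc[i] = exc
            rf_inh[i] = inh
            group_of[i] = g
            i += 1

    w_inh = np.zeros((n_py, n_py))
    np.fill_diagonal(w_inh, w_cin)
    return CorticalNetwork(
        tuple(orientations_deg), tuple(locations_mm), w_exc, w_cin_mat, w_inh,
        group_of, rf_exc, rf_inh,
    )


@dataclass
class CorticalResponse:
    py_spikes: np.ndarray  # bool (n_steps, n_py)
    cin_spikes: np.ndarray
    dt_ms: float
    group_of: np.ndarray
    py_current: np.ndarray | None = None  # net synaptic input per PY

    def group_current(self) -> np.ndarray:
        """(n_steps, n_groups) mean net input current per orientation group."""
        if self.py_current is None:
            raise ValueError("response was recorded without currents")
        n_groups = self.group_of.max() + 1
        out = np.zeros((self.py_current.shape[0], n_groups))
        for g in range(n_groups):
            out[:, g] = self.py_current[:, self.group_of == g].mean(axis=1)
        return out


def cortical_response(
    network: CorticalNetwork,
    pn_spikes: np.ndarray,
    dt_ms: float = 0.1,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    keep_currents: bool = False,
) -> CorticalResponse:
    """Drive the cortical layer with the PN spike matrix."""
    rng = np.random.default_rng(rng)
    kin = network.kinetics
    tau_rA, tau_dA = kin.ampa
    tau_rG, tau_dG = kin.gaba
    lat = kin.tau_latency_ms

    I_cin = synaptic_current(pn_spikes, network.w_cin, tau_rA, tau_dA, dt_ms, lat)
    cin_spikes, _ = simulate_izhikevich(I_cin, network.params, dt_ms, noise_sd, rng)

    I_py_ex = synaptic_current(pn_spikes, network.w_exc, tau_rA, tau_dA, dt_ms, lat)
    I_py_inh = synaptic_current(cin_spikes, network.w_inh, tau_rG, tau_dG, dt_ms, lat)
    I_py = I_py_ex - I_py_inh
    py_spikes, _ = simulate_izhikevich(I_py, network.params, dt_ms, noise_sd, rng)
    return CorticalResponse(py_spikes, cin_spikes, dt_ms, network.group_of,
                            py_current=I_py if keep_currents else None)


def rate_group_scores(
    network: CorticalNetwork,
    pn_counts: np.ndarray,
) -> np.ndarray:
    """Fast rate-based cortical readout (no spiking dynamics).

    Each PY's score is its excitatory template applied to cumulative PN
    spike counts minus the paired inhibitory template; each group is scored
    by its best-matching PY (the spike threshold in the spiking cortex acts
    as this max-pool: only the best-placed PY of a group fires strongly).
    A quick-test shortcut for the spiking cortex.
    """
    py = pn_counts @ network.w_exc.T - pn_counts @ network.w_cin.T
    n_groups = network.n_groups
    return np.array([py[..., network.group_of == g].max(axis=-1) for g in range(n_groups)]).T
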