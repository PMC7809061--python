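"""First-order tactile neurons: SA-I and RA-I afferent populations.

Each afferent innervates exactly 28 mechanoreceptors drawn from per-axis
Gaussians around its receptive-field centre (sigma_d = 0.3 mm for SA-I,
0.39 mm for RA-I) with innervation weights uniform on [0.1, 1], giving the
multi-hotspot receptive fields characteristic of type-I afferents.  SA-I
centres tile the 80x80 grid as a 10x10 lattice (100 units), RA-I as a 14x14
lattice (196 units); 296 afferents in total.

Transduction converts the weighted force sum I_in into the Izhikevich drive:

* static SA-I:   I_SA = k1 I_in                       (memoryless Merkel gain)
* dynamic SA-I:  tau_r dx/dt   = k2 dI_in/dt + k1 I_in - x
                 tau_d dI_SA/dt = x - I_SA
  (Merkel-cell component plus a neurite component sensitive to the input
  derivative: sustained response with an onset overshoot)
* RA-I:          tau_RA dI_RA/dt = k3 |dI_in/dt| - I_RA
  (responds only while the skin is moving; onset/offset bursts)

with k1 = 0.05, k2 = 3, k3 = 2, tau_r = 5 ms, tau_d = tau_RA = 30 ms.
All filters are discretized with the same forward-Euler step as the neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, sparse

from .grid import MechanoreceptorGrid
from .neuron import AFFERENT_PARAMS, simulate_izhikevich
from .stimulus import StimulusMovie

#: innervated mechanoreceptors per afferent
N_SITES_PER_AFFERENT = 28
#: receptive-field spread, mm
SIGMA_D_MM = {"SA": 0.3, "RA": 0.39}
#: lattice of receptive-field centres per kind
LATTICE = {"SA": 10, "RA": 14}
#: intrinsic membrane noise SD (mV per sqrt(ms)); keeps spontaneous activity
#: sparse while perturbing spike timing
INTRINSIC_NOISE_SD = 1.5


@dataclass(frozen=True)
class TransductionParams:
    k1: float = 0.05
    k2: float = 3.0
    k3: float = 2.0
    tau_r_sa_ms: float = 5.0
    tau_d_sa_ms: float = 30.0
    tau_ra_ms: float = 30.0


@dataclass
class ReceptiveField:
    """Weighted mechanoreceptor subset innervated by one afferent."""

    afferent_id: int
    kind: str
    center_rowcol: tuple[float, float]
    sites: np.ndarray  # (28,) flat mechanoreceptor indices, distinct
    weights: np.ndarray  # (28,) in [0.1, 1]


@dataclass
class AfferentPopulation:
    kind: str  # "SA" | "RA"
    grid: MechanoreceptorGrid
    receptive_fields: list[ReceptiveField]
    sigma_d_mm: float

    def __len__(self) -> int:
        return len(self.receptive_fields)

    @property
    def centers_rowcol(self) -> np.ndarray:
        return np.array([rf.center_rowcol for rf in self.receptive_fields])

    def centers_norm(self) -> np.ndarray:
        rc = self.centers_rowcol
        x, y = self.grid.rowcol_to_norm(rc[:, 0], rc[:, 1])
        return np.column_stack([x, y])

    def weight_matrix(self) -> sparse.csr_matrix:
        """(n_afferents, n_sites) sparse innervation-weight matrix."""
        n = len(self)
        rows = np.repeat(np.arange(n), N_SITES_PER_AFFERENT)
        cols = np.concatenate([rf.sites for rf in self.receptive_fields])
        data = np.concatenate([rf.weights for rf in self.receptive_fields])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, self.grid.n_sites))

    def rf_image(self, afferent_id: int) -> np.ndarray:
        """Dense (n_rows, n_cols) innervation-weight map of one afferent."""
        rf = self.receptive_fields[afferent_id]
        img = np.zeros(self.grid.n_sites)
        img[rf.sites] = rf.weights
        return img.reshape(self.grid.n_rows, self.grid.n_cols)


def _lattice_centers(n_lattice: int, n_grid: int) -> np.ndarray:
    """Centres of n_lattice equal sections of an n_grid-point axis."""
    step = n_grid / n_lattice
    return (np.arange(n_lattice) + 0.5) * step - 0.5


def build_population(
    kind: str,
    grid: MechanoreceptorGrid | None = None,
    sigma_d_mm: float | None = None,
    rng: np.random.Generator | int | None = None,
    sigma_scale: float = 1.0,
) -> AfferentPopulation:
    """Construct an SA-I or RA-I population with seeded random innervation.

    ``sigma_scale`` multiplies sigma_d (receptive-field size sweeps).
    Sites falling off-grid or duplicated are rejection-resampled, so fields
    near the border are slightly biased inward.
    """
    kind = kind.upper()[:2]
    if kind not in ("SA", "RA"):
        raise ValueError(f"kind must be SA or RA, got {kind!r}")
    grid = grid or MechanoreceptorGrid()
    sigma = (sigma_d_mm if sigma_d_mm is not None else SIGMA_D_MM[kind]) * sigma_scale
    if sigma <= 0:
        raise ValueError("sigma_d must be positive")
    sigma_px = sigma / grid.pitch_mm
    rng = np.random.default_rng(rng)

    n_lat = LATTICE[kind]
    rows = _lattice_centers(n_lat, grid.n_rows)
    cols = _lattice_centers(n_lat, grid.n_cols)
    rfs: list[ReceptiveField] = []
    aff_id = 0
    for cr in rows:
        for cc in cols:
            chosen: list[int] = []
            seen: set[int] = set()
            while len(chosen) < N_SITES_PER_AFFERENT:
                need = N_SITES_PER_AFFERENT - len(chosen)
                r = np.rint(rng.normal(cr, sigma_px, size=4 * need)).astype(int)
                c = np.rint(rng.normal(cc, sigma_px, size=4 * need)).astype(int)
                ok = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
                for idx in grid.site_index(r[ok], c[ok]):
                    if idx not in seen:
                        seen.add(int(idx))
                        chosen.append(int(idx))
                        if len(chosen) == N_SITES_PER_AFFERENT:
                            break
            weights = rng.uniform(0.1, 1.0, size=N_SITES_PER_AFFERENT)
            rfs.append(ReceptiveField(aff_id, kind, (cr, cc), np.array(chosen), weights))
            aff_id += 1
    return AfferentPopulation(kind, grid, rfs, sigma)


# ---------------------------------------------------------------------------
# transduction filters (exact forward-Euler semantics)
# ---------------------------------------------------------------------------


def _euler_lowpass(u: np.ndarray, tau_ms: float, dt_ms: float) -> np.ndarray:
    """One-pole low-pass x[n] = (1-a) x[n-1] + a u[n-1], a = dt/tau, x[0]=0.

    This is the forward-Euler discretization of tau dx/dt = u - x from zero
    initial state, applied along axis 0.
    """
    alpha = dt_ms / tau_ms
    return signal.lfilter([0.0, alpha], [1.0, -(1.0 - alpha)], u, axis=0)


def backward_diff(I: np.ndarray, dt_ms: float) -> np.ndarray:
    """First-order backward difference along time (zero at the first sample)."""
    return np.diff(I, axis=0, prepend=I[:1]) / dt_ms


def sa_static(I_in: np.ndarray, params: TransductionParams = TransductionParams()) -> np.ndarray:
    """Static Merkel-only SA-I drive: I_SA = k1 I_in (memoryless)."""
    return params.k1 * np.asarray(I_in, dtype=float)


def sa_dynamic(
    I_in: np.ndarray, dt_ms: float = 0.1, params: TransductionParams = TransductionParams()
) -> np.ndarray:
    """Dynamic SA-I drive: two-stage cascade with derivative-sensitive input."""
    I_in = np.asarray(I_in, dtype=float)
    u = params.k2 * backward_diff(I_in, dt_ms) + params.k1 * I_in
    x = _euler_lowpass(u, params.tau_r_sa_ms, dt_ms)
    return _euler_lowpass(x, params.tau_d_sa_ms, dt_ms)


def ra_filter(
    I_in: np.ndarray, dt_ms: float = 0.1, params: TransductionParams = TransductionParams()
) -> np.ndarray:
    """RA-I drive: low-passed absolute input derivative."""
    I_in = np.asarray(I_in, dtype=float)
    u = params.k3 * np.abs(backward_diff(I_in, dt_ms))
    return _euler_lowpass(u, params.tau_ra_ms, dt_ms)


# ---------------------------------------------------------------------------
# population responses
# ---------------------------------------------------------------------------


@dataclass
class AfferentResponse:
    """Spikes and currents of one population for one trial."""

    kind: str
    spikes: np.ndarray  # bool (n_steps, n_afferents)
    dt_ms: float
    I_in: np.ndarray | None = None  # weighted force sum per afferent
    I_drive: np.ndarray | None = None  # transduced Izhikevich input


def input_current(pop: AfferentPopulation, movie: StimulusMovie) -> np.ndarray:
    """Weighted force sum per afferent and time step: (n_steps, n_afferents).

    Exploits the fixed innervation count: one gather of all innervated sites
    followed by a weighted per-afferent reduction.
    """
    sites = np.stack([rf.sites for rf in pop.receptive_fields])  # (n_aff, 28)
    weights = np.stack([rf.weights for rf in pop.receptive_fields])
    gathered = movie.frames[:, sites.ravel()].reshape(
        movie.frames.shape[0], len(pop), N_SITES_PER_AFFERENT
    )
    return np.einsum(
        "tak,ak->ta", gathered, weights, dtype=float, casting="unsafe"
    )


def afferent_response(
    pop: AfferentPopulation,
    movie: StimulusMovie,
    sa_model: str = "dynamic",
    params: TransductionParams = TransductionParams(),
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    keep_currents: bool = False,
) -> AfferentResponse:
    """Transduce a stimulus movie and emit spikes for one population."""
    I_in = input_current(pop, movie)
    if pop.kind == "SA":
        if sa_model == "dynamic":
            I_drive = sa_dynamic(I_in, movie.dt_ms, params)
        elif sa_model == "static":
            I_drive = sa_static(I_in, params)
        else:
            raise ValueError(f"sa_model must be 'static' or 'dynamic', got {sa_model!r}")
    else:
        I_drive = ra_filter(I_in, movie.dt_ms, params)
    spikes, _ = simulate_izhikevich(
        I_drive, AFFERENT_PARAMS, movie.dt_ms, noise_sd=noise_sd, rng=rng
    )
    return AfferentResponse(
        pop.kind,
        spikes,
        movie.dt_ms,
        I_in=I_in if keep_currents else None,
        I_drive=I_drive if keep_currents else None,
    )
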