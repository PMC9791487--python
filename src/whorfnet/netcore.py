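"""Twelve-area spiking network: construction and single-step dynamics.

The model is a discrete-time leaky-integrator network of 12 cortical areas,
each a 25 × 25 grid of excitatory graded-potential spiking cells, every one
paired with one local inhibitory cell.  Four processing "streams" of three
areas each are modelled: an auditory (*A1 → *AB → *PB) and an articulatory
(*M1_i → *PM_i → *PF_i) perisylvian stream, and a visual (*V1 → *TO → *AT)
and a hand-motor (*M1_L → *PM_L → *PF_L) extrasylvian stream.  Reciprocal
between-area pathways comprise next-neighbour links within each stream,
"jumping" links between each stream's primary and central area, and
long-distance links between all pairs of the four central multimodal areas
(*PB, *PF_i, *AT, *PF_L) — 18 reciprocal pairs in total.

Per time step, each excitatory cell integrates weighted excitatory input
(within- and between-area), external drive, subtractive local and global
inhibition and optional background noise; it emits a binary spike when its
membrane potential exceeds the spiking threshold by more than its current
adaptation, which itself tracks the cell's firing.  A low-pass estimate of
each cell's firing rate (ω) and a per-area global-inhibition accumulator
(G, tracking the area's total spike count) complete the state.

All cell-level connectivity is sparse and random.  Within-area and
within-stream (next-neighbour, jumping) projections use a 2-D Gaussian
neighbourhood kernel — applied topographically between corresponding grid
positions for between-area links — reflecting the retinotopic/somatotopic
organisation of sensory hierarchies.  The long-distance projections
between the four multimodal hub areas are uniform random with the same
expected out-degree: association cortex converges broadly, and it is this
spatially unstructured convergence that lets assemblies grounded at
arbitrary positions in different streams bind to one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AREA_NAMES",
    "PRIMARY_AREAS",
    "SECONDARY_AREAS",
    "CENTRAL_AREAS",
    "EXTRASYLVIAN_PRIMARY",
    "EXTRASYLVIAN_CENTRAL",
    "BETWEEN_AREA_PAIRS",
    "GRID",
    "AREA_SIZE",
    "N_AREAS",
    "N_CELLS",
    "ModelParams",
    "AreaSpec",
    "Network",
    "NetworkState",
    "NoiseSpec",
    "build_network",
    "step",
    "reset_state",
    "spike_output",
    "external_drive",
]

GRID = 25
AREA_SIZE = GRID * GRID  # 625 excitatory cells per area
N_AREAS = 12
N_CELLS = N_AREAS * AREA_SIZE

AREA_NAMES = (
    "*A1", "*AB", "*PB",          # perisylvian auditory
    "*M1_i", "*PM_i", "*PF_i",    # perisylvian articulatory
    "*V1", "*TO", "*AT",          # extrasylvian visual
    "*M1_L", "*PM_L", "*PF_L",    # extrasylvian hand-motor
)
_SYSTEMS = (
    "perisylvian-auditory", "perisylvian-auditory", "perisylvian-auditory",
    "perisylvian-articulatory", "perisylvian-articulatory", "perisylvian-articulatory",
    "extrasylvian-visual", "extrasylvian-visual", "extrasylvian-visual",
    "extrasylvian-hand-motor", "extrasylvian-hand-motor", "extrasylvian-hand-motor",
)
PRIMARY_AREAS = ("*A1", "*M1_i", "*V1", "*M1_L")
CENTRAL_AREAS = ("*PB", "*PF_i", "*AT", "*PF_L")
SECONDARY_AREAS = ("*AB", "*PM_i", "*TO", "*PM_L")
EXTRASYLVIAN_PRIMARY = ("*V1", "*M1_L")
EXTRASYLVIAN_CENTRAL = ("*AT", "*PF_L")

_NEXT_NEIGHBOUR = (
    ("*A1", "*AB"), ("*AB", "*PB"),
    ("*M1_i", "*PM_i"), ("*PM_i", "*PF_i"),
    ("*V1", "*TO"), ("*TO", "*AT"),
    ("*M1_L", "*PM_L"), ("*PM_L", "*PF_L"),
)
_JUMPING = (
    ("*A1", "*PB"), ("*M1_i", "*PF_i"), ("*V1", "*AT"), ("*M1_L", "*PF_L"),
)
_LONG_DISTANCE = (
    ("*PB", "*PF_i"), ("*PB", "*AT"), ("*PB", "*PF_L"),
    ("*PF_i", "*AT"), ("*PF_i", "*PF_L"), ("*AT", "*PF_L"),
)
#: The 18 reciprocal between-area pathways.
BETWEEN_AREA_PAIRS = _NEXT_NEIGHBOUR + _JUMPING + _LONG_DISTANCE

_SQRT3 = np.sqrt(3.0)  # uniform noise on [-sqrt(3), sqrt(3)] has unit variance


@dataclass(frozen=True)
class ModelParams:
    """Model parameters; the physiological defaults follow the reference
    simulations, connectivity/free parameters are package choices and
    configurable.

    Time constants are in simulation time steps; Δt = 0.5 ms enters only
    through the noise-amplitude formula k2 = 7·√(24/Δt).
    """

    tau_exc: float = 2.5            # membrane time constant, excitatory cells
    tau_inh: float = 5.0            # membrane time constant, inhibitory cells
    k1: float = 0.01                # total input rescaling factor
    k2: float = 7.0 * float(np.sqrt(24.0 / 0.5))  # noise amplitude (≈48.497)
    kG: float = 0.80                # global inhibition strength
    thresh: float = 0.18            # spiking threshold
    alpha: float = 8.0              # adaptation strength
    tau_adapt: float = 10.0         # adaptation time constant
    tau_favg_train: float = 30.0    # rate-estimate time constant (training)
    tau_favg_test: float = 5.0      # rate-estimate time constant (testing)
    tau_glob: float = 12.0          # global inhibition time constant
    theta_ltp: float = 0.15         # postsynaptic potential threshold, LTP
    theta_ltd: float = 0.14         # postsynaptic potential threshold, LTD
    theta_pre: float = 0.05         # presynaptic activity threshold
    delta_w: float = 0.0008         # learning rate
    w_max: float = 6.0              # weight cap; large enough that a
                                    # potentiated assembly sustains reverberation
    stimulus_amplitude: float = 500.0  # external drive per stimulated cell
    isi_inhibition_threshold: float = 30.0  # G level ending an ISI (see docs)
    isi_max_steps: int = 50         # hard cap on ISI length
    sigma: float = 4.5              # Gaussian kernel width (grid units)
    max_radius: float = 9.0         # kernel cut-off radius (grid units)
    out_degree: float = 100.0       # expected out-degree per projection
    inh_pool: int = 5               # side of the local inhibitory pooling window
    hetero_ltd: bool = True         # heterosynaptic LTD branch on/off
    isi_learning: bool = True       # keep Hebbian learning on during ISIs

    def __post_init__(self) -> None:
        for name in ("tau_exc", "tau_inh", "tau_adapt", "tau_favg_train",
                     "tau_favg_test", "tau_glob"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.theta_ltd < self.theta_ltp:
            raise ValueError("theta_ltd must be below theta_ltp")
        if not 0 < self.delta_w < self.w_max:
            raise ValueError("require 0 < delta_w << w_max")
        if self.thresh <= 0:
            raise ValueError("thresh must be > 0")


@dataclass(frozen=True)
class AreaSpec:
    name: str
    system: str
    centrality: str  # primary | secondary | central


def _area_specs() -> tuple[AreaSpec, ...]:
    out = []
    for name, system in zip(AREA_NAMES, _SYSTEMS):
        if name in PRIMARY_AREAS:
            centrality = "primary"
        elif name in CENTRAL_AREAS:
            centrality = "central"
        else:
            centrality = "secondary"
        out.append(AreaSpec(name=name, system=system, centrality=centrality))
    return tuple(out)


@dataclass
class Network:
    """Area graph plus sparse plastic excitatory connectivity.

    ``weights`` is a CSR matrix with rows indexed by the *postsynaptic*
    cell (global index = area index · 625 + cell index) and columns by the
    presynaptic cell, so ``weights @ phi`` is each cell's total excitatory
    input; the row layout also lets the plasticity kernel skip whole rows
    whose postsynaptic potential admits no weight change.  ``inh_pool``
    maps excitatory spikes onto each paired inhibitory cell's input (unit
    weights over a local window of the same area).
    """

    params: ModelParams
    areas: tuple[AreaSpec, ...]
    weights: sp.csr_matrix
    inh_pool: sp.csr_matrix
    init_seed: int
    learning_enabled: bool = True

    def area_index(self, name: str) -> int:
        return AREA_NAMES.index(name)

    def area_slice(self, name: str) -> slice:
        i = self.area_index(name)
        return slice(i * AREA_SIZE, (i + 1) * AREA_SIZE)

    def weight_checksum(self) -> float:
        """Cheap fingerprint used to assert testing never changes weights."""
        w = self.weights.data
        return float(w.sum() + (w * w).sum())


@dataclass
class NetworkState:
    """Per-cell dynamic variables (see module docstring)."""

    V: np.ndarray          # excitatory membrane potentials (N_CELLS,)
    V_inh: np.ndarray      # inhibitory membrane potentials (N_CELLS,)
    a: np.ndarray          # adaptation, excitatory cells
    phi: np.ndarray        # binary output, excitatory cells (0.0/1.0)
    phi_inh: np.ndarray    # rectified output of inhibitory cells
    omega: np.ndarray      # low-pass firing-rate estimate ω_E
    G: np.ndarray          # per-area global-inhibition accumulator (N_AREAS,)

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.V.copy(), self.V_inh.copy(), self.a.copy(), self.phi.copy(),
            self.phi_inh.copy(), self.omega.copy(), self.G.copy(),
        )


@dataclass
class NoiseSpec:
    """Noise switches for one step.

    ``baseline`` gates the ever-present background noise in every cell;
    ``extra_areas`` lists areas receiving additional uncorrelated white
    noise on the external-input channel (same amplitude k2).  Noise is
    zero-mean unit-variance uniform white noise, drawn from ``rng``; the
    extra channel can draw from its own ``extra_rng`` so that the baseline
    stream stays aligned between runs that differ only in the extra input
    (common random numbers across conditions).
    """

    rng: np.random.Generator | None = None
    baseline: bool = True
    extra_areas: tuple[str, ...] = ()
    extra_rng: np.random.Generator | None = None

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(rng=None, baseline=False, extra_areas=())


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def _kernel_offsets(params: ModelParams, include_self: bool):
    """Offsets (dy, dx) within the cut-off radius and their link probability.

    The per-offset probability is a Gaussian of the Euclidean offset length
    normalised so that the expected out-degree of an interior cell equals
    ``params.out_degree`` (boundary cells lose clipped targets).
    """
    r = int(np.floor(params.max_radius))
    dy, dx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    dy, dx = dy.ravel(), dx.ravel()
    d2 = dy.astype(float) ** 2 + dx.astype(float) ** 2
    keep = d2 <= params.max_radius**2
    if not include_self:
        keep &= d2 > 0
    dy, dx, d2 = dy[keep], dx[keep], d2[keep]
    g = np.exp(-d2 / (2.0 * params.sigma**2))
    # normalisation uses the within-area kernel mass (self excluded) so the
    # two kernel variants share one probability scale
    g_norm = np.exp(
        -(d2[d2 > 0] if include_self else d2) / (2.0 * params.sigma**2)
    ).sum()
    p = np.minimum(params.out_degree * g / g_norm, 1.0)
    return dy, dx, p


def _random_projection(
    rng: np.random.Generator, params: ModelParams, within: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Random (source, target) cell pairs for one topographic projection."""
    dy, dx, p = _kernel_offsets(params, include_self=not within)
    src = np.arange(AREA_SIZE)
    sy, sx = src // GRID, src % GRID
    hits = rng.random((AREA_SIZE, dy.size)) < p[None, :]
    s_idx, o_idx = np.nonzero(hits)
    ty = sy[s_idx] + dy[o_idx]
    tx = sx[s_idx] + dx[o_idx]
    ok = (ty >= 0) & (ty < GRID) & (tx >= 0) & (tx < GRID)  # clipped, no torus
    return src[s_idx[ok]], ty[ok] * GRID + tx[ok]


def _uniform_projection(
    rng: np.random.Generator, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially unstructured random pairs (long-distance hub links)."""
    hits = rng.random((AREA_SIZE, AREA_SIZE)) < params.out_degree / AREA_SIZE
    return np.nonzero(hits)


def build_network(params: ModelParams | None = None, seed: int = 0) -> Network:
    """Build the 12-area network with random sparse connectivity.

    Deterministic given ``seed``.  Initial weights are uniform on
    [0, 0.1·w_max] ("initially weak" links).
    """
    if params is None:
        params = ModelParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0]))

    rows: list[np.ndarray] = []  # post
    cols: list[np.ndarray] = []  # pre
    # fixed build order for determinism: within-areas, then each reciprocal pair
    for ai in range(N_AREAS):
        s, t = _random_projection(rng, params, within=True)
        cols.append(s + ai * AREA_SIZE)
        rows.append(t + ai * AREA_SIZE)
    for a, b in BETWEEN_AREA_PAIRS:
        ia, ib = AREA_NAMES.index(a), AREA_NAMES.index(b)
        long_distance = (a, b) in _LONG_DISTANCE
        for src_area, tgt_area in ((ia, ib), (ib, ia)):
            if long_distance:
                s, t = _uniform_projection(rng, params)
            else:
                s, t = _random_projection(rng, params, within=False)
            cols.append(s + src_area * AREA_SIZE)
            rows.append(t + tgt_area * AREA_SIZE)

    row = np.concatenate(rows)
    col = np.concatenate(cols)
    data = rng.uniform(0.0, 0.1 * params.w_max, row.size)
    weights = sp.csr_matrix((data, (row, col)), shape=(N_CELLS, N_CELLS))

    # local inhibition: each inhibitory cell pools spikes over a small
    # square window of its own area's excitatory grid (unit weights)
    half = params.inh_pool // 2
    py, px = np.meshgrid(
        np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij"
    )
    py, px = py.ravel(), px.ravel()
    src = np.arange(AREA_SIZE)
    sy, sx = src // GRID, src % GRID
    i_rows, i_cols = [], []
    ty = sy[:, None] + py[None, :]
    tx = sx[:, None] + px[None, :]
    ok = (ty >= 0) & (ty < GRID) & (tx >= 0) & (tx < GRID)
    s_idx, o_idx = np.nonzero(ok)
    base_r, base_c = src[s_idx], ty[s_idx, o_idx] * GRID + tx[s_idx, o_idx]
    for ai in range(N_AREAS):
        i_rows.append(base_r + ai * AREA_SIZE)
        i_cols.append(base_c + ai * AREA_SIZE)
    pool = sp.csr_matrix(
        (np.ones(base_r.size * N_AREAS), (np.concatenate(i_rows), np.concatenate(i_cols))),
        shape=(N_CELLS, N_CELLS),
    )

    return Network(
        params=params, areas=_area_specs(), weights=weights, inh_pool=pool,
        init_seed=int(seed),
    )


def reset_state(network: Network) -> NetworkState:
    """Global reset: all membrane potentials and auxiliary variables zeroed."""
    z = lambda: np.zeros(N_CELLS)
    return NetworkState(
        V=z(), V_inh=z(), a=z(), phi=z(), phi_inh=z(), omega=z(),
        G=np.zeros(N_AREAS),
    )


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def spike_output(V: np.ndarray, a: np.ndarray, params: ModelParams) -> np.ndarray:
    """Binary spike rule: fire iff V − α·a ≥ thresh."""
    return (V - params.alpha * a >= params.thresh).astype(float)


def external_drive(
    network: Network,
    cells_by_area: dict[str, "frozenset[int] | set[int] | np.ndarray"],
    amplitude: float | None = None,
) -> np.ndarray:
    """Build a full external-drive vector from per-area active-cell sets."""
    if amplitude is None:
        amplitude = network.params.stimulus_amplitude
    drive = np.zeros(N_CELLS)
    for area, cells in cells_by_area.items():
        idx = np.fromiter((int(c) for c in cells), dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= AREA_SIZE):
            raise ValueError(f"cell index out of range for area {area}")
        drive[np.asarray(idx) + network.area_index(area) * AREA_SIZE] = amplitude
    return drive


def step(
    network: Network,
    state: NetworkState,
    external_input: np.ndarray | dict | None = None,
    noise_spec: NoiseSpec | None = None,
    tau_favg: float | None = None,
) -> NetworkState:
    """Advance the network one synchronous discrete time step (in place).

    Update order: excitatory membrane integration (with noise), inhibitory
    integration, spike outputs, adaptation, rate estimate ω (with the given
    ``tau_favg``), per-area global inhibition G.
    """
    p = network.params
    if noise_spec is None:
        noise_spec = NoiseSpec.off()
    if tau_favg is None:
        tau_favg = p.tau_favg_train

    if isinstance(external_input, dict):
        ext = external_drive(network, external_input)
    elif external_input is None:
        ext = None
    else:
        ext = np.asarray(external_input)
        if ext.shape != (N_CELLS,):
            raise ValueError(
                f"external_input has shape {ext.shape}, expected ({N_CELLS},)"
            )

    # total input u: recurrent excitation + drive − local − global inhibition
    u = network.weights @ state.phi
    if ext is not None:
        u += ext
    u -= state.phi_inh
    u -= np.repeat(p.kG * state.G, AREA_SIZE)
    rng = noise_spec.rng
    if noise_spec.extra_areas:
        extra_rng = noise_spec.extra_rng or rng
        if extra_rng is None:
            raise ValueError("noise requested but NoiseSpec.rng is None")
        for area in noise_spec.extra_areas:
            sl = network.area_slice(area)
            u[sl] += p.k2 * extra_rng.uniform(-_SQRT3, _SQRT3, AREA_SIZE)
    if noise_spec.baseline:
        if rng is None:
            raise ValueError("noise requested but NoiseSpec.rng is None")
        u += p.k2 * rng.uniform(-_SQRT3, _SQRT3, N_CELLS)

    state.V += (-state.V + p.k1 * u) / p.tau_exc
    state.V_inh += (-state.V_inh + network.inh_pool @ state.phi) / p.tau_inh

    if not np.isfinite(state.V).all():
        raise FloatingPointError("non-finite membrane potential V detected")

    phi_new = spike_output(state.V, state.a, p)
    state.phi_inh = np.maximum(state.V_inh, 0.0)
    state.a += (-state.a + phi_new) / p.tau_adapt
    state.omega += (-state.omega + phi_new) / tau_favg
    state.G += (-state.G + phi_new.reshape(N_AREAS, AREA_SIZE).sum(axis=1)) / p.tau_glob
    state.phi = phi_new
    return state
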