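"""Brownian dynamics of a semiflexible DNA chain with multivalent bridges.

The model behind bridging-induced phase separation (BIPS): DNA is a
bead-spring polymer (FENE backbone, Kratky-Porod bending, WCA excluded
volume) and DNA-binding proteins are diffusing spheres that may hold up to
``valence`` simultaneous harmonic bonds to chain beads.  Bonds are created
and removed by a Metropolis scheme with energy ``-binding_energy_kt`` per
bond, so a bridge bound to two sequence-distant beads stabilises a DNA loop
— the nucleation event of BIPS.

Reduced units: bead diameter sigma = 1, k_B T = 1, friction = 1.  One bead
represents ``bead_diameter_nm / 0.34`` base pairs of double-stranded DNA
(29.4 bp for the default 10-nm bead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from . import _kernels

NM_PER_BP = 0.34

__all__ = [
    "ChainConfig",
    "BridgeConfig",
    "SimParams",
    "SimState",
    "Trajectory",
    "stiffness_for_persistence_length",
    "discrete_persistence_length",
    "init_state",
    "integrate",
    "update_binding",
    "largest_cluster",
    "run_simulation",
    "wlc_mean_square_end_to_end",
]


def discrete_persistence_length(kappa: float, bond_length: float = 1.0) -> float:
    """Persistence length (in sigma) of a discrete Kratky-Porod chain.

    Uses l_P = -b / ln<cos theta> with <cos theta> = coth(kappa) - 1/kappa.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    mean_cos = 1.0 / math.tanh(kappa) - 1.0 / kappa
    return -bond_length / math.log(mean_cos)


def stiffness_for_persistence_length(
    lp_sigma: float, bond_length: float = 1.0
) -> float:
    """Bending stiffness kappa (k_B T) giving persistence length lp_sigma."""
    return brentq(
        lambda k: discrete_persistence_length(k, bond_length) - lp_sigma, 0.05, 500.0
    )


def wlc_mean_square_end_to_end(contour: float, lp: float) -> float:
    """Worm-like-chain <R^2> = 2 lp L - 2 lp^2 (1 - exp(-L/lp))."""
    return 2.0 * lp * contour - 2.0 * lp * lp * (1.0 - math.exp(-contour / lp))


@dataclass(frozen=True)
class ChainConfig:
    """Semiflexible DNA chain.

    kappa defaults to the stiffness that gives a 50-nm persistence length at
    a 10-nm bead (kappa = 5.51 k_B T for the discrete Kratky-Porod chain).
    """

    n_beads: int
    bead_diameter_nm: float = 10.0
    persistence_length_nm: float = 50.0
    kappa: float | None = None
    excluded_volume: bool = True

    def __post_init__(self):
        if self.n_beads < 1:
            raise ValueError("a chain needs at least 1 bead")
        if self.kappa is None:
            lp_sigma = self.persistence_length_nm / self.bead_diameter_nm
            object.__setattr__(
                self, "kappa", stiffness_for_persistence_length(lp_sigma)
            )
        lp = discrete_persistence_length(self.kappa) * self.bead_diameter_nm
        if abs(lp - self.persistence_length_nm) > 0.05 * self.persistence_length_nm:
            raise ValueError(
                f"kappa={self.kappa:.3g} gives l_P={lp:.1f} nm, more than 5% from "
                f"the {self.persistence_length_nm:.1f} nm target"
            )

    @property
    def bp_per_bead(self) -> float:
        return self.bead_diameter_nm / NM_PER_BP

    @property
    def length_bp(self) -> float:
        return self.n_beads * self.bp_per_bead

    @property
    def contour_length_nm(self) -> float:
        return self.n_beads * self.bead_diameter_nm


@dataclass(frozen=True)
class BridgeConfig:
    """Multivalent DNA-binding bridge particles (cohesin stand-ins).

    valence is the hard cap on simultaneous bead bonds (2, 3 or ~10);
    binding_energy_kt defaults to 4 k_B T, the middle of the 3-5 k_B T range
    over which bridging-induced clustering is predicted to operate.
    number_per_bead fixes the bridge count at a constant ratio to chain
    length so that concentration, not copy number, is the controlled
    variable.
    """

    valence: int = 2
    binding_energy_kt: float = 4.0
    capture_radius_sigma: float = 1.5
    number_per_bead: float = 0.2
    concentration_sigma3: float = 2.0e-4  # ~0.33 uM at sigma = 10 nm
    link_stiffness: float = 30.0
    link_rest_length: float = 1.0

    def __post_init__(self):
        if self.valence < 2:
            raise ValueError("a bridge needs valence >= 2")
        if self.binding_energy_kt < 0:
            raise ValueError("binding energy must be non-negative")

    def n_bridges(self, n_beads: int) -> int:
        return max(1, round(self.number_per_bead * n_beads))

    def box_size(self, n_beads: int) -> float:
        """Periodic box edge (sigma) keeping bridge concentration constant."""
        return (self.n_bridges(n_beads) / self.concentration_sigma3) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SimParams:
    """Integration parameters (reduced units, k_B T = 1)."""

    timestep: float = 2e-4
    friction: float = 1.0
    n_steps: int = 100_000
    binding_update_interval: int = 20
    box_size: float | None = None  # overrides the concentration-derived box
    k_fene: float = 30.0
    r0_fene: float = 1.5
    seed: int = 0


@dataclass
class SimState:
    """Evolving configuration: bead and bridge coordinates plus the bond
    registry mapping each bridge to the chain beads it currently holds."""

    positions: np.ndarray  # (n_beads + n_bridges, 3), sigma units, unwrapped
    n_beads: int
    bond_bead: np.ndarray  # (n_bridges, valence) int32, -1 padded via counts
    bond_count: np.ndarray  # (n_bridges,) int32
    box: float
    time_steps: int = 0
    sticky: np.ndarray | None = None  # bool per bead; None = all bindable

    @property
    def n_bridges(self) -> int:
        return self.positions.shape[0] - self.n_beads

    @property
    def bead_positions(self) -> np.ndarray:
        return self.positions[: self.n_beads]

    @property
    def bridge_positions(self) -> np.ndarray:
        return self.positions[self.n_beads :]

    def bonds(self) -> list[tuple[int, int]]:
        """(bridge_index, bead_index) pairs currently registered."""
        out = []
        for b in range(self.bond_count.shape[0]):
            for s in range(self.bond_count[b]):
                out.append((b, int(self.bond_bead[b, s])))
        return out

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(),
            self.n_beads,
            self.bond_bead.copy(),
            self.bond_count.copy(),
            self.box,
            self.time_steps,
            None if self.sticky is None else self.sticky.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered snapshots with full provenance."""

    chain: ChainConfig
    bridges: BridgeConfig | None
    params: SimParams
    stride: int
    snapshots: list[SimState] = field(default_factory=list)

    def __iter__(self) -> Iterator[SimState]:
        return iter(self.snapshots)

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_steps for s in self.snapshots])


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _sample_wlc_walk(
    n_beads: int, kappa: float, bond: float, rng: np.random.Generator,
    avoid: bool, confine_radius: float | None = None,
) -> np.ndarray:
    """Random walk with Boltzmann-distributed bond angles.

    cos(theta) is drawn from p(c) ~ exp(kappa c) by inverse transform, so a
    phantom chain starts in its equilibrium ensemble; with ``avoid`` the walk
    rejects steps landing within one bead diameter of previous beads, which
    only perturbs the stiff-chain statistics weakly.  ``confine_radius``
    additionally rejects steps leaving a sphere around the origin (used for
    condensed-phase starting configurations); when the stiffness-sampled
    angle cannot turn fast enough the angle bias is dropped for that step.
    """
    pos = np.zeros((n_beads, 3))
    if n_beads == 1:
        return pos
    t = rng.standard_normal(3)
    t /= np.linalg.norm(t)
    pos[1] = pos[0] + bond * t
    for i in range(2, n_beads):
        placed = False
        for attempt in range(400):
            u = rng.random()
            # inverse CDF of p(c) ~ exp(kappa c) on [-1, 1]; after many failed
            # tries fall back to an unbiased direction (confinement override)
            if kappa > 1e-8 and attempt < 300:
                c = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
            else:
                c = 2.0 * u - 1.0
            c = min(1.0, max(-1.0, c))
            phi = 2.0 * math.pi * rng.random()
            s = math.sqrt(max(0.0, 1.0 - c * c))
            # local frame around current tangent t
            a = np.array([1.0, 0.0, 0.0])
            if abs(t[0]) > 0.9:
                a = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(t, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            new_t = c * t + s * (math.cos(phi) * e1 + math.sin(phi) * e2)
            new_t /= np.linalg.norm(new_t)
            cand = pos[i - 1] + bond * new_t
            if confine_radius is not None and np.linalg.norm(cand) > confine_radius:
                continue
            if avoid and i > 8:
                d = np.linalg.norm(pos[: i - 4] - cand, axis=1)
                if d.min() < 0.85:
                    continue
            pos[i] = cand
            t = new_t
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place bead {i} without overlap after 400 retries"
            )
    return pos


def init_state(
    chain: ChainConfig,
    bridges: BridgeConfig | None,
    params: SimParams,
    sticky: np.ndarray | None = None,
    bridge_placement: str = "uniform",
    chain_init: str = "coil",
) -> SimState:
    """Initial configuration: random walk for the chain, bridges unbound and
    placed per ``bridge_placement``.

    ``bridge_placement="uniform"`` scatters bridges over the whole box;
    ``"near_chain"`` places each within a few diameters of a random bead.
    At the default binding energy nearly all bridges are chain-associated in
    equilibrium, so ``near_chain`` merely skips the diffusion-limited
    recruitment transient (useful for production cluster runs); the steady
    state sampled is the same.

    ``chain_init="coil"`` samples the equilibrium worm-like-chain ensemble;
    ``"compact"`` confines the walk to a sphere of semi-dilute density,
    starting the run inside the condensed basin.  Cluster formation is
    nucleation-limited, so condensate properties are measured from the
    condensed side: a valence that does not sustain a condensate will
    disperse from this start, one that does will relax within it.
    """
    rng = _rng(params.seed)
    if bridges is not None:
        n_br = bridges.n_bridges(chain.n_beads)
        box = params.box_size or bridges.box_size(chain.n_beads)
        valence = bridges.valence
    else:
        n_br = 0
        box = params.box_size or max(
            10.0, 3.0 * math.sqrt(
                wlc_mean_square_end_to_end(
                    chain.n_beads,
                    chain.persistence_length_nm / chain.bead_diameter_nm,
                )
            ),
        )
        valence = 2
    coil = math.sqrt(
        wlc_mean_square_end_to_end(
            chain.n_beads, chain.persistence_length_nm / chain.bead_diameter_nm
        )
    )
    if box < 1.2 * coil / 2.0:
        raise ValueError(
            f"box ({box:.0f} sigma) too small for the equilibrium coil "
            f"(R ~ {coil:.0f} sigma)"
        )
    if chain_init not in ("coil", "compact"):
        raise ValueError(f"unknown chain_init {chain_init!r}")
    confine = None
    if chain_init == "compact":
        # sphere at ~10% volume fraction, never tighter than the stiffness
        # allows (a few persistence lengths)
        confine = max(
            (chain.n_beads / (0.10 * 8.0)) ** (1.0 / 3.0), 4.0
        )
    pos = np.empty((chain.n_beads + n_br, 3))
    walk = None
    for attempt in range(50):
        try:
            walk = _sample_wlc_walk(
                chain.n_beads, chain.kappa, 0.97, rng,
                avoid=chain.excluded_volume,
                # a confined self-avoiding walk can dead-end; widen the
                # sphere slightly on repeated failures (the push-off
                # relaxation below removes any residual crowding bias)
                confine_radius=None if confine is None
                else confine * (1.0 + 0.05 * (attempt // 10)),
            )
            break
        except RuntimeError:
            continue
    if walk is None:
        raise RuntimeError(
            f"could not construct a {chain.n_beads}-bead starting walk "
            "after 50 restarts"
        )
    pos[: chain.n_beads] = walk
    pos[: chain.n_beads] += box / 2.0 - pos[: chain.n_beads].mean(axis=0)
    if n_br:
        # uniform placement, rejecting overlap with chain beads and other
        # bridges (minimum-image distance < 1 sigma)
        if bridge_placement not in ("uniform", "near_chain"):
            raise ValueError(f"unknown bridge_placement {bridge_placement!r}")
        tree = cKDTree(np.mod(pos[: chain.n_beads], box), boxsize=box)
        placed = []
        for b in range(n_br):
            for _ in range(1000):
                if bridge_placement == "near_chain":
                    bead = pos[rng.integers(chain.n_beads)]
                    u = rng.standard_normal(3)
                    u /= np.linalg.norm(u)
                    cand = np.mod(bead + u * rng.uniform(1.2, 4.0), box)
                else:
                    cand = rng.random(3) * box
                if tree.query(cand, k=1)[0] < 1.0:
                    continue
                if placed and cKDTree(
                    np.array(placed), boxsize=box
                ).query(cand, k=1)[0] < 1.0:
                    continue
                placed.append(cand)
                break
            else:
                raise RuntimeError(
                    f"could not place bridge {b} without overlap after 1000 tries"
                )
        pos[chain.n_beads :] = np.array(placed)
    bond_bead = np.full((max(n_br, 1), valence), -1, dtype=np.int32)
    bond_count = np.zeros(max(n_br, 1), dtype=np.int32)
    # noise-free push-off removes residual construction overlaps so the
    # stochastic integrator never starts against a deep excluded-volume core
    status = _kernels.relax_chunk(
        pos,
        chain.n_beads,
        bond_bead,
        bond_count,
        30.0,
        1.0,
        chain.kappa,
        params.k_fene,
        params.r0_fene,
        chain.excluded_volume,
        box,
        300,
        _ncell(box, 1.5),
        max(4096, 64 * pos.shape[0]),
    )
    if status != _kernels.OK:
        raise RuntimeError("initial-state relaxation failed (overflow)")
    if sticky is not None:
        sticky = np.asarray(sticky, dtype=np.bool_)
        if sticky.shape != (chain.n_beads,):
            raise ValueError("sticky mask must have one flag per bead")
    return SimState(pos, chain.n_beads, bond_bead, bond_count, box, 0, sticky)


def _ncell(box: float, r_capture: float) -> int:
    # cells must cover both the WCA pair list (cutoff + skin) and the
    # binding capture radius
    r_list = max(_kernels.WCA_CUT2 ** 0.5 + 0.7, r_capture)
    n = int(box / r_list)
    if n < 3:
        raise ValueError("periodic box smaller than 3 interaction ranges")
    return min(n, 64)


def integrate(
    state: SimState,
    chain: ChainConfig,
    params: SimParams,
    n_steps: int,
    bridges: BridgeConfig | None = None,
    seed: int | None = None,
    with_binding: bool = True,
) -> SimState:
    """Advance ``state`` in place by n_steps of overdamped dynamics.

    Binding Metropolis sweeps run every ``binding_update_interval`` steps
    when ``bridges`` is given and ``with_binding`` is true.  Raises on FENE
    overstretch (timestep too large) with a state dump in the message.
    """
    if n_steps <= 0:
        return state
    if bridges is not None:
        valence = bridges.valence
        eps = bridges.binding_energy_kt
        r_cap = bridges.capture_radius_sigma
        k_link, r0_link = bridges.link_stiffness, bridges.link_rest_length
        interval = params.binding_update_interval if with_binding else 0
    else:
        valence, eps, r_cap, k_link, r0_link = 2, 1.0, 1.5, 30.0, 1.0
        interval = 0
    sticky = (
        state.sticky
        if state.sticky is not None
        else np.ones(state.n_beads, dtype=np.bool_)
    )
    if seed is None:
        seed = params.seed
    ncell = _ncell(state.box, r_cap)
    n = state.positions.shape[0]
    pair_cap = max(4096, 64 * n)
    dt = params.timestep / params.friction
    for _ in range(4):
        status, peak = _kernels.simulate_chunk(
            state.positions,
            state.n_beads,
            sticky,
            state.bond_bead,
            state.bond_count,
            valence,
            eps,
            r_cap,
            k_link,
            r0_link,
            chain.kappa,
            params.k_fene,
            params.r0_fene,
            chain.excluded_volume,
            state.box,
            dt,
            n_steps,
            interval,
            int(seed) & 0x7FFFFFFF,
            ncell,
            pair_cap,
        )
        if status == _kernels.NEIGHBOR_OVERFLOW:
            pair_cap *= 4
            continue
        break
    if status == _kernels.FENE_OVERSTRETCH:
        raise RuntimeError(
            "FENE bond exceeded maximum extension: timestep too large. "
            f"state: t={state.time_steps}, n={n}, dt={params.timestep}"
        )
    if status != _kernels.OK:
        raise RuntimeError(f"simulation kernel failed with status {status}")
    state.time_steps += n_steps
    assert (state.bond_count <= valence).all(), "valence cap violated"
    return state


def update_binding(
    state: SimState,
    bridges: BridgeConfig,
    seed: int,
) -> SimState:
    """One Metropolis binding sweep at frozen particle positions."""
    sticky = (
        state.sticky
        if state.sticky is not None
        else np.ones(state.n_beads, dtype=np.bool_)
    )
    ncell = _ncell(state.box, bridges.capture_radius_sigma)
    n = state.positions.shape[0]
    head = np.empty(ncell**3, dtype=np.int32)
    stamp = np.zeros(ncell**3, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    cand = np.empty(1024, dtype=np.int32)
    wrapped = np.mod(state.positions, state.box)
    _kernels._build_cells(wrapped, state.box, ncell, head, nxt, stamp, 1)
    _kernels._sweep_with_seed(
        wrapped, state.n_beads, state.box, sticky,
        state.bond_bead, state.bond_count, bridges.valence,
        bridges.binding_energy_kt, bridges.capture_radius_sigma,
        bridges.link_stiffness, bridges.link_rest_length,
        ncell, head, nxt, stamp, 1, cand, seed & 0x7FFFFFFF,
    )
    assert (state.bond_count <= bridges.valence).all(), "valence cap violated"
    return state


def largest_cluster(state: SimState, r_c: float = 2.5) -> np.ndarray:
    """Indices of the biggest bridge-mediated connected component.

    Connectivity models the experimental cluster — a protein-dense clump
    together with the DNA it engages.  Registered bonds and bridge-bridge
    proximity below ``r_c`` (sigma) connect; a chain bead merely *near* a
    bridge (within ``r_c``, unbonded) joins as a member but does not
    transmit connectivity, so two cohesins sitting two beads apart on a
    bare stretch of DNA remain separate single complexes (as they appear
    in AFM), while bridges sharing a bonded bead, or packed against each
    other in a condensate, form one cluster.  Bead-bead proximity never
    links (the backbone would trivially join everything).  Deterministic
    for a given state.
    """
    n = state.positions.shape[0]
    nb = state.n_beads
    wrapped = np.mod(state.positions, state.box)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    n_br = n - nb
    if n_br > 0:
        br_tree = cKDTree(wrapped[nb:], boxsize=state.box)
        for a, b in br_tree.query_pairs(r_c):
            union(nb + int(a), nb + int(b))
    bonded = np.zeros(nb, dtype=bool)
    for br, bead in _iter_bonds(state):
        union(nb + br, bead)
        bonded[bead] = True
    # unbonded beads near a member bridge join as leaves of the nearest one
    if n_br > 0 and nb > 0:
        bead_tree = cKDTree(wrapped[:nb], boxsize=state.box)
        near = bead_tree.query_ball_tree(br_tree, r_c)
        for bead, bridges_near in enumerate(near):
            if bridges_near and not bonded[bead]:
                d = np.linalg.norm(
                    _min_image_vec(
                        wrapped[nb + np.asarray(bridges_near)] - wrapped[bead],
                        state.box,
                    ),
                    axis=1,
                )
                union(bead, nb + int(bridges_near[int(np.argmin(d))]))
    roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
    labels, counts = np.unique(roots, return_counts=True)
    best = labels[np.argmax(counts)]
    return np.flatnonzero(roots == best)


def _min_image_vec(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _iter_bonds(state: SimState):
    for b in range(state.bond_count.shape[0]):
        for s in range(state.bond_count[b]):
            yield b, int(state.bond_bead[b, s])


def unwrap_cluster(state: SimState, members: np.ndarray) -> np.ndarray:
    """Coordinates of a cluster made whole across periodic images."""
    pos = state.positions[members]
    ref = pos[0]
    d = pos - ref
    d -= state.box * np.round(d / state.box)
    return ref + d


def run_simulation(
    chain: ChainConfig,
    bridges: BridgeConfig | None,
    params: SimParams,
    stride: int = 5_000,
    sticky: np.ndarray | None = None,
    bridge_placement: str = "uniform",
    chain_init: str = "coil",
) -> Trajectory:
    """Full run: init, integrate in stride-sized chunks, snapshot each chunk."""
    state = init_state(
        chain, bridges, params, sticky=sticky,
        bridge_placement=bridge_placement, chain_init=chain_init,
    )
    traj = Trajectory(chain, bridges, params, stride)
    traj.snapshots.append(state.copy())
    ss = np.random.SeedSequence(params.seed)
    chunk_seeds = ss.generate_state(max(1, params.n_steps // stride) + 1)
    done = 0
    k = 0
    while done < params.n_steps:
        n = min(stride, params.n_steps - done)
        integrate(
            state, chain, params, n, bridges=bridges,
            seed=int(chunk_seeds[k] & 0x7FFFFFFF),
        )
        done += n
        k += 1
        traj.snapshots.append(state.copy())
    return traj
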