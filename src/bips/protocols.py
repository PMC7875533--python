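"""Reference experiment protocols built from the simulator and analyses.

These functions define the package's standard desk-scale computational
experiments — the cluster-size-versus-DNA-length scaling measurement for a
given bridge valence, the phantom-chain (ideal polymer) control, and the
in-silico Hi-C compartment comparison — with every knob given a documented
default.  The same entry points back both the test suite and the
acceptance script, so reported numbers always come from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import aggregate_map, block_sticky_pattern, compartment_strength
from .scaling import ScalingFit, fit_power_law, radius_of_gyration
from .simulator import (
    BridgeConfig,
    ChainConfig,
    SimParams,
    largest_cluster,
    run_simulation,
    unwrap_cluster,
)

# chain lengths for the scaling experiment, in beads (29.4 bp per bead);
# 14-34 beads (0.4-1 kbp) are the deep sub-critical lengths where cluster
# size should be DNA-length independent, 57-80 beads sit in the crossover
# approaching l_C (~99 beads = 2903 bp), and 113-453 beads span the
# power-law regime up to ~13 kbp
SCALING_LENGTHS_BEADS = (14, 20, 34, 57, 80, 113, 160, 226, 320, 453)
FIT_MIN_BEADS = 113  # first length above l_C
CONSTANT_REGIME_BEADS = (14, 20, 34)

# phantom-chain control lengths: one decade, far above l_P so the
# worm-like-chain finite-length correction to the 0.5 slope is small
PHANTOM_LENGTHS_BEADS = (150, 213, 302, 428, 607, 860, 1219)


def _seed_for(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(base, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _steps_for(n_beads: int) -> int:
    # relaxation from the condensed start slows with chain length
    return int(max(120_000, 500 * n_beads))


@dataclass
class ScalingExperiment:
    """Per-length cluster sizes and the fitted exponent."""

    valence: int
    table: pd.DataFrame  # length_bp, replicate, rg_nm
    medians: pd.DataFrame  # length_bp, rg_nm
    fit: ScalingFit


def cluster_scaling_experiment(
    valence: int,
    seed: int,
    lengths_beads=SCALING_LENGTHS_BEADS,
    replicates: int = 10,
    timestep: float = 5e-4,
    r_c: float = 2.5,
    binding_energy_kt: float = 4.0,
    fit_min_beads: int = FIT_MIN_BEADS,
    steps_override: int | None = None,
) -> ScalingExperiment:
    """Measure largest-cluster R_G versus DNA length and fit the power law.

    Per (length, replicate): run from the condensed basin (compact chain,
    bridges near the chain), discard the first half of the snapshots as
    relaxation, take the median largest-cluster R_G over the tail; medians
    over replicates enter a log-log fit restricted to lengths above the
    critical looping length.  R_G is reported in nm (bead diameter 10 nm),
    lengths in bp.
    """
    rows = []
    for nb in lengths_beads:
        chain = ChainConfig(n_beads=int(nb))
        bridges = BridgeConfig(valence=valence, binding_energy_kt=binding_energy_kt)
        n_steps = steps_override or _steps_for(nb)
        # above l_C the condensed basin exists and runs start inside it
        # (nucleation is too slow to wait for); below l_C thermal looping is
        # impossible, so seeding a compact state would manufacture the very
        # clusters whose absence is the prediction — those chains start
        # from the equilibrium coil
        chain_init = "compact" if nb >= fit_min_beads else "coil"
        for rep in range(replicates):
            params = SimParams(
                seed=_seed_for(seed, valence, nb, rep),
                timestep=timestep,
                n_steps=n_steps,
            )
            traj = run_simulation(
                chain, bridges, params,
                stride=max(n_steps // 10, 1),
                bridge_placement="near_chain",
                chain_init=chain_init,
            )
            tail = traj.snapshots[len(traj.snapshots) // 2 + 1 :]
            rgs = [
                radius_of_gyration(unwrap_cluster(st, largest_cluster(st, r_c)))
                for st in tail
            ]
            rows.append(
                {
                    "length_bp": chain.length_bp,
                    "replicate": rep,
                    "rg_nm": float(np.median(rgs)) * chain.bead_diameter_nm,
                }
            )
    table = pd.DataFrame(rows)
    medians = (
        table.groupby("length_bp", as_index=False)["rg_nm"].median()
    )
    bp_cut = fit_min_beads * ChainConfig(n_beads=2).bp_per_bead
    sel = medians[medians["length_bp"] >= bp_cut - 1e-9]
    fit = fit_power_law(sel["length_bp"], sel["rg_nm"])
    return ScalingExperiment(valence, table, medians, fit)


def phantom_scaling_experiment(
    seed: int,
    lengths_beads=PHANTOM_LENGTHS_BEADS,
    replicates: int = 40,
    n_steps: int = 2_000,
    timestep: float = 2e-4,
) -> ScalingExperiment:
    """Ideal-polymer control: no excluded volume, no bridges.

    The chain starts in its equilibrium worm-like-chain ensemble and is
    integrated briefly; the ensemble mean R_G per length over replicates is
    fitted on log-log axes.  The ideal-chain exponent 0.5 is approached
    from above (worm-like-chain finite-length corrections contribute
    ~ +0.02 over this decade of lengths).
    """
    rows = []
    for nb in lengths_beads:
        chain = ChainConfig(n_beads=int(nb), excluded_volume=False)
        for rep in range(replicates):
            params = SimParams(
                seed=_seed_for(seed, 0, nb, rep),
                timestep=timestep,
                n_steps=n_steps,
            )
            traj = run_simulation(chain, None, params, stride=n_steps)
            rg = radius_of_gyration(traj.snapshots[-1].bead_positions)
            rows.append(
                {
                    "length_bp": chain.length_bp,
                    "replicate": rep,
                    "rg_nm": rg * chain.bead_diameter_nm,
                }
            )
    table = pd.DataFrame(rows)
    means = table.groupby("length_bp", as_index=False)["rg_nm"].mean()
    fit = fit_power_law(means["length_bp"], means["rg_nm"])
    return ScalingExperiment(0, table, means, fit)


def compartment_experiment(
    valence: int,
    seed: int,
    n_beads: int = 200,
    block: int = 20,
    replicates: int = 3,
    n_steps: int = 200_000,
    timestep: float = 5e-4,
    r_c: float = 2.5,
) -> float:
    """Compartment strength of an in-silico Hi-C map at a given valence.

    The chain carries alternating sticky/neutral blocks (only sticky beads
    bindable); maps are averaged over replicates before scoring.
    """
    maps = []
    sticky = block_sticky_pattern(n_beads, block)
    chain = ChainConfig(n_beads=n_beads)
    bridges = BridgeConfig(valence=valence)
    for rep in range(replicates):
        params = SimParams(
            seed=_seed_for(seed, valence, n_beads, rep),
            timestep=timestep,
            n_steps=n_steps,
        )
        traj = run_simulation(
            chain, bridges, params,
            stride=max(n_steps // 20, 1),
            sticky=sticky,
            bridge_placement="near_chain",
            chain_init="compact",
        )
        maps.append(aggregate_map(traj.snapshots[1:], r_c=r_c).matrix)
    from .contacts import ContactMap

    mean_map = ContactMap(np.mean(maps, axis=0), r_c, replicates)
    return compartment_strength(mean_map)


def constant_regime_spread(experiment: ScalingExperiment) -> float:
    """Relative spread of cluster size across the sub-critical lengths.

    (max - min) / mean of the per-length medians for chains below the
    critical looping length; small values mean the cluster size is
    length-independent there.
    """
    bp_per_bead = ChainConfig(n_beads=2).bp_per_bead
    sel = experiment.medians[
        experiment.medians["length_bp"] <= max(CONSTANT_REGIME_BEADS) * bp_per_bead + 1
    ]["rg_nm"].to_numpy()
    if len(sel) < 2:
        raise ValueError("need at least two sub-critical lengths")
    return float((sel.max() - sel.min()) / sel.mean())
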