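"""High-level pipeline assembly: config → structure → ENM → bias → H-REMD.

Thin glue used by the CLI, the examples and the acceptance machinery; all
science lives in the per-stage modules.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import bias as bias_mod
from . import enm as enm_mod
from .config import RunConfig
from .engine import NetworkPotential
from .errors import ConfigurationError
from .fixtures import ToyDimerParams, make_toy_dimer
from .hremd import CentroidBias, HREMDResult, run_hremd
from .structure import (
    CoarseStructure,
    DomainPartition,
    assign_domains,
    read_structure,
    truncate_n_terminal,
)

__all__ = ["PreparedSystem", "prepare_system", "run_remd_pipeline", "run_md_pipeline"]


@dataclass
class PreparedSystem:
    """Everything the sampling stages need, derived once from a config."""

    structure: CoarseStructure
    partition: DomainPartition
    model: enm_mod.ENMModel
    excitation: enm_mod.ModeExcitation
    halfwidths: np.ndarray      # Δd_ij, Å
    d0: np.ndarray              # reference centroid distances, Å
    spec: bias_mod.BiasSpec
    ladder: bias_mod.ReplicaLadder
    potential: NetworkPotential


def prepare_system(cfg: RunConfig, seed: int = 0) -> PreparedSystem:
    """Build structure, partition, ENM, Δd widths and bias ladder."""
    if cfg.structure == "fixture":
        params = ToyDimerParams(
            beads_per_domain=cfg.beads_per_domain,
            hinge_angle=cfg.hinge_angle,
            seed=seed,
        )
        structure, partition = make_toy_dimer(params)
    else:
        text = Path(cfg.structure).read_text()
        structure = read_structure(text, chain_filter=cfg.chains or None)
        if cfg.truncation_boundary > 0:
            structure = truncate_n_terminal(structure, cfg.truncation_boundary)
        if not cfg.domain_ranges:
            raise ConfigurationError(
                "domain_ranges required for a PDB structure source"
            )
        ranges = {
            chain: [tuple(iv) for iv in ivs]
            for chain, ivs in cfg.domain_ranges.items()
        }
        partition = assign_domains(structure, ranges)

    rule_params = {"cutoff": cfg.cutoff} if cfg.enm_rule == "cutoff" else {}
    model = enm_mod.build_network(structure, spring_rule=cfg.enm_rule, **rule_params)
    enm_mod.compute_modes(model)
    excitation = enm_mod.excite_modes(
        model, n_modes=cfg.n_modes, temperature=cfg.temperature
    )
    halfwidths = enm_mod.distance_fluctuations(model, excitation, partition)
    d0 = bias_mod.centroid_distances(structure.coords, partition)
    spec = bias_mod.BiasSpec.from_level(1.0, d0=d0, halfwidth=halfwidths)
    ladder = bias_mod.build_ladder(
        n_replicas=cfg.n_replicas,
        start_increment=cfg.start_level,
        spacing=cfg.ladder_spacing,
    )
    potential = NetworkPotential(model)
    return PreparedSystem(
        structure=structure,
        partition=partition,
        model=model,
        excitation=excitation,
        halfwidths=halfwidths,
        d0=d0,
        spec=spec,
        ladder=ladder,
        potential=potential,
    )


def run_remd_pipeline(
    cfg: RunConfig,
    seed: int,
    record_replicas: tuple = (0,),
    adapt: bool = True,
    update_d0: bool = True,
) -> tuple[PreparedSystem, HREMDResult]:
    """Prepare the system from config and run the adaptive H-REMD."""
    sys_ = prepare_system(cfg, seed=seed)
    biases = [
        CentroidBias(sys_.spec, sys_.partition)
        for _ in range(cfg.n_replicas)
    ]
    result = run_hremd(
        sys_.potential,
        biases,
        sys_.ladder,
        init_coords=sys_.structure.coords,
        masses=sys_.structure.masses,
        n_steps=cfg.n_steps,
        exchange_period_steps=cfg.exchange_period_steps(),
        control_period_steps=cfg.control_period_steps(),
        d0_window_steps=cfg.d0_window_steps(),
        temperature=cfg.temperature,
        dt=cfg.dt,
        friction=cfg.friction,
        output_stride=cfg.output_stride,
        seed=seed,
        adapt=adapt,
        controller_mode=cfg.controller_mode,
        update_d0=update_d0,
        d0_mode=cfg.d0_mode,
        record_replicas=record_replicas,
    )
    return sys_, result


def run_md_pipeline(cfg: RunConfig, seed: int):
    """Plain (unbiased) Langevin run of the same physical model.

    Implemented as a single-slot ladder run of the same engine so a
    zero-bias H-REMD and an unbiased run with the same seed are literally
    the same trajectory.
    """
    from .engine import SimState, maxwell_velocities, run_segment

    sys_ = prepare_system(cfg, seed=seed)
    seqs = np.random.SeedSequence(seed).spawn(cfg.n_replicas + 2)
    rng = np.random.default_rng(seqs[0])
    rng_init = np.random.default_rng(seqs[cfg.n_replicas + 1])
    vel = maxwell_velocities(
        sys_.structure.masses, cfg.temperature, rng_init,
        (1,) + sys_.structure.coords.shape,
    )[0]
    state = SimState(
        coords=sys_.structure.coords.copy(), velocities=vel, rng=rng
    )
    state, frames = run_segment(
        state,
        cfg.n_steps,
        sys_.potential,
        masses=sys_.structure.masses,
        dt=cfg.dt,
        friction=cfg.friction,
        temperature=cfg.temperature,
        stride=cfg.output_stride,
    )
    return sys_, state, frames
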