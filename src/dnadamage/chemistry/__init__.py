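"""Physicochemical and chemical stages: dissociation, diffusion, reaction.

``run_chemistry`` drives the stage over the radiolysis dataset: records are
grouped per (voxel, track) -- species react only with others from the same
track and the same voxel (independent-track approximation plus the per-voxel
isolation that stands in for scavenging) -- dissociated into initial
radicals, and evolved against that voxel's static DNA molecules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..geometry import constituents as cst
from ..geometry.nucleus import BASE_CODES
from .dissociation import dissociate, validate_channels
from .indirect import score_indirect_breaks
from .kinetics import brownian_bridge_reaction_prob, rate_to_reaction_radius
from .simulate import (ChemistryConfig, EVENT_COLUMNS,
                       simulate_voxel_chemistry)
from .species import (ReactionSpec, ReactionTable, SpeciesSpec,
                      default_reactions, default_species)

__all__ = [
    "ChemistryConfig", "EVENT_COLUMNS", "ReactionSpec", "ReactionTable",
    "SpeciesSpec", "brownian_bridge_reaction_prob", "default_reactions",
    "default_species", "dissociate", "rate_to_reaction_radius",
    "run_chemistry", "score_indirect_breaks", "simulate_voxel_chemistry",
    "validate_channels", "voxel_static_molecules",
]


def voxel_static_molecules(geometry_index, voxel_index: int,
                           include_phosphate: bool = False) -> pd.DataFrame:
    """Static DNA molecules of one placed voxel, in nucleus coordinates.

    Includes the reactive targets (deoxyriboses, named bases resolved from
    the sequence) and histone absorbers; phosphates are added only when the
    phosphate-reactivity flag is on.
    """
    placement, domain = geometry_index.placements[voxel_index]
    voxel = geometry_index.library[placement.kind]
    keep_codes = [cst.KIND_DEOXYRIBOSE, cst.KIND_BASE]
    if include_phosphate:
        keep_codes.append(cst.KIND_PHOSPHATE)
    mask = np.isin(voxel.cons_kind, keep_codes)
    pos = voxel.cons_pos[mask] @ placement.rotation.T + placement.center
    bp_local = voxel.cons_bp[mask]
    strand = voxel.cons_strand[mask].astype(int)
    kinds = voxel.cons_kind[mask]
    seq_ofs = placement.bp_start - domain.bp_start
    base_code = domain.sequence[seq_ofs + bp_local].astype(int)
    base_code = np.where(strand == 2, 3 - base_code, base_code)
    names = np.empty(mask.sum(), dtype=object)
    names[kinds == cst.KIND_DEOXYRIBOSE] = "deoxyribose"
    names[kinds == cst.KIND_PHOSPHATE] = "phosphate"
    is_base = kinds == cst.KIND_BASE
    names[is_base] = np.array(BASE_CODES, dtype=object)[base_code[is_base]]
    df = pd.DataFrame(dict(
        name=names, x=pos[:, 0], y=pos[:, 1], z=pos[:, 2],
        chromosome=domain.chromosome_id,
        bp=placement.bp_start + bp_local, strand=strand))
    hist = voxel.histone_pos @ placement.rotation.T + placement.center
    df_h = pd.DataFrame(dict(
        name="histone", x=hist[:, 0], y=hist[:, 1], z=hist[:, 2],
        chromosome=domain.chromosome_id, bp=-1, strand=0))
    return pd.concat([df, df_h], ignore_index=True)


def run_chemistry(radiolysis: pd.DataFrame, geometry_index,
                  rng, config: ChemistryConfig | None = None,
                  reactions: ReactionTable | None = None,
                  channel_table: dict | None = None,
                  include_phosphate: bool = False) -> pd.DataFrame:
    """Dissociate and evolve every (voxel, track) group; concatenated log."""
    if config is None:
        config = ChemistryConfig()
    if reactions is None:
        reactions = ReactionTable()
    if len(radiolysis) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)

    half = geometry_index._half
    static_cache: dict[int, tuple[pd.DataFrame, cKDTree]] = {}
    frames = []
    groups = radiolysis.groupby(["voxel_index", "track_id"], sort=True)
    for (voxel_index, track_id), seeds in groups:
        voxel_index = int(voxel_index)
        initial = dissociate(seeds, rng, channel_table,
                             config.dissociation_radius_nm)
        if len(initial) == 0:
            continue
        if voxel_index not in static_cache:
            dna = voxel_static_molecules(geometry_index, voxel_index,
                                         include_phosphate)
            static_cache[voxel_index] = (
                dna, cKDTree(dna[["x", "y", "z"]].to_numpy()))
        dna, tree = static_cache[voxel_index]
        center = geometry_index._vox_centers[voxel_index]
        box = (center - half, center + half)
        ev = simulate_voxel_chemistry(
            initial, dna, reactions, config, rng, box=box,
            voxel_index=voxel_index, track_id=int(track_id),
            static_tree=tree)
        if len(ev):
            frames.append(ev)
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
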