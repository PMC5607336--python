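"""Physicochemical stage: water dissociation into initial chemical species.

Each radiolysis seed (ionised water, excited water, solvated electron)
decays through a branching channel table into zero or more chemical
species, each placed uniformly within a 1 nm sphere around the seed
position. A solvated-electron seed maps to one e_aq unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..constants import DISSOCIATION_CHANNELS, DISSOCIATION_RADIUS_NM
from ..errors import ConfigurationError

SPECIES_COLUMNS = ["name", "x", "y", "z", "track_id", "voxel_index"]


def validate_channels(table: dict) -> None:
    for seed, channels in table.items():
        total = sum(p for p, _ in channels)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"branching ratios for {seed!r} sum to {total}, not 1")


def _uniform_in_ball(rng, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    u = rng.random(n) ** (1.0 / 3.0)
    return v * (radius * u)[:, None]


def dissociate(radiolysis: pd.DataFrame, rng,
               channel_table: dict | None = None,
               radius_nm: float = DISSOCIATION_RADIUS_NM) -> pd.DataFrame:
    """Products of every radiolysis record, with their initial positions."""
    table = DISSOCIATION_CHANNELS if channel_table is None else channel_table
    validate_channels(table)
    names, xs, ys, zs, tracks, voxels = [], [], [], [], [], []
    for row in radiolysis.itertuples(index=False):
        channels = table.get(row.species_seed)
        if channels is None:
            raise ConfigurationError(
                f"no dissociation channel for seed {row.species_seed!r}")
        probs = np.array([p for p, _ in channels])
        idx = rng.choice(len(channels), p=probs)
        products = channels[idx][1]
        if not products:
            continue
        offsets = _uniform_in_ball(rng, len(products), radius_nm)
        for name, off in zip(products, offsets):
            names.append(name)
            xs.append(row.x + off[0])
            ys.append(row.y + off[1])
            zs.append(row.z + off[2])
            tracks.append(row.track_id)
            voxels.append(row.voxel_index)
    return pd.DataFrame(dict(name=names, x=xs, y=ys, z=zs,
                             track_id=tracks, voxel_index=voxels),
                        columns=SPECIES_COLUMNS)
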