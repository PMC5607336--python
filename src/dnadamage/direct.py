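"""Direct strand breaks from energy deposits in the DNA backbone.

Energy deposited in the phosphate, 2-deoxyribose and strand-assigned
hydration-shell volumes of a nucleotide is accumulated per
(event, chromosome, bp, strand) site; base deposits never contribute.
A site becomes a direct strand break either when the accumulated energy
reaches a threshold (default 17.5 eV, variants 12.5 and 30 eV) or, in
linear mode, with a probability that ramps from 0 below 5 eV to 1 above
37.5 eV. At most one direct break is scored per site and event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (DIRECT_LINEAR_HI_EV, DIRECT_LINEAR_LO_EV,
                        DIRECT_THRESHOLD_EV)
from .errors import ConfigurationError

BACKBONE_KINDS = frozenset({"phosphate", "deoxyribose", "hydration_shell"})
KNOWN_KINDS = BACKBONE_KINDS | {"adenine", "cytosine", "guanine", "thymine",
                                "histone"}

SB_COLUMNS = ["chromosome", "bp", "strand", "origin", "track_id"]


@dataclass(frozen=True)
class DirectCriterion:
    """Selection rule converting backbone energy into a strand break."""

    mode: str = "threshold"            # "threshold" or "linear"
    threshold_ev: float = DIRECT_THRESHOLD_EV
    linear_lo_ev: float = DIRECT_LINEAR_LO_EV
    linear_hi_ev: float = DIRECT_LINEAR_HI_EV

    def __post_init__(self):
        if self.mode not in ("threshold", "linear"):
            raise ConfigurationError(f"unknown criterion mode {self.mode!r}")
        if self.threshold_ev <= 0:
            raise ConfigurationError("threshold must be positive")
        if self.linear_lo_ev > self.linear_hi_ev:
            raise ConfigurationError("linear ramp bounds are inverted")

    def probability(self, energy_ev) -> np.ndarray:
        """Break probability for accumulated energies (vectorised)."""
        e = np.asarray(energy_ev, dtype=float)
        if self.mode == "threshold":
            return (e >= self.threshold_ev).astype(float)
        if self.linear_lo_ev == self.linear_hi_ev:  # degenerate ramp
            return (e >= self.linear_lo_ev).astype(float)
        return np.clip((e - self.linear_lo_ev)
                       / (self.linear_hi_ev - self.linear_lo_ev), 0.0, 1.0)


def accumulate_backbone_energy(dataset1: pd.DataFrame,
                               include_labels=None) -> pd.DataFrame:
    """Sum backbone energy per (track_id, chromosome, bp, strand).

    ``include_labels`` restricts the interaction labels that contribute
    (default: all). Base and histone deposits are excluded by the backbone
    rule; an unknown volume kind raises.
    """
    if len(dataset1) == 0:
        return pd.DataFrame(columns=["track_id", "chromosome", "bp",
                                     "strand", "energy_ev"])
    unknown = set(dataset1["kind"].unique()) - KNOWN_KINDS - {""}
    if unknown:
        raise ConfigurationError(
            f"records with unknown volume kind: {sorted(unknown)}")
    df = dataset1[dataset1["kind"].isin(BACKBONE_KINDS)]
    if include_labels is not None:
        df = df[df["label"].isin(set(include_labels))]
    if len(df) == 0:
        return pd.DataFrame(columns=["track_id", "chromosome", "bp",
                                     "strand", "energy_ev"])
    grouped = (df.groupby(["track_id", "chromosome", "bp", "strand"],
                          sort=True)["energy_ev"].sum().reset_index())
    return grouped


def score_direct_breaks(energy_map: pd.DataFrame,
                        criterion: DirectCriterion,
                        rng=None) -> pd.DataFrame:
    """Apply the criterion to an accumulated-energy map.

    Threshold mode is deterministic; linear mode draws one uniform variate
    per site (``rng`` required). Returns a strand-break table with
    origin='direct'.
    """
    if len(energy_map) == 0:
        return pd.DataFrame(columns=SB_COLUMNS)
    e = energy_map["energy_ev"].to_numpy(dtype=float)
    if (e < 0).any():
        raise ConfigurationError("negative accumulated energy")
    p = criterion.probability(e)
    if criterion.mode == "threshold":
        accept = p >= 1.0
    else:
        if rng is None:
            raise ConfigurationError("linear criterion requires an rng")
        accept = rng.random(len(e)) < p
    hits = energy_map[accept]
    return pd.DataFrame(dict(
        chromosome=hits["chromosome"].to_numpy(),
        bp=hits["bp"].to_numpy(),
        strand=hits["strand"].to_numpy(),
        origin="direct",
        track_id=hits["track_id"].to_numpy()), columns=SB_COLUMNS)


def dedupe_breaks(sbs: pd.DataFrame, per_event: bool = True) -> pd.DataFrame:
    """Collapse repeated breaks at one site (a site is broken once)."""
    keys = ["chromosome", "bp", "strand"]
    if per_event:
        keys = ["track_id"] + keys
    return sbs.drop_duplicates(subset=keys).reset_index(drop=True)
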