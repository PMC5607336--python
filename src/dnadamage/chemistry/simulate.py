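"""Chemical stage: Brownian diffusion-reaction simulation per voxel/track.

Mobile radiolysis species random-walk with per-axis Gaussian displacements
(variance 2 D dt); static DNA molecules and histones never move. A pair
reacts when the end-of-step distance is within its encounter radius, or
with the Brownian-bridge probability for within-step passages. Reactants
are removed (the histone absorber persists), products appear at the
reactant midpoint, and every reaction is logged with its time, position and
-- for DNA reactants -- the genomic address. The simulation is confined to
one voxel (reflecting walls by default) and one track, and stops at the
configured cutoff (default 2.5 ns), which together stand in for radical
scavenging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..constants import CHEMISTRY_T_END_NS
from ..errors import ConfigurationError
from .kinetics import brownian_bridge_reaction_prob, rate_to_reaction_radius
from .species import (ReactionTable, SpeciesSpec, contact_distance,
                      default_species)

EVENT_COLUMNS = ["time_ns", "reactant_a", "reactant_b", "products",
                 "x", "y", "z", "chromosome", "bp", "strand",
                 "voxel_index", "track_id"]

#: geometric time-step ladder: (dt_ns, until_ns); fine steps early, when the
#: species distribution is still strongly clustered, coarser later
DEFAULT_SCHEDULE = ((1e-4, 1e-2), (5e-4, 1e-1), (2e-3, 5e-1),
                    (5e-3, CHEMISTRY_T_END_NS))

_NM2_PER_NS_PER_M2_S = 1e9  # 1 m^2/s = 1e9 nm^2/ns


@dataclass
class ChemistryConfig:
    t_end_ns: float = CHEMISTRY_T_END_NS
    step_schedule: tuple = DEFAULT_SCHEDULE
    dissociation_radius_nm: float = 1.0
    boundary: str = "reflect"          # or "absorb"
    candidate_sigmas: float = 3.0      # search margin in step widths

    def __post_init__(self):
        if self.t_end_ns <= 0:
            raise ConfigurationError("t_end must be positive")
        if self.boundary not in ("reflect", "absorb"):
            raise ConfigurationError(f"unknown boundary {self.boundary!r}")
        last = 0.0
        for dt, until in self.step_schedule:
            if dt <= 0 or until <= last:
                raise ConfigurationError("invalid step schedule")
            last = until
        if last < self.t_end_ns:
            raise ConfigurationError(
                "step schedule does not cover [0, t_end]")

    def steps(self):
        """Yield (t_start_ns, dt_ns) covering [0, t_end]."""
        t = 0.0
        for dt, until in self.step_schedule:
            until = min(until, self.t_end_ns)
            while t < until - 1e-12:
                step = min(dt, until - t)
                yield t, step
                t += step
            if t >= self.t_end_ns - 1e-12:
                return


def _reflect(pos, lo, hi):
    span = hi - lo
    q = np.mod(pos - lo, 2.0 * span)
    q = np.where(q > span, 2.0 * span - q, q)
    return lo + q


class _Radii:
    """Cache of encounter radii per species pair."""

    def __init__(self, table: ReactionTable, species: dict[str, SpeciesSpec]):
        self.table = table
        self.species = species
        self._cache: dict[frozenset, float] = {}

    def radius(self, a: str, b: str) -> float | None:
        key = frozenset((a, b))
        if key in self._cache:
            return self._cache[key]
        r = self.table.lookup(a, b)
        if r is None:
            out = None
        elif r.rate_m_s is None:  # contact reaction (histone absorber)
            out = contact_distance(self.species, a, b)
        else:
            sa, sb = self.species[a], self.species[b]
            d = sa.diffusion_m2_s + sb.diffusion_m2_s
            out = rate_to_reaction_radius(r.rate_m_s, d) if d > 0 else None
        self._cache[key] = out
        return out


def simulate_voxel_chemistry(initial_species: pd.DataFrame,
                             dna: pd.DataFrame,
                             reactions: ReactionTable,
                             config: ChemistryConfig,
                             rng,
                             box=None,
                             species_table=None,
                             voxel_index: int = -1,
                             track_id: int = -1,
                             static_tree: cKDTree | None = None) -> pd.DataFrame:
    """Run the diffusion-reaction walk for one (voxel, track) pair.

    ``initial_species``: columns name,x,y,z (mobile radicals after
    dissociation). ``dna``: columns name,x,y,z,chromosome,bp,strand (static
    molecules; histone rows use bp=-1, strand=0). ``box``: ((lo), (hi))
    bounds in nm; None disables walls. A prebuilt KD-tree over the dna
    positions may be passed to amortise construction across tracks.
    """
    species = default_species() if species_table is None else species_table
    radii = _Radii(reactions, species)

    names = initial_species["name"].to_numpy(dtype=object).copy()
    pos = initial_species[["x", "y", "z"]].to_numpy(dtype=float).copy()
    alive = np.ones(len(names), dtype=bool)

    s_names = dna["name"].to_numpy(dtype=object)
    s_pos = dna[["x", "y", "z"]].to_numpy(dtype=float)
    s_alive = np.ones(len(s_names), dtype=bool)
    s_chrom = dna["chromosome"].to_numpy(dtype=object) if len(dna) else \
        np.empty(0, dtype=object)
    s_bp = dna["bp"].to_numpy() if len(dna) else np.empty(0, dtype=int)
    s_strand = dna["strand"].to_numpy() if len(dna) else np.empty(0, dtype=int)
    tree = static_tree
    if tree is None and len(s_pos):
        tree = cKDTree(s_pos)

    # largest encounter radius against statics, for the candidate search
    static_kinds = sorted(set(s_names)) if len(s_names) else []
    max_static_r = 0.0
    for sk in static_kinds:
        for mk in set(species) - set(static_kinds):
            r = radii.radius(mk, sk)
            if r:
                max_static_r = max(max_static_r, r)

    mobile_kinds = [k for k, s in species.items() if s.diffusion_m2_s > 0]
    max_mm_r = 0.0
    for a in mobile_kinds:
        for b in mobile_kinds:
            r = radii.radius(a, b)
            if r:
                max_mm_r = max(max_mm_r, r)
    mm_pairs_exist = max_mm_r > 0.0

    events: list[tuple] = []
    if box is not None:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)

    for t, dt_ns in config.steps():
        idx_alive = np.nonzero(alive)[0]
        if len(idx_alive) == 0:
            break
        dt_s = dt_ns * 1e-9
        d_coef = np.array([species[n].diffusion_m2_s for n in names[idx_alive]])
        sigma = np.sqrt(2.0 * d_coef * _NM2_PER_NS_PER_M2_S * dt_ns)
        prev = pos[idx_alive].copy()
        stepped = prev + rng.normal(size=(len(idx_alive), 3)) * sigma[:, None]
        if box is not None:
            if config.boundary == "reflect":
                stepped = _reflect(stepped, lo, hi)
            else:
                gone = ((stepped < lo) | (stepped > hi)).any(axis=1)
                alive[idx_alive[gone]] = False
        pos[idx_alive] = stepped

        candidates = []  # (d_end, order_key, kind, i, j)
        sigma_max = sigma.max() if len(sigma) else 0.0
        # mobile vs static
        if tree is not None and max_static_r > 0.0:
            search = max_static_r + config.candidate_sigmas * sigma_max
            hits = tree.query_ball_point(pos[idx_alive], search)
            for k, js in enumerate(hits):
                i = idx_alive[k]
                if not alive[i]:
                    continue
                for j in js:
                    if not s_alive[j]:
                        continue
                    r = radii.radius(names[i], s_names[j])
                    if not r:
                        continue
                    d1 = float(np.linalg.norm(pos[i] - s_pos[j]))
                    if d1 <= r:
                        candidates.append((d1, (0, i, j), "ms", i, j))
                    else:
                        d0 = float(np.linalg.norm(prev[k] - s_pos[j]))
                        p = brownian_bridge_reaction_prob(
                            d0, d1, r,
                            species[names[i]].diffusion_m2_s, dt_s)
                        if rng.random() < p:
                            candidates.append((d1, (0, i, j), "ms", i, j))
        # mobile vs mobile
        if mm_pairs_exist and len(idx_alive) > 1:
            mtree = cKDTree(pos[idx_alive])
            search_mm = max_mm_r + config.candidate_sigmas * sigma_max
            for ka, kb in mtree.query_pairs(search_mm):
                i, j = idx_alive[ka], idx_alive[kb]
                r = radii.radius(names[i], names[j])
                if not r:
                    continue
                d1 = float(np.linalg.norm(pos[i] - pos[j]))
                if d1 <= r:
                    candidates.append((d1, (1, i, j), "mm", i, j))
                else:
                    d0 = float(np.linalg.norm(prev[ka] - prev[kb]))
                    dmut = (species[names[i]].diffusion_m2_s
                            + species[names[j]].diffusion_m2_s)
                    p = brownian_bridge_reaction_prob(d0, d1, r, dmut, dt_s)
                    if d1 <= r or rng.random() < p:
                        candidates.append((d1, (1, i, j), "mm", i, j))

        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        new_names, new_pos = [], []
        for d1, _, kind, i, j in candidates:
            if kind == "ms":
                if not (alive[i] and s_alive[j]):
                    continue
                spec = reactions.lookup(names[i], s_names[j])
                alive[i] = False
                if not spec.preserve_first:
                    s_alive[j] = False
                mid = 0.5 * (pos[i] + s_pos[j])
                addr = (s_chrom[j], int(s_bp[j]), int(s_strand[j]))
            else:
                if not (alive[i] and alive[j]):
                    continue
                spec = reactions.lookup(names[i], names[j])
                alive[i] = False
                alive[j] = False
                mid = 0.5 * (pos[i] + pos[j])
                addr = ("", -1, 0)
            for pname in spec.products:
                new_names.append(pname)
                new_pos.append(mid)
            other = s_names[j] if kind == "ms" else names[j]
            events.append((t + dt_ns, names[i], other,
                           "+".join(spec.products), mid[0], mid[1], mid[2],
                           addr[0], addr[1], addr[2], voxel_index, track_id))
        if new_names:
            names = np.concatenate([names, np.array(new_names, dtype=object)])
            pos = np.vstack([pos, np.array(new_pos)])
            alive = np.concatenate([alive, np.ones(len(new_names), bool)])

    return pd.DataFrame(events, columns=EVENT_COLUMNS)
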