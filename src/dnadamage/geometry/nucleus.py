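"""Nucleus-scale genome geometry.

The cell nucleus is an ellipsoid filled hierarchically: each chromosome copy
owns a territory, a territory owns spherical chromatin domains (default
radius 500 nm), and each domain is filled with chromatin voxels placed on a
50 nm cubic grid clipped to the domain sphere. The sequence of voxel kinds
along the fill path forms a continuous fibre: the exit face of each voxel
abuts the entry face of the next. Nucleotide-pair indices run consecutively
along the path, so the genomic index maps any placed volume to
(chromosome copy, bp, strand).

Territory placement is a direct non-overlapping sphere packing around a
random territory centre (a simplification of a condensation/relaxation
simulation, which is out of scope here); domains of one chromosome stay
within a compact ball, giving a contiguous territory region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..constants import (DOMAIN_RADIUS_NM, NUCLEUS_HALF_AXES_UM,
                         default_territory_table)
from ..errors import ConfigurationError, GeometryStateError, PackingError
from .voxel import Voxel, build_voxel, default_voxel_library

BASE_CODES = ("adenine", "cytosine", "guanine", "thymine")
BASE_LETTERS = "ACGT"

_AXIS_DIRS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int)

# canonical rotation taking the local +z (voxel entry direction) onto each
# axis direction; signed permutation matrices, det +1
_CANONICAL_ROT = {
    (0, 0, 1): np.eye(3, dtype=int),
    (0, 0, -1): np.diag([1, -1, -1]).astype(int),
    (1, 0, 0): np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]]),
    (-1, 0, 0): np.array([[0, 0, -1], [0, 1, 0], [1, 0, 0]]),
    (0, 1, 0): np.array([[1, 0, 0], [0, 0, 1], [0, -1, 0]]),
    (0, -1, 0): np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]]),
}

_LOCAL_EXIT = {
    "straight": np.array([0, 0, 1]),
    "right": np.array([1, 0, 0]),
    "left": np.array([-1, 0, 0]),
    "up": np.array([0, 1, 0]),
    "down": np.array([0, -1, 0]),
}
_KIND_FROM_EXIT = {tuple(v): k for k, v in _LOCAL_EXIT.items()}


@dataclass
class TerritorySpec:
    chromosome_id: str
    n_domains: int
    bp_length: int | None = None


def default_territories() -> list[TerritorySpec]:
    """The 46 chromosome copies with their default domain counts."""
    return [TerritorySpec(cid, n) for cid, n in default_territory_table()]


@dataclass
class PlacedVoxel:
    kind: str
    center: np.ndarray          # nm, nucleus frame
    rotation: np.ndarray        # (3,3) signed permutation, local -> global
    bp_start: int               # chromosome-local index of the first pair
    n_bp: int

    @property
    def entry_dir(self) -> np.ndarray:
        return self.rotation @ np.array([0, 0, 1])

    @property
    def exit_dir(self) -> np.ndarray:
        return self.rotation @ _LOCAL_EXIT[self.kind]


@dataclass
class Domain:
    domain_id: int
    chromosome_id: str
    center: np.ndarray
    radius: float
    placements: list[PlacedVoxel] = field(default_factory=list)
    sequence: np.ndarray | None = None  # strand-1 base codes, one per pair
    bp_start: int = 0                   # chromosome-local

    @property
    def n_bp(self) -> int:
        return int(sum(p.n_bp for p in self.placements))


class NucleusModel:
    """Hierarchical genome geometry plus the genomic index."""

    def __init__(self, half_axes_nm, territories: list[TerritorySpec],
                 domains: list[Domain] | None = None,
                 voxel_specs: dict | None = None):
        self.half_axes_nm = np.asarray(half_axes_nm, dtype=float)
        if np.any(self.half_axes_nm <= 0):
            raise ConfigurationError("nucleus half axes must be positive")
        self.territories = list(territories)
        self.domains = list(domains) if domains else []
        self.voxel_specs = voxel_specs  # None means package defaults
        self._index = None

    # -- bookkeeping --------------------------------------------------------

    @property
    def total_bp(self) -> int:
        return int(sum(d.n_bp for d in self.domains))

    def chromosome_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.domains:
            out[d.chromosome_id] = out.get(d.chromosome_id, 0) + d.n_bp
        for t in self.territories:
            out.setdefault(t.chromosome_id, 0)
        return out

    def domains_of(self, chromosome_id: str) -> list[Domain]:
        return [d for d in self.domains if d.chromosome_id == chromosome_id]

    def voxel_library(self) -> dict[str, Voxel]:
        if self.voxel_specs is None:
            return default_voxel_library()
        return {k: build_voxel(k, spec) for k, spec in self.voxel_specs.items()}

    # -- spatial queries ----------------------------------------------------

    def build_index(self):
        from .locate import GeometryIndex
        self._index = GeometryIndex(self)
        return self._index

    @property
    def index(self):
        if self._index is None:
            raise GeometryStateError(
                "model is not indexed for spatial queries; "
                "call build_index() first")
        return self._index

    def locate(self, points):
        return self.index.locate(points)


# ---------------------------------------------------------------------------
# Layout: territory and domain placement
# ---------------------------------------------------------------------------

def _sample_in_ellipsoid(half_axes, rng, n=1):
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 8, 3))
        ok = (cand**2).sum(axis=1) <= 1.0
        take = cand[ok][: n - filled]
        out[filled:filled + len(take)] = take * half_axes
        filled += len(take)
    return out


def build_nucleus_layout(territories, rng,
                         half_axes_nm=None,
                         domain_radius_nm=DOMAIN_RADIUS_NM,
                         packing_fraction=0.35,
                         max_domain_retries=400,
                         max_territory_retries=8) -> NucleusModel:
    """Place the domain spheres of every territory inside the ellipsoid.

    Domains are non-overlapping, fully inside the nucleus, and those of one
    chromosome are grouped around a common territory centre. Raises
    PackingError (reporting the achieved fraction) when the requested volume
    does not fit or placement fails after bounded retries.
    """
    if half_axes_nm is None:
        half_axes_nm = np.array(NUCLEUS_HALF_AXES_UM) * 1000.0
    half_axes_nm = np.asarray(half_axes_nm, dtype=float)
    r = float(domain_radius_nm)
    inner = half_axes_nm - r
    if np.any(inner <= 0):
        raise PackingError(
            f"domain radius {r} nm does not fit inside half axes "
            f"{half_axes_nm} nm", 0.0)

    n_total = sum(t.n_domains for t in territories)
    v_req = n_total * 4.0 / 3.0 * np.pi * r**3
    v_nuc = 4.0 / 3.0 * np.pi * np.prod(half_axes_nm)
    if v_req > packing_fraction * v_nuc:
        raise PackingError(
            f"requested {n_total} domains occupy "
            f"{v_req / v_nuc:.2f} of the nucleus volume, above the "
            f"packing fraction {packing_fraction}", 0.0)

    placed = np.empty((0, 3))
    domains: list[Domain] = []
    n_done = 0
    for terr in territories:
        ok = False
        for _ in range(max_territory_retries):
            t_center = _sample_in_ellipsoid(inner, rng, 1)[0]
            # compact ball holding n_domains spheres at moderate packing
            ball = r * (1.0 + 1.9 * terr.n_domains ** (1.0 / 3.0))
            centers: list[np.ndarray] = []
            tries = 0
            while len(centers) < terr.n_domains and tries < max_domain_retries:
                tries += 1
                c = t_center + _sample_in_ellipsoid(
                    np.full(3, ball), rng, 1)[0]
                if ((c / inner) ** 2).sum() > 1.0:
                    continue
                pool = placed if not centers else np.vstack(
                    [placed, np.stack(centers)])
                if len(pool) and (np.linalg.norm(
                        pool - c[None, :], axis=1) < 2.0 * r).any():
                    continue
                centers.append(c)
            if len(centers) == terr.n_domains:
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place the {terr.n_domains} domains of chromosome "
                f"{terr.chromosome_id}; achieved fraction "
                f"{n_done / n_total:.2f}", n_done / n_total)
        for c in centers:
            domains.append(Domain(domain_id=len(domains),
                                  chromosome_id=terr.chromosome_id,
                                  center=c, radius=r))
        placed = np.vstack([placed, np.stack(centers)])
        n_done += terr.n_domains
    return NucleusModel(half_axes_nm, territories, domains)


# ---------------------------------------------------------------------------
# Domain filling: self-avoiding voxel walk on the 50 nm grid
# ---------------------------------------------------------------------------

def fill_domain(domain: Domain, voxel_library: dict[str, Voxel], rng,
                bp_target: int | None = None,
                backtrack_budget: int = 2000) -> list[PlacedVoxel]:
    """Fill a domain with a continuous self-avoiding fibre of voxels.

    Voxels sit on a cubic grid (voxel edge spacing) clipped so every cube
    lies fully inside the domain sphere. The walk extends straight or turns
    (one of the four turn kinds); at a dead end it backtracks within a
    bounded budget. If a bp target is requested and cannot be reached, a
    partial-fill warning reports the achieved count.
    """
    edge = next(iter(voxel_library.values())).spec.edge_nm
    half_diag = edge / 2.0 * np.sqrt(3.0)
    reach = domain.radius - half_diag
    if reach < 0:
        warnings.warn(
            f"domain {domain.domain_id}: radius {domain.radius} nm is too "
            "small for a voxel; 0 voxels placed", stacklevel=2)
        domain.placements = []
        domain.sequence = np.empty(0, dtype=np.uint8)
        return []

    m = int(reach // edge)
    cells = {
        (i, j, k)
        for i in range(-m, m + 1)
        for j in range(-m, m + 1)
        for k in range(-m, m + 1)
        if edge * np.sqrt(i * i + j * j + k * k) <= reach
    }
    n_bp_of = {k: v.n_bp for k, v in voxel_library.items()}
    target = bp_target if bp_target is not None else sum(
        n_bp_of.values()) / len(n_bp_of) * len(cells)

    start = (0, 0, 0) if (0, 0, 0) in cells else min(
        cells, key=lambda c: sum(x * x for x in c))
    d0 = _AXIS_DIRS[rng.integers(0, 6)]

    # DFS over (cell, d_in) states with bounded backtracking
    best_path: list[tuple[tuple, np.ndarray, str]] = []
    path: list[tuple[tuple, np.ndarray, str]] = []  # (cell, d_in, kind)
    visited = {start}
    pops = 0

    def options(cell, d_in):
        opts = []
        rot = _CANONICAL_ROT[tuple(d_in)]
        for d_out in rng.permutation(6):
            d = _AXIS_DIRS[d_out]
            if np.array_equal(d, -d_in):
                continue
            nxt = (cell[0] + d[0], cell[1] + d[1], cell[2] + d[2])
            local_exit = tuple(rot.T @ d)
            kind = _KIND_FROM_EXIT[local_exit]
            opts.append((kind, d, nxt, nxt in cells and nxt not in visited))
        return opts

    stack = [(start, d0, iter(options(start, d0)))]
    while stack:
        cell, d_in, it = stack[-1]
        advanced = False
        for kind, d_out, nxt, legal in it:
            if not legal:
                continue
            path.append((cell, d_in, kind))
            visited.add(nxt)
            stack.append((nxt, d_out, iter(options(nxt, d_out))))
            advanced = True
            break
        if advanced:
            if sum(n_bp_of[k] for _, _, k in path) >= target:
                best_path = list(path)
                break
            continue
        # dead end: close the fibre with a terminal voxel, then backtrack
        terminal = path + [(cell, d_in, "straight")]
        if (sum(n_bp_of[k] for _, _, k in terminal)
                > sum(n_bp_of[k] for _, _, k in best_path)):
            best_path = terminal
        pops += 1
        if pops > backtrack_budget:
            break
        stack.pop()          # abandon this dead-end cell ...
        visited.discard(cell)
        if path:             # ... and the move that led into it
            path.pop()

    if not best_path:
        best_path = path + [(stack[-1][0], stack[-1][1], "straight")] if stack else []

    placements: list[PlacedVoxel] = []
    bp = 0
    for cell, d_in, kind in best_path:
        rot = _CANONICAL_ROT[tuple(d_in)].astype(int)
        center = domain.center + edge * np.array(cell, dtype=float)
        placements.append(PlacedVoxel(kind=kind, center=center,
                                      rotation=rot, bp_start=bp,
                                      n_bp=n_bp_of[kind]))
        bp += n_bp_of[kind]

    if bp_target is not None and bp < bp_target:
        warnings.warn(
            f"domain {domain.domain_id}: partial fill, achieved {bp} bp of "
            f"the {bp_target} bp target", stacklevel=2)
    domain.placements = placements
    return placements


def build_nucleus(territories, seed_or_rng,
                  half_axes_nm=None,
                  domain_radius_nm=DOMAIN_RADIUS_NM,
                  voxel_specs: dict | None = None) -> NucleusModel:
    """Layout + fill + sequence assignment: the complete genome model."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    model = build_nucleus_layout(territories, rng, half_axes_nm=half_axes_nm,
                                 domain_radius_nm=domain_radius_nm)
    model.voxel_specs = voxel_specs
    library = model.voxel_library()
    offsets: dict[str, int] = {}
    for domain in model.domains:
        fill_domain(domain, library, rng)
        ofs = offsets.get(domain.chromosome_id, 0)
        domain.bp_start = ofs
        for p in domain.placements:
            p.bp_start += ofs
        domain.sequence = rng.integers(
            0, 4, size=domain.n_bp).astype(np.uint8)
        offsets[domain.chromosome_id] = ofs + domain.n_bp
    for terr in model.territories:
        terr.bp_length = offsets.get(terr.chromosome_id, 0)
    return model


def check_fibre_continuity(domain: Domain, edge_nm: float = 50.0) -> bool:
    """Face-adjacency check: exit face of voxel i abuts entry face of i+1."""
    ps = domain.placements
    for a, b in zip(ps, ps[1:]):
        step = (b.center - a.center) / edge_nm
        if not np.allclose(step, a.exit_dir, atol=1e-9):
            return False
        if not np.allclose(b.entry_dir, a.exit_dir, atol=1e-9):
            return False
    return True
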