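"""Chromatin-voxel templates.

A voxel is a 50 nm cube containing a shaped piece of chromatin fibre. Five
kinds tile the genome: ``straight`` (fibre axis crossing between opposite
faces) and four quarter-turn kinds (``up``, ``down``, ``right``, ``left``)
whose fibre axis is a quarter circle joining the entry face to an orthogonal
exit face. Nucleosomes sit on a solenoid around the fibre axis (6 per turn,
helix diameter 10.46 nm, pitch per kind); the DNA path wraps ~1.65 left-handed
turns around each histone sphere and runs through straight linkers between
nucleosomes, entering and exiting the cube at the face centres.

Nucleotide pairs are placed at uniform arc-length spacing along the DNA path.
The per-kind pair totals are not integer multiples of the nucleosome count, so
pairs are apportioned to the path segments proportionally to arc length and
rounded with the largest-remainder rule, which makes the totals match the
configured counts exactly.

A template is geometry only: the base sequence is drawn when the voxel is
placed in a domain, because base identity does not alter the sphere layout
(all four bases share the same radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from ..constants import HISTONE_RADIUS_NM, VOXEL_COMMON, VOXEL_KINDS, VOXEL_TABLE
from ..errors import ConfigurationError, ConstructionError
from . import constituents as cst

# DNA wrap around the histone complex: canonical nucleosome-like superhelix
WRAP_RADIUS_NM = 3.3
WRAP_PITCH_NM = 2.4
WRAP_TURNS = 1.65
PAIR_ENVELOPE_NM = 1.25  # max lateral extent of a pair (hydration shell)
TWIST_PER_BP_DEG = 36.0

_EXIT_FACE = {"straight": "+z", "right": "+x", "left": "-x", "up": "+y", "down": "-y"}
_FACE_DIR = {
    "+x": np.array([1, 0, 0]), "-x": np.array([-1, 0, 0]),
    "+y": np.array([0, 1, 0]), "-y": np.array([0, -1, 0]),
    "+z": np.array([0, 0, 1]), "-z": np.array([0, 0, -1]),
}


@dataclass(frozen=True)
class VoxelSpec:
    """Geometric parameters of one voxel kind (defaults per configuration)."""

    kind: str
    n_nucleosomes: int
    n_bp: int
    pitch_nm: float
    helix_diameter_nm: float = VOXEL_COMMON["helix_diameter_nm"]
    nucleosomes_per_turn: int = VOXEL_COMMON["nucleosomes_per_turn"]
    delta_angle_deg: float = VOXEL_COMMON["delta_angle_deg"]
    fibre_radius_nm: float = VOXEL_COMMON["fibre_radius_nm"]
    fibre_length_nm: float = 50.0
    edge_nm: float = VOXEL_COMMON["edge_nm"]

    @staticmethod
    def default(kind: str) -> "VoxelSpec":
        if kind not in VOXEL_TABLE:
            raise ConfigurationError(
                f"unknown voxel kind {kind!r}; expected one of {VOXEL_KINDS}")
        row = VOXEL_TABLE[kind]
        return VoxelSpec(kind=kind, **row)

    def validate(self) -> None:
        if self.kind not in VOXEL_TABLE:
            raise ConfigurationError(
                f"unknown voxel kind {self.kind!r}; expected one of {VOXEL_KINDS}")
        for name in ("n_nucleosomes", "n_bp", "pitch_nm", "helix_diameter_nm",
                     "nucleosomes_per_turn", "edge_nm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"VoxelSpec.{name} must be positive")


def largest_remainder(weights, total: int) -> np.ndarray:
    """Apportion ``total`` integer counts proportionally to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _fibre_axis(kind: str, edge: float):
    """Axis curve of the fibre: (point(s), tangent(s), normal_frame(s), length).

    Returns callables p(s), t(s), (e1(s), e2(s)) for arc length s, plus the
    total length. e1/e2 span the plane normal to the tangent and are
    continuous along the axis.
    """
    h = edge / 2.0
    if kind == "straight":
        L = edge

        def p(s):
            s = np.atleast_1d(np.asarray(s, float))
            out = np.zeros((len(s), 3))
            out[:, 2] = s - h
            return out

        def t(s):
            s = np.atleast_1d(s)
            return np.tile([0.0, 0.0, 1.0], (len(s), 1))

        def frame(s):
            s = np.atleast_1d(s)
            e1 = np.tile([1.0, 0.0, 0.0], (len(s), 1))
            e2 = np.tile([0.0, 1.0, 0.0], (len(s), 1))
            return e1, e2

        return p, t, frame, L

    exit_dir = _FACE_DIR[_EXIT_FACE[kind]].astype(float)
    # quarter circle of radius h from the entry face centre (0,0,-h) with
    # initial tangent +z to the exit face centre, bending toward exit_dir
    center = exit_dir * h + np.array([0.0, 0.0, -h])
    L = h * math.pi / 2.0
    out_of_plane = np.cross(np.array([0.0, 0.0, 1.0]), exit_dir)

    def p(s):
        s = np.atleast_1d(np.asarray(s, float))
        alpha = s / h
        return (center[None, :]
                - np.cos(alpha)[:, None] * (exit_dir * h)[None, :]
                + np.sin(alpha)[:, None] * np.array([0.0, 0.0, h])[None, :])

    def t(s):
        s = np.atleast_1d(np.asarray(s, float))
        alpha = s / h
        return (np.sin(alpha)[:, None] * exit_dir[None, :]
                + np.cos(alpha)[:, None] * np.array([0.0, 0.0, 1.0])[None, :])

    def frame(s):
        s = np.atleast_1d(np.asarray(s, float))
        alpha = s / h
        e1 = (-np.cos(alpha)[:, None] * exit_dir[None, :]
              + np.sin(alpha)[:, None] * np.array([0.0, 0.0, 1.0])[None, :])
        e2 = np.tile(out_of_plane, (len(s), 1))
        return e1, e2

    return p, t, frame, L


def _wrap_path(center, axis_dir, tangent, n_samples=160):
    """DNA superhelix around one histone: sample points along the wrap."""
    a = axis_dir / np.linalg.norm(axis_dir)
    b1 = tangent - np.dot(tangent, a) * a
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(a, b1)
    tau = np.linspace(0.0, WRAP_TURNS, n_samples)
    ang = 2.0 * math.pi * tau + math.pi  # start on the incoming-fibre side
    pts = (center[None, :]
           + WRAP_RADIUS_NM * (np.cos(ang)[:, None] * b1[None, :]
                               + np.sin(ang)[:, None] * b2[None, :])
           + WRAP_PITCH_NM * (tau - WRAP_TURNS / 2.0)[:, None] * a[None, :])
    return pts


class Voxel:
    """An assembled voxel template: DNA path, pair frames, constituents.

    Attributes
    ----------
    pair_pos : (n_bp, 3) pair-centre positions, local cube frame (nm)
    pair_rot : (n_bp, 3, 3) rotation matrices; column 0 is the strand-1
        azimuth, column 2 the local helix tangent
    histone_pos : (n_nucleosomes, 3)
    segment_bp_counts : pairs apportioned to each path segment
    cons_pos/cons_radius/cons_kind/cons_strand/cons_bp : packed constituent
        arrays (6 spheres per pair)
    """

    def __init__(self, spec: VoxelSpec, pair_pos, pair_rot, histone_pos,
                 segment_bp_counts, entry_point, exit_point):
        self.spec = spec
        self.kind = spec.kind
        self.pair_pos = pair_pos
        self.pair_rot = pair_rot
        self.histone_pos = histone_pos
        self.segment_bp_counts = segment_bp_counts
        self.entry_point = entry_point
        self.exit_point = exit_point
        self.entry_face = "-z"
        self.exit_face = _EXIT_FACE[spec.kind]
        self._build_constituents()

    @property
    def n_bp(self) -> int:
        return len(self.pair_pos)

    @property
    def n_nucleosomes(self) -> int:
        return len(self.histone_pos)

    def _build_constituents(self):
        local_c, local_r, local_k, local_s = cst.pair_local_layout()
        n = self.n_bp
        # global = pair_pos + R @ local for each of the 6 constituents
        pos = (self.pair_pos[:, None, :]
               + np.einsum("nij,cj->nci", self.pair_rot, local_c))
        self.cons_pos = pos.reshape(n * 6, 3)
        self.cons_radius = np.tile(local_r, n)
        self.cons_kind = np.tile(local_k, n)
        self.cons_strand = np.tile(local_s, n)
        self.cons_bp = np.repeat(np.arange(n), 6)

    def constituent(self, index: int) -> cst.ConstituentSpec:
        """Object view of one constituent with its radical-plane cuts."""
        c = self.cons_pos[index]
        r = self.cons_radius[index]
        d = np.linalg.norm(self.cons_pos - c[None, :], axis=1)
        neighbours = np.nonzero((d < r + self.cons_radius) & (d > 1e-12))[0]
        planes = tuple(
            cst.radical_plane(c, r, self.cons_pos[j], self.cons_radius[j])
            for j in neighbours)
        return cst.ConstituentSpec(
            kind=cst.KIND_NAMES[int(self.cons_kind[index])],
            radius=float(r), center=c.copy(),
            bp_index=int(self.cons_bp[index]),
            strand=int(self.cons_strand[index]),
            cut_planes=planes)


def build_voxel(kind: str, spec: VoxelSpec | None = None) -> Voxel:
    """Assemble the voxel template for ``kind``.

    Raises ConfigurationError for an unknown kind and ConstructionError when
    the pair count cannot be distributed over the nucleosome + linker layout.
    """
    if spec is None:
        spec = VoxelSpec.default(kind)
    elif spec.kind != kind:
        spec = replace(spec, kind=kind)
    spec.validate()

    if spec.n_bp < 2 * spec.n_nucleosomes:
        raise ConstructionError(
            f"{spec.n_bp} pairs cannot be distributed over "
            f"{spec.n_nucleosomes} nucleosomes plus linkers "
            "(need at least 2 pairs per nucleosome segment)")

    p, t, frame, L = _fibre_axis(kind, spec.edge_nm)
    n_nuc = spec.n_nucleosomes
    ds = spec.pitch_nm / spec.nucleosomes_per_turn
    span = (n_nuc - 1) * ds
    if span >= L:
        raise ConstructionError(
            f"{n_nuc} nucleosomes at pitch {spec.pitch_nm} nm do not fit on a "
            f"{L:.1f} nm fibre axis")
    s_k = L / 2.0 + (np.arange(n_nuc) - (n_nuc - 1) / 2.0) * ds
    theta = np.deg2rad(spec.delta_angle_deg) * np.arange(n_nuc)
    axis_pts = p(s_k)
    tangents = t(s_k)
    e1, e2 = frame(s_k)
    radial = (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    histone_pos = axis_pts + (spec.helix_diameter_nm / 2.0) * radial

    # DNA path: entry linker, then wrap/linker alternation, then exit linker
    wraps = [_wrap_path(histone_pos[k], radial[k], tangents[k])
             for k in range(n_nuc)]
    entry_point = np.array([0.0, 0.0, -spec.edge_nm / 2.0])
    exit_point = _FACE_DIR[_EXIT_FACE[kind]] * spec.edge_nm / 2.0
    segments = [np.stack([entry_point, wraps[0][0]])]
    for k in range(n_nuc):
        segments.append(wraps[k])
        if k + 1 < n_nuc:
            segments.append(np.stack([wraps[k][-1], wraps[k + 1][0]]))
    segments.append(np.stack([wraps[-1][-1], exit_point.astype(float)]))

    seg_lengths = np.array([
        np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in segments])
    counts = largest_remainder(seg_lengths, spec.n_bp)

    # place pairs at uniform arc length within each segment
    pair_pos = np.empty((spec.n_bp, 3))
    tangent_arr = np.empty((spec.n_bp, 3))
    i0 = 0
    for seg, n_seg in zip(segments, counts):
        if n_seg == 0:
            continue
        d = np.linalg.norm(np.diff(seg, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(d)])
        s_pair = (np.arange(n_seg) + 0.5) / n_seg * cum[-1]
        for axis in range(3):
            pair_pos[i0:i0 + n_seg, axis] = np.interp(s_pair, cum, seg[:, axis])
        # tangent from the polyline edge containing each pair
        edge = np.clip(np.searchsorted(cum, s_pair, side="right") - 1,
                       0, len(d) - 1)
        tv = np.diff(seg, axis=0)[edge]
        tangent_arr[i0:i0 + n_seg] = tv / np.linalg.norm(tv, axis=1)[:, None]
        i0 += n_seg

    pair_rot = _transport_frames(tangent_arr)
    voxel = Voxel(spec, pair_pos, pair_rot, histone_pos, counts,
                  entry_point, exit_point.astype(float))

    half = spec.edge_nm / 2.0
    if np.abs(voxel.pair_pos).max() > half + 1e-9:
        raise ConstructionError(
            f"voxel {kind!r}: DNA path leaves the {spec.edge_nm} nm cube")
    return voxel


def _transport_frames(tangents: np.ndarray) -> np.ndarray:
    """Parallel-transported frames with the helical twist applied.

    The strand-1 azimuth advances 36 degrees per pair around the local
    tangent, on top of a twist-free transported normal, so the double helix
    winds continuously along wraps and linkers.
    """
    n = len(tangents)
    rot = np.empty((n, 3, 3))
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    normal = ref - np.dot(ref, t0) * t0
    normal /= np.linalg.norm(normal)
    twist = np.deg2rad(TWIST_PER_BP_DEG)
    for i in range(n):
        t = tangents[i]
        if i > 0:
            normal = normal - np.dot(normal, t) * t
            nn = np.linalg.norm(normal)
            if nn < 1e-9:  # pathological kink; restart the frame
                ref = np.array([1.0, 0.0, 0.0])
                if abs(np.dot(ref, t)) > 0.9:
                    ref = np.array([0.0, 1.0, 0.0])
                normal = ref - np.dot(ref, t) * t
                nn = np.linalg.norm(normal)
            normal /= nn
        binormal = np.cross(t, normal)
        phi = twist * i
        x_axis = math.cos(phi) * normal + math.sin(phi) * binormal
        y_axis = np.cross(t, x_axis)
        rot[i, :, 0] = x_axis
        rot[i, :, 1] = y_axis
        rot[i, :, 2] = t
    return rot


@lru_cache(maxsize=None)
def default_voxel_library() -> dict:
    """The five default voxel templates, built once per process."""
    return {kind: build_voxel(kind) for kind in VOXEL_KINDS}
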