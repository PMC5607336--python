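"""Nucleotide-pair constituent geometry.

A nucleotide pair is modelled as six spheres -- two phosphates, two
2-deoxyriboses and two complementary bases -- wrapped in a hydration-shell
volume representing the inner bound-water layer. The spheres of neighbouring
constituents overlap when first placed; overlaps are removed by radical-plane
cuts, realised here as the power diagram of the sphere arrangement: a point is
assigned to the sphere that contains it with the smallest power distance
``|x - c|^2 - r^2``. This assignment is equivalent to cutting every sphere by
the radical planes against its overlapping neighbours and yields pairwise
disjoint constituent volumes by construction.

The hydration shell is the part of a 1.25 nm sphere around the pair centre not
claimed by any constituent sphere; it is split into two half-shells by the
plane separating the strands, so that shell energy deposits are attributable
to a specific strand (a strand break is strand-specific).

The local pair frame has the helix axis along +z and the strand-1 azimuth
along +x; strand 2 occupies the opposite azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import CONSTITUENT_RADII_NM, HYDRATION_SHELL_RADIUS_NM

# constituent kind codes used in the packed template arrays
KIND_PHOSPHATE = 0
KIND_DEOXYRIBOSE = 1
KIND_BASE = 2  # resolved to the actual base name via the sequence
KIND_SHELL = 3
KIND_HISTONE = 4

KIND_NAMES = {
    KIND_PHOSPHATE: "phosphate",
    KIND_DEOXYRIBOSE: "deoxyribose",
    KIND_BASE: "base",
    KIND_SHELL: "hydration_shell",
    KIND_HISTONE: "histone",
}


@dataclass(frozen=True)
class ConstituentSpec:
    """One spherical constituent with the half-space cuts applied to it.

    ``cut_planes`` is a list of ``(normal, offset)`` pairs; the retained
    region satisfies ``normal . x <= offset`` for every plane. The planes are
    the radical planes against overlapping sibling spheres.
    """

    kind: str
    radius: float
    center: np.ndarray
    bp_index: int
    strand: int
    cut_planes: tuple = field(default_factory=tuple)

    def contains(self, point: np.ndarray) -> bool:
        p = np.asarray(point, dtype=float)
        if np.dot(p - self.center, p - self.center) > self.radius**2:
            return False
        for normal, offset in self.cut_planes:
            if float(np.dot(normal, p)) > offset + 1e-12:
                return False
        return True


def radical_plane(c_i, r_i, c_j, r_j):
    """Half-space kept by sphere i against sphere j (power bisector).

    Returns (normal, offset) with the kept side ``normal . x <= offset``.
    """
    c_i = np.asarray(c_i, float)
    c_j = np.asarray(c_j, float)
    normal = 2.0 * (c_j - c_i)
    offset = float(np.dot(c_j, c_j) - np.dot(c_i, c_i) - r_j**2 + r_i**2)
    norm = np.linalg.norm(normal)
    return normal / norm, offset / norm


# Local constituent layout of one pair (strand-1 azimuth = +x).
_PHOS_R = 0.95       # radial position of the phosphate centre, nm
_PHOS_ANGLE = np.deg2rad(18.0)  # half a helical twist ahead of the sugar
_SUGAR_R = 0.75
_BASE_R = 0.25


def pair_local_layout():
    """(centers (6,3), radii (6,), kinds (6,), strands (6,)) in the pair frame.

    Order: phosphate s1, phosphate s2, deoxyribose s1, deoxyribose s2,
    base s1, base s2.
    """
    p1 = np.array([_PHOS_R * np.cos(_PHOS_ANGLE), _PHOS_R * np.sin(_PHOS_ANGLE), 0.0])
    s1 = np.array([_SUGAR_R, 0.0, 0.0])
    b1 = np.array([_BASE_R, 0.0, 0.0])
    centers = np.stack([p1, -p1, s1, -s1, b1, -b1])
    radii = np.array([
        CONSTITUENT_RADII_NM["phosphate"], CONSTITUENT_RADII_NM["phosphate"],
        CONSTITUENT_RADII_NM["deoxyribose"], CONSTITUENT_RADII_NM["deoxyribose"],
        0.30, 0.30,
    ])
    kinds = np.array([KIND_PHOSPHATE, KIND_PHOSPHATE,
                      KIND_DEOXYRIBOSE, KIND_DEOXYRIBOSE,
                      KIND_BASE, KIND_BASE], dtype=np.int8)
    strands = np.array([1, 2, 1, 2, 1, 2], dtype=np.int8)
    return centers, radii, kinds, strands


SHELL_RADIUS_NM = HYDRATION_SHELL_RADIUS_NM
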