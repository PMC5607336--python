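"""Spatial attribution of points to DNA volumes.

``GeometryIndex.locate`` maps nucleus-frame points to the unique post-cut
volume containing them: a DNA constituent sphere (phosphate, deoxyribose,
base), a strand-assigned hydration half-shell, a histone sphere, or nothing
(water). Constituent assignment follows the power-diagram cut: among the
spheres containing a point, the one with the smallest power distance
``|x-c|^2 - r^2`` owns it. Points inside no constituent but within the shell
radius of a pair centre belong to that pair's hydration shell; the strand is
the one whose backbone faces the point (sign of the projection on the pair's
strand axis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..constants import HISTONE_RADIUS_NM
from . import constituents as cst

_MAX_CONS_RADIUS = 0.30


class GeometryIndex:
    """KD-tree index over placed voxels and their shared templates."""

    def __init__(self, model):
        self.model = model
        self.library = model.voxel_library()
        rows = []
        for domain in model.domains:
            for p in domain.placements:
                rows.append((p, domain))
        self.placements = rows
        if rows:
            self._vox_centers = np.stack([p.center for p, _ in rows])
            self._vox_rot = np.stack([p.rotation for p, _ in rows]).astype(float)
            self._vox_tree = cKDTree(self._vox_centers)
        else:
            self._vox_centers = np.empty((0, 3))
            self._vox_tree = None
        edge = (next(iter(self.library.values())).spec.edge_nm
                if self.library else 50.0)
        self._half = edge / 2.0
        self._search_r = np.sqrt(3.0) * self._half + cst.SHELL_RADIUS_NM
        self._cons_trees = {
            kind: cKDTree(v.cons_pos) for kind, v in self.library.items()}
        self._pair_trees = {
            kind: cKDTree(v.pair_pos) for kind, v in self.library.items()}

    # -- voxel membership ---------------------------------------------------

    def voxel_of(self, points) -> np.ndarray:
        """Index of the placed voxel whose cube contains each point, or -1."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(points), -1, dtype=int)
        if self._vox_tree is None:
            return out
        neighbours = self._vox_tree.query_ball_point(
            points, np.sqrt(3.0) * self._half + 1e-9)
        for i, cand in enumerate(neighbours):
            for vi in cand:
                q = self._vox_rot[vi].T @ (points[i] - self._vox_centers[vi])
                if np.max(np.abs(q)) <= self._half + 1e-12:
                    out[i] = vi
                    break
        return out

    def voxel_local(self, point, voxel_index: int) -> np.ndarray:
        return self._vox_rot[voxel_index].T @ (
            np.asarray(point, float) - self._vox_centers[voxel_index])

    # -- volume attribution -------------------------------------------------

    def locate(self, points) -> pd.DataFrame:
        """Attribute each point to its DNA volume.

        Returns a DataFrame with columns kind ('' if none), chromosome,
        bp (-1 if none), strand (0 if none), voxel_index (-1 if outside all
        voxels' reach).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        kind = np.full(n, "", dtype=object)
        chrom = np.full(n, "", dtype=object)
        bp = np.full(n, -1, dtype=np.int64)
        strand = np.zeros(n, dtype=np.int8)
        voxel_index = np.full(n, -1, dtype=int)
        if self._vox_tree is None:
            return pd.DataFrame(dict(kind=kind, chromosome=chrom, bp=bp,
                                     strand=strand, voxel_index=voxel_index))
        neighbours = self._vox_tree.query_ball_point(points, self._search_r)
        for i, cand in enumerate(neighbours):
            res = self._locate_one(points[i], cand)
            if res is None:
                continue
            kind[i], chrom[i], bp[i], strand[i], voxel_index[i] = res
        return pd.DataFrame(dict(kind=kind, chromosome=chrom, bp=bp,
                                 strand=strand, voxel_index=voxel_index))

    def _locate_one(self, point, cand):
        best_power = np.inf
        best = None           # (kind, chrom, bp, strand, vi)
        best_shell = None     # (dist, chrom, bp, strand, vi)
        for vi in cand:
            placement, domain = self.placements[vi]
            voxel = self.library[placement.kind]
            q = self._vox_rot[vi].T @ (point - self._vox_centers[vi])
            # constituent spheres
            for ci in self._cons_trees[placement.kind].query_ball_point(
                    q, _MAX_CONS_RADIUS):
                d2 = float(((q - voxel.cons_pos[ci]) ** 2).sum())
                r = voxel.cons_radius[ci]
                power = d2 - r * r
                if d2 <= r * r and power < best_power:
                    best_power = power
                    pair = int(voxel.cons_bp[ci])
                    s = int(voxel.cons_strand[ci])
                    best = (self._resolve_kind(voxel, domain, placement,
                                               ci, pair, s),
                            domain.chromosome_id,
                            placement.bp_start + pair, s, vi)
            # histone spheres
            for h in voxel.histone_pos:
                d2 = float(((q - h) ** 2).sum())
                power = d2 - HISTONE_RADIUS_NM**2
                if d2 <= HISTONE_RADIUS_NM**2 and power < best_power:
                    best_power = power
                    best = ("histone", domain.chromosome_id, -1, 0, vi)
            # hydration shell candidate (nearest pair centre)
            dist, pi = self._pair_trees[placement.kind].query(q)
            if dist <= cst.SHELL_RADIUS_NM:
                if best_shell is None or dist < best_shell[0]:
                    u = voxel.pair_rot[pi][:, 0]  # strand-1 azimuth
                    side = 1 if float(
                        np.dot(q - voxel.pair_pos[pi], u)) >= 0.0 else 2
                    best_shell = (dist, domain.chromosome_id,
                                  placement.bp_start + int(pi), side, vi)
        if best is not None:
            return best
        if best_shell is not None:
            _, c, b, s, vi = best_shell
            return ("hydration_shell", c, b, s, vi)
        return None

    @staticmethod
    def _resolve_kind(voxel, domain, placement, ci, pair, strand):
        code = int(voxel.cons_kind[ci])
        if code == cst.KIND_BASE:
            local = placement.bp_start + pair - domain.bp_start
            base_code = int(domain.sequence[local])
            if strand == 2:
                base_code = 3 - base_code  # complement under ACGT coding
            from .nucleus import BASE_CODES
            return BASE_CODES[base_code]
        return cst.KIND_NAMES[code]
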