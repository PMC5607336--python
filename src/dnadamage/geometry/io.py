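"""Line-oriented text interchange format for the genome geometry.

Sections, in order: NUCLEUS, TERRITORY*, VOXELSPEC*, DOMAIN*, VOXEL*, SEQ*,
END. Floats are written with Python's shortest round-trip repr, so
``read_geometry(write_geometry(m))`` reproduces the model bit-exactly. A
``.gz`` suffix selects the gzip-compressed variant.

    #dnadamage-geometry 1
    NUCLEUS <ax> <ay> <az>                          # half axes, nm
    TERRITORY <chromosome> <n_domains> <bp_length|->
    VOXELSPEC <kind> <n_nuc> <n_bp> <pitch> <helix_d> <n_per_turn>
              <delta_deg> <fibre_r> <fibre_len> <edge>
    DOMAIN <id> <chromosome> <cx> <cy> <cz> <radius> <bp_start>
    VOXEL <domain_id> <kind> <cx> <cy> <cz> <r00..r22> <bp_start> <n_bp>
    SEQ <domain_id> <ACGT...>
    END
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

from ..errors import GeometryParseError
from ..constants import VOXEL_KINDS
from .nucleus import BASE_LETTERS, Domain, NucleusModel, PlacedVoxel, TerritorySpec
from .voxel import VoxelSpec

FORMAT_VERSION = 1
_SEQ_CHUNK = 120


def _f(x) -> str:
    return repr(float(x))


def _open(path, mode):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_geometry(model: NucleusModel, path) -> None:
    with _open(path, "w") as fh:
        fh.write(f"#dnadamage-geometry {FORMAT_VERSION}\n")
        ax = model.half_axes_nm
        fh.write(f"NUCLEUS {_f(ax[0])} {_f(ax[1])} {_f(ax[2])}\n")
        for t in model.territories:
            bp = "-" if t.bp_length is None else str(t.bp_length)
            fh.write(f"TERRITORY {t.chromosome_id} {t.n_domains} {bp}\n")
        specs = model.voxel_specs
        if specs is None:
            specs = {k: VoxelSpec.default(k) for k in VOXEL_KINDS}
        for kind in sorted(specs):
            s = specs[kind]
            fh.write("VOXELSPEC "
                     f"{s.kind} {s.n_nucleosomes} {s.n_bp} {_f(s.pitch_nm)} "
                     f"{_f(s.helix_diameter_nm)} {s.nucleosomes_per_turn} "
                     f"{_f(s.delta_angle_deg)} {_f(s.fibre_radius_nm)} "
                     f"{_f(s.fibre_length_nm)} {_f(s.edge_nm)}\n")
        for d in model.domains:
            c = d.center
            fh.write(f"DOMAIN {d.domain_id} {d.chromosome_id} "
                     f"{_f(c[0])} {_f(c[1])} {_f(c[2])} {_f(d.radius)} "
                     f"{d.bp_start}\n")
        for d in model.domains:
            for p in d.placements:
                r = " ".join(str(int(x)) for x in p.rotation.ravel())
                c = p.center
                fh.write(f"VOXEL {d.domain_id} {p.kind} "
                         f"{_f(c[0])} {_f(c[1])} {_f(c[2])} {r} "
                         f"{p.bp_start} {p.n_bp}\n")
        for d in model.domains:
            if d.sequence is None or len(d.sequence) == 0:
                continue
            letters = "".join(BASE_LETTERS[b] for b in d.sequence)
            for i in range(0, len(letters), _SEQ_CHUNK):
                fh.write(f"SEQ {d.domain_id} {letters[i:i + _SEQ_CHUNK]}\n")
        fh.write("END\n")


def read_geometry(path) -> NucleusModel:
    """Parse a geometry file; raises GeometryParseError with a line number."""
    territories: list[TerritorySpec] = []
    domains: dict[int, Domain] = {}
    specs: dict[str, VoxelSpec] = {}
    half_axes = None
    seq_parts: dict[int, list[str]] = {}
    saw_end = False
    base_index = {c: i for i, c in enumerate(BASE_LETTERS)}

    with _open(path, "r") as fh:
        first = fh.readline()
        tokens = first.split()
        if len(tokens) != 2 or tokens[0] != "#dnadamage-geometry":
            raise GeometryParseError(
                "missing geometry header '#dnadamage-geometry <version>'", 1)
        if int(tokens[1]) != FORMAT_VERSION:
            raise GeometryParseError(
                f"geometry format version {tokens[1]} is not supported "
                f"(expected {FORMAT_VERSION})", 1)
        for ln, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            tag = tok[0]
            try:
                if tag == "NUCLEUS":
                    half_axes = np.array([float(x) for x in tok[1:4]])
                    if len(tok) != 4:
                        raise ValueError("expected 3 half axes")
                elif tag == "TERRITORY":
                    bp = None if tok[3] == "-" else int(tok[3])
                    territories.append(TerritorySpec(tok[1], int(tok[2]), bp))
                elif tag == "VOXELSPEC":
                    if len(tok) != 11:
                        raise ValueError("expected 10 fields")
                    specs[tok[1]] = VoxelSpec(
                        kind=tok[1], n_nucleosomes=int(tok[2]),
                        n_bp=int(tok[3]), pitch_nm=float(tok[4]),
                        helix_diameter_nm=float(tok[5]),
                        nucleosomes_per_turn=int(tok[6]),
                        delta_angle_deg=float(tok[7]),
                        fibre_radius_nm=float(tok[8]),
                        fibre_length_nm=float(tok[9]), edge_nm=float(tok[10]))
                elif tag == "DOMAIN":
                    did = int(tok[1])
                    domains[did] = Domain(
                        domain_id=did, chromosome_id=tok[2],
                        center=np.array([float(x) for x in tok[3:6]]),
                        radius=float(tok[6]), bp_start=int(tok[7]))
                elif tag == "VOXEL":
                    if len(tok) != 17:
                        raise ValueError("expected 16 fields")
                    did = int(tok[1])
                    rot = np.array([int(x) for x in tok[6:15]]).reshape(3, 3)
                    domains[did].placements.append(PlacedVoxel(
                        kind=tok[2],
                        center=np.array([float(x) for x in tok[3:6]]),
                        rotation=rot, bp_start=int(tok[15]),
                        n_bp=int(tok[16])))
                elif tag == "SEQ":
                    seq_parts.setdefault(int(tok[1]), []).append(tok[2])
                elif tag == "END":
                    saw_end = True
                    break
                else:
                    raise ValueError(f"unknown section {tag!r}")
            except GeometryParseError:
                raise
            except (ValueError, KeyError, IndexError) as exc:
                raise GeometryParseError(
                    f"malformed {tag} line: {exc}", ln) from exc

    if half_axes is None:
        raise GeometryParseError("truncated file: missing NUCLEUS section")
    if not saw_end:
        raise GeometryParseError("truncated file: missing END section")

    for did, parts in seq_parts.items():
        letters = "".join(parts)
        domains[did].sequence = np.fromiter(
            (base_index[c] for c in letters), dtype=np.uint8,
            count=len(letters))
    for d in domains.values():
        if d.sequence is None:
            d.sequence = np.zeros(d.n_bp, dtype=np.uint8)

    model = NucleusModel(
        half_axes, territories,
        [domains[k] for k in sorted(domains)],
        voxel_specs=specs or None)
    return model


def models_equal(a: NucleusModel, b: NucleusModel) -> bool:
    """Bit-exact structural equality (used by round-trip checks)."""
    if not np.array_equal(a.half_axes_nm, b.half_axes_nm):
        return False
    if [(t.chromosome_id, t.n_domains, t.bp_length) for t in a.territories] \
            != [(t.chromosome_id, t.n_domains, t.bp_length) for t in b.territories]:
        return False
    if len(a.domains) != len(b.domains):
        return False
    for da, db in zip(a.domains, b.domains):
        if (da.domain_id != db.domain_id
                or da.chromosome_id != db.chromosome_id
                or da.radius != db.radius
                or da.bp_start != db.bp_start
                or not np.array_equal(da.center, db.center)
                or not np.array_equal(da.sequence, db.sequence)
                or len(da.placements) != len(db.placements)):
            return False
        for pa, pb in zip(da.placements, db.placements):
            if (pa.kind != pb.kind or pa.bp_start != pb.bp_start
                    or pa.n_bp != pb.n_bp
                    or not np.array_equal(pa.center, pb.center)
                    or not np.array_equal(pa.rotation, pb.rotation)):
                return False
    return True
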