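"""Run configuration: YAML parsing, validation, presets.

Unset fields fall back to the chain's default parameters (17.5 eV direct
threshold, 2/5 indirect acceptance, 2.5 ns chemical stage, 10 bp cluster
distance, 10000 bp fragment threshold); unknown keys are rejected by name.
The ``desk`` preset shrinks the genome to a few domains of two chromosomes
so the whole chain runs on a workstation; all per-bp semantics are identical
to the full-scale configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import constants as C
from .errors import ConfigurationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySettings(_Strict):
    path: Optional[str] = None          # load instead of building
    half_axes_um: tuple[float, float, float] = C.NUCLEUS_HALF_AXES_UM
    domain_radius_nm: float = C.DOMAIN_RADIUS_NM
    #: (chromosome id, n_domains) pairs; None selects the full default table
    territories: Optional[list[tuple[str, int]]] = None
    #: per-kind overrides of the voxel table, e.g. {straight: {n_bp: 4860}}
    voxel_specs: Optional[dict[str, dict]] = None


class SourceSettings(_Strict):
    square_x_um: float = C.SOURCE_SQUARE_UM[0]
    square_y_um: float = C.SOURCE_SQUARE_UM[1]
    proton_energy_mev: float = 1.0
    let_kev_per_um: Optional[float] = None
    n_events: int = 100
    deposit_min_ev: float = 5.0
    deposit_mean_ev: float = 45.0
    deposit_max_ev: float = 500.0
    sigma_lateral_nm: float = 5.0


class DirectSettings(_Strict):
    mode: Literal["threshold", "linear"] = "threshold"
    threshold_ev: float = C.DIRECT_THRESHOLD_EV
    linear_lo_ev: float = C.DIRECT_LINEAR_LO_EV
    linear_hi_ev: float = C.DIRECT_LINEAR_HI_EV
    include_labels: Optional[list[str]] = None


class ChemistrySettings(_Strict):
    t_end_ns: float = C.CHEMISTRY_T_END_NS
    boundary: Literal["reflect", "absorb"] = "reflect"
    include_phosphate: bool = False
    p_indirect: float = C.INDIRECT_SB_PROBABILITY


class ScoringSettings(_Strict):
    cluster_distance_bp: int = C.CLUSTER_DISTANCE_BP
    min_fragment_bp: int = C.MIN_FRAGMENT_BP
    rel_uncertainty_stop: float = C.REL_UNCERTAINTY_STOP
    batch_size: int = C.BATCH_SIZE
    cut_position: str = "midpoint"
    distant_mode: str = "adjacent"


class RunConfig(_Strict):
    preset: Literal["desk", "full"] = "desk"
    geometry: GeometrySettings = GeometrySettings()
    source: SourceSettings = SourceSettings()
    direct: DirectSettings = DirectSettings()
    chemistry: ChemistrySettings = ChemistrySettings()
    scoring: ScoringSettings = ScoringSettings()
    output_dir: str = "results"
    seed: int = 1

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = self.model_dump()
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


#: desk-scale study conditions: a small nucleus with 2 chromosomes of 2
#: domains each, source rectangle shadowing the nucleus like the full-scale
#: 16 x 12 um square does
DESK_OVERRIDES = dict(
    geometry=dict(half_axes_um=(1.2, 0.9, 0.6), domain_radius_nm=140.0,
                  territories=[("1", 2), ("2", 2)]),
    source=dict(square_x_um=1.95, square_y_um=1.52, n_events=30),
    scoring=dict(batch_size=30, min_fragment_bp=10000),
)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def make_config(data: dict | None = None) -> RunConfig:
    """Build a RunConfig from a raw mapping, applying preset defaults."""
    data = dict(data or {})
    preset = data.get("preset", "desk")
    if preset == "desk":
        data = _deep_merge(DESK_OVERRIDES, data)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        bad = sorted({".".join(str(p) for p in e["loc"])
                      for e in exc.errors()})
        raise ConfigurationError(
            f"invalid configuration keys/values: {', '.join(bad)}") from exc


def parse_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    return make_config(data)
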