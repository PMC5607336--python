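"""Synthetic proton-track generator.

Stands in for a full track-structure physics stage: primaries start on a
rectangular source above the nucleus and travel along -z; energy deposits are
placed along the chord through the ellipsoidal nucleus with a Gaussian
lateral spread, at a linear density calibrated so the expected deposited
energy per unit path length equals the configured LET. Each deposit is
classified against the genome geometry, producing the two physical-stage
datasets:

* dataset 1 -- deposits inside DNA volumes (constituents + hydration
  shells), used for direct strand-break scoring;
* dataset 2 -- radiolysis seeds (ionised/excited water, solvated electrons)
  for deposits that fall inside a chromatin voxel but outside any DNA
  volume, used to start the chemistry stage. Seeds outside every voxel are
  not recorded.

The per-deposit energy spectrum is an explicit model input (default: shifted
exponential, minimum 5 eV, mean 45 eV, capped at 500 eV); all downstream
results are conditional on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import LET_TABLE_KEV_PER_UM, SOURCE_SQUARE_UM
from .errors import ConfigurationError

DEPOSIT_COLUMNS = ["track_id", "x", "y", "z", "energy_ev", "label",
                   "particle", "kind", "chromosome", "bp", "strand",
                   "voxel_index"]
RADIOLYSIS_COLUMNS = ["track_id", "voxel_index", "species_seed",
                      "x", "y", "z", "energy_ev"]

_SEED_OF_LABEL = {"ionisation": "ionised_water",
                  "excitation": "excited_water",
                  "attachment": "solvated_electron"}


@dataclass
class SourceConfig:
    """Primary source geometry and the synthetic deposit model."""

    square_x_um: float = SOURCE_SQUARE_UM[0]
    square_y_um: float = SOURCE_SQUARE_UM[1]
    proton_energy_mev: float = 1.0
    let_kev_per_um: float | None = None   # defaults from the LET table
    deposit_min_ev: float = 5.0
    deposit_mean_ev: float = 45.0
    deposit_max_ev: float = 500.0
    sigma_lateral_nm: float = 5.0
    #: sampling weights of the interaction labels
    label_fractions: dict = field(default_factory=lambda: {
        "ionisation": 0.60, "excitation": 0.25,
        "attachment": 0.05, "elastic": 0.10})
    electron_fraction: float = 0.8  # deposits attributed to secondaries

    def __post_init__(self):
        if self.let_kev_per_um is None:
            self.let_kev_per_um = LET_TABLE_KEV_PER_UM.get(
                float(self.proton_energy_mev))
            if self.let_kev_per_um is None:
                raise ConfigurationError(
                    f"no LET table entry for {self.proton_energy_mev} MeV; "
                    "set let_kev_per_um explicitly")
        if self.let_kev_per_um <= 0:
            raise ConfigurationError("LET must be positive")
        if not self.deposit_min_ev < self.deposit_max_ev:
            raise ConfigurationError("deposit energy bounds are inverted")
        total = sum(self.label_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("label fractions must sum to 1")


def sample_primary(source: SourceConfig, rng, n: int = 1) -> np.ndarray:
    """(x, y) origins in nm, uniform on the centred source rectangle.

    The direction is always -z (parallel beam).
    """
    half = np.array([source.square_x_um, source.square_y_um]) * 1000.0 / 2.0
    return rng.uniform(-half, half, size=(n, 2))


def _sample_energies(source: SourceConfig, rng, n: int) -> np.ndarray:
    scale = source.deposit_mean_ev - source.deposit_min_ev
    e = source.deposit_min_ev + rng.exponential(scale, size=n)
    over = e > source.deposit_max_ev
    while over.any():
        e[over] = source.deposit_min_ev + rng.exponential(
            scale, size=int(over.sum()))
        over = e > source.deposit_max_ev
    return e


def chord_through_ellipsoid(xy_nm, half_axes_nm):
    """(z_top, z_bottom, length) of the vertical chord, NaN when missing."""
    xy = np.atleast_2d(np.asarray(xy_nm, dtype=float))
    a, b, c = half_axes_nm
    s = 1.0 - (xy[:, 0] / a) ** 2 - (xy[:, 1] / b) ** 2
    hit = s > 0.0
    z = np.full(len(xy), np.nan)
    z[hit] = c * np.sqrt(s[hit])
    return z, -z, 2.0 * z


def generate_track_deposits(track_id: int, xy_nm, source: SourceConfig,
                            half_axes_nm, rng, geometry_index=None):
    """Deposit and radiolysis records for one primary track.

    Returns (deposits, radiolysis) DataFrames with the documented schemas.
    A track missing the nucleus yields two empty frames. The sum of the
    deposit energies is the track's total deposited energy, exactly.
    """
    z_top, z_bot, length = chord_through_ellipsoid([xy_nm], half_axes_nm)
    if not np.isfinite(length[0]):
        return (pd.DataFrame(columns=DEPOSIT_COLUMNS),
                pd.DataFrame(columns=RADIOLYSIS_COLUMNS))
    l_nm = float(length[0])
    # 1 keV/um = 1 eV/nm, so the linear deposit density is LET / mean energy
    n_dep = rng.poisson(l_nm * source.let_kev_per_um / source.deposit_mean_ev)
    if n_dep == 0:
        return (pd.DataFrame(columns=DEPOSIT_COLUMNS),
                pd.DataFrame(columns=RADIOLYSIS_COLUMNS))
    z = rng.uniform(z_bot[0], z_top[0], size=n_dep)
    lateral = rng.normal(0.0, source.sigma_lateral_nm, size=(n_dep, 2))
    pos = np.column_stack([np.full(n_dep, xy_nm[0]) + lateral[:, 0],
                           np.full(n_dep, xy_nm[1]) + lateral[:, 1], z])
    energy = _sample_energies(source, rng, n_dep)
    labels = list(source.label_fractions)
    lab = rng.choice(labels, p=[source.label_fractions[k] for k in labels],
                     size=n_dep)
    particle = np.where(rng.random(n_dep) < source.electron_fraction,
                        "electron", "proton")

    if geometry_index is not None:
        hit = geometry_index.locate(pos)
        voxel = geometry_index.voxel_of(pos)
    else:
        hit = pd.DataFrame(dict(
            kind=np.full(n_dep, "", dtype=object),
            chromosome=np.full(n_dep, "", dtype=object),
            bp=np.full(n_dep, -1), strand=np.zeros(n_dep, dtype=int)))
        voxel = np.full(n_dep, -1)

    deposits = pd.DataFrame(dict(
        track_id=track_id, x=pos[:, 0], y=pos[:, 1], z=pos[:, 2],
        energy_ev=energy, label=lab, particle=particle,
        kind=hit["kind"].to_numpy(), chromosome=hit["chromosome"].to_numpy(),
        bp=hit["bp"].to_numpy(), strand=hit["strand"].to_numpy(),
        voxel_index=voxel))

    seed_mask = ((deposits["kind"] == "")
                 & (deposits["voxel_index"] >= 0)
                 & deposits["label"].isin(_SEED_OF_LABEL))
    seeds = deposits[seed_mask]
    radiolysis = pd.DataFrame(dict(
        track_id=seeds["track_id"].to_numpy(),
        voxel_index=seeds["voxel_index"].to_numpy(),
        species_seed=seeds["label"].map(_SEED_OF_LABEL).to_numpy(),
        x=seeds["x"].to_numpy(), y=seeds["y"].to_numpy(),
        z=seeds["z"].to_numpy(), energy_ev=seeds["energy_ev"].to_numpy()),
        columns=RADIOLYSIS_COLUMNS)
    return deposits, radiolysis


def irradiate(source: SourceConfig, half_axes_nm, n_events: int, rng,
              geometry_index=None):
    """Run ``n_events`` primaries; returns concatenated record tables."""
    xy = sample_primary(source, rng, n_events)
    dep_frames, rad_frames = [], []
    for track_id in range(n_events):
        d, r = generate_track_deposits(track_id, xy[track_id], source,
                                       half_axes_nm, rng, geometry_index)
        if len(d):
            dep_frames.append(d)
        if len(r):
            rad_frames.append(r)
    deposits = pd.concat(dep_frames, ignore_index=True) if dep_frames \
        else pd.DataFrame(columns=DEPOSIT_COLUMNS)
    radiolysis = pd.concat(rad_frames, ignore_index=True) if rad_frames \
        else pd.DataFrame(columns=RADIOLYSIS_COLUMNS)
    return deposits, radiolysis


def partition_datasets(deposits: pd.DataFrame, radiolysis: pd.DataFrame):
    """Split the physical-stage records into the two analysis datasets.

    Dataset 1 keeps deposits located in DNA volumes; dataset 2 keeps
    radiolysis seeds located inside a voxel (seeds outside any voxel are
    dropped). The two outputs are disjoint by construction: a record is
    either an energy deposit in a DNA volume or a water radiolysis seed.
    """
    for col in ("kind",):
        if col not in deposits.columns:
            raise ConfigurationError(
                f"deposit records are untagged: missing column {col!r}")
    for col in ("voxel_index", "species_seed"):
        if col not in radiolysis.columns:
            raise ConfigurationError(
                f"radiolysis records are untagged: missing column {col!r}")
    if deposits["kind"].isna().any():
        raise ConfigurationError("deposit records with missing volume tag")
    dataset1 = deposits[deposits["kind"] != ""].reset_index(drop=True)
    dataset2 = radiolysis[radiolysis["voxel_index"] >= 0].reset_index(
        drop=True)
    return dataset1, dataset2


def write_datasets_hdf5(path, dataset1: pd.DataFrame,
                        dataset2: pd.DataFrame) -> None:
    """Optional HDF5 container for the two datasets (CSV is the primary)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, df in (("dna_deposits", dataset1),
                         ("radiolysis", dataset2)):
            grp = fh.create_group(name)
            for col in df.columns:
                data = df[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                grp.create_dataset(col, data=data)
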