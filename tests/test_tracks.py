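"""Synthetic track generator: source sampling, LET calibration, datasets."""

import numpy as np
import pandas as pd
import pytest

from dnadamage.errors import ConfigurationError
from dnadamage.tracks import (DEPOSIT_COLUMNS, RADIOLYSIS_COLUMNS,
                              SourceConfig, chord_through_ellipsoid,
                              generate_track_deposits, partition_datasets,
                              sample_primary)

HALF_AXES = np.array([9850.0, 7100.0, 2500.0])  # nm


def test_source_sampling_bounds_mean_and_determinism():
    src = SourceConfig(proton_energy_mev=1.0)
    rng = np.random.default_rng(0)
    xy = sample_primary(src, rng, 100000)
    assert (np.abs(xy[:, 0]) <= 8000.0).all()
    assert (np.abs(xy[:, 1]) <= 6000.0).all()
    se = np.array([8000.0, 6000.0]) / np.sqrt(3.0) / np.sqrt(len(xy))
    assert (np.abs(xy.mean(axis=0)) <= 3.0 * se).all()
    xy2 = sample_primary(src, np.random.default_rng(0), 100000)
    np.testing.assert_array_equal(xy, xy2)


def test_let_table_defaults():
    assert SourceConfig(proton_energy_mev=0.5).let_kev_per_um == 47.9
    assert SourceConfig(proton_energy_mev=1.0).let_kev_per_um == 27.2
    assert SourceConfig(proton_energy_mev=2.0).let_kev_per_um == 16.1
    assert SourceConfig(proton_energy_mev=20.0).let_kev_per_um == 2.6
    with pytest.raises(ConfigurationError):
        SourceConfig(proton_energy_mev=7.77)
    with pytest.raises(ConfigurationError):
        SourceConfig(let_kev_per_um=-1.0)


def test_let_calibration_and_linearity():
    """Mean deposited energy per unit chord recovers the configured LET."""
    rng = np.random.default_rng(7)
    ratios = {}
    for let in (27.2, 54.4):
        src = SourceConfig(let_kev_per_um=let)
        xy = sample_primary(src, rng, 1800)
        _, _, lengths = chord_through_ellipsoid(xy, HALF_AXES)
        totals, chords = [], []
        for i in range(len(xy)):
            if not np.isfinite(lengths[i]):
                continue
            dep, _ = generate_track_deposits(i, xy[i], src, HALF_AXES, rng)
            totals.append(dep["energy_ev"].sum())
            chords.append(lengths[i])
        totals, chords = np.array(totals), np.array(chords)
        assert len(totals) >= 1000
        # eV/nm equals keV/um
        per_track = totals / chords
        se = per_track.std(ddof=1) / np.sqrt(len(per_track))
        assert abs(per_track.mean() - let) <= 3.0 * se
        ratios[let] = per_track.mean()
    assert ratios[54.4] / ratios[27.2] == pytest.approx(2.0, rel=0.05)


def test_track_missing_nucleus_is_empty():
    src = SourceConfig(proton_energy_mev=1.0)
    dep, rad = generate_track_deposits(
        0, np.array([7900.0, 5900.0]), src, HALF_AXES,
        np.random.default_rng(0))
    assert len(dep) == 0 and len(rad) == 0
    assert list(dep.columns) == DEPOSIT_COLUMNS
    assert list(rad.columns) == RADIOLYSIS_COLUMNS


def test_deposit_energy_spectrum_respects_bounds():
    src = SourceConfig(proton_energy_mev=1.0)
    rng = np.random.default_rng(1)
    dep, _ = generate_track_deposits(0, np.array([0.0, 0.0]), src,
                                     HALF_AXES, rng)
    e = dep["energy_ev"]
    assert (e >= src.deposit_min_ev).all()
    assert (e <= src.deposit_max_ev).all()


def test_partition_toy_records():
    deposits = pd.DataFrame(dict(
        track_id=[0, 0, 1], kind=["deoxyribose", "", "hydration_shell"],
        energy_ev=[10.0, 20.0, 30.0], voxel_index=[0, 0, 2]))
    radiolysis = pd.DataFrame(dict(
        track_id=[0, 1], voxel_index=[3, -1],
        species_seed=["ionised_water", "excited_water"],
        x=[0.0, 1.0], y=[0.0, 1.0], z=[0.0, 1.0], energy_ev=[12.0, 8.0]))
    ds1, ds2 = partition_datasets(deposits, radiolysis)
    assert len(ds1) == 2 and set(ds1["kind"]) == {"deoxyribose",
                                                  "hydration_shell"}
    # the out-of-voxel radiolysis seed is dropped
    assert len(ds2) == 1 and ds2.iloc[0]["voxel_index"] == 3


def test_hdf5_dataset_container_round_trips(tmp_path):
    import h5py
    from dnadamage.tracks import write_datasets_hdf5
    ds1 = pd.DataFrame(dict(track_id=[0, 1], kind=["phosphate", "adenine"],
                            energy_ev=[12.0, 30.0]))
    ds2 = pd.DataFrame(dict(track_id=[0], voxel_index=[2],
                            species_seed=["ionised_water"],
                            x=[1.0], y=[2.0], z=[3.0], energy_ev=[9.0]))
    path = tmp_path / "datasets.h5"
    write_datasets_hdf5(path, ds1, ds2)
    with h5py.File(path) as fh:
        np.testing.assert_allclose(fh["dna_deposits/energy_ev"][:],
                                   [12.0, 30.0])
        assert fh["radiolysis/species_seed"][0] == b"ionised_water"


def test_partition_empty_and_untagged():
    ds1, ds2 = partition_datasets(
        pd.DataFrame(columns=DEPOSIT_COLUMNS),
        pd.DataFrame(columns=RADIOLYSIS_COLUMNS))
    assert len(ds1) == 0 and len(ds2) == 0
    with pytest.raises(ConfigurationError):
        partition_datasets(pd.DataFrame({"energy_ev": [1.0]}),
                           pd.DataFrame(columns=RADIOLYSIS_COLUMNS))
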