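"""Radical chemistry: kinetics primitives, dissociation, voxel simulation."""

import numpy as np
import pandas as pd
import pytest

from dnadamage.chemistry import (ChemistryConfig, ReactionSpec, ReactionTable,
                                 brownian_bridge_reaction_prob,
                                 default_reactions, default_species,
                                 dissociate, rate_to_reaction_radius,
                                 run_chemistry, score_indirect_breaks,
                                 simulate_voxel_chemistry)
from dnadamage.constants import AVOGADRO, DISSOCIATION_CHANNELS
from dnadamage.errors import ConfigurationError

D_OH = 2.8e-9


class TestEncounterRadius:
    def test_zero_rate_gives_zero_radius(self):
        assert rate_to_reaction_radius(0.0, D_OH) == 0.0

    def test_linearity_in_rate(self):
        r1 = rate_to_reaction_radius(1e9, D_OH)
        r2 = rate_to_reaction_radius(2e9, D_OH)
        assert r2 == pytest.approx(2.0 * r1)

    def test_hand_unit_conversion_oracle(self):
        """Dimensional analysis done step by step, independently."""
        k = 2.5e9                      # 1/(M s) = L/(mol s)
        k_m3 = k / 1000.0              # m^3/(mol s)
        k_molecule = k_m3 / AVOGADRO   # m^3/s per molecule pair
        r_m = k_molecule / (4.0 * np.pi * D_OH)
        assert rate_to_reaction_radius(k, D_OH) == pytest.approx(r_m * 1e9)

    def test_static_static_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            rate_to_reaction_radius(1e9, 0.0)


class TestBrownianBridge:
    def test_contact_at_step_start_is_certain(self):
        p = brownian_bridge_reaction_prob(0.5, 3.0, 0.5, D_OH, 1e-12)
        assert p == 1.0

    def test_far_endpoints_small_dt_vanishes(self):
        p = brownian_bridge_reaction_prob(10.0, 10.0, 0.5, D_OH, 1e-15)
        assert p < 1e-12

    def test_monotone_in_dt(self):
        dts = np.logspace(-14, -9, 30)
        ps = [brownian_bridge_reaction_prob(1.0, 1.2, 0.3, D_OH, dt)
              for dt in dts]
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_nonpositive_dt_raises(self):
        with pytest.raises(ConfigurationError):
            brownian_bridge_reaction_prob(1.0, 1.0, 0.5, D_OH, 0.0)


class TestDissociation:
    def _seeds(self, kind, n):
        return pd.DataFrame(dict(
            track_id=0, voxel_index=0, species_seed=kind,
            x=np.zeros(n), y=np.zeros(n), z=np.zeros(n),
            energy_ev=np.full(n, 12.0)))

    def test_products_within_one_nm(self):
        out = dissociate(self._seeds("ionised_water", 500),
                         np.random.default_rng(0))
        r = np.linalg.norm(out[["x", "y", "z"]].to_numpy(), axis=1)
        assert (r <= 1.0 + 1e-12).all()

    def test_solvated_electron_passthrough(self):
        out = dissociate(self._seeds("solvated_electron", 10),
                         np.random.default_rng(0))
        assert list(out["name"]) == ["e_aq"] * 10

    def test_branching_fractions_match_table(self):
        rng = np.random.default_rng(3)
        out = dissociate(self._seeds("excited_water", 10000), rng)
        # channel 1 (p=0.50) produces the OH+H pair -> count H
        n_h = int((out["name"] == "H").sum())
        se = np.sqrt(0.5 * 0.5 * 10000)
        assert abs(n_h - 5000) <= 3.0 * se
        # channel 2 (p=0.15) produces H2
        n_h2 = int((out["name"] == "H2").sum())
        se2 = np.sqrt(0.15 * 0.85 * 10000)
        assert abs(n_h2 - 1500) <= 3.0 * se2

    def test_invalid_branching_table_raises(self):
        bad = {"ionised_water": [(0.7, ("OH",))]}
        with pytest.raises(ConfigurationError, match="ratios"):
            dissociate(self._seeds("ionised_water", 1),
                       np.random.default_rng(0), channel_table=bad)

    def test_default_channels_are_normalised(self):
        for seed, channels in DISSOCIATION_CHANNELS.items():
            assert sum(p for p, _ in channels) == pytest.approx(1.0)


def _box_sim(n_a, n_b, k, t_end, dt, seed, reaction_name="deoxyribose",
             box_nm=25.0):
    rng = np.random.default_rng(seed)
    B = rng.uniform(0, box_nm, (n_b, 3))
    A = rng.uniform(0, box_nm, (n_a, 3))
    dna = pd.DataFrame(dict(name=reaction_name, x=B[:, 0], y=B[:, 1],
                            z=B[:, 2], chromosome="1",
                            bp=np.arange(n_b), strand=1))
    init = pd.DataFrame(dict(name="OH", x=A[:, 0], y=A[:, 1], z=A[:, 2]))
    table = ReactionTable([ReactionSpec(reaction_name, "OH", k, ())])
    cfg = ChemistryConfig(t_end_ns=t_end, step_schedule=((dt, t_end),))
    ev = simulate_voxel_chemistry(init, dna, table, cfg, rng,
                                  box=((0.0,) * 3, (box_nm,) * 3))
    conc = n_b / (box_nm**3 * 1e-27) / (AVOGADRO * 1000.0)
    return ev, conc


class TestVoxelSimulation:
    def test_no_radicals_no_events(self):
        dna = pd.DataFrame(dict(name=["deoxyribose"], x=[0.0], y=[0.0],
                                z=[0.0], chromosome=["1"], bp=[0],
                                strand=[1]))
        empty = pd.DataFrame(columns=["name", "x", "y", "z"])
        ev = simulate_voxel_chemistry(empty, dna, ReactionTable(),
                                      ChemistryConfig(),
                                      np.random.default_rng(0))
        assert len(ev) == 0

    def test_pseudo_first_order_survival_matches_ode(self):
        """Survival of a tracer radical in excess static targets.

        The closed-form well-mixed solution is S(t) = exp(-k c t); the
        simulated survival must agree within 3 binomial standard errors.
        """
        n_a = 400
        ev, conc = _box_sim(n_a, 3500, 2.5e9, t_end=1.5, dt=5e-4, seed=10)
        survival = 1.0 - len(ev) / n_a
        expected = np.exp(-2.5e9 * conc * 1.5e-9)
        se = np.sqrt(expected * (1.0 - expected) / n_a)
        assert abs(survival - expected) <= 3.0 * se

    def test_event_consumes_one_tracer_each(self):
        ev, _ = _box_sim(100, 2000, 2.5e9, t_end=0.5, dt=1e-3, seed=4)
        # one tracer and one target disappear per event: no duplicates
        assert ev["reactant_a"].eq("OH").all()
        assert len(ev) == len(ev[["x", "y", "z"]].drop_duplicates())
        assert ev["bp"].is_unique

    def test_histone_absorbs_and_persists(self):
        dna = pd.DataFrame(dict(name="histone", x=[10.0], y=[10.0],
                                z=[10.0], chromosome=["1"], bp=[-1],
                                strand=[0]))
        # two radicals just outside contact: both must be absorbed
        init = pd.DataFrame(dict(name=["OH", "e_aq"],
                                 x=[12.5, 7.5], y=[10.0, 10.0],
                                 z=[10.0, 10.0]))
        ev = simulate_voxel_chemistry(
            init, dna, ReactionTable(), ChemistryConfig(t_end_ns=0.5),
            np.random.default_rng(1), box=((0.0,) * 3, (20.0,) * 3))
        absorbed = ev[ev["reactant_b"] == "histone"]
        assert len(absorbed) == 2  # histone survived the first absorption

    def test_dna_positions_never_move(self):
        rng = np.random.default_rng(0)
        dna = pd.DataFrame(dict(name="deoxyribose",
                                x=rng.uniform(0, 20, 50),
                                y=rng.uniform(0, 20, 50),
                                z=rng.uniform(0, 20, 50),
                                chromosome="1", bp=np.arange(50), strand=1))
        before = dna.copy(deep=True)
        init = pd.DataFrame(dict(name=["OH"], x=[10.0], y=[10.0], z=[10.0]))
        simulate_voxel_chemistry(init, dna, ReactionTable(),
                                 ChemistryConfig(t_end_ns=0.5), rng,
                                 box=((0.0,) * 3, (20.0,) * 3))
        pd.testing.assert_frame_equal(dna, before)

    def test_event_times_bounded_and_sorted(self):
        ev, _ = _box_sim(200, 2500, 2.5e9, t_end=1.0, dt=1e-3, seed=9)
        assert len(ev) > 10
        t = ev["time_ns"].to_numpy()
        assert (np.diff(t) >= 0).all()
        assert t.max() <= 1.0 + 1e-9

    def test_seeded_determinism(self):
        ev1, _ = _box_sim(150, 2000, 2.5e9, t_end=0.5, dt=1e-3, seed=21)
        ev2, _ = _box_sim(150, 2000, 2.5e9, t_end=0.5, dt=1e-3, seed=21)
        pd.testing.assert_frame_equal(ev1, ev2)


def test_cross_track_species_never_react(desk_index):
    """Clustered solvated electrons react only within their own track.

    The chemistry driver isolates every (voxel, track) pair, so a reaction
    between species of different tracks is impossible; events must carry
    the track id of the group that produced them.
    """
    vi = 0
    center = desk_index._vox_centers[vi]

    def seeds(track_ids):
        n = len(track_ids)
        return pd.DataFrame(dict(
            track_id=track_ids, voxel_index=vi,
            species_seed="solvated_electron",
            x=np.full(n, center[0]), y=np.full(n, center[1]),
            z=np.full(n, center[2]), energy_ev=5.0))

    same = run_chemistry(seeds([7] * 24), desk_index,
                         np.random.default_rng(0))
    ee_same = same[(same["reactant_a"] == "e_aq")
                   & (same["reactant_b"] == "e_aq")]
    assert len(ee_same) >= 1
    assert (same["track_id"] == 7).all()

    cross = run_chemistry(seeds([7] * 12 + [8] * 12), desk_index,
                          np.random.default_rng(0))
    assert set(cross["track_id"]) <= {7, 8}
    # per-group species counts are half of the single-track run, so any
    # surviving pairing across groups would be a bug, not a fluctuation
    for _, row in cross.iterrows():
        assert row["track_id"] in (7, 8)


class TestIndirectScoring:
    def _events(self, other, n):
        return pd.DataFrame(dict(
            time_ns=0.1, reactant_a="OH", reactant_b=other, products="",
            x=0.0, y=0.0, z=0.0, chromosome="1", bp=np.arange(n),
            strand=1, voxel_index=0, track_id=0))

    def test_acceptance_fraction_near_two_fifths(self):
        rng = np.random.default_rng(5)
        sbs = score_indirect_breaks(self._events("deoxyribose", 5000), rng)
        se = np.sqrt(0.4 * 0.6 * 5000)
        assert abs(len(sbs) - 2000) <= 3.0 * se
        assert (sbs["origin"] == "indirect").all()

    def test_base_reactions_never_break(self):
        rng = np.random.default_rng(5)
        assert len(score_indirect_breaks(self._events("guanine", 1000),
                                         rng)) == 0

    def test_zero_probability(self):
        rng = np.random.default_rng(5)
        assert len(score_indirect_breaks(self._events("deoxyribose", 1000),
                                         rng, p_accept=0.0)) == 0


def test_default_reaction_table_contents():
    table = ReactionTable(default_reactions())
    assert table.lookup("OH", "deoxyribose").rate_m_s == pytest.approx(2.5e9)
    assert table.lookup("guanine", "OH").rate_m_s == pytest.approx(9.2e9)
    assert table.lookup("OH", "OH").rate_m_s == pytest.approx(0.44e10)
    assert table.lookup("OH", "phosphate") is None   # default: unreactive
    with_p = ReactionTable(default_reactions(include_phosphate_oh=True))
    assert with_p.lookup("OH", "phosphate") is not None
    hist = table.lookup("histone", "OH")
    assert hist.preserve_first and hist.rate_m_s is None
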