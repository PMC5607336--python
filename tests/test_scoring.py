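"""Clustering, fragment analysis, normalization constants, convergence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnadamage.errors import ConfigurationError
from dnadamage.scoring import (ScoringConfig, YieldParams,
                               apply_detection_threshold, cluster_breaks,
                               compute_E1Gy, compute_fragments,
                               coverage_fraction, dsb_yield_normalization,
                               mean_chord, run_until_converged)


def _sbs(rows, chrom="1"):
    return pd.DataFrame([(chrom, bp, s, "direct", 0) for bp, s in rows],
                        columns=["chromosome", "bp", "strand", "origin",
                                 "track_id"])


def brute_force_clusters(rows, d_bp=10):
    """Independent transitive-closure oracle (union-find over all pairs)."""
    rows = sorted(set(rows))
    parent = list(range(len(rows)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if (rows[i][0] == rows[j][0]
                    and abs(rows[i][1] - rows[j][1]) < d_bp):
                parent[find(i)] = find(j)
    groups = {}
    for i, row in enumerate(rows):
        groups.setdefault(find(i), []).append(row)
    out = []
    for members in groups.values():
        strands = {m[2] for m in members}
        if len(members) >= 2 and len(strands) == 2:
            cls = "DSB"
        elif len(members) >= 2:
            cls = "complex_SSB"
        else:
            cls = "simple_SSB"
        out.append((frozenset(members), cls))
    return set(out)


CASES = [
    # (sites, expected classifications with complexities)
    ([(0, 1), (5, 2)], [("DSB", 2)]),
    ([(0, 1), (10, 2)], [("simple_SSB", 1), ("simple_SSB", 1)]),
    ([(0, 1), (5, 1)], [("complex_SSB", 2)]),
    ([(0, 1), (8, 2), (16, 1)], [("DSB", 3)]),  # chained by merging
    # removing the only opposite-strand break turns a DSB into an SSB
    ([(0, 1), (4, 1), (7, 2)], [("DSB", 3)]),
    ([(0, 1), (4, 1)], [("complex_SSB", 2)]),
]


@pytest.mark.parametrize("rows,expected", CASES)
def test_cluster_classification_examples(rows, expected):
    clusters = cluster_breaks(_sbs(rows))
    got = sorted((c.classification, c.complexity) for c in clusters)
    assert got == sorted(expected)


def test_clusters_never_span_chromosomes():
    sbs = pd.concat([_sbs([(0, 1)], "1"), _sbs([(3, 2)], "2")],
                    ignore_index=True)
    clusters = cluster_breaks(sbs)
    assert len(clusters) == 2
    assert all(c.classification == "simple_SSB" for c in clusters)


def test_clustering_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(99)
    for _ in range(400):
        n = int(rng.integers(1, 50))
        rows = [("1" if rng.random() < 0.7 else "2",
                 int(rng.integers(0, 200)), int(rng.integers(1, 3)))
                for _ in range(n)]
        sbs = pd.DataFrame(rows, columns=["chromosome", "bp", "strand"])
        sbs["origin"] = "direct"
        sbs["track_id"] = 0
        got = {(frozenset((c.chromosome, int(b), int(s))
                          for b, s in zip(c.members["bp"],
                                          c.members["strand"])),
                c.classification)
               for c in cluster_breaks(sbs)}
        expected = brute_force_clusters(
            [(c, b, s) for c, b, s in rows])
        assert got == expected


@settings(max_examples=80, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 120), st.integers(1, 2)),
                min_size=1, max_size=25), st.randoms(use_true_random=False))
def test_clustering_invariances(rows, pyrandom):
    """Input order must not matter; swapping strand labels preserves the
    partition and maps classifications onto themselves."""
    shuffled = list(rows)
    pyrandom.shuffle(shuffled)
    base = cluster_breaks(_sbs(rows))
    perm = cluster_breaks(_sbs(shuffled))
    key = lambda cs: sorted((c.bp_min, c.bp_max, c.classification,
                             c.complexity) for c in cs)
    assert key(base) == key(perm)
    swapped = cluster_breaks(_sbs([(bp, 3 - s) for bp, s in rows]))
    assert key(base) == key(swapped)


class TestFragments:
    def test_no_cut_single_fragment(self):
        frags = compute_fragments([], {"1": 10**6})
        assert len(frags) == 1
        assert frags.iloc[0]["length"] == 10**6

    def test_two_cuts_three_fragments(self):
        clusters = cluster_breaks(_sbs([(100, 1), (105, 2),
                                        (500, 1), (503, 2)]))
        frags = compute_fragments(clusters, {"1": 1000})
        assert len(frags) == 3
        assert frags["length"].sum() == 1000

    def test_length_conservation_on_random_cut_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            length = int(rng.integers(1000, 10**6))
            cuts = rng.integers(0, length, rng.integers(0, 20))
            clusters = cluster_breaks(
                _sbs([(int(c), 1) for c in cuts]
                     + [(int(c) + 1, 2) for c in cuts]))
            frags = compute_fragments(clusters, {"1": length})
            assert frags["length"].sum() == length
            dsb = sum(c.classification == "DSB" for c in clusters)
            assert len(frags) == dsb + 1

    def test_cut_outside_chromosome_raises(self):
        clusters = cluster_breaks(_sbs([(500, 1), (504, 2)]))
        with pytest.raises(ConfigurationError, match="outside"):
            compute_fragments(clusters, {"1": 100})


class TestDetectionThreshold:
    def _frags(self, lengths, chrom="1"):
        edges = np.concatenate([[0], np.cumsum(lengths)])
        return pd.DataFrame(dict(chromosome=chrom, start=edges[:-1],
                                 end=edges[1:], length=lengths))

    def test_boundary_exactly_at_threshold_survives(self):
        kept, distant = apply_detection_threshold(
            self._frags([9999, 10000, 50000]), 10000)
        assert sorted(kept["length"]) == [10000, 50000]
        assert distant == 2  # both cuts flank a surviving fragment

    def test_no_dsb_no_distant(self):
        kept, distant = apply_detection_threshold(self._frags([10**6]))
        assert distant == 0 and len(kept) == 1

    def test_all_surviving_equals_raw_count(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lengths = rng.integers(10000, 10**6, rng.integers(1, 15))
            _, distant = apply_detection_threshold(self._frags(lengths))
            assert distant == len(lengths) - 1

    def test_interior_mode_is_stricter(self):
        frags = self._frags([5000, 50000, 4000, 60000, 3000])
        _, adjacent = apply_detection_threshold(frags, mode="adjacent")
        _, interior = apply_detection_threshold(frags, mode="interior")
        assert adjacent == 4
        assert interior == 0


class TestNormalizationConstants:
    def test_e1gy_matches_printed_value(self):
        e = compute_E1Gy((9.85, 7.1, 2.5))
        # 3 significant figures as printed
        assert round(e, -1) == 4570.0

    def test_e1gy_volume_scaling(self):
        e1 = compute_E1Gy((2.0, 3.0, 4.0))
        e2 = compute_E1Gy((4.0, 6.0, 8.0))
        assert e2 == pytest.approx(8.0 * e1)

    def test_e1gy_sphere_closed_form(self):
        r = 5.0
        expected = (4.0 / 3.0 * np.pi * r**3 * 1e-18 * 1000.0
                    / 1.602176634e-16)
        assert compute_E1Gy((r, r, r)) == pytest.approx(expected)

    def test_coverage_full_projection_is_one(self):
        assert coverage_fraction((9.85, 7.1, 2.5), 100.0, 100.0) == \
            pytest.approx(1.0, abs=1e-9)

    def test_coverage_defaults_round_to_92_percent(self):
        f = coverage_fraction((9.85, 7.1, 2.5), 16.0, 12.0)
        assert round(100.0 * f) == 92

    def test_coverage_single_cut_matches_cap_formula(self):
        """|x| <= x0 slab vs the spherical-cap closed form."""
        a, b, c = 9.85, 7.1, 2.5
        for u0 in (0.3, 0.6, 0.9):
            f = coverage_fraction((a, b, c), 2.0 * u0 * a, 1e6)
            cap = (2.0 - 3.0 * u0 + u0**3) / 4.0
            assert f == pytest.approx(1.0 - 2.0 * cap, abs=1e-6)

    def test_mean_chord_full_projection_closed_form(self):
        a, b, c = 9.85, 7.1, 2.5
        assert mean_chord((a, b, c)) == pytest.approx(4.0 * c / 3.0)

    def test_mean_chord_sphere_against_monte_carlo(self):
        r = 5.0
        rng = np.random.default_rng(8)
        xy = rng.uniform(-r, r, (200000, 2))
        s = r**2 - (xy**2).sum(axis=1)
        chords = 2.0 * np.sqrt(s[s > 0])
        mc = chords.mean()
        assert mean_chord((r, r, r), 2 * r, 2 * r) == pytest.approx(
            mc, rel=5e-3)

    def test_mean_chord_defaults_in_expected_band(self):
        value = mean_chord((9.85, 7.1, 2.5), 16.0, 12.0)
        assert 3.3 <= value <= 3.7


class TestYieldNormalization:
    def test_linear_in_dsb_count(self):
        p = YieldParams(let_keV_per_um=27.2)
        assert dsb_yield_normalization(2.0, p) == pytest.approx(
            2.0 * dsb_yield_normalization(1.0, p))

    def test_identity_configuration(self):
        p = YieldParams(E_1Gy_keV=27.2, l_bar_um=1.0, n_Gbp=1.0, F=1.0,
                        let_keV_per_um=27.2)
        assert dsb_yield_normalization(3.5, p) == pytest.approx(3.5)

    def test_zero_let_rejected(self):
        with pytest.raises(ConfigurationError):
            YieldParams(let_keV_per_um=0.0)


class TestConvergence:
    def _config(self, stop=0.02, batch=25):
        return ScoringConfig(rel_uncertainty_stop=stop, batch_size=batch)

    def test_zero_variance_stops_at_minimum(self):
        result = run_until_converged(
            lambda b: np.full(25, 3.0), self._config(), YieldParams())
        assert result.n_batches == 2
        assert result.converged
        assert result.n_dsb_per_event == 3.0

    def test_loose_threshold_stops_immediately(self):
        rng = np.random.default_rng(0)
        result = run_until_converged(
            lambda b: rng.poisson(2.0, 25), self._config(stop=1.0),
            YieldParams())
        assert result.n_batches == 2

    def test_stopping_batch_count_near_analytic_prediction(self):
        """Batches of N(mu=10, sigma=3): SE of batch means reaches 2% of
        the mean near n* = (sigma_batch / (0.02 mu))^2 batches."""
        mu, sigma, batch = 10.0, 3.0, 25
        n_star = (sigma / np.sqrt(batch) / (0.02 * mu)) ** 2
        stops = []
        for rep in range(30):
            rng = np.random.default_rng(1000 + rep)
            res = run_until_converged(
                lambda b: rng.normal(mu, sigma, batch),
                self._config(), YieldParams(), max_batches=200)
            assert res.converged
            stops.append(res.n_batches)
        med = np.median(stops)
        assert n_star / 2.0 <= med <= n_star * 2.0

    def test_yield_uses_equation_normalization(self):
        params = YieldParams(let_keV_per_um=27.2)
        res = run_until_converged(lambda b: np.full(10, 1.0),
                                  ScoringConfig(batch_size=10), params)
        assert res.n_dsb_gy_gbp == pytest.approx(
            4570.0 / (3.5 * 27.2 * 6.4) * 0.95)
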