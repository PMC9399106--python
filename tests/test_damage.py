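import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphafoci.damage import (
    ClusteringParams,
    TrackEmulatorConfig,
    dbscan_cluster,
    dsbs_for_nuclei,
    emulate_track,
    induce_ssbs,
    register_dsbs,
    ssb_probability,
)
from alphafoci.geometry import sample_traversals_for_dose


def brute_force_dbscan(points, eps, min_pts):
    """Reachability-closure oracle for DBSCAN (exact for min_pts <= 2;
    core/noise sets and core partition for larger min_pts)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts  # neighbourhood includes the point
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack, labels[i] = [i], cluster
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels, core


def partitions_equal(a, b):
    """Same grouping regardless of label numbering (noise = -1)."""
    if np.any((a == -1) != (b == -1)):
        return False
    m = a != -1
    pairs_a = a[m][:, None] == a[m][None, :]
    pairs_b = b[m][:, None] == b[m][None, :]
    return np.array_equal(pairs_a, pairs_b)


class TestSSBProbability:
    @pytest.mark.parametrize("energy,expected", [(0.0, 0.0), (5.0, 0.0),
                                                 (21.25, 0.5), (37.5, 1.0),
                                                 (100.0, 1.0)])
    def test_linear_ramp(self, energy, expected):
        assert ssb_probability(energy) == pytest.approx(expected)

    def test_induction_below_threshold_never_breaks(self, rng):
        pos = rng.random((500, 3))
        ssb, _ = induce_ssbs(pos, np.full(500, 4.9), rng=rng)
        assert len(ssb) == 0

    def test_saturated_energy_always_breaks_when_fully_dna(self, rng):
        params = ClusteringParams(f_dna=1.0)
        pos = rng.random((500, 3))
        ssb, strands = induce_ssbs(pos, np.full(500, 40.0), params, rng)
        assert len(ssb) == 500
        assert set(np.unique(strands)) <= {0, 1}

    def test_binomial_thinning_rate(self, rng):
        params = ClusteringParams(f_dna=0.5)
        pos = rng.random((10_000, 3))
        ssb, _ = induce_ssbs(pos, np.full(10_000, 21.25), params, rng)
        # keep probability 0.5 x 0.5; 4 sigma band of Binomial(1e4, 0.25)
        assert abs(len(ssb) - 2500) < 4 * np.sqrt(10_000 * 0.25 * 0.75)


class TestDBSCAN:
    def test_pair_within_epsilon_clusters(self):
        labels = dbscan_cluster([[0, 0, 0], [3.0, 0, 0]], 3.3, 2)
        assert labels[0] == labels[1] != -1

    def test_pair_beyond_epsilon_is_noise(self):
        labels = dbscan_cluster([[0, 0, 0], [4.0, 0, 0]], 3.3, 2)
        assert np.all(labels == -1)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(2, 25), st.integers(0, 10_000),
           st.sampled_from([1.0, 2.0, 3.3]))
    def test_matches_brute_force_oracle(self, n, seed, eps):
        pts = np.random.default_rng(seed).uniform(0, 12, (n, 3))
        got = dbscan_cluster(pts, eps, 2)
        want, _ = brute_force_dbscan(pts, eps, 2)
        assert partitions_equal(got, want)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(4, 25), st.integers(0, 10_000))
    def test_core_and_noise_sets_for_min_points_three(self, n, seed):
        pts = np.random.default_rng(seed).uniform(0, 8, (n, 3))
        got = dbscan_cluster(pts, 3.0, 3)
        want, core = brute_force_dbscan(pts, 3.0, 3)
        # border points may attach to either adjacent cluster; core points
        # and the noise set are unambiguous
        assert np.array_equal(got[core] == -1, want[core] == -1)
        assert partitions_equal(got[core], want[core])
        assert np.array_equal(got == -1, want == -1)


class TestRegisterDSBs:
    def test_same_strand_pair_is_not_a_dsb(self, rng):
        cents, _ = register_dsbs([[0, 0, 0], [1, 0, 0]], [0, 0],
                                 ClusteringParams(p_f=1.0), rng)
        assert len(cents) == 0

    def test_opposite_strand_pair_forms_dsb_at_midpoint(self, rng):
        cents, counts = register_dsbs([[0, 0, 0], [1, 0, 0]], [0, 1],
                                      ClusteringParams(p_f=1.0), rng)
        assert counts.tolist() == [2]
        assert cents[0] == pytest.approx([0.5, 0, 0])

    def test_zero_fiber_fraction_suppresses_all_dsbs(self, rng):
        pts = rng.normal(scale=0.5, size=(40, 3))
        strands = rng.integers(0, 2, 40)
        cents, _ = register_dsbs(pts, strands, ClusteringParams(p_f=0.0), rng)
        assert len(cents) == 0


class TestEmulateTrack:
    def test_zero_chord_is_empty(self, rng):
        pos, en = emulate_track([0, 0, -5], [0, 0, 1], 0.0, 100.0, rng=rng)
        assert len(pos) == 0 and len(en) == 0

    def test_event_count_and_total_energy_track_let(self, rng):
        # expected events = LET[eV/um] x chord / mean event energy ~ 14,816
        counts, totals = [], []
        for _ in range(60):
            pos, en = emulate_track([0, 0, -10 / 3], [0, 0, 1], 20 / 3,
                                    100.0, rng=rng, nucleus_radius_um=5.0)
            counts.append(len(en))
            totals.append(en.sum())
        assert np.mean(counts) == pytest.approx(1e5 * (20 / 3) / 45, rel=0.02)
        assert np.mean(totals) == pytest.approx(1e5 * (20 / 3), rel=0.02)

    def test_events_confined_to_nucleus(self, rng):
        pos, _ = emulate_track([0, 0, -5], [0, 0, 1], 10.0, 100.0, rng=rng)
        assert np.all(np.linalg.norm(pos, axis=1) <= 5000.0)


@pytest.fixture(scope="module")
def traversal_batch():
    return sample_traversals_for_dose(0.4, 120, rng=np.random.default_rng(17))


class TestDamageChain:
    def test_bit_reproducible_for_fixed_seed(self, traversal_batch):
        a = dsbs_for_nuclei(traversal_batch, rng=np.random.default_rng(5))
        b = dsbs_for_nuclei(traversal_batch, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.nucleus_id, b.nucleus_id)
        np.testing.assert_array_equal(a.centroid, b.centroid)
        np.testing.assert_array_equal(a.n_ssb, b.n_ssb)

    def test_dsb_members_meet_minimum(self, traversal_batch):
        dsbs = dsbs_for_nuclei(traversal_batch, rng=np.random.default_rng(5))
        assert np.all(dsbs.n_ssb >= 2)
        # centroids stay inside the nucleus sphere
        assert np.all(np.linalg.norm(dsbs.centroid, axis=1) <= 5000.0)

    def test_yield_monotone_in_volume_fractions_and_epsilon(self,
                                                            traversal_batch):
        base = ClusteringParams()
        counts = {}
        for name, params in {
            "base": base,
            "low_fdna": dataclasses.replace(base, f_dna=0.05),
            "low_pf": dataclasses.replace(base, p_f=0.05),
            "small_eps": dataclasses.replace(base, epsilon_nm=1.5),
            "big_eps": dataclasses.replace(base, epsilon_nm=6.0),
        }.items():
            dsbs = dsbs_for_nuclei(traversal_batch, params=params,
                                   rng=np.random.default_rng(5))
            counts[name] = len(dsbs.nucleus_id)
        assert counts["low_fdna"] < counts["base"]
        assert counts["low_pf"] < counts["base"]
        assert counts["small_eps"] < counts["base"] < counts["big_eps"]

    def test_dsb_yield_linear_in_dose(self, small_pipeline):
        doses, dsb_rates = [], []
        for dose, res in small_pipeline.per_dose.items():
            doses.append(dose)
            dsb_rates.append(res.nuclei["n_dsbs"].mean())
        slope, intercept = np.polyfit(doses, dsb_rates, 1)
        # intercept consistent with zero relative to the 1 Gy level
        assert abs(intercept) < 0.05 * slope
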