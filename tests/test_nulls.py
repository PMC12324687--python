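import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfmap import smooth_field
from perfmap.geometry import fibonacci_sphere, great_circle_distance
from perfmap.nulls import (NullEnsemble, apply_ensemble, bh_fdr, perm_pvalue,
                           spin_assignments, spin_correlation,
                           variogram_surrogates, vasa_assignments)


def _identity_rotations(n):
    return np.broadcast_to(np.eye(3), (n, 3, 3)).copy()


class TestSpin:
    def test_identity_rotation_gives_identity_assignment(self, centroids400):
        ens = spin_assignments(centroids400, 2, rotations=_identity_rotations(2))
        assert np.array_equal(ens.assignments, np.tile(np.arange(400), (2, 1)))

    def test_assignments_in_range(self, spin1000):
        a = spin1000.assignments
        assert a.min() >= 0 and a.max() < 400

    def test_half_turn_swaps_opposite_equatorial_parcels(self):
        # parcels at longitudes 0, 90, 180, 270 on the equator
        lon = np.deg2rad([0, 90, 180, 270])
        coords = np.column_stack([np.cos(lon), np.sin(lon), np.zeros(4)])
        rot = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]])  # 180 deg about z
        ens = spin_assignments(coords, 1, rotations=rot[None])
        assert ens.assignments[0].tolist() == [2, 3, 0, 1]

    def test_medial_wall_rule_takes_next_closest(self):
        lon = np.deg2rad([0, 90, 180, 270])
        coords = np.column_stack([np.cos(lon), np.sin(lon), np.zeros(4)])
        rot = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]])
        excl = np.array([False, False, True, False])
        ens = spin_assignments(coords, 1, exclusion=excl, rotations=rot[None])
        # parcel 0's nearest rotated parcel (2) is excluded -> next closest
        assert ens.assignments[0, 0] in (1, 3)
        assert 2 not in ens.assignments[0]

    def test_rejects_bad_arguments(self, centroids400):
        with pytest.raises(ValueError, match="n_null"):
            spin_assignments(centroids400, 0)
        with pytest.raises(ValueError, match="2 parcels"):
            spin_assignments(centroids400[:1], 5)


class TestVasa:
    def test_identity_rotation_gives_identity_permutation(self, centroids400):
        ens = vasa_assignments(centroids400, 1, rotations=_identity_rotations(1))
        assert np.array_equal(ens.assignments[0], np.arange(400))

    def test_rows_are_bijections(self, vasa1000):
        expect = np.arange(400)
        for row in vasa1000.assignments[::97]:
            assert np.array_equal(np.sort(row), expect)

    def test_greedy_rule_matches_bruteforce_on_conflict(self):
        """3-parcel case where greedy-by-distance differs from optimal matching."""
        lon = np.deg2rad([0.0, 20.0, 40.0])
        coords = np.column_stack([np.cos(lon), np.sin(lon), np.zeros(3)])
        ang = np.deg2rad(11.0)  # rotate +11 deg about z
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        ens = vasa_assignments(coords, 1, rotations=rot[None])

        # brute-force re-enactment of the documented greedy rule
        rotated = coords @ rot.T
        d = np.arccos(np.clip(coords @ rotated.T, -1, 1))
        pairs = sorted(((d[i, j], i, j) for i in range(3) for j in range(3)))
        assign, used_i, used_j = {}, set(), set()
        for _, i, j in pairs:
            if i not in used_i and j not in used_j:
                assign[i] = j
                used_i.add(i)
                used_j.add(j)
        expected = np.array([assign[i] for i in range(3)])
        assert np.array_equal(ens.assignments[0], expected)

        # and it differs from the Hungarian optimum for this configuration
        hung = vasa_assignments(coords, 1, method="hungarian", rotations=rot[None])
        assert not np.array_equal(hung.assignments[0], ens.assignments[0])

    def test_hungarian_rows_are_bijections(self, centroids400):
        ens = vasa_assignments(centroids400, 3, seed=1, method="hungarian")
        for row in ens.assignments:
            assert np.array_equal(np.sort(row), np.arange(400))


class TestVariogram:
    def test_surrogates_preserve_value_multiset(self, distances400):
        f = smooth_field(distances400, 0.4, 8)
        ens = variogram_surrogates(f, distances400, 20, seed=3)
        for row in ens.assignments:
            assert np.allclose(np.sort(row), np.sort(f))

    def test_variograms_match_source(self, distances400):
        f = smooth_field(distances400, 0.4, 9)
        ens = variogram_surrogates(f, distances400, 100, seed=4)
        iu, ju = np.triu_indices(400, k=1)
        d_pairs = distances400[iu, ju]
        edges = np.quantile(d_pairs, np.linspace(0, 1, 26))
        bins = np.clip(np.searchsorted(edges, d_pairs, side="right") - 1, 0, 24)
        counts = np.bincount(bins, minlength=25)

        def vg(vals):
            sq = 0.5 * (vals[iu] - vals[ju]) ** 2
            return np.bincount(bins, weights=sq, minlength=25) / counts

        source = vg(f)
        rel = [np.mean(np.abs(vg(row) - source) / source) for row in ens.assignments]
        assert np.mean(rel) <= 0.10

    def test_white_noise_picks_smallest_scale(self, distances400):
        rng = np.random.default_rng(10)
        noise = rng.standard_normal(400)
        _, scales = variogram_surrogates(noise, distances400, 100, seed=5,
                                         return_scales=True)
        assert np.mean(scales == scales.min()) >= 0.80

    def test_rejects_bad_inputs(self, distances400):
        f = smooth_field(distances400, 0.4, 8)
        with pytest.raises(ValueError, match="n_bins"):
            variogram_surrogates(f, distances400, 5, n_bins=2)
        with pytest.raises(ValueError, match="non-finite"):
            variogram_surrogates(np.r_[f[:-1], np.nan], distances400, 5)


class TestPermPvalue:
    def test_all_nulls_below_gives_min_p(self):
        assert perm_pvalue(1.0, np.zeros(1000)) == pytest.approx(1 / 1001)

    def test_all_nulls_above_gives_one(self):
        assert perm_pvalue(0.0, np.ones(1000)) == 1.0

    def test_direct_count(self):
        nulls = np.r_[np.ones(500), -np.ones(500)]
        assert perm_pvalue(0.5, nulls) == pytest.approx(501 / 1001)

    def test_empty_nulls_rejected(self):
        with pytest.raises(ValueError):
            perm_pvalue(1.0, np.array([]))

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50),
           st.floats(-10, 10),
           st.sampled_from(["greater", "less", "two-sided"]))
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, nulls, obs, side):
        p = perm_pvalue(obs, np.array(nulls), side)
        assert 1 / (len(nulls) + 1) <= p <= 1.0


class TestSpinCorrelation:
    def test_self_correlation_is_extreme(self, distances400, spin1000):
        f = smooth_field(distances400, 0.4, 12)
        res = spin_correlation(f, f, spin1000)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_spin == pytest.approx(1 / 1001)

    def test_near_copy_is_extreme(self, distances400, spin1000):
        f = smooth_field(distances400, 0.4, 13)
        noisy = f + 0.01 * np.random.default_rng(0).standard_normal(400)
        res = spin_correlation(f, noisy, spin1000)
        assert res.p_spin == pytest.approx(1 / 1001)

    def test_zero_variance_rejected(self, spin1000):
        with pytest.raises(ValueError, match="zero-variance"):
            spin_correlation(np.zeros(400), np.ones(400), spin1000)

    def test_pvalues_roughly_uniform_under_independence(self, distances400, spin1000):
        from scipy import stats
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            a = smooth_field(distances400, 0.4, rng)
            b = smooth_field(distances400, 0.4, rng)
            ps.append(spin_correlation(a, b, spin1000).p_spin)
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.1


class TestEnsembleContracts:
    def test_spin_values_are_submultiset(self, spin1000):
        vals = np.random.default_rng(1).standard_normal(400)
        nulls = apply_ensemble(spin1000, vals)
        assert set(np.unique(nulls)).issubset(set(vals))

    def test_vasa_and_variogram_preserve_multiset(self, vasa1000, distances400):
        vals = smooth_field(distances400, 0.4, 14)
        nulls = apply_ensemble(vasa1000, vals)
        for row in nulls[::211]:
            assert np.allclose(np.sort(row), np.sort(vals))

    def test_save_load_roundtrip(self, tmp_path, spin1000):
        path = tmp_path / "ens.npy"
        spin1000.save(path)
        back = NullEnsemble.load(path)
        assert back.kind == "spin"
        assert np.array_equal(back.assignments, spin1000.assignments)


class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        adj, rej = bh_fdr(np.array([0.03]))
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_stepup(self):
        adj, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        adj, _ = bh_fdr(np.full(7, 0.2))
        assert np.allclose(adj, 0.2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.01, np.nan]))
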