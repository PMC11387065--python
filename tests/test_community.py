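import itertools

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc

from dietshift import (
    IncidenceFrequencies,
    bray_curtis,
    dprime,
    estimate_richness_at,
    herd_dprime,
    incidence_from_samples,
    richness,
    species_dprime,
)
from dietshift.community import bray_curtis_pair, chao2_q0
from dietshift.diet_table import DietTableError

from conftest import make_table


class TestBrayCurtis:
    def test_identical_rows_give_zero(self):
        D = bray_curtis([[3, 1, 2], [3, 1, 2]])
        assert D.data[0, 1] == 0.0

    def test_disjoint_supports_give_one(self):
        D = bray_curtis([[5, 0], [0, 9]])
        assert D.data[0, 1] == 1.0

    def test_hand_worked_value(self):
        D = bray_curtis([[6, 2, 0], [2, 2, 4]])
        assert D.data[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            X = rng.integers(0, 50, size=(6, 9)).astype(float)
            X[X.sum(axis=1) == 0, 0] = 1
            D = bray_curtis(X).data
            for i, j in itertools.combinations(range(6), 2):
                assert D[i, j] == pytest.approx(scipy_bc(X[i], X[j]), abs=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([[1, 2], [0, 0]])


class TestRichness:
    @pytest.mark.parametrize(
        "row,expected", [([0, 0, 0], 0), ([1, 0, 7], 2), ([2, 2, 2], 3)]
    )
    def test_counts_positive_entries(self, row, expected):
        assert richness([row])[0] == expected

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(20, 15))
        expected = [sum(1 for v in row if v > 0) for row in X]
        assert richness(X).tolist() == expected


class TestIncidence:
    def test_worked_tally(self):
        # four units; detections per taxon 4, 2, 1, 1
        X = np.array(
            [
                [1, 1, 1, 0],
                [1, 1, 0, 0],
                [1, 0, 0, 1],
                [1, 0, 0, 0],
            ]
        )
        inc = incidence_from_samples(X)
        assert inc.S_obs == 4
        assert inc.T == 4
        assert inc.Q == {1: 2, 2: 1, 4: 1}

    def test_taxon_in_all_units(self):
        inc = incidence_from_samples([[2, 0], [5, 0], [1, 0]])
        assert inc.Q == {3: 1}


@pytest.fixture
def worked_incidence():
    return IncidenceFrequencies(T=4, Y=[4, 2, 1, 1])


class TestRichnessEstimation:
    def test_endpoint_equals_observed(self, worked_incidence):
        assert estimate_richness_at(worked_incidence, 4) == pytest.approx(4.0)

    def test_single_unit_equals_mean_per_unit_richness(self, worked_incidence):
        assert estimate_richness_at(worked_incidence, 1) == pytest.approx(2.0)

    def test_worked_extrapolation(self, worked_incidence):
        assert chao2_q0(worked_incidence) == pytest.approx(1.5)
        assert estimate_richness_at(worked_incidence, 8) == pytest.approx(
            5.0254, abs=1e-4
        )

    def test_interpolation_equals_subset_enumeration(self):
        """S(t) for t <= T is the average richness over all size-t unit subsets."""
        rng = np.random.default_rng(3)
        for _ in range(15):
            T = int(rng.integers(2, 7))
            X = (rng.random(size=(T, 12)) < 0.4).astype(int)
            X[:, rng.integers(0, 12)] = 1  # avoid empty matrices
            inc = incidence_from_samples(X)
            for t in range(1, T + 1):
                brute = np.mean(
                    [
                        int((X[list(sub)].sum(axis=0) > 0).sum())
                        for sub in itertools.combinations(range(T), t)
                    ]
                )
                assert estimate_richness_at(inc, t) == pytest.approx(brute, abs=1e-9)

    def test_monotone_and_bounded(self, worked_incidence):
        vals = [estimate_richness_at(worked_incidence, t) for t in range(1, 30)]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        ceiling = worked_incidence.S_obs + chao2_q0(worked_incidence)
        assert all(v <= ceiling + 1e-9 for v in vals)

    def test_no_uniques_extrapolates_to_observed(self):
        inc = IncidenceFrequencies(T=3, Y=[3, 2, 2])
        assert estimate_richness_at(inc, 10) == inc.S_obs

    def test_invalid_t(self, worked_incidence):
        with pytest.raises(ValueError):
            estimate_richness_at(worked_incidence, 0)


class TestDprime:
    def test_opportunistic_row_is_zero(self):
        # row shares equal to network-wide availability -> KL = 0
        res = dprime([[6, 3, 1], [6, 3, 1]])
        assert np.allclose(res.d, 0.0)
        assert np.allclose(res.d_prime, 0.0)

    def test_exclusive_resources_reach_one(self):
        res = dprime([[10, 0], [0, 10]])
        assert np.allclose(res.d, np.log(2))
        assert np.allclose(res.d_prime, 1.0)

    def test_balanced_row_in_exclusive_network(self):
        res = dprime([[10, 0], [0, 10], [5, 5]])
        assert res.d_prime[2] == pytest.approx(0.0, abs=1e-12)

    def test_row_scaling_invariance(self):
        A = np.array([[4.0, 1.0, 5.0], [2.0, 7.0, 1.0]])
        base = dprime(A)
        same = dprime(A * 1.0)
        assert np.allclose(base.d_prime, same.d_prime)
        # scaling one row leaves its share vector (hence its KL against any
        # fixed availability) unchanged
        scaled = A.copy()
        scaled[0] *= 37.0
        p0 = scaled[0] / scaled[0].sum()
        q = A.sum(axis=0) / A.sum()
        d_fixed_q = np.sum(p0 * np.log(p0 / q))
        assert d_fixed_q == pytest.approx(base.d[0], abs=1e-12)

    def test_concentration_on_rare_resource_monotone(self):
        # a heavy background fixes availability; moving the light focal
        # row's mass onto the rarest column must increase its specialization
        background = np.array([[9000.0, 900.0, 100.0]] * 3)
        last = -1.0
        for w in np.linspace(0.0, 1.0, 20):
            row = np.array([(1 - w) * 90.0, (1 - w) * 10.0, w * 100.0])
            res = dprime(np.vstack([background, row + 1e-9]))
            assert res.d_prime[3] >= last - 1e-9
            last = res.d_prime[3]

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            dprime([[0, 0], [1, 2]])


class TestHerdAndSpeciesDprime:
    def test_identical_samples_all_zero(self):
        t = make_table(
            [[5, 5]] * 4,
            species=["elk", "elk", "bison", "bison"],
            season=["summer"] * 4,
        )
        assert np.allclose(herd_dprime(t, "summer").values, 0.0)
        assert np.allclose(species_dprime(t, "summer").values, 0.0)

    def test_exclusive_species_reaches_one(self):
        # elk's exclusive column is also the rarest network-wide, so its
        # samples attain the continuous-convention maximum ln(1/q_min)
        t = make_table(
            [[5, 0, 0], [5, 0, 0], [0, 20, 0], [0, 0, 20]],
            species=["elk", "elk", "bison", "bison"],
            season=["summer"] * 4,
        )
        assert herd_dprime(t, "summer")["elk"] == pytest.approx(1.0)

    def test_disjoint_equal_total_species_profiles(self):
        t = make_table(
            [[8, 0], [0, 8]],
            species=["elk", "bison"],
            season=["summer"] * 2,
        )
        assert np.allclose(species_dprime(t, "summer").values, 1.0)

    def test_herd_matches_per_sample_brute_force(self, small_dataset):
        table, _, _ = small_dataset
        got = herd_dprime(table, "winter")
        sub = table.season_filter(("winter",))
        A = sub.counts.values.astype(float)
        q = A.sum(axis=0) / A.sum()
        qmin = q[q > 0].min()
        per_sample = []
        for row in A:
            p = row / row.sum()
            d = sum(pi * np.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)
            per_sample.append(min(max(d, 0.0) / np.log(1 / qmin), 1.0))
        per_sample = np.array(per_sample)
        for sp in got.index:
            mask = (sub.sample_meta["species"] == sp).values
            assert got[sp] == pytest.approx(per_sample[mask].mean(), abs=1e-9)

    def test_species_matches_hand_network(self, small_dataset):
        table, _, _ = small_dataset
        got = species_dprime(table, "summer")
        sub = table.season_filter(("summer",))
        rel = sub.counts.div(sub.counts.sum(axis=1), axis=0)
        means = rel.groupby(sub.sample_meta["species"]).mean()
        A = means.values
        q = A.sum(axis=0) / A.sum()
        qmin = q[q > 0].min()
        for i, sp in enumerate(means.index):
            p = A[i] / A[i].sum()
            d = sum(pi * np.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)
            assert got[sp] == pytest.approx(
                min(max(d, 0.0) / np.log(1 / qmin), 1.0), abs=1e-9
            )

    def test_single_species_season_is_error(self):
        t = make_table([[1, 2], [3, 4]], species=["elk", "elk"])
        with pytest.raises(DietTableError):
            species_dprime(t, "summer")
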