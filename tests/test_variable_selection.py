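import numpy as np
import pandas as pd
import pytest

from nirselect.core_io import WavenumberGrid
from nirselect.pls import cross_validate
from nirselect.synthetic_data import BandSpec, SyntheticConfig, generate_dataset
from nirselect.variable_selection import (
    SelectionError,
    SelectionResult,
    cars_ratio_schedule,
    cars_select,
    consensus_vote,
    lpg_select,
    mcuve_select,
    spa_select,
)

from conftest import make_set


def two_band_set(seed: int, n_noise: int = 48):
    """40 samples, 2 informative variables + noise: a small recovery problem."""
    grid = WavenumberGrid(6000.0 - 4.0 * np.arange(n_noise + 2))
    c1, c2 = float(grid.points[10]), float(grid.points[35])
    cfg = SyntheticConfig(
        tissue="BFL",
        n_per_class=(8, 8, 8, 8, 8),
        grid=grid,
        bands=[
            BandSpec(center=c1, width=2.0, amplitude_by_class=(0.04, 0.06, 0.08, 0.10, 0.12)),
            BandSpec(center=c2, width=2.0, amplitude_by_class=(0.12, 0.10, 0.08, 0.06, 0.04)),
        ],
        baseline_jitter_sd=0.005,
        noise_sd=0.005,
        seed=seed,
    )
    s, truth = generate_dataset(cfg)
    return s, truth


class TestCars:
    def test_ratio_schedule_endpoints(self):
        for p, n_iter in ((886, 50), (50, 20)):
            r = cars_ratio_schedule(p, n_iter)
            assert round(r[0] * p) == p
            assert round(r[-1] * p) == 2

    def test_recovers_planted_variables_with_high_frequency(self):
        freqs = []
        recovered = []
        for seed in range(20):
            s, truth = two_band_set(seed)
            res = cars_select(s, n_runs=15, n_iter=25, seed=seed)
            idx = [s.grid.nearest_index(t) for t in truth]
            freqs.append(res.scores["frequency"].to_numpy()[idx].mean())
            recovered.append(all(np.min(np.abs(res.selected - t)) < 1e-6 for t in truth))
        assert np.mean(freqs) >= 0.9
        assert np.mean(recovered) >= 0.9

    def test_best_rmsecv_not_worse_than_full_model(self):
        s, _ = two_band_set(3)
        res = cars_select(s, n_runs=8, n_iter=25, seed=3)
        cv_seed = int(np.random.default_rng([3, 8]).integers(2**31 - 1))
        full = cross_validate(s.absorbance, s.region_classes.astype(float), 5, seed=cv_seed)
        assert min(res.rmsecv_path) <= full.rmsecv

    def test_deterministic(self):
        s, _ = two_band_set(1)
        a = cars_select(s, n_runs=5, n_iter=20, seed=9)
        b = cars_select(s, n_runs=5, n_iter=20, seed=9)
        assert np.array_equal(a.selected, b.selected)


class TestMcuve:
    def test_informative_variables_outrank_noise_median(self):
        margins = []
        for seed in range(20):
            s, truth = two_band_set(seed)
            res = mcuve_select(s, n_mc=40, forward_max=10, seed=seed)
            ri = np.abs(res.scores["ri"].to_numpy())
            idx = [s.grid.nearest_index(t) for t in truth]
            noise = np.delete(ri, idx)
            margins.append(min(ri[idx]) > np.median(noise))
        assert np.mean(margins) >= 0.95

    def test_duplicated_column_gets_equal_ri(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10))
        X[:, 4] = X[:, 7]  # exact duplicate
        y = X[:, 4] + 0.1 * rng.normal(size=30)
        s = make_set(X)
        res = mcuve_select(s, y=y, n_mc=30, forward_max=5, seed=0)
        ri = res.scores["ri"].to_numpy()
        assert ri[4] == pytest.approx(ri[7], rel=1e-9)

    def test_permuted_labels_erase_planted_reliability(self):
        # breaking the label-spectrum link collapses a planted variable's
        # reliability index toward the bulk of the noise distribution
        true_ri, perm_ri = [], []
        for seed in range(10):
            s, truth = two_band_set(seed)
            j = s.grid.nearest_index(truth[0])
            res_t = mcuve_select(s, n_mc=40, forward_max=5, seed=seed)
            y_perm = np.random.default_rng(seed).permutation(
                s.region_classes.astype(float)
            )
            res_p = mcuve_select(s, y=y_perm, n_mc=40, forward_max=5, seed=seed)
            true_ri.append(abs(res_t.scores["ri"].iloc[j]))
            ri_p = np.abs(res_p.scores["ri"].to_numpy())
            perm_ri.append(ri_p[j] / np.median(ri_p))
        assert np.mean(true_ri) > 3 * np.mean(perm_ri)

    def test_threshold_is_ri_of_last_kept_variable(self):
        s, _ = two_band_set(0)
        res = mcuve_select(s, n_mc=30, forward_max=10, seed=0)
        ri = np.abs(res.scores["ri"].to_numpy())
        kept_ri = sorted(
            (ri[s.grid.nearest_index(w)] for w in res.selected), reverse=True
        )
        assert res.chosen_threshold == pytest.approx(kept_ri[-1])


class TestSpa:
    def test_informative_variable_scores_above_two(self):
        wins = []
        for seed in range(20):
            s, truth = two_band_set(seed)
            res = spa_select(s, n_mc=400, q_vars=5, seed=seed)
            coss = res.scores["coss"].to_numpy()
            idx = [s.grid.nearest_index(t) for t in truth]
            wins.append(all(coss[i] > 2 for i in idx))
        assert np.mean(wins) >= 0.9

    def test_noise_variable_median_coss_below_one(self):
        medians = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = make_set(rng.normal(size=(40, 30)))
            y = (np.arange(40) % 5 + 1).astype(float)
            res = spa_select(s, y=rng.permutation(y), n_mc=300, q_vars=5, seed=seed)
            medians.append(np.median(res.scores["coss"].to_numpy()))
        assert np.median(medians) < 1.0

    def test_every_variable_sampled_or_error(self):
        big, _ = two_band_set(0, n_noise=498)
        with pytest.raises(SelectionError, match="n_mc"):
            spa_select(big, n_mc=100, q_vars=4, seed=0)
        s, _ = two_band_set(0)
        res = spa_select(s, n_mc=300, q_vars=5, seed=0)
        assert res.scores["n_included"].min() >= 1


class TestLpg:
    def test_collinear_middle_variable_not_selected(self):
        # rank-one data: all loading points sit on a line through the plane
        rng = np.random.default_rng(0)
        t_lat = rng.normal(size=30)
        X = np.outer(t_lat, [1.0, 2.0, -3.0])
        s = make_set(X)
        res = lpg_select(s)
        middle = float(s.grid.points[1])
        assert middle not in set(np.round(res.selected, 6))

    def test_triangle_loadings_all_selected(self):
        # three mutually independent variables: loading points form a
        # triangle, so every variable lies on the convex hull
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        s = make_set(X)
        res = lpg_select(s)
        assert len(res.selected) == 3

    def test_planted_band_centers_are_vertices(self):
        s, truth = two_band_set(2)
        res = lpg_select(s)
        for t in truth:
            assert np.min(np.abs(res.selected - t)) <= 2 * s.grid.spacing + 1e-9


class TestConsensus:
    def _mk(self, wns):
        return SelectionResult(
            method="x", selected=np.asarray(wns, dtype=float), scores=pd.DataFrame()
        )

    def test_counting_example(self):
        sets = [self._mk(w) for w in ([1.0, 2.0], [2.0, 3.0], [3.0], [4.0])]
        assert consensus_vote(sets, min_votes=2).tolist() == [2.0, 3.0]

    def test_min_votes_one_is_union(self):
        sets = [self._mk(w) for w in ([1.0], [2.0], [3.0])]
        assert consensus_vote(sets, min_votes=1).tolist() == [1.0, 2.0, 3.0]

    def test_identical_sets_idempotent(self):
        sets = [self._mk([5.0, 6.0])] * 4
        for v in (1, 2, 3, 4):
            assert consensus_vote(sets, min_votes=v).tolist() == [5.0, 6.0]

    def test_needs_two_results(self):
        with pytest.raises(SelectionError):
            consensus_vote([self._mk([1.0])])
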