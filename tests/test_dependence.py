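"""Relative distances, bootstrapped KL vs uniform, MRVL, repeated-measures ANOVA."""

import numpy as np
import pytest
from scipy import stats

from wholereport.dependence import (
    dependence_report,
    kl_baseline,
    kl_bootstrap,
    mrvl_summary,
    relative_distances,
    rm_anova_oneway,
    RelativeDistanceSample,
)
from wholereport.synth import ObserverConfig, sample_stimuli, simulate_independent_observer
from wholereport.task import SessionDataset, TrialRecord


def _dataset(reported_lists, task="continuous"):
    trials = []
    for i, rep in enumerate(reported_lists):
        n = len(rep)
        trials.append(TrialRecord(trial_id=i, set_size=n, presented=np.zeros(n) if task ==
                                  "continuous" else np.arange(n) * np.pi / 4,
                                  reported=rep, locations=np.arange(n)))
    return SessionDataset(participant_id="p", task=task, trials=trials)


class TestRelativeDistances:
    def test_simple_pair(self):
        ds = _dataset([[0.0, np.pi / 4, 1.0]])
        s = relative_distances(ds, (1, 2))
        assert s.distances[0] == pytest.approx(np.pi / 4)

    def test_wraps_across_boundary(self):
        ds = _dataset([[np.pi - 0.1, -np.pi + 0.1]])
        s = relative_distances(ds, (1, 2))
        assert s.distances[0] == pytest.approx(0.2)

    def test_count_matches_qualifying_trials(self, rng):
        reported = [rng.uniform(-np.pi, np.pi, 6) for _ in range(50)]
        reported += [rng.uniform(-np.pi, np.pi, 3) for _ in range(20)]
        ds = _dataset(reported)
        assert relative_distances(ds, (1, 6)).n == 50
        assert relative_distances(ds, (1, 2)).n == 70

    def test_invalid_pair_rejected(self):
        ds = _dataset([[0.0, 1.0]])
        with pytest.raises(ValueError):
            relative_distances(ds, (2, 1))
        with pytest.raises(ValueError):
            relative_distances(ds, (1, 5))


class TestKLBootstrap:
    def test_point_mass_gives_full_divergence(self):
        s = RelativeDistanceSample((1, 2), np.zeros(200))
        est = kl_bootstrap(s, n_bins=8, n_boot=100, seed=0)
        assert est.median_bits == pytest.approx(3.0)
        assert est.q025 == pytest.approx(3.0)

    def test_seeded_reproducibility(self):
        s = RelativeDistanceSample((1, 2), np.random.default_rng(0).uniform(-3, 3, 300))
        a = kl_bootstrap(s, 36, n_boot=200, seed=5)
        b = kl_bootstrap(s, 36, n_boot=200, seed=5)
        assert a == b

    def test_uniform_sample_within_baseline_band(self):
        rng = np.random.default_rng(1)
        s = RelativeDistanceSample((1, 2), rng.uniform(-np.pi, np.pi, 500))
        data = kl_bootstrap(s, 36, n_boot=1000, seed=2)
        base = kl_baseline(500, 36, n_boot=1000, seed=3)
        assert base.q025 <= data.median_bits <= base.q975

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            kl_bootstrap(RelativeDistanceSample((1, 2), np.array([])), 8)


class TestKLBaseline:
    def test_positive_bias_and_shrinks_with_sample_size(self):
        small = kl_baseline(100, 36, n_boot=500, seed=4)
        big = kl_baseline(10_000, 36, n_boot=500, seed=5)
        assert small.median_bits > 0
        assert big.median_bits < small.median_bits

    def test_matches_chisquare_approximation(self):
        # two resampling layers -> bias ~ 2 * (n_bins - 1) / (2 N ln 2)
        est = kl_baseline(2000, 36, n_boot=1000, seed=6)
        approx = 35.0 / (2000 * np.log(2))
        assert approx / 2 < est.median_bits < approx * 2

    def test_is_flagged_as_baseline(self):
        assert kl_baseline(50, 8, n_boot=50, seed=0).is_baseline


class TestDependenceReport:
    def test_row_count_is_participants_times_pairs(self):
        datasets = []
        for p in range(3):
            stim = sample_stimuli("continuous", 4, 40, p)
            datasets.append(simulate_independent_observer(
                stim, ObserverConfig(kind="independent", seed=p + 10), "continuous", f"p{p}"))
        rep = dependence_report(datasets, n_boot=100, seed=0)
        assert len(rep) == 3 * 3  # pairs (1,2),(1,3),(1,4) per participant


class TestMrvlSummary:
    def test_perfect_reports_have_unit_mrvl(self):
        ds = _dataset([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        m = mrvl_summary(ds)
        np.testing.assert_allclose(m["mrvl"].dropna(), 1.0)

    def test_mrvl_decreases_with_noisier_later_reports(self, rng):
        # construct noise growing with report order
        trials = []
        for i in range(400):
            noise = np.concatenate([rng.vonmises(0, 50, 2), rng.vonmises(0, 2, 2)])
            trials.append(TrialRecord(trial_id=i, set_size=4, presented=np.zeros(4),
                                      reported=noise, locations=np.arange(4)))
        ds = SessionDataset(participant_id="p", task="continuous", trials=trials)
        m = mrvl_summary(ds)
        per_order = m.dropna(subset=["report_order"]).sort_values("report_order")
        vals = per_order["mrvl"].to_numpy()
        assert vals[0] > vals[-1]

    def test_all_guess_dataset_has_tiny_mrvl(self, rng):
        reported = rng.uniform(-np.pi, np.pi, (1250, 4))
        ds = _dataset(list(reported))
        m = mrvl_summary(ds)
        pooled = m[m["report_order"].isna()]
        assert (pooled["mrvl"] < 0.05).all()

    def test_small_cells_flagged(self):
        ds = _dataset([[0.1, 0.2]])
        m = mrvl_summary(ds, min_reports=3)
        pooled = m[m["report_order"].isna()].iloc[0]
        assert pooled["flagged"] and np.isnan(pooled["mrvl"])


def _rm_anova_oracle(matrix):
    """Independent sums-of-squares computation for the blocked one-way design."""
    matrix = np.asarray(matrix, dtype=float)
    s, l = matrix.shape
    grand = matrix.mean()
    ss_level = s * ((matrix.mean(axis=0) - grand) ** 2).sum()
    ss_subj = l * ((matrix.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((matrix - grand) ** 2).sum()
    ss_err = ss_tot - ss_level - ss_subj
    df_l, df_e = l - 1, (l - 1) * (s - 1)
    f = (ss_level / df_l) / (ss_err / df_e)
    p = stats.f.sf(f, df_l, df_e)
    return f, df_l, df_e, p


class TestRmAnova:
    def test_matches_sum_of_squares_oracle(self):
        matrix = np.array([[1.0, 2.0, 4.0], [1.5, 2.5, 3.5], [0.5, 2.2, 4.4]])
        res = rm_anova_oneway(matrix)
        f, df_l, df_e, p = _rm_anova_oracle(matrix)
        assert res.F == pytest.approx(f, abs=1e-10)
        assert (res.df_effect, res.df_error) == (df_l, df_e)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_zero_effect_when_level_means_identical(self):
        matrix = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [3.5, 3.5, 3.5]])
        matrix = matrix + np.array([[0.1, -0.1, 0.0], [-0.2, 0.2, 0.0], [0.0, 0.1, -0.1]])
        matrix -= matrix.mean(axis=0, keepdims=True)  # equalize level means exactly
        res = rm_anova_oneway(matrix)
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        matrix = rng.normal(size=(7, 4))
        res = rm_anova_oneway(matrix)
        assert res.df_effect == 3
        assert res.df_error == 18

    def test_incomplete_matrix_rejected(self):
        bad = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            rm_anova_oneway(bad)
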