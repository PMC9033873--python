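"""Agreement statistics, t-tests, cross matrix, and t-SNE embedding."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import stdtr

from brightwell.evaluate import (
    cross_evaluate,
    embed_features,
    hill_region_labels,
    linear_agreement,
    series_from_predictions,
    t_test,
)
from brightwell.hill import DoseResponseParams, hill_response
from conftest import DOSES


def ols_oracle(x, y):
    """Textbook closed forms computed from raw sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    return slope, intercept, r * r


def unpaired_t_oracle(a, b):
    """Pooled-variance Student t with p from the t CDF."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * (1 - stdtr(df, abs(t)))
    return t, p


def paired_t_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    p = 2 * (1 - stdtr(len(d) - 1, abs(t)))
    return t, p


class TestLinearAgreement:
    def test_identity_prediction(self):
        m = np.array([0.1, 0.5, 1.4, 1.9])
        a = linear_agreement(m, m)
        assert a.r_squared == pytest.approx(1.0)
        assert a.slope == pytest.approx(1.0)
        assert a.intercept == pytest.approx(0.0, abs=1e-12)
        assert a.mean_difference == 0 and a.sd_difference == 0

    def test_exact_line(self):
        a = linear_agreement([0, 1, 2], [0, 2, 4])
        assert a.slope == pytest.approx(2.0)
        assert a.intercept == pytest.approx(0.0, abs=1e-12)
        assert a.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_oracle_on_random_sample(self, rng):
        m = rng.uniform(0, 2, 50)
        p = 0.8 * m + 0.1 + rng.normal(0, 0.2, 50)
        a = linear_agreement(m, p)
        slope, intercept, r2 = ols_oracle(m, p)
        assert a.slope == pytest.approx(slope, abs=1e-10)
        assert a.intercept == pytest.approx(intercept, abs=1e-10)
        assert a.r_squared == pytest.approx(r2, abs=1e-10)
        assert a.mean_difference == pytest.approx(np.mean(p - m), abs=1e-12)
        assert a.sd_difference == pytest.approx(np.std(p - m, ddof=1), abs=1e-12)

    def test_zero_variance_in_measured_flagged(self):
        a = linear_agreement([1.0, 1.0, 1.0], [0.5, 0.6, 0.7])
        assert a.degenerate
        assert math.isnan(a.slope)

    def test_r_squared_equals_squared_pearson(self, rng):
        m = rng.uniform(0, 2, 40)
        p = m + rng.normal(0, 0.3, 40)
        a = linear_agreement(m, p)
        r = np.corrcoef(m, p)[0, 1]
        assert a.r_squared == pytest.approx(r * r, abs=1e-12)


class TestTTest:
    def test_paired_identical_samples(self):
        r = t_test([1.0, 2, 3], [1.0, 2, 3], paired=True)
        assert r.statistic == 0 and r.p_value == 1

    def test_unpaired_matches_hand_computation(self, rng):
        a = rng.normal(0.5, 0.1, 5)
        b = rng.normal(0.7, 0.1, 5)
        r = t_test(a, b, paired=False)
        t, p = unpaired_t_oracle(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-8)
        assert r.p_value == pytest.approx(p, abs=1e-8)
        assert r.df == 8

    def test_paired_matches_hand_computation(self, rng):
        a = rng.normal(0.5, 0.1, 8)
        b = a + rng.normal(0.05, 0.05, 8)
        r = t_test(a, b, paired=True)
        t, p = paired_t_oracle(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-8)
        assert r.p_value == pytest.approx(p, abs=1e-8)

    def test_group_swap_flips_sign_keeps_p(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        r1 = t_test(a, b)
        r2 = t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_constant_offset_pairs_flagged_zero_variance(self):
        a = np.array([1.0, 2.0, 3.0])
        r = t_test(a, a + 0.5, paired=True)
        assert r.zero_variance
        assert math.isnan(r.p_value)

    def test_welch_option_differs_with_unequal_variance(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(0.5, 2.0, 10)
        student = t_test(a, b, equal_var=True)
        welch = t_test(a, b, equal_var=False)
        assert student.df != pytest.approx(welch.df)


class TestCrossEvaluate:
    def _preds(self, rng, quality):
        rows = []
        truth = DoseResponseParams(1.8, 0.15, 0.4, 1.1)
        for s in range(1, 3):
            for rep in range(1, 4):
                for c in DOSES:
                    v = hill_response(truth, c)
                    noise = rng.normal(0, 0.05)
                    pred = v + rng.normal(0, 0.05 + (1 - quality))
                    rows.append(
                        {
                            "well_id": f"s{s}r{rep}c{c}",
                            "set": s, "replicate": rep,
                            "concentration_um": c,
                            "measured_viability": np.clip(v + noise, 0, 2),
                            "predicted_viability": np.clip(pred, 0, 2),
                        }
                    )
        return pd.DataFrame(rows)

    def test_matrix_marks_autologous_and_best_trainer(self, rng):
        good = self._preds(rng, 1.0)
        bad = self._preds(rng, 0.3)
        matrix = cross_evaluate({
            ("A", "A"): good, ("B", "A"): bad,
            ("A", "B"): bad, ("B", "B"): good,
        })
        assert matrix.entries[("A", "A")].autologous
        assert not matrix.entries[("B", "A")].autologous
        assert matrix.best_trainer("A") == "A"
        assert matrix.best_trainer("B") == "B"
        r2 = matrix.r2_table()
        assert r2.loc["A", "A"] > r2.loc["B", "A"]

    def test_single_line_gives_1x1_matrix(self, rng):
        m = cross_evaluate({("A", "A"): self._preds(rng, 1.0)})
        assert len(m.entries) == 1
        assert m.entries[("A", "A")].autologous

    def test_ic50_ttests_present_for_converged_series(self, rng):
        m = cross_evaluate({("A", "A"): self._preds(rng, 1.0)})
        e = m.entries[("A", "A")]
        assert e.unpaired is not None and 0 <= e.unpaired.p_value <= 1
        assert e.paired is not None and e.paired.paired


class TestSeriesFromPredictions:
    def test_grouping_by_set_and_replicate(self, rng):
        df = TestCrossEvaluate._preds(TestCrossEvaluate(), rng, 1.0)
        series = series_from_predictions(df)
        assert len(series) == 6  # 2 sets x 3 replicates
        assert all(len(s.concentrations_um) == 11 for s in series)
        assert all(np.all(np.diff(s.concentrations_um) > 0) for s in series)


class TestHillRegions:
    def test_labels_partition_the_curve(self):
        p = DoseResponseParams(1.8, 0.2, 0.4, 1.2)
        labels = hill_region_labels(DOSES, p)
        assert labels[0] == "top"
        assert labels[-1] == "bottom"
        assert "slope" in labels

    def test_unconverged_fit_rejected(self):
        from brightwell.hill import HillFitResult

        bad = HillFitResult(params=None, rss=0, converged=False, n_starts=0)
        with pytest.raises(ValueError):
            hill_region_labels(DOSES, bad)


class TestEmbedding:
    def _three_regime_features(self, rng, n_per=20, d=30):
        """Synthetic features from three well-separated density regimes."""
        centers = rng.normal(0, 5, (3, d))
        feats, concs = [], []
        regime_doses = [0.0001, 0.4, 100.0]  # top, slope, bottom
        for i in range(3):
            feats.append(centers[i] + rng.normal(0, 0.3, (n_per, d)))
            concs.extend([regime_doses[i]] * n_per)
        return np.vstack(feats), np.array(concs)

    def test_three_regimes_have_positive_silhouette(self, rng):
        from sklearn.metrics import silhouette_score

        x, concs = self._three_regime_features(rng)
        p = DoseResponseParams(1.8, 0.2, 0.4, 1.2)
        emb = embed_features(x, concs, p, seed=0)
        labels = emb.region_labels
        assert set(labels) == {"top", "slope", "bottom"}
        assert silhouette_score(emb.coordinates, labels) > 0

    def test_duplicated_points_stay_close(self, rng):
        x, concs = self._three_regime_features(rng, n_per=10)
        x2 = np.vstack([x, x[:5]])
        c2 = np.concatenate([concs, concs[:5]])
        p = DoseResponseParams(1.8, 0.2, 0.4, 1.2)
        emb = embed_features(x2, c2, p, seed=0)
        coords = emb.coordinates
        diam = np.ptp(coords, axis=0).max()
        for i in range(5):
            d = np.linalg.norm(coords[len(x) + i] - coords[i])
            assert d < 0.05 * diam

    def test_fixed_seed_reproducible(self, rng):
        x, concs = self._three_regime_features(rng)
        p = DoseResponseParams(1.8, 0.2, 0.4, 1.2)
        e1 = embed_features(x, concs, p, seed=3)
        e2 = embed_features(x, concs, p, seed=3)
        assert np.array_equal(e1.coordinates, e2.coordinates)

    def test_too_few_points_rejected(self, rng):
        p = DoseResponseParams(1.8, 0.2, 0.4, 1.2)
        with pytest.raises(ValueError):
            embed_features(rng.random((5, 10)), [0.1] * 5, p)
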