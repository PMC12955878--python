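"""Segmentation metrics, AUC, correlations, C-index, KM/log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hist_st.grid import LabelGrid
from hist_st.metrics import (classification_metrics, concordance_index,
                             confusion_metrics, km_logrank, mean_t_ci,
                             median_split, per_gene_correlation, roc_auc)


def _random_grid_pair(rng, h=6, w=8):
    truth = LabelGrid((rng.random((h, w)) > 0.5).astype(float),
                      rng.random((h, w)) > 0.2)
    probs = rng.random((h, w))
    return probs, truth


class TestConfusionMetrics:
    def test_perfect_prediction_gives_all_ones(self):
        rng = np.random.default_rng(0)
        truth = LabelGrid((rng.random((5, 5)) > 0.5).astype(float),
                          np.ones((5, 5), bool))
        m = confusion_metrics(truth.values, truth)
        for key in ("iou", "dice", "se", "pc", "f1", "sp", "acc"):
            assert m[key] == 1.0

    def test_dice_iou_identity_holds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            probs, truth = _random_grid_pair(rng)
            m = confusion_metrics(probs, truth)
            if np.isfinite(m["iou"]):
                assert m["dice"] == pytest.approx(2 * m["iou"] / (1 + m["iou"]))

    def test_counts_match_cell_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            probs, truth = _random_grid_pair(rng)
            m = confusion_metrics(probs, truth, threshold=0.5)
            tp = fp = tn = fn = 0
            for r in range(truth.values.shape[0]):
                for c in range(truth.values.shape[1]):
                    if not truth.validity[r, c]:
                        continue
                    pred = probs[r, c] >= 0.5
                    pos = truth.values[r, c] >= 0.5
                    tp += pred and pos
                    fp += pred and not pos
                    fn += (not pred) and pos
                    tn += (not pred) and (not pos)
            assert (m["counts"].tp, m["counts"].fp, m["counts"].tn,
                    m["counts"].fn) == (tp, fp, tn, fn)
            assert m["counts"].total == int(truth.validity.sum())

    def test_empty_positive_class_reports_missing(self):
        truth = LabelGrid(np.zeros((3, 3)), np.ones((3, 3), bool))
        m = confusion_metrics(np.zeros((3, 3)), truth)
        assert np.isnan(m["se"])
        assert m["sp"] == 1.0

    def test_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(3)
        probs = rng.random(30)
        labels = (rng.random(30) > 0.5).astype(float)
        perm = rng.permutation(30)
        a = confusion_metrics(probs.reshape(5, 6),
                              LabelGrid(labels.reshape(5, 6), np.ones((5, 6), bool)))
        b = confusion_metrics(probs[perm].reshape(5, 6),
                              LabelGrid(labels[perm].reshape(5, 6),
                                        np.ones((5, 6), bool)))
        assert a["iou"] == b["iou"] and a["acc"] == b["acc"]


class TestAuc:
    def test_perfect_separation_gives_one(self):
        truth = LabelGrid(np.array([[1, 1], [0, 0.]]), np.ones((2, 2), bool))
        assert roc_auc(np.array([[0.9, 0.8], [0.1, 0.2]]), truth) == 1.0

    def test_constant_scores_give_half(self):
        truth = LabelGrid(np.array([[1, 0], [1, 0.]]), np.ones((2, 2), bool))
        assert roc_auc(np.full((2, 2), 0.5), truth) == 0.5

    def test_matches_mann_whitney_pair_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 40
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # with ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            truth = LabelGrid(labels.reshape(5, 8).astype(float),
                              np.ones((5, 8), bool))
            got = roc_auc(scores.reshape(5, 8), truth)
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
                     for p in pos for q in neg]
            assert got == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(24)
        labels = rng.integers(0, 2, 24)
        labels[:2] = [0, 1]
        truth = LabelGrid(labels.reshape(4, 6).astype(float), np.ones((4, 6), bool))
        a = roc_auc(scores.reshape(4, 6), truth)
        b = roc_auc(np.exp(5 * scores).reshape(4, 6), truth)
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        truth = LabelGrid(np.ones((2, 2)), np.ones((2, 2), bool))
        with pytest.raises(ValueError):
            roc_auc(np.random.default_rng(0).random((2, 2)), truth)


class TestCorrelation:
    def _tables(self, rng, g=5, n=30):
        t = pd.DataFrame(rng.normal(size=(g, n)),
                         index=[f"g{i}" for i in range(g)])
        p = t + rng.normal(scale=0.5, size=(g, n))
        return p, t

    def test_identical_tables_give_r_one(self):
        rng = np.random.default_rng(6)
        p, t = self._tables(rng)
        s = per_gene_correlation(t, t)
        assert np.allclose(s.per_gene_r, 1.0)

    def test_negated_tables_give_r_minus_one(self):
        rng = np.random.default_rng(7)
        p, t = self._tables(rng)
        s = per_gene_correlation(-t, t)
        assert np.allclose(s.per_gene_r, -1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        p, t = self._tables(rng)
        s = per_gene_correlation(p, t)
        for gene in p.index:
            x, y = p.loc[gene].to_numpy(), t.loc[gene].to_numpy()
            xz, yz = x - x.mean(), y - y.mean()
            manual = (xz * yz).sum() / np.sqrt((xz ** 2).sum() * (yz ** 2).sum())
            assert s.per_gene_r[gene] == pytest.approx(manual, abs=1e-12)

    def test_spearman_is_rank_based(self):
        rng = np.random.default_rng(9)
        p, t = self._tables(rng, g=1)
        s = per_gene_correlation(np.exp(p), t, kind="spearman")
        s2 = per_gene_correlation(p, t, kind="spearman")
        assert s.per_gene_r.iloc[0] == pytest.approx(s2.per_gene_r.iloc[0])

    def test_zero_variance_gene_excluded_with_warning(self):
        t = pd.DataFrame([[1.0, 2, 3], [4, 4, 4]], index=["a", "b"])
        with pytest.warns(UserWarning, match="zero variance"):
            s = per_gene_correlation(t, t)
        assert list(s.per_gene_r.index) == ["a"]

    def test_ci_width_shrinks_like_inverse_sqrt_n(self):
        rng = np.random.default_rng(10)
        widths = []
        for n in (10, 40, 160):
            vals = rng.normal(0.5, 0.1, size=n)
            _, (lo, hi) = mean_t_ci(vals)
            widths.append(hi - lo)
        assert widths[0] > 1.5 * widths[1] > 1.5 * 1.5 * widths[2]


class TestConcordance:
    def test_perfectly_anti_ordered_risks_give_one(self):
        times = np.array([1.0, 2, 3, 4])
        risks = np.array([4.0, 3, 2, 1])
        assert concordance_index(risks, times, np.ones(4, int)) == 1.0

    def test_risks_ordered_with_time_give_zero(self):
        times = np.array([1.0, 2, 3, 4])
        assert concordance_index(times, times, np.ones(4, int)) == 0.0

    def test_matches_exhaustive_pair_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = 25
            risks = rng.choice(np.linspace(0, 1, 7), size=n)
            times = rng.exponential(1.0, size=n)
            events = rng.integers(0, 2, n)
            events[0] = 1
            conc = comp = 0.0
            for i in range(n):
                for j in range(n):
                    if times[i] < times[j] and events[i] == 1:
                        comp += 1
                        conc += (1.0 if risks[i] > risks[j]
                                 else 0.5 if risks[i] == risks[j] else 0.0)
            assert concordance_index(risks, times, events) == pytest.approx(
                conc / comp, abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [1, 2], [0, 0])


class TestKmLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        events = np.array([1, 1, 0, 1, 1, 1, 1, 0, 1, 1])
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = km_logrank(times, events, groups)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_independent_logrank_implementation(self):
        """Direct evaluation of the log-rank chi-square from the risk tables."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = 40
            times = np.round(rng.exponential(5.0, size=n), 1)
            events = rng.integers(0, 2, n)
            events[:4] = 1
            groups = np.where(rng.random(n) < 0.5, "high", "low")
            if len(np.unique(groups)) < 2:
                continue
            res = km_logrank(times, events, groups)
            # hand implementation: sum over distinct event times
            o_minus_e = 0.0
            var = 0.0
            a = groups == "high"
            for t in np.unique(times[events == 1]):
                at_risk = times >= t
                n1, n2 = at_risk[a].sum(), at_risk[~a].sum()
                d = ((times == t) & (events == 1)).sum()
                d1 = ((times == t) & (events == 1) & a).sum()
                ntot = n1 + n2
                o_minus_e += d1 - d * n1 / ntot
                if ntot > 1:
                    var += d * (n1 / ntot) * (n2 / ntot) * (ntot - d) / (ntot - 1)
            chi2 = o_minus_e ** 2 / var
            assert res["statistic"] == pytest.approx(chi2, abs=1e-8)
            assert res["p_value"] == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-8)

    def test_median_split_sizes_and_tie_convention(self):
        risks = np.array([1.0, 2, 3, 4, 5])
        groups = median_split(risks)
        assert (groups == "low").sum() == 3    # ceil(n/2), median goes low
        assert (groups == "high").sum() == 2
        assert groups[2] == "low"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2], [1, 1], ["a", "a"])


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 1, 0])
        m = classification_metrics(y, y)
        assert all(v == 1.0 for v in m.values())

    def test_all_positive_prediction_recall(self):
        truth = np.array([1, 0, 1, 0])
        m = classification_metrics(np.ones(4, int), truth)
        assert m["recall"] == 1.0
        assert m["precision"] == 0.5

    def test_matches_confusion_count_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            truth = rng.integers(0, 2, 30)
            pred = rng.integers(0, 2, 30)
            m = classification_metrics(pred, truth)
            tp = ((pred == 1) & (truth == 1)).sum()
            fp = ((pred == 1) & (truth == 0)).sum()
            fn = ((pred == 0) & (truth == 1)).sum()
            acc = (pred == truth).mean()
            assert m["accuracy"] == pytest.approx(acc)
            if tp + fp:
                assert m["precision"] == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert m["recall"] == pytest.approx(tp / (tp + fn))
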