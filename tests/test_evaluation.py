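import numpy as np
import pytest

from pseomp.classifier import SVMConfig
from pseomp.evaluation import (
    ConfusionCounts,
    MetricsReport,
    compute_metrics,
    confusion_from_predictions,
    counts_from_rates,
    grid_search,
    jackknife_evaluate,
    roc_auc,
    roc_curve_points,
    round_pct,
)
from pseomp.pseaac import PseAACConfig
from pseomp.seq_io import DatasetManifest
from pseomp.synthetic import SyntheticSpec, generate

from oracles import auroc_oracle, confusion_oracle

# Published-table fixture rows: (sn%, sp%, expected mcc%, oa%, aa%)
TABLE_ROWS = [
    (84.61, 95.11, 78.19, 93.10, 89.86),  # omega 0.5, lam 5, gamma 0.07
    (78.85, 96.59, 77.49, 93.19, 87.72),  # omega 0.2, lam 3, gamma 0.08
    (79.81, 96.59, 78.17, 93.38, 88.20),  # omega 0.1, lam 5, gamma 0.07
]


class TestConfusion:
    def test_mixed_example(self):
        c = confusion_from_predictions([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_identity_prediction_has_no_errors(self):
        y = [1, 0, 1, 1, 0]
        c = confusion_from_predictions(y, y)
        assert (c.fn, c.fp) == (0, 0)

    def test_random_pairs_match_loop_oracle(self):
        rng = np.random.default_rng(10)
        y_true = rng.integers(0, 2, size=100)
        y_pred = rng.integers(0, 2, size=100)
        c = confusion_from_predictions(y_true, y_pred)
        assert (c.tp, c.fn, c.fp, c.tn) == confusion_oracle(y_true, y_pred)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([1, 0], [1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, fp=0, tn=0)


class TestMetrics:
    @pytest.mark.parametrize("sn,sp,mcc,oa,aa", TABLE_ROWS)
    def test_published_rows_reproduce_from_reconstructed_counts(
        self, sn, sp, mcc, oa, aa
    ):
        # Sn/Sp are the reconstruction inputs (published tables mix
        # rounding and truncation for them); MCC/OA/AA must reproduce
        # exactly at 2-decimal rounding.
        c = counts_from_rates(sn, sp, 208, 879)
        r = compute_metrics(c)
        assert round_pct(r.mcc) == mcc
        assert round_pct(r.oa) == oa
        assert round_pct(r.aa) == aa

    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=208, fn=0, fp=0, tn=879))
        assert (r.sn, r.sp, r.oa, r.aa, r.mcc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_aa_is_mean_of_sn_sp_and_oa_is_count_ratio(self):
        c = ConfusionCounts(tp=5, fn=3, fp=2, tn=10)
        r = compute_metrics(c)
        assert r.aa == (r.sn + r.sp) / 2
        assert r.oa == (c.tp + c.tn) / c.n

    def test_mcc_undefined_with_zero_marginal(self):
        c = ConfusionCounts(tp=0, fn=4, fp=0, tn=6)  # TP+FP == 0
        with pytest.warns(UserWarning, match="MCC undefined"):
            r = compute_metrics(c)
        assert r.mcc is None

    def test_mcc_bounds_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tp, fn, fp, tn = (int(v) for v in rng.integers(1, 50, size=4))
            r = compute_metrics(ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn))
            assert -1.0 <= r.mcc <= 1.0
            if fn == 0 and fp == 0:
                assert r.mcc == pytest.approx(1.0)

    def test_percent_display_uses_half_up_rounding(self):
        assert round_pct(0.93102) == 93.10
        assert round_pct(0.84615) == 84.62  # half-away-from-zero
        assert round_pct(0.777749) == 77.77


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        assert roc_auc([1, 1, 0, 0], [2.0, 1.5, -1.0, -2.0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            assert roc_auc(y, scores) == pytest.approx(
                auroc_oracle(y, scores), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=60)
        scores = rng.normal(size=60)
        assert roc_auc(y, scores) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.1, 0.2])

    def test_curve_endpoints(self):
        pts = roc_curve_points([1, 0], [1.0, -1.0])
        assert tuple(pts[0][1:]) == (0.0, 0.0)
        assert tuple(pts[-1][1:]) == (1.0, 1.0)


class TestCountsFromRates:
    def test_reconstructs_published_confusion_counts(self):
        c = counts_from_rates(84.61, 95.11, 208, 879)
        assert (c.tp, c.fn, c.tn, c.fp) == (176, 32, 836, 43)
        c = counts_from_rates(78.85, 96.59, 208, 879)
        assert (c.tp, c.fn, c.tn, c.fp) == (164, 44, 849, 30)

    def test_perfect_rates(self):
        c = counts_from_rates(100.0, 100.0, 208, 879)
        assert (c.tp, c.fn, c.tn, c.fp) == (208, 0, 879, 0)

    def test_inconsistent_rates_are_an_error(self):
        with pytest.raises(ValueError, match="inconsistent"):
            counts_from_rates(50.0, 90.0, 3, 10)


@pytest.fixture(scope="module")
def small_separable_manifest():
    return generate(SyntheticSpec(n_pos=5, n_neg=5, comp_divergence=0.5,
                                  length_range=(30, 60), seed=21))


class TestJackknife:
    def test_one_fit_per_sample(self, small_separable_manifest, monkeypatch):
        import pseomp.evaluation as ev

        calls = []
        real_train = ev.clf.train

        def counting_train(*args, **kwargs):
            calls.append(1)
            return real_train(*args, **kwargs)

        monkeypatch.setattr(ev.clf, "train", counting_train)
        _, scores = jackknife_evaluate(
            small_separable_manifest, PseAACConfig(), SVMConfig(), scale=True
        )
        assert len(calls) == len(small_separable_manifest)
        assert scores.shape == (len(small_separable_manifest),)

    def test_deterministic_across_runs(self, small_separable_manifest):
        args = (small_separable_manifest, PseAACConfig(), SVMConfig())
        r1, s1 = jackknife_evaluate(*args, scale=True)
        r2, s2 = jackknife_evaluate(*args, scale=True)
        assert np.array_equal(s1, s2)
        assert r1.oa == r2.oa and r1.auroc == r2.auroc

    def test_duplicating_a_sample_changes_its_held_out_score(
        self, small_separable_manifest
    ):
        from pseomp.seq_io import ProteinRecord

        base = small_separable_manifest
        _, scores = jackknife_evaluate(base, PseAACConfig(), SVMConfig(),
                                       scale=True)
        rec0 = base.records[0]
        dup = DatasetManifest(
            records=base.records
            + [ProteinRecord("dup_0", rec0.sequence, rec0.label)]
        )
        _, dup_scores = jackknife_evaluate(dup, PseAACConfig(), SVMConfig(),
                                           scale=True)
        assert dup_scores[0] != scores[0]

    def test_too_small_dataset_is_an_error(self):
        m = generate(SyntheticSpec(n_pos=1, n_neg=5, length_range=(30, 40),
                                   seed=1))
        with pytest.raises(ValueError, match="jackknife"):
            jackknife_evaluate(m, PseAACConfig(), SVMConfig())


def _stub_metrics(oa, auroc=0.9, mcc=0.5):
    return MetricsReport(sn=oa, sp=oa, oa=oa, aa=oa, mcc=mcc, auroc=auroc)


class TestGridSearch:
    PAPER_OMEGAS = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    PAPER_LAMS = [3, 5]
    PAPER_GAMMAS = [0.04, 0.05, 0.06, 0.07, 0.08, 0.09]

    def _stub_eval(self):
        def evaluate(manifest, pse, svm):
            # deterministic pseudo-metrics keyed on the grid point
            h = (hash((round(pse.weight, 3), pse.lam, round(svm.gamma, 3)))
                 % 1000) / 1000.0
            return _stub_metrics(oa=0.5 + h / 2, auroc=h, mcc=h - 0.5)

        return evaluate

    def test_published_grids_enumerate_72_points(self):
        result = grid_search(
            DatasetManifest(records=[]),
            self.PAPER_OMEGAS, self.PAPER_LAMS, self.PAPER_GAMMAS, [32.0],
            evaluate_fn=self._stub_eval(),
        )
        assert len(result.rows) == 72

    def test_best_row_matches_offline_argmax(self):
        result = grid_search(
            DatasetManifest(records=[]),
            self.PAPER_OMEGAS, self.PAPER_LAMS, self.PAPER_GAMMAS, [32.0],
            criterion="oa",
            evaluate_fn=self._stub_eval(),
        )
        offline = max(range(len(result.rows)),
                      key=lambda i: result.rows[i].report.oa)
        assert result.rows[result.best].report.oa == result.rows[offline].report.oa

    def test_higher_oa_row_selected(self):
        reports = {(0.1, 3): 0.8, (0.2, 3): 0.9}

        def evaluate(manifest, pse, svm):
            return _stub_metrics(oa=reports[(round(pse.weight, 1), pse.lam)])

        result = grid_search(DatasetManifest(records=[]),
                             [0.1, 0.2], [3], [0.05], [32.0],
                             evaluate_fn=evaluate)
        assert result.best_point.omega == 0.2

    def test_sensitivity_criterion_selects_by_sn(self):
        def evaluate(manifest, pse, svm):
            if pse.lam == 3:
                return MetricsReport(sn=0.9, sp=0.5, oa=0.6, aa=0.7, mcc=0.2,
                                     auroc=0.7)
            return MetricsReport(sn=0.6, sp=0.9, oa=0.8, aa=0.75, mcc=0.5,
                                 auroc=0.8)

        result = grid_search(DatasetManifest(records=[]),
                             [0.1], [3, 5], [0.05], [32.0], criterion="sn",
                             evaluate_fn=evaluate)
        assert result.best_point.lam == 3

    def test_ties_break_toward_smaller_lambda(self):
        def evaluate(manifest, pse, svm):
            return _stub_metrics(oa=0.9)

        result = grid_search(DatasetManifest(records=[]),
                             [0.1], [3, 5], [0.05], [32.0],
                             evaluate_fn=evaluate)
        assert result.best_point.lam == 3

    def test_failing_point_recorded_not_skipped(self):
        def evaluate(manifest, pse, svm):
            if pse.lam == 5:
                raise ValueError("boom")
            return _stub_metrics(oa=0.7)

        result = grid_search(DatasetManifest(records=[]),
                             [0.1], [3, 5], [0.05], [32.0],
                             evaluate_fn=evaluate)
        failed = [p for p in result.rows if p.report is None]
        assert len(failed) == 1 and "boom" in failed[0].error
        assert result.best_point.lam == 3

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError, match="gamma"):
            grid_search(DatasetManifest(records=[]), [0.1], [3], [], [32.0])

    def test_grid_tsv_round_trip(self, tmp_path):
        result = grid_search(DatasetManifest(records=[]),
                             [0.1, 0.2], [3], [0.05], [32.0],
                             evaluate_fn=self._stub_eval())
        path = tmp_path / "grid.tsv"
        result.to_tsv(path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3  # header + 2 rows
        assert lines[0].split("\t")[0] == "omega"
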