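"""Metric oracles and the evaluation report.

Hand-computed expected values are frozen below; Bray-Curtis and CLR are
additionally cross-checked against independent implementations
(scipy.spatial.distance.braycurtis, skbio.stats.composition.clr).
"""

import json

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance
from hypothesis import given, settings, strategies as st
from skbio.stats.composition import clr as skbio_clr

from pseudomix import (
    PredictionTable,
    aitchison_distance,
    bray_curtis,
    build_error_table,
    clr,
    confusion_analysis,
    immune_only_aitchison,
    mixture_metrics,
    per_type_accuracy,
    report,
    rpe_table,
)


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert bray_curtis([50, 30, 20], [50, 30, 20]) == 0.0

    def test_disjoint_support_is_one(self):
        assert bray_curtis([100, 0], [0, 100]) == 1.0

    def test_hand_value(self):
        # min-sum 50; 1 - 2*50/200 = 0.5
        assert bray_curtis([50, 50, 0], [25, 25, 50]) == pytest.approx(0.5)

    def test_symmetric(self):
        a, b = [70, 20, 10], [10, 30, 60]
        assert bray_curtis(a, b) == bray_curtis(b, a)

    def test_percent_and_count_scales_agree(self):
        # with 500-cell mixtures, percentages and counts are proportional
        a, b = np.array([50.0, 30, 20]), np.array([25.0, 25, 50])
        assert bray_curtis(a, b) == pytest.approx(bray_curtis(a * 5, b * 5))

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=9),
        st.lists(st.floats(0, 100), min_size=2, max_size=9),
    )
    def test_matches_scipy_and_stays_in_unit_interval(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if a.sum() == 0 or b.sum() == 0:
            return
        ours = bray_curtis(a, b)
        assert 0.0 <= ours <= 1.0
        np.testing.assert_allclose(
            ours, scipy.spatial.distance.braycurtis(a, b), atol=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bray_curtis([1, 2], [1, 2, 3])


class TestCLR:
    def test_equal_parts(self):
        np.testing.assert_allclose(clr([50.0, 50.0]), [0.0, 0.0], atol=1e-12)

    def test_hand_value(self):
        # (80,20): geometric mean 40 -> (ln2, -ln2)
        np.testing.assert_allclose(
            clr([80.0, 20.0]), [np.log(2), -np.log(2)], atol=1e-12
        )

    def test_output_sums_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.uniform(0, 100, size=6)
            assert abs(clr(x).sum()) < 1e-9

    def test_matches_skbio_on_positive_compositions(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.uniform(1, 100, size=5)
            np.testing.assert_allclose(clr(x), skbio_clr(x / x.sum()), atol=1e-10)

    def test_zero_policy_pseudocount(self):
        out = clr([50.0, 50.0, 0.0])
        assert np.isfinite(out).all()
        assert abs(out.sum()) < 1e-9

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            clr([0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            clr([-1.0, 2.0])


class TestAitchison:
    def test_identical_is_zero(self):
        assert aitchison_distance([30, 70], [30, 70]) == 0.0

    def test_hand_value(self):
        # from the clr example: sqrt(2) * ln 2
        assert aitchison_distance([50.0, 50.0], [80.0, 20.0]) == pytest.approx(
            0.9803, abs=1e-4
        )

    def test_perturbation_invariance(self):
        """Scaling both compositions by the same positive vector (then
        re-closing) leaves the distance unchanged."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.uniform(1, 50, 5), rng.uniform(1, 50, 5)
            g = rng.uniform(0.5, 2.0, 5)
            d0 = aitchison_distance(a / a.sum(), b / b.sum())
            pa, pb = a * g, b * g
            d1 = aitchison_distance(pa / pa.sum(), pb / pb.sum())
            assert d1 == pytest.approx(d0, abs=1e-6)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a, b, c = rng.uniform(1, 100, (3, 4))
            dab = aitchison_distance(a, b)
            assert dab == pytest.approx(aitchison_distance(b, a))
            assert dab <= aitchison_distance(a, c) + aitchison_distance(c, b) + 1e-9


def _errors(pred_rows, truth_rows, types=None, groups=None):
    types = types or [f"T{i}" for i in range(len(pred_rows[0]))]
    ids = [f"m{i}" for i in range(len(pred_rows))]
    pred = pd.DataFrame(pred_rows, index=ids, columns=types)
    truth = pd.DataFrame(truth_rows, index=ids, columns=types)
    g = None
    if groups is not None:
        g = pd.DataFrame(groups, index=ids)
    return build_error_table(pred, truth, g)


class TestErrorTable:
    def test_raw_error_signed_and_rpe_defined_only_for_present(self):
        errs = _errors([[60.0, 40.0, 0.0]], [[50.0, 50.0, 0.0]])
        rec = errs.set_index("type")
        assert rec.loc["T0", "raw_error"] == 10.0
        assert rec.loc["T1", "raw_error"] == -10.0
        assert rec.loc["T0", "rpe"] == pytest.approx(0.2)
        assert np.isnan(rec.loc["T2", "rpe"])

    def test_mismatched_ids_rejected(self):
        pred = pd.DataFrame([[100.0]], index=["a"], columns=["T0"])
        truth = pd.DataFrame([[100.0]], index=["b"], columns=["T0"])
        with pytest.raises(ValueError, match="ids"):
            build_error_table(pred, truth)


class TestPerTypeAccuracy:
    def test_perfect_prediction(self):
        truth = [[60.0, 40.0], [30.0, 70.0], [50.0, 50.0]]
        errs = _errors(truth, truth)
        table, summary = per_type_accuracy(errs)
        assert (table["rmse"] == 0).all()
        np.testing.assert_allclose(table["pearson_r"], 1.0)

    def test_constant_offset(self):
        truth = np.array([[60.0, 40.0], [30.0, 70.0], [50.0, 50.0]])
        pred = truth + np.array([5.0, -5.0])
        errs = _errors(pred.tolist(), truth.tolist())
        table, summary = per_type_accuracy(errs)
        np.testing.assert_allclose(table["rmse"], 5.0)
        np.testing.assert_allclose(table["pearson_r"], 1.0)
        np.testing.assert_allclose(summary["median_rmse"], 5.0)

    def test_absent_type_rmse_is_rms_of_pred(self):
        pred = [[3.0, 97.0], [4.0, 96.0]]
        truth = [[0.0, 100.0], [0.0, 100.0]]
        _, summary = per_type_accuracy(_errors(pred, truth))
        t0 = summary.set_index("type").loc["T0"]
        assert t0["median_rmse"] == pytest.approx(np.sqrt((9 + 16) / 2))
        assert t0["n_undefined_r"] == 1  # zero-variance truth -> r undefined

    def test_grouped_median(self):
        truth = [[60.0, 40.0]] * 4
        pred = [[62.0, 38.0], [62.0, 38.0], [66.0, 34.0], [66.0, 34.0]]
        errs = _errors(pred, truth, groups={"donor": ["d1", "d1", "d2", "d2"]})
        table, summary = per_type_accuracy(errs, group_by=["donor"])
        t0 = table[table["type"] == "T0"].set_index("donor")
        assert t0.loc["d1", "rmse"] == 2.0 and t0.loc["d2", "rmse"] == 6.0
        assert summary.set_index("type").loc["T0", "median_rmse"] == 4.0

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(5)
        truth = rng.dirichlet(np.ones(4), size=6) * 100
        pred = rng.dirichlet(np.ones(4), size=6) * 100
        errs = _errors(pred.tolist(), truth.tolist())
        table, _ = per_type_accuracy(errs)
        for i in range(4):
            expected = np.sqrt(np.mean((pred[:, i] - truth[:, i]) ** 2))
            got = table.set_index("type").loc[f"T{i}", "rmse"]
            assert got == pytest.approx(expected)


class TestRPE:
    @pytest.mark.parametrize(
        "pred, truth, expected",
        [(7.0, 2.0, 2.5), (35.0, 30.0, 1 / 6), (40.0, 40.0, 0.0)],
    )
    def test_hand_values(self, pred, truth, expected):
        errs = _errors([[pred, 100 - pred]], [[truth, 100 - truth]])
        out = rpe_table(errs).set_index("type")
        assert out.loc["T0", "median_rpe"] == pytest.approx(expected, abs=1e-9)

    def test_undefined_counted_not_dropped(self):
        errs = _errors([[5.0, 95.0]], [[0.0, 100.0]])
        out = rpe_table(errs).set_index("type")
        assert out.loc["T0", "n_defined"] == 0
        assert out.loc["T0", "n_undefined"] == 1


class TestConfusion:
    def test_toy_four_components(self):
        """truths (0, 0.5, 5, 94.5) vs preds (0.5, 0.05, 5, 94.45):
        one FP in the 0.1-1% bin, one FN in the 0.1-1% bin, two TP."""
        errs = pd.DataFrame(
            {
                "mixture_id": ["m0"] * 4,
                "type": ["A", "B", "C", "D"],
                "pred": [0.5, 0.05, 5.0, 94.45],
                "truth": [0.0, 0.5, 5.0, 94.5],
                "raw_error": [0.5, -0.45, 0.0, -0.05],
                "rpe": [np.nan, 0.9, 0.0, 0.0005],
            }
        )
        summary = confusion_analysis(errs)
        overall = summary.overall
        assert overall["FP"] == 1 and overall["TN"] == 0
        assert overall["FN"] == 1 and overall["TP"] == 2
        assert overall["fp_rate"] == 1.0
        assert overall["fn_rate"] == pytest.approx(1 / 3)
        assert summary.fp_bins.loc["A", "0.1-1%"] == 1
        assert summary.fn_bins.loc["B", "0.1-1%"] == 1

    def test_perfect_prediction_has_no_fp_fn(self):
        truth = [[50.0, 49.95, 0.05, 0.0]]
        errs = _errors(truth, truth)
        summary = confusion_analysis(errs)
        assert summary.overall["FP"] == 0 and summary.overall["FN"] == 0
        # the 0.05% and 0.0% components are below threshold on both sides: TNs
        assert summary.overall["TN"] == 2 and summary.overall["TP"] == 2

    def test_counts_partition_components(self):
        rng = np.random.default_rng(7)
        pred = rng.dirichlet(np.ones(9), size=40) * 100
        truth = rng.dirichlet(np.ones(9) * 0.3, size=40) * 100
        summary = confusion_analysis(_errors(pred.tolist(), truth.tolist()))
        assert summary.n_components == 40 * 9
        assert summary.fp_bins.to_numpy().sum() == summary.overall["FP"]
        assert summary.fn_bins.to_numpy().sum() == summary.overall["FN"]

    def test_exclude_types(self):
        pred = [[50.0, 25.0, 25.0]]
        truth = [[50.0, 0.0, 50.0]]
        summary = confusion_analysis(
            _errors(pred, truth, types=["cancer", "B", "C"]),
            exclude_types={"cancer"},
        )
        assert summary.n_components == 2
        assert "cancer" not in summary.per_type.index

    def test_bin_edges_lower_inclusive(self):
        # predicted exactly 1.0% falls in the 1-10% bin, 10.0% in >10%
        errs = _errors([[1.0, 10.0, 89.0]], [[0.0, 0.0, 100.0]])
        summary = confusion_analysis(errs)
        assert summary.fp_bins.loc["T0", "1-10%"] == 1
        assert summary.fp_bins.loc["T1", ">10%"] == 1

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            confusion_analysis(_errors([[100.0]], [[100.0]]), presence_threshold=0)


class TestReport:
    def _tables(self):
        rng = np.random.default_rng(11)
        truth = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=12) * 100,
            index=[f"m{i}" for i in range(12)],
            columns=["cancer", "T", "B", "myeloid"],
        )
        good = PredictionTable(truth * 0.9 + truth.mean() * 0.1, "good")
        noisy = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=12) * 100,
            index=truth.index, columns=truth.columns,
        )
        bad = PredictionTable(noisy, "bad")
        groups = pd.DataFrame(
            {"donor": ["d1"] * 6 + ["d2"] * 6, "purity": [0.5] * 12},
            index=truth.index,
        )
        return [good, bad], truth, groups

    def test_ranking_orders_by_median_bray_curtis(self, tmp_path):
        tables, truth, groups = self._tables()
        rep = report(tables, truth, groups, outdir=tmp_path)
        assert rep.ranking["method"].tolist() == ["good", "bad"]
        assert rep.ranking["median_bray_curtis"].is_monotonic_increasing

    def test_report_artifacts_written(self, tmp_path):
        tables, truth, groups = self._tables()
        rep = report(
            tables, truth, groups, outdir=tmp_path,
            exclude_types={"cancer"}, immune_types=["T", "B", "myeloid"],
        )
        for name in (
            "mixture_metrics.tsv", "method_ranking.tsv", "per_type_accuracy.tsv",
            "per_type_summary.tsv", "rpe_summary.tsv", "confusion.json",
            "immune_aitchison.tsv",
        ):
            assert (tmp_path / name).exists(), name
        conf = json.loads((tmp_path / "confusion.json").read_text())
        assert set(conf) == {"good", "bad"}
        assert conf["good"]["excluded_types"] == ["cancer"]

    def test_immune_only_excludes_zero_mass_mixtures(self):
        truth = pd.DataFrame(
            [[100.0, 0.0, 0.0], [50.0, 25.0, 25.0]],
            index=["m0", "m1"], columns=["cancer", "T", "B"],
        )
        pred = truth.copy()
        out = immune_only_aitchison(pred, truth, ["T", "B"])
        assert list(out.index) == ["m1"]
        assert out["immune_aitchison"].iloc[0] == 0.0

    def test_mixture_metrics_columns(self):
        tables, truth, groups = self._tables()
        mm = mixture_metrics(tables[0].data, truth, groups)
        assert {"bray_curtis", "aitchison", "donor", "purity"} <= set(mm.columns)
        assert len(mm) == 12
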