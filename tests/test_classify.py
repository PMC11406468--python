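"""Balancing, leave-one-specimen-out KNN, importance, selection, rank test."""
import numpy as np
import pandas as pd
import pytest

import muellermap as mm


def _table(rng, n_specimens=4, n_per_class=60, gap=3.0, informative=("f0",)):
    """Synthetic feature table; only ``informative`` features separate classes."""
    rows = []
    for sp in range(n_specimens):
        for cls, shift in (("GM", 0.0), ("WM", gap)):
            n = n_per_class + sp * 3    # uneven cells exercise balancing
            block = {"specimen": sp, "class": cls}
            frame = pd.DataFrame({k: v for k, v in block.items()}, index=range(n))
            for f in ("f0", "f1", "f2"):
                loc = shift if f in informative else 0.0
                frame[f] = rng.normal(loc, 1.0, size=n)
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def test_balance_min_rule_and_determinism(rng):
    table = _table(rng)
    bal = mm.balance(table, seed=3)
    counts = bal.groupby(["specimen", "class"], observed=True).size()
    assert counts.nunique() == 1
    assert counts.iloc[0] == table.groupby(["specimen", "class"]).size().min()
    bal2 = mm.balance(table, seed=3)
    pd.testing.assert_frame_equal(bal, bal2)


def test_balance_idempotent_and_cap(rng):
    table = _table(rng)
    bal = mm.balance(table, seed=3)
    again = mm.balance(bal, seed=9)
    assert len(again) == len(bal)
    capped = mm.balance(table, seed=3, max_per_cell=10)
    assert capped.groupby(["specimen", "class"]).size().eq(10).all()


def test_balance_drops_single_class_specimen(rng):
    table = _table(rng)
    table = table[~((table["specimen"] == 2) & (table["class"] == "WM"))]
    bal = mm.balance(table, seed=0)
    assert 2 not in bal["specimen"].unique()


def test_confusion_metrics_hand_values():
    m = mm.confusion_metrics(np.array([[50, 0], [0, 50]]))
    assert m == {"accuracy": 100.0, "true_gm_rate": 100.0, "true_wm_rate": 100.0}
    m = mm.confusion_metrics(np.array([[40, 10], [10, 40]]))
    assert m["accuracy"] == pytest.approx(80.0)
    assert m["true_gm_rate"] == pytest.approx(80.0)
    assert m["true_wm_rate"] == pytest.approx(80.0)
    m = mm.confusion_metrics(np.array([[0, 0], [7, 7]]))
    assert m["true_gm_rate"] == pytest.approx(0.0)
    assert np.isnan(mm.confusion_metrics(np.array([[0, 3], [0, 3]]))["true_gm_rate"])
    with pytest.raises(ValueError):
        mm.confusion_metrics(np.array([[1, -1], [0, 0]]))


def test_losocv_separable_and_train_fraction(rng):
    table = mm.balance(_table(rng, n_specimens=6, gap=12.0), seed=1)
    report = mm.losocv_knn(table, ["f0", "f1", "f2"], kn=1)
    assert len(report.folds) == 6
    assert report.train_fraction == pytest.approx(5 / 6)
    assert report.mean_test_accuracy() == pytest.approx(100.0)
    for fold in report.folds:
        assert fold.train_metrics["accuracy"] == pytest.approx(100.0)


def test_losocv_null_labels_near_chance(rng):
    table = mm.balance(_table(rng, n_specimens=4, gap=0.0), seed=1)
    report = mm.losocv_knn(table, ["f0", "f1", "f2"], kn=15)
    acc = report.mean_test_accuracy()
    assert 38.0 < acc < 62.0   # ~ binomial CI around chance


def test_losocv_errors():
    df = pd.DataFrame({"specimen": [0] * 8, "class": ["GM", "WM"] * 4, "f0": range(8)})
    with pytest.raises(ValueError):
        mm.losocv_knn(df, ["f0"], kn=1)


def test_no_class_bias_on_balanced_data(rng):
    table = mm.balance(_table(rng, n_specimens=6, gap=2.0), seed=1)
    report = mm.losocv_knn(table, ["f0", "f1", "f2"], kn=15)
    s = report.summary()
    gm = s[(s.split == "test") & (s.metric == "true_gm_rate")]["mean"].iloc[0]
    wm = s[(s.split == "test") & (s.metric == "true_wm_rate")]["mean"].iloc[0]
    assert abs(gm - wm) < 10.0


def test_permutation_importance_ranks_informative_feature(rng):
    table = mm.balance(_table(rng, n_specimens=4, gap=3.0), seed=1)
    imp = mm.permutation_importance(table, ["f0", "f1", "f2"], kn=9, s=10, seed=2)
    assert imp.iloc[0]["feature"] == "f0"
    f0 = imp.set_index("feature")["importance"]
    assert f0["f0"] > 5 * max(abs(f0["f1"]), abs(f0["f2"]), 0.5)


def test_permutation_importance_uninformative_near_zero(rng):
    table = mm.balance(_table(rng, n_specimens=4, gap=3.0), seed=1)
    imp1 = mm.permutation_importance(table, ["f0", "f1"], kn=9, s=1, seed=5)
    imp10 = mm.permutation_importance(table, ["f0", "f1"], kn=9, s=10, seed=5)
    # same ranking, tighter spread with more shuffles
    assert list(imp1["feature"]) == list(imp10["feature"]) == ["f0", "f1"]
    assert abs(imp10.set_index("feature").loc["f1", "importance"]) < 2.0


def test_sffs_picks_separating_feature_first(rng):
    table = mm.balance(_table(rng, n_specimens=4, gap=6.0), seed=1)
    sel_f = mm.sequential_feature_selection(
        table, ["f0", "f1", "f2"], n_select=1, direction="forward", kn=9
    )
    sel_b = mm.sequential_feature_selection(
        table, ["f0", "f1", "f2"], n_select=1, direction="backward", kn=9
    )
    assert sel_f == ["f0"]
    assert sel_b == ["f0"]


def test_sffs_argument_validation(rng):
    table = mm.balance(_table(rng), seed=1)
    with pytest.raises(ValueError):
        mm.sequential_feature_selection(table, ["f0"], n_select=2)
    with pytest.raises(ValueError):
        mm.sequential_feature_selection(table, ["f0"], n_select=1, direction="sideways")


def test_mann_whitney_identical_and_separated(rng):
    x = rng.normal(0, 1, 500)
    assert mm.compare_distributions(x, x)["p_value"] > 0.9
    y = rng.normal(3, 1, 500)
    r = mm.compare_distributions(x, y)
    assert r["p_value"] < 1e-5
    # two-sided symmetry
    assert mm.compare_distributions(y, x)["p_value"] == pytest.approx(r["p_value"])
    # all-tied inputs
    assert mm.compare_distributions([1.0] * 5, [1.0] * 7)["p_value"] == 1.0
    with pytest.raises(ValueError):
        mm.compare_distributions([], [1.0])
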