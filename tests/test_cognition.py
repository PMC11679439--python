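import math

import numpy as np
import pandas as pd
import pytest

from smartdrive.cognition import (
    PILOT1_FEATURES,
    PILOT2_FEATURES,
    SubjectArtifacts,
    build_feature_table,
    compare_conditions,
    correlation_matrix,
    holdout_subject_test,
    resampled_evaluation,
    univariate_roc,
)
from smartdrive.metabolic import HybridIndicators
from smartdrive.pathscore import score_path
from smartdrive.turns import SignatureSet


def _signatures(base=1.0):
    s = SignatureSet()
    for f in (
        "left90_max_angular_velocity", "right90_max_angular_velocity",
        "combined90_max_angular_velocity", "left90_max_angular_acceleration",
        "right90_max_angular_acceleration", "combined90_max_angular_acceleration",
        "left90_min_angular_acceleration", "right90_min_angular_acceleration",
        "combined90_min_angular_acceleration", "left90_speed_at_peak",
        "right90_speed_at_peak", "combined90_speed_at_peak", "uturn_period",
        "uturn_speed_at_peak", "uturn_max_angular_velocity",
        "uturn_max_angular_acceleration",
    ):
        setattr(s, f, base)
    return s


def _artifact(sid, label, ee_change=20.0, speed=18.0, path_score_total=0.0):
    ind = HybridIndicators(
        ee_change_pct=ee_change,
        speed_x_ee=speed * ee_change,
        eq_feature=10 * speed * ee_change + path_score_total,
        path_deviation=path_score_total,
    )
    rep = score_path({"off_path": int(path_score_total)})
    rep.total_score = path_score_total
    return SubjectArtifacts(
        subject_id=sid,
        label=label,
        signatures={"normal": _signatures(1.0), "aggressive": _signatures(1.3)},
        indicators=ind,
        path_report=rep,
        aggressive_speed_mph=speed,
    )


def _toy_table(n_per_class=8, gap=5.0, seed=0):
    """Perfectly separable two-cluster table in the cognitive layout."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_class):
        label = "mci" if i < n_per_class else "normal_cognition"
        mu = 0.0 if label == "mci" else gap
        feats = {name: mu + rng.normal(0, 0.3) for name in PILOT2_FEATURES}
        rows.append({"subject_id": f"S{i}", "label": label, **feats})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def test_pilot2_layout_has_twelve_features():
    arts = [_artifact("a", "normal_cognition"), _artifact("b", "mci", ee_change=5.0)]
    table = build_feature_table(arts, layout="pilot2")
    assert list(table.columns[2:]) == list(PILOT2_FEATURES)
    assert len(table.columns) == 14  # id + label + 12


def test_pilot1_layout_has_seven_features_two_rows_per_subject():
    arts = [_artifact("a", "normal_cognition")]
    table = build_feature_table(arts, layout="pilot1")
    assert list(table.columns[2:]) == list(PILOT1_FEATURES)
    assert sorted(table["label"]) == ["aggressive_driving", "normal_driving"]


def test_left_right_consolidation_mean():
    art = _artifact("a", "normal_cognition")
    art.signatures["normal"].left90_speed_at_peak = 9.0
    art.signatures["normal"].right90_speed_at_peak = 11.0
    art.signatures["normal"].combined90_speed_at_peak = 10.0
    table = build_feature_table([art, _artifact("b", "mci")], layout="pilot2")
    assert table.loc[table.subject_id == "a", "normal_90_speed"].item() == 10.0


def test_missing_feature_row_excluded():
    art = _artifact("a", "normal_cognition")
    art.signatures["normal"].uturn_period = None
    with pytest.warns(UserWarning, match="excluded"):
        table = build_feature_table([art, _artifact("b", "mci")], layout="pilot2")
    assert list(table["subject_id"]) == ["b"]


def test_empty_artifacts_rejected():
    with pytest.raises(ValueError):
        build_feature_table([], layout="pilot2")


# ---------------------------------------------------------------------------
# resampled evaluation
# ---------------------------------------------------------------------------


def test_separable_table_perfect_accuracy():
    rep = resampled_evaluation(_toy_table(), n_iterations=25, seed=0, positive_label="mci")
    assert rep.accuracy_pct == 100.0
    assert rep.fp == 0 and rep.fn == 0
    assert rep.tp + rep.tn == 25 * 5  # 30 % of 16 = 5 test subjects per iteration


def test_confusion_totals_match_iterations():
    rep = resampled_evaluation(_toy_table(), n_iterations=10, seed=1)
    assert rep.tp + rep.fp + rep.tn + rep.fn == 10 * 5


def test_permuted_labels_near_chance():
    rng = np.random.default_rng(3)
    table = _toy_table(n_per_class=10)
    table["label"] = rng.permutation(table["label"].to_numpy())
    rep = resampled_evaluation(table, n_iterations=100, seed=2, positive_label="mci")
    assert 35.0 < rep.accuracy_pct < 65.0


def test_evaluation_deterministic():
    a = resampled_evaluation(_toy_table(), n_iterations=10, seed=9)
    b = resampled_evaluation(_toy_table(), n_iterations=10, seed=9)
    assert a.accuracy_pct == b.accuracy_pct
    assert (a.feature_importances == b.feature_importances).all()
    assert a.confusion_matrix.tolist() == b.confusion_matrix.tolist()


def test_too_few_subjects_rejected():
    t = _toy_table(n_per_class=1)
    with pytest.raises(ValueError):
        resampled_evaluation(t)


# ---------------------------------------------------------------------------
# hold-out protocol
# ---------------------------------------------------------------------------


def test_holdout_centroid_always_correct():
    table = _toy_table()
    hold = table.iloc[0].copy()
    hold["subject_id"] = "HOLD"
    frac = holdout_subject_test(table, hold, n_iterations=20, seed=0)
    assert frac == 1.0


def test_holdout_single_iteration_quantized():
    table = _toy_table()
    hold = table.iloc[0].copy()
    hold["subject_id"] = "HOLD"
    frac = holdout_subject_test(table, hold, n_iterations=1, seed=0)
    assert frac in (0.0, 1.0)


def test_holdout_must_not_be_in_reference():
    table = _toy_table()
    with pytest.raises(ValueError, match="present"):
        holdout_subject_test(table, table.iloc[0], n_iterations=1, seed=0)


# ---------------------------------------------------------------------------
# univariate ROC
# ---------------------------------------------------------------------------


def test_roc_perfect_separation():
    res = univariate_roc([1, 2, 3, 10, 11, 12], ["n"] * 3 + ["m"] * 3, "m")
    assert res.auc == 1.0
    assert res.accuracy_pct == 100.0
    assert 3 < res.best_threshold < 10


def test_roc_small_worked_example():
    """values {1,2,3,4}, labels {m,m,n,n} with lower-is-positive: AUC 1, threshold 2.5."""
    res = univariate_roc([1, 2, 3, 4], ["m", "m", "n", "n"], "m", "lower_is_positive")
    assert res.auc == 1.0
    assert res.best_threshold == pytest.approx(-2.5)  # on the negated scale


def test_roc_identical_distributions_near_half():
    rng = np.random.default_rng(0)
    v = rng.normal(0, 1, 400)
    labels = np.array(["m", "n"] * 200)
    res = univariate_roc(v, labels, "m")
    assert abs(res.auc - 0.5) < 0.1


def test_roc_constant_values_degenerate():
    res = univariate_roc([5.0] * 6, ["m", "n"] * 3, "m")
    assert res.degenerate and res.auc == 0.5


def test_roc_matches_brute_force_enumeration():
    """Sweep accuracy/AUC equal an independent exhaustive enumeration and
    the rank-statistic AUC on every random input up to size 50."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    for trial in range(20):
        n = int(rng.integers(4, 51))
        labels = np.array(["m"] * (n // 2) + ["n"] * (n - n // 2))
        rng.shuffle(labels)
        if len(set(labels)) < 2:
            continue
        values = np.round(rng.normal(0, 1, n), 2)
        res = univariate_roc(values, labels, "m")
        y = (labels == "m").astype(int)
        # brute force: accuracy over every candidate threshold
        cands = np.concatenate([[values.min() - 1], np.sort(np.unique(values)), [values.max() + 1]])
        best_acc = max(np.mean((values >= th) == y) for th in cands)
        assert res.accuracy_pct == pytest.approx(100 * best_acc, abs=1e-9)
        if len(np.unique(values)) > 1:
            assert res.auc == pytest.approx(roc_auc_score(y, values), abs=1e-9)


# ---------------------------------------------------------------------------
# paired comparison and correlations
# ---------------------------------------------------------------------------


def _paired_frames(n=20, shift=0.0, seed=0, equal=False):
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, n)
    normal = pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(n)], "label": "normal_driving", "sig": base}
    )
    agg_vals = base if equal else base + shift + rng.normal(0, 1e-6, n)
    aggressive = pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(n)], "label": "aggressive_driving", "sig": agg_vals}
    )
    return normal, aggressive


def test_identical_conditions_p_one():
    n, a = _paired_frames(equal=True)
    out = compare_conditions(n, a)
    assert out.loc[0, "p_value"] == 1.0


def test_constant_shift_minimal_wilcoxon_p():
    """A uniform shift with n=20 and no ties attains the smallest achievable
    two-sided exact Wilcoxon p-value, 2 / 2**20."""
    n, a = _paired_frames(shift=3.0)
    out = compare_conditions(n, a)
    assert out.loc[0, "p_value"] == pytest.approx(2.0 / 2**20, rel=1e-9)


def test_compare_invariant_to_subject_order():
    n, a = _paired_frames(shift=0.7, seed=3)
    shuffled = a.sample(frac=1.0, random_state=1).reset_index(drop=True)
    p1 = compare_conditions(n, a).loc[0, "p_value"]
    p2 = compare_conditions(n, shuffled).loc[0, "p_value"]
    assert p1 == pytest.approx(p2)


def test_small_sample_warns():
    n, a = _paired_frames(n=4, shift=1.0)
    with pytest.warns(UserWarning, match="pairs"):
        compare_conditions(n, a)


def test_correlation_with_target():
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(10)],
            "label": ["normal_driving", "aggressive_driving"] * 5,
            "equal": [1.0, 0.0] * 5,
            "anti": [0.0, 1.0] * 5,
        }
    )
    corr = correlation_matrix(df)
    assert corr.loc["equal", "target"] == pytest.approx(1.0)
    assert corr.loc["anti", "target"] == pytest.approx(-1.0)


def test_correlation_independent_feature_small():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(200)],
            "label": ["normal_driving", "aggressive_driving"] * 100,
            "noise": rng.normal(0, 1, 200),
        }
    )
    corr = correlation_matrix(df)
    assert abs(corr.loc["noise", "target"]) < 0.2


def test_correlation_zero_variance_nan():
    df = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c"],
            "label": ["normal_driving", "aggressive_driving", "normal_driving"],
            "const": [1.0, 1.0, 1.0],
        }
    )
    corr = correlation_matrix(df)
    assert math.isnan(corr.loc["const", "target"])
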