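"""Feature assembly and the resampled random-forest evaluation harness.

Two feature layouts are supported.  The driving-performance layout
(``pilot1``) carries seven per-session signatures and discriminates normal
from aggressive driving; the cognitive layout (``pilot2``) carries twelve
features per subject — ten session signatures across the two driving
phases plus two engineered indicators (the speed/EE-change/path composite
and the total path-deviation score) — and discriminates normal cognition
from mild cognitive impairment (MCI).  No demographic fields enter either
layout.

Evaluation repeats a stratified 70/30 train/test split over (by default)
100 iterations, fits a fresh random forest each time, accumulates the test
confusion matrix across iterations, and averages accuracy, sensitivity,
specificity and precision over iterations.  Stratification is used because
with eight MCI subjects an unstratified split can produce one-class
training sets.  A hold-out protocol trains on a 40 % sample of a reference
cohort per iteration and reports the fraction of iterations that classify
one held-out subject correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .metabolic import HybridIndicators, MetabolicEstimate, hybrid_indicators
from .pathscore import PathDiscrepancyReport
from .turns import SignatureSet

__all__ = [
    "PILOT1_FEATURES",
    "PILOT2_FEATURES",
    "SubjectArtifacts",
    "EvaluationReport",
    "RocResult",
    "build_feature_table",
    "resampled_evaluation",
    "holdout_subject_test",
    "univariate_roc",
    "compare_conditions",
    "correlation_matrix",
]

#: Driving-performance layout: the seven most relevant session signatures.
PILOT1_FEATURES = (
    "uturn_period",
    "combined90_speed_at_peak",
    "combined90_max_angular_velocity",
    "uturn_max_angular_velocity",
    "uturn_speed_at_peak",
    "uturn_max_angular_acceleration",
    "combined90_max_angular_acceleration",
)

#: Cognitive layout: ten direct features plus two engineered indicators.
PILOT2_FEATURES = (
    "composite_indicator",  # speed^2 * EE-change / (0.1 * speed) + path deviation
    "total_path_deviation",
    "aggressive_90_speed",
    "normal_90_right_speed",
    "normal_90_speed",
    "normal_180_max_angular_acceleration",
    "ee_change_x_aggressive_90_speed",
    "normal_180_max_angular_velocity",
    "normal_180_period",
    "aggressive_180_period",
    "normal_90_max_angular_velocity",
    "aggressive_180_max_angular_velocity",
)


@dataclass
class SubjectArtifacts:
    """Per-subject analysis products feeding the feature table."""

    subject_id: str
    label: str  # normal_cognition | mci (pilot2) or normal_driving | aggressive_driving
    signatures: dict[str, SignatureSet] = field(default_factory=dict)  # by phase
    metabolic: dict[str, MetabolicEstimate] = field(default_factory=dict)
    indicators: HybridIndicators | None = None
    path_report: PathDiscrepancyReport | None = None
    aggressive_speed_mph: float | None = None


def _pilot2_row(a: SubjectArtifacts) -> dict[str, float | None]:
    sn = a.signatures.get("normal")
    sa = a.signatures.get("aggressive")
    if sn is None or sa is None:
        return {}
    ee_change = a.indicators.ee_change_pct if a.indicators else None
    path_dev = a.path_report.total_score if a.path_report else None
    composite = None
    ee_x_speed90 = None
    if ee_change is not None and a.aggressive_speed_mph and path_dev is not None:
        composite = hybrid_indicators(
            ee_change, a.aggressive_speed_mph, path_dev
        ).eq_feature
    if ee_change is not None and sa.combined90_speed_at_peak is not None:
        ee_x_speed90 = ee_change * sa.combined90_speed_at_peak
    return {
        "composite_indicator": composite,
        "total_path_deviation": path_dev,
        "aggressive_90_speed": sa.combined90_speed_at_peak,
        "normal_90_right_speed": sn.right90_speed_at_peak,
        "normal_90_speed": sn.combined90_speed_at_peak,
        "normal_180_max_angular_acceleration": sn.uturn_max_angular_acceleration,
        "ee_change_x_aggressive_90_speed": ee_x_speed90,
        "normal_180_max_angular_velocity": sn.uturn_max_angular_velocity,
        "normal_180_period": sn.uturn_period,
        "aggressive_180_period": sa.uturn_period,
        "normal_90_max_angular_velocity": sn.combined90_max_angular_velocity,
        "aggressive_180_max_angular_velocity": sa.uturn_max_angular_velocity,
    }


def _pilot1_rows(a: SubjectArtifacts) -> list[tuple[str, dict[str, float | None]]]:
    rows = []
    for phase, label in (("normal", "normal_driving"), ("aggressive", "aggressive_driving")):
        sig = a.signatures.get(phase)
        if sig is None:
            continue
        rows.append(
            (
                label,
                {
                    "uturn_period": sig.uturn_period,
                    "combined90_speed_at_peak": sig.combined90_speed_at_peak,
                    "combined90_max_angular_velocity": sig.combined90_max_angular_velocity,
                    "uturn_max_angular_velocity": sig.uturn_max_angular_velocity,
                    "uturn_speed_at_peak": sig.uturn_speed_at_peak,
                    "uturn_max_angular_acceleration": sig.uturn_max_angular_acceleration,
                    "combined90_max_angular_acceleration": sig.combined90_max_angular_acceleration,
                },
            )
        )
    return rows


def build_feature_table(
    artifacts: list[SubjectArtifacts], layout: str = "pilot2"
) -> pd.DataFrame:
    """Assemble the per-subject feature table for the requested layout.

    Rows with any missing feature are dropped with a warning.  ``pilot1``
    produces one row per subject per driving condition labelled by the
    condition; ``pilot2`` one row per subject labelled by cognitive status.
    """
    if not artifacts:
        raise ValueError("no subject artifacts provided")
    if layout == "pilot2":
        feature_names = PILOT2_FEATURES
        raw = [(a.subject_id, a.label, _pilot2_row(a)) for a in artifacts]
    elif layout == "pilot1":
        feature_names = PILOT1_FEATURES
        raw = [
            (a.subject_id, label, row) for a in artifacts for label, row in _pilot1_rows(a)
        ]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    rows = []
    for sid, label, feats in raw:
        vals = [feats.get(name) for name in feature_names]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            warnings.warn(
                f"subject {sid!r} ({label}): missing features, row excluded", stacklevel=2
            )
            continue
        rows.append({"subject_id": sid, "label": label, **dict(zip(feature_names, vals))})
    if not rows:
        raise ValueError("no complete feature rows could be built")
    return pd.DataFrame(rows, columns=["subject_id", "label", *feature_names])


# ---------------------------------------------------------------------------
# resampled evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Accumulated confusion matrix and iteration-averaged metrics (%)."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    precision_pct: float
    feature_importances: pd.Series
    n_iterations: int
    split_fraction: float
    seed: int | None
    positive_label: str

    @property
    def confusion_matrix(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def _default_positive(labels: pd.Series) -> str:
    for cand in ("mci", "aggressive_driving"):
        if cand in set(labels):
            return cand
    return sorted(set(labels))[0]


def _split_features(table: pd.DataFrame) -> tuple[np.ndarray, pd.Series, list[str]]:
    feat_cols = [c for c in table.columns if c not in ("subject_id", "label")]
    return table[feat_cols].to_numpy(dtype=float), table["label"], feat_cols


def resampled_evaluation(
    table: pd.DataFrame,
    split_fraction: float = 0.7,
    n_iterations: int = 100,
    seed: int | None = None,
    positive_label: str | None = None,
    n_estimators: int = 100,
    max_retries: int = 20,
) -> EvaluationReport:
    """Repeated stratified split + random-forest evaluation.

    ``split_fraction`` is the training share (0.7 = 70/30).  Metrics are
    averaged over iterations (iterations where a ratio is undefined are
    skipped for that metric); the confusion matrix accumulates raw test
    counts.  Deterministic given ``seed``.
    """
    X, y, feat_cols = _split_features(table)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError("resampled evaluation expects exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    pos = positive_label or _default_positive(y)
    y_bin = (y == pos).to_numpy()

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(2 * n_iterations) % (2**31)
    TP = FP = TN = FN = 0
    accs, sens, specs, precs = [], [], [], []
    importances = np.zeros(len(feat_cols))
    for i in range(n_iterations):
        split_seed = int(iter_seeds[2 * i])
        for retry in range(max_retries):
            Xtr, Xte, ytr, yte = train_test_split(
                X,
                y_bin,
                train_size=split_fraction,
                random_state=(split_seed + retry) % (2**31),
                stratify=y_bin,
            )
            if len(set(ytr)) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class training split")
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(iter_seeds[2 * i + 1])
        )
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        tp = int(np.sum(pred & yte))
        fp = int(np.sum(pred & ~yte))
        tn = int(np.sum(~pred & ~yte))
        fn = int(np.sum(~pred & yte))
        TP, FP, TN, FN = TP + tp, FP + fp, TN + tn, FN + fn
        accs.append((tp + tn) / len(yte))
        if tp + fn:
            sens.append(tp / (tp + fn))
        if tn + fp:
            specs.append(tn / (tn + fp))
        if tp + fp:
            precs.append(tp / (tp + fp))
        importances += clf.feature_importances_
    return EvaluationReport(
        tp=TP,
        fp=FP,
        tn=TN,
        fn=FN,
        accuracy_pct=100.0 * float(np.mean(accs)),
        sensitivity_pct=100.0 * float(np.mean(sens)) if sens else float("nan"),
        specificity_pct=100.0 * float(np.mean(specs)) if specs else float("nan"),
        precision_pct=100.0 * float(np.mean(precs)) if precs else float("nan"),
        feature_importances=pd.Series(importances / n_iterations, index=feat_cols),
        n_iterations=n_iterations,
        split_fraction=split_fraction,
        seed=seed,
        positive_label=pos,
    )


def holdout_subject_test(
    table: pd.DataFrame,
    holdout: pd.Series | pd.DataFrame,
    train_fraction: float = 0.4,
    n_iterations: int = 100,
    seed: int | None = None,
    positive_label: str | None = None,
    n_estimators: int = 100,
    max_retries: int = 20,
) -> float:
    """Fraction of iterations that classify one held-out subject correctly.

    Each iteration draws a stratified ``train_fraction`` sample of the
    reference table, fits a random forest, and predicts the held-out
    subject's label.
    """
    if isinstance(holdout, pd.DataFrame):
        if len(holdout) != 1:
            raise ValueError("holdout must be a single subject")
        holdout = holdout.iloc[0]
    if holdout["subject_id"] in set(table["subject_id"]):
        raise ValueError("holdout subject present in the reference table")
    X, y, feat_cols = _split_features(table)
    pos = positive_label or _default_positive(y)
    y_bin = (y == pos).to_numpy()
    x_hold = np.asarray([float(holdout[c]) for c in feat_cols]).reshape(1, -1)
    y_hold = holdout["label"] == pos

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(2 * n_iterations) % (2**31)
    correct = 0
    for i in range(n_iterations):
        split_seed = int(iter_seeds[2 * i])
        for retry in range(max_retries):
            Xtr, _Xte, ytr, _yte = train_test_split(
                X,
                y_bin,
                train_size=train_fraction,
                random_state=(split_seed + retry) % (2**31),
                stratify=y_bin,
            )
            if len(set(ytr)) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class training sample")
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(iter_seeds[2 * i + 1])
        )
        clf.fit(Xtr, ytr)
        correct += int(clf.predict(x_hold)[0] == y_hold)
    return correct / n_iterations


# ---------------------------------------------------------------------------
# univariate ROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    best_threshold: float
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    degenerate: bool = False


def univariate_roc(
    values,
    labels,
    positive_label: str,
    direction: str = "higher_is_positive",
) -> RocResult:
    """ROC analysis of one scalar indicator by exhaustive threshold sweep.

    Thresholds are the midpoints between adjacent sorted unique values plus
    sentinels below and above the range; a case is called positive when the
    (direction-adjusted) value is >= the threshold.  The best threshold
    maximizes accuracy, ties broken toward higher specificity.  AUC is the
    trapezoidal area under the swept curve.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos_mask = labels == positive_label
    if not pos_mask.any() or pos_mask.all():
        raise ValueError("both classes must be present")
    if direction == "higher_is_positive":
        score = values
    elif direction == "lower_is_positive":
        score = -values
    else:
        raise ValueError(f"unknown direction {direction!r}")

    uniq = np.unique(score)
    if uniq.size == 1:
        return RocResult(
            thresholds=np.array([uniq[0]]),
            tpr=np.array([1.0]),
            fpr=np.array([1.0]),
            auc=0.5,
            best_threshold=float(uniq[0]),
            accuracy_pct=100.0 * float(np.mean(pos_mask)),
            sensitivity_pct=100.0,
            specificity_pct=0.0,
            degenerate=True,
        )
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    acc = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        pred = score >= th
        tp = int(np.sum(pred & pos_mask))
        fp = int(np.sum(pred & ~pos_mask))
        tpr[i] = tp / n_pos
        fpr[i] = fp / n_neg
        acc[i] = (tp + (n_neg - fp)) / (n_pos + n_neg)
        spec[i] = (n_neg - fp) / n_neg
    # best threshold: max accuracy, ties -> higher specificity
    order = np.lexsort((spec, acc))
    best = order[-1]
    # AUC by trapezoid over the swept staircase, ordered by (FPR, TPR); the
    # sentinel thresholds guarantee the (0,0) and (1,1) endpoints are present
    srt = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[srt], fpr[srt]))
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        best_threshold=float(thresholds[best]),
        accuracy_pct=100.0 * float(acc[best]),
        sensitivity_pct=100.0 * float(tpr[best]),
        specificity_pct=100.0 * float(spec[best]),
    )


# ---------------------------------------------------------------------------
# paired condition comparison and correlations
# ---------------------------------------------------------------------------


def compare_conditions(
    normal: pd.DataFrame,
    aggressive: pd.DataFrame,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Paired two-sided tests per signature between driving conditions.

    Rows are matched by ``subject_id``.  Default is the Wilcoxon
    signed-rank test (exact null for small samples without ties); ``test=
    "ttest"`` selects the paired t-test.  Columns with identical paired
    values yield p = 1 (no detectable difference).
    """
    merged = normal.merge(aggressive, on="subject_id", suffixes=("_n", "_a"))
    feat_cols = [c for c in normal.columns if c not in ("subject_id", "label")]
    if len(merged) < 5:
        warnings.warn(
            f"only {len(merged)} pairs: small-sample exact test variant in use",
            stacklevel=2,
        )
    rows = []
    for cname in feat_cols:
        a = merged[f"{cname}_n"].to_numpy(dtype=float)
        b = merged[f"{cname}_a"].to_numpy(dtype=float)
        d = b - a
        if np.allclose(d, 0.0):
            rows.append({"signature": cname, "statistic": np.nan, "p_value": 1.0})
            continue
        if test == "wilcoxon":
            method = "exact" if (len(d) <= 25 and np.unique(np.abs(d[d != 0])).size == np.sum(d != 0)) else "auto"
            res = stats.wilcoxon(a, b, method=method)
        elif test == "ttest":
            res = stats.ttest_rel(a, b)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {"signature": cname, "statistic": float(res.statistic), "p_value": float(res.pvalue)}
        )
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, target_positive: str | None = None
) -> pd.DataFrame:
    """Pearson correlations among features and the 0/1 target.

    Target coding follows the driving-performance convention: 1 = the
    "normal" class, 0 = the other.  ``target_positive`` overrides which
    label maps to 1.  Zero-variance columns give NaN correlations.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    feat_cols = [c for c in table.columns if c not in ("subject_id", "label")]
    if target_positive is None:
        labels = set(table["label"])
        target_positive = next(
            (lb for lb in sorted(labels) if str(lb).startswith("normal")),
            sorted(labels)[0],
        )
    df = table[feat_cols].astype(float).copy()
    df["target"] = (table["label"] == target_positive).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return df.corr(method="pearson")
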