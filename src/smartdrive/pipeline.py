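"""End-to-end orchestration: simulated session -> artifacts -> evaluation.

``analyze_subject`` runs the full single-subject chain: turn detection and
signature aggregation per driving phase, CO2 accumulation-segment fitting
and per-phase energy expenditure, path-discrepancy scoring, and the
engineered indicators.  ``run_cohort_analysis`` generates a synthetic
cohort, analyzes every subject, builds the cognitive feature table, and
runs the resampled random-forest evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metabolic
from .cognition import (
    EvaluationReport,
    SubjectArtifacts,
    build_feature_table,
    resampled_evaluation,
)
from .pathscore import ScoreTable, path_discrepancy_report, score_path
from .simulate import CohortConfig, SimulatedSubject, generate_cohort
from .traces import SensorTrace
from .turns import TurnConfig, aggregate_signatures, detect_turns, speed_at_peaks

__all__ = ["analyze_subject", "run_cohort_analysis", "CohortAnalysis"]


def _phase_estimates(
    subj: SimulatedSubject, constants: metabolic.MetabolicConstants
) -> dict[str, metabolic.MetabolicEstimate]:
    """Duration-weighted per-phase EE from all accumulation segments."""
    segments = metabolic.extract_accumulation_segments(
        subj.co2, subj.vent_log, subj.session
    )
    stpd_in = metabolic.StpdInputs(
        float(np.mean(subj.env_traces["temperature"].values)),
        float(np.mean(subj.env_traces["pressure"].values)),
        float(np.mean(subj.env_traces["humidity"].values)),
    )
    cf_stpd = metabolic.stpd_factor(stpd_in, constants)
    by_phase: dict[str, list[tuple[metabolic.MetabolicEstimate, float]]] = {}
    for phase_label, seg in segments:
        if phase_label == "parked":
            mean_speed = 0.0
        else:
            kin = subj.kinematics.get(phase_label)
            mean_speed = float(np.mean(kin.gps.speed_at(seg.timestamps))) if kin else 0.0
        lam = metabolic.lambda_from_speed(mean_speed, constants)
        fit = metabolic.fit_kgen(seg, lam, constants.co2_outdoor_ppm)
        est = metabolic.ee_from_kgen(
            fit.params,
            subj.session,
            cf_stpd,
            constants,
            phase=phase_label,
            fit_rmse=fit.rmse_ppm,
            segment=(float(seg.timestamps[0]), float(seg.timestamps[-1])),
        )
        by_phase.setdefault(phase_label, []).append((est, seg.duration))
    out: dict[str, metabolic.MetabolicEstimate] = {}
    for phase_label, items in by_phase.items():
        weights = np.array([w for _e, w in items])
        ee = float(np.average([e.ee for e, _w in items], weights=weights))
        k = float(np.average([e.k_gen for e, _w in items], weights=weights))
        best = max(items, key=lambda it: it[1])[0]
        out[phase_label] = metabolic.MetabolicEstimate(
            phase=phase_label,
            k_gen=k,
            k_gen_prime=constants.kgen_prime(k),
            vco2=float(np.average([e.vco2 for e, _w in items], weights=weights)),
            vo2=float(np.average([e.vo2 for e, _w in items], weights=weights)),
            ee=ee,
            fit_rmse=best.fit_rmse,
            segment=best.segment,
        )
    return out


def analyze_subject(
    subj: SimulatedSubject,
    turn_config: TurnConfig | None = None,
    score_table: ScoreTable | None = None,
    constants: metabolic.MetabolicConstants | None = None,
) -> SubjectArtifacts:
    """Run the full analysis chain on one simulated subject."""
    turn_config = turn_config or TurnConfig()
    constants = constants or metabolic.MetabolicConstants()

    signatures = {}
    path_counts: dict[str, int] = {}
    all_events = []
    unlocatable = 0
    for phase_label, kin in subj.kinematics.items():
        events = detect_turns(kin.gyro, turn_config)
        events = speed_at_peaks(events, kin.gps)
        signatures[phase_label] = aggregate_signatures(events)
        report = path_discrepancy_report(
            events, kin.gps, subj.path, score_table, kin.gps.fix_error
        )
        for k, v in report.counts.items():
            path_counts[k] = path_counts.get(k, 0) + v
        all_events.extend(report.events)
        unlocatable += report.unlocatable_uturns
    path_report = score_path(path_counts, score_table, all_events, unlocatable)

    estimates = _phase_estimates(subj, constants)
    indicators = metabolic.phase_ee_change(estimates)
    aggressive_speed = None
    if "aggressive" in subj.kinematics:
        aggressive_speed = float(np.mean(subj.kinematics["aggressive"].gps.speed_mph))
    if indicators.ee_change_pct is not None and aggressive_speed:
        full = metabolic.hybrid_indicators(
            indicators.ee_change_pct, aggressive_speed, path_report.total_score
        )
        full.ee_change_parked_to_normal_pct = indicators.ee_change_parked_to_normal_pct
        full.ee_change_parked_to_aggressive_pct = indicators.ee_change_parked_to_aggressive_pct
        indicators = full

    return SubjectArtifacts(
        subject_id=subj.subject_id,
        label=subj.label,
        signatures=signatures,
        metabolic=estimates,
        indicators=indicators,
        path_report=path_report,
        aggressive_speed_mph=aggressive_speed,
    )


@dataclass
class CohortAnalysis:
    manifest: pd.DataFrame
    artifacts: list[SubjectArtifacts]
    feature_table: pd.DataFrame
    report: EvaluationReport


def run_cohort_analysis(
    n_normal: int = 13,
    n_mci: int = 8,
    seed: int | None = None,
    config: CohortConfig | None = None,
    n_iterations: int = 100,
    split_fraction: float = 0.7,
) -> CohortAnalysis:
    """Cohort simulation + per-subject analysis + resampled evaluation."""
    subjects, manifest = generate_cohort(n_normal, n_mci, config, seed)
    artifacts = [analyze_subject(s) for s in subjects]
    table = build_feature_table(artifacts, layout="pilot2")
    ss = np.random.SeedSequence(seed)
    eval_seed = int(ss.generate_state(101)[-1] % (2**31))
    report = resampled_evaluation(
        table,
        split_fraction=split_fraction,
        n_iterations=n_iterations,
        seed=eval_seed,
        positive_label="mci",
    )
    return CohortAnalysis(manifest, artifacts, table, report)
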