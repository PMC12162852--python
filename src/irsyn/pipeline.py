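"""End-to-end orchestration: simulate → process → QC → features → classify →
analyze, as one reproducible run.

A pipeline run is a pure function of (inputs, configuration, seed): running
the same :class:`RunConfig` twice produces identical artifacts.  The report
records the exact configuration (with a hash), post-QC n, every decision
threshold used, and all cohort-level metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as cls
from . import features as feat
from . import preprocess as pre
from . import qc as qcmod
from . import stats as st
from .spectra_io import MeasurementRun, Spectrum, SubjectRecord, write_cohort_table
from .synthetic_data import CohortConfig, default_cohort_config, simulate_cohort, vapor_reference

logger = logging.getLogger("irsyn")

__all__ = ["RunConfig", "RunReport", "process_run", "extract_features",
           "analyze_records", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    cohort: CohortConfig
    thresholds: cls.Thresholds = field(default_factory=cls.Thresholds)
    smooth_window: int = 9
    smooth_polyorder: int = 3
    com_fraction: float = 0.85
    out_dir: Optional[str] = None

    @classmethod
    def default(cls_, seed: int, n_positive: int = 62, n_control: int = 72,
                out_dir: Optional[str] = None) -> "RunConfig":
        return cls_(cohort=default_cohort_config(seed, n_positive, n_control),
                    out_dir=out_dir)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    config: dict
    n_total: int
    n_qc_excluded: int
    n_feature_invalid: int
    traffic_counts: dict
    metrics: dict
    timings: dict
    features_table: pd.DataFrame


def process_run(run: MeasurementRun, vapor_ref: Spectrum,
                smooth_window: int = 9, smooth_polyorder: int = 3
                ) -> tuple[Spectrum, Spectrum]:
    """Canonical processing chain for one acquisition.

    average → vapor-correct → baseline-correct → difference → smooth.
    Returns (smoothed, unsmoothed) difference spectra; the unsmoothed one is
    kept for the S/N gate.
    """
    bg = pre.average_spectra(run.background)
    wash = pre.average_spectra(run.sample_wash)
    bg = pre.correct_baseline(pre.correct_water_vapor(bg, vapor_ref))
    wash = pre.correct_baseline(pre.correct_water_vapor(wash, vapor_ref))
    diff = pre.difference_spectrum(wash, bg)
    diff.meta["smoothed"] = False
    smoothed = pre.smooth(diff, smooth_window, smooth_polyorder)
    return smoothed, diff


def extract_features(smoothed: Spectrum, unsmoothed: Spectrum,
                     run: Optional[MeasurementRun] = None,
                     com_fraction: float = 0.85) -> feat.FeatureSet:
    """QC plus the full per-subject feature set; invalid features are flagged,
    never dropped."""
    report = qcmod.run_qc(smoothed, unsmoothed)
    kin = None
    if run is not None and run.kinetics is not None and len(run.kinetics) >= 10:
        kin = feat.kinetic_amplitude(run.kinetics)
    try:
        ratio = feat.spectral_ratio(smoothed)
        amax = feat.absolute_max(smoothed)
        cmax = feat.com_max(smoothed, fraction=com_fraction)
        valid = True
    except (feat.InvalidFeatureError, ValueError):
        ratio = amax = cmax = float("nan")
        valid = False
    return feat.FeatureSet(abs_max=amax, com_max=cmax, ratio_1656_1623=ratio,
                           kinetic_amplitude=kin, qc=report, valid=valid)


def analyze_records(records: list[SubjectRecord],
                    thresholds: cls.Thresholds = cls.DEFAULT_THRESHOLDS,
                    seed: Optional[int] = None) -> dict:
    """Cohort statistics on QC-passing subjects with valid features."""
    usable = [r for r in records
              if r.features is not None and r.features.valid
              and r.features.qc is not None and r.features.qc.passed]
    pos_ratios = [r.features.ratio_1656_1623 for r in usable if r.is_positive]
    ctl_ratios = [r.features.ratio_1656_1623 for r in usable if not r.is_positive]
    metrics: dict = {
        "n_analyzed": len(usable),
        "n_positive": len(pos_ratios),
        "n_control": len(ctl_ratios),
        "median_ratio_positive": float(np.median(pos_ratios)) if pos_ratios else None,
        "median_ratio_control": float(np.median(ctl_ratios)) if ctl_ratios else None,
    }
    if pos_ratios and ctl_ratios:
        mwu = st.mann_whitney_u(pos_ratios, ctl_ratios)
        metrics["mann_whitney"] = {"U": mwu.statistic, "p": mwu.p_value,
                                   "test": mwu.test}
        score = st.fit_logistic_score(usable)
        roc = st.roc_auc(score.scores, score.truth,
                         coefficients=score.coefficients, seed=seed)
        metrics["roc"] = {"auc": roc.auc, "ci_low": roc.ci_low,
                          "ci_high": roc.ci_high,
                          "coefficients": roc.coefficients,
                          "fallback": score.fallback}
        cov = st.covariate_only_auc(usable, seed=seed)
        metrics["roc_covariates_only"] = {"auc": cov.auc, "ci_low": cov.ci_low,
                                          "ci_high": cov.ci_high}
        # extreme-group (red vs green) confusion
        try:
            extremes = cls.confusion_from_extremes(usable)
            metrics["confusion_extremes"] = {
                "tp": extremes.tp, "fn": extremes.fn,
                "fp": extremes.fp, "tn": extremes.tn,
                "sensitivity_pct": extremes.sensitivity,
                "specificity_pct": extremes.specificity,
            }
            score_ext = [-r.features.ratio_1656_1623 for r in usable
                         if r.label in ("red", "green")]
            truth_ext = [int(r.is_positive) for r in usable
                         if r.label in ("red", "green")]
            if score_ext and len(set(truth_ext)) == 2:
                roc_ext = st.roc_auc(score_ext, truth_ext, seed=seed)
                metrics["roc_extremes"] = {"auc": roc_ext.auc,
                                           "ci_low": roc_ext.ci_low,
                                           "ci_high": roc_ext.ci_high}
        except ValueError as e:
            metrics["confusion_extremes"] = f"undefined ({e})"
        # Q_Alb cross-tab against the misfolding call
        with_q = [r for r in usable if r.q_alb is not None]
        if with_q:
            bbb = [(st.qalb_positivity(r.age, r.q_alb), r.is_positive,
                    r.label == "red" or (r.label == "yellow"
                                         and r.features.ratio_1656_1623 < thresholds.single))
                   for r in with_q]
            n_pos_bbb = sum(1 for q, p, _ in bbb if q and p)
            n_pos = sum(1 for _, p, _ in bbb if p)
            metrics["qalb"] = {
                "n_with_qalb": len(with_q),
                "bbb_positive_rate_pd_msa_pct": (
                    100.0 * n_pos_bbb / n_pos if n_pos else None),
            }
    return metrics


def records_from_feature_table(table: pd.DataFrame) -> list[SubjectRecord]:
    """Rebuild SubjectRecords (with features, QC and labels) from a
    ``features.tsv`` table written by :func:`run_pipeline`."""
    records = []
    for _, row in table.iterrows():
        q = row.get("q_alb")
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]), diagnosis=str(row["diagnosis"]),
            age=float(row["age"]), sex=str(row["sex"]),
            q_alb=None if pd.isna(q) else float(q))
        reasons = (str(row["qc_reasons"]).split(";")
                   if isinstance(row.get("qc_reasons"), str) and row["qc_reasons"]
                   else [])
        qc_report = qcmod.QCReport(amide_ratio=float(row["amide_ratio"]),
                                   snr=float(row["snr"]),
                                   passed=bool(row["qc_passed"]),
                                   reasons=reasons)
        rec.features = feat.FeatureSet(
            abs_max=float(row["abs_max"]), com_max=float(row["com_max"]),
            ratio_1656_1623=float(row["ratio_1656_1623"]),
            qc=qc_report, valid=bool(np.isfinite(row["ratio_1656_1623"])))
        label = row.get("label")
        rec.label = label if isinstance(label, str) and label else None
        records.append(rec)
    return records


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full synthetic study and return a machine-readable report."""
    if config.cohort.positive.n + config.cohort.control.n < 1:
        raise ValueError("cohort is empty: nothing to run")
    timings: dict = {}
    t0 = time.perf_counter()
    records, runs = simulate_cohort(config.cohort)
    timings["simulate_s"] = time.perf_counter() - t0
    grid = config.cohort.grid()
    vref = vapor_reference(grid)

    t0 = time.perf_counter()
    n_excluded = 0
    n_invalid = 0
    rows = []
    for rec, run in zip(records, runs):
        try:
            smoothed, unsmoothed = process_run(run, vref, config.smooth_window,
                                               config.smooth_polyorder)
        except ValueError as e:
            raise ValueError(f"stage 'process' failed for subject "
                             f"{rec.subject_id}: {e}") from e
        fs = extract_features(smoothed, unsmoothed, run, config.com_fraction)
        rec.features = fs
        if not fs.qc.passed:
            n_excluded += 1
            logger.warning("subject %s excluded by QC: %s",
                           rec.subject_id, fs.qc.reasons)
        elif not fs.valid:
            n_invalid += 1
            logger.warning("subject %s has invalid features", rec.subject_id)
        else:
            rec.label = cls.classify_traffic_light(fs.ratio_1656_1623,
                                                   config.thresholds)
        rows.append({
            "subject_id": rec.subject_id, "diagnosis": rec.diagnosis,
            "group": rec.group, "age": rec.age, "sex": rec.sex,
            "q_alb": rec.q_alb, "qc_passed": fs.qc.passed,
            "qc_reasons": ";".join(fs.qc.reasons),
            "amide_ratio": fs.qc.amide_ratio, "snr": fs.qc.snr,
            "abs_max": fs.abs_max, "com_max": fs.com_max,
            "ratio_1656_1623": fs.ratio_1656_1623,
            "kinetic_amplitude": fs.kinetic_amplitude,
            "label": rec.label,
            "single_call": (cls.classify_single(fs.ratio_1656_1623,
                                                config.thresholds.single)
                            if fs.valid and fs.qc.passed else None),
        })
    timings["process_s"] = time.perf_counter() - t0

    table = pd.DataFrame(rows)
    labeled = [r for r in records if r.label is not None]
    counts = {c: sum(1 for r in labeled if r.label == c)
              for c in ("red", "yellow", "green")}

    t0 = time.perf_counter()
    metrics = analyze_records(records, config.thresholds,
                              seed=config.cohort.seed)
    timings["analyze_s"] = time.perf_counter() - t0

    logger.info("thresholds used: single=%s lower=%s upper=%s; "
                "QC gates amide ratio %s, S/N >= %s; COM fraction %s",
                config.thresholds.single, config.thresholds.lower,
                config.thresholds.upper, qcmod.AMIDE_RATIO_BOUNDS,
                qcmod.SNR_MINIMUM, config.com_fraction)

    report = RunReport(
        config_hash=config.hash(), config=config.to_dict(),
        n_total=len(records), n_qc_excluded=n_excluded,
        n_feature_invalid=n_invalid, traffic_counts=counts,
        metrics=metrics, timings=timings, features_table=table,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.tsv", sep="\t", index=False)
        write_cohort_table(records, out / "cohort.tsv")
        payload = {k: v for k, v in dataclasses.asdict(report).items()
                   if k != "features_table"}
        (out / "report.json").write_text(
            json.dumps(payload, indent=2, default=str))
    return report


def make_report(report: RunReport) -> str:
    """Human-readable run summary."""
    m = report.metrics
    lines = [
        f"irsyn run {report.config_hash}",
        f"subjects: {report.n_total}  "
        f"excluded by QC: {report.n_qc_excluded}  "
        f"invalid features: {report.n_feature_invalid}",
        f"traffic light: red={report.traffic_counts['red']} "
        f"yellow={report.traffic_counts['yellow']} "
        f"green={report.traffic_counts['green']}",
    ]
    if m.get("median_ratio_positive") is not None:
        lines.append(f"median 1656.0/1623.5 ratio: "
                     f"PD/MSA {m['median_ratio_positive']:.3f}  "
                     f"control {m['median_ratio_control']:.3f}")
    if "mann_whitney" in m:
        lines.append(f"Mann-Whitney U={m['mann_whitney']['U']:.1f} "
                     f"p={m['mann_whitney']['p']:.3g}")
    if "roc" in m:
        r = m["roc"]
        lines.append(f"AUC (ratio+age+sex): {r['auc']:.2f} "
                     f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f})")
    if "roc_covariates_only" in m:
        r = m["roc_covariates_only"]
        lines.append(f"AUC (age+sex only): {r['auc']:.2f}")
    ce = m.get("confusion_extremes")
    if isinstance(ce, dict):
        lines.append(f"extremes: sensitivity {ce['sensitivity_pct']}% "
                     f"specificity {ce['specificity_pct']}% "
                     f"(tp={ce['tp']} fn={ce['fn']} fp={ce['fp']} tn={ce['tn']})")
    elif ce is not None:
        lines.append(f"extremes confusion: {ce}")
    return "\n".join(lines)
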