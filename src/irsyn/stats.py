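"""Cohort-level statistics for the misfolding read-out.

Primary analysis: a logistic regression with disease status (PD/MSA vs
disease control) as the outcome and the 1656.0/1623.5 ratio, age and sex as
covariates; ROC curves and AUCs are computed from the predicted
probabilities, with DeLong 95% confidence intervals (bootstrap available).
Group location differences use the two-sided Mann–Whitney U test (the ratio
is not normally distributed), sex imbalance a Pearson chi-square.  Small
supporting computations: the age-dependent albumin-quotient positivity rule
(Q_Alb > 4 + age/15), antibody extraction efficiency from ELISA
concentrations, and the thioflavin-T aggregation verdict
(413 → 450 nm excitation shift plus ≥20× emission gain at 482 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "GroupTestResult", "RocResult", "LogisticScore",
    "mann_whitney_u", "chi_square_sex", "fit_logistic_score",
    "roc_auc", "covariate_only_auc", "qalb_positivity", "albumin_norm_value",
    "extraction_efficiency", "tht_verdict",
]


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    test: str
    n: tuple

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    coefficients: dict = field(default_factory=dict)
    ci_method: str = "delong"

    def __post_init__(self):
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC")


@dataclass
class LogisticScore:
    scores: np.ndarray          # predicted probability of disease
    truth: np.ndarray           # 1 = misfolding positive
    coefficients: dict
    fallback: bool = False
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when the smaller group has ≤ 8 observations and
    there are no ties; normal approximation with tie correction otherwise.
    The reported statistic is min(U₁, U₂).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        u = x.size * y.size / 2.0
        return GroupTestResult(u, 1.0, "mann_whitney_u", (x.size, y.size))
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return GroupTestResult(u, min(float(res.pvalue), 1.0),
                           f"mann_whitney_u_{method}", (x.size, y.size))


def chi_square_sex(table: np.ndarray, correction: bool = False) -> GroupTestResult:
    """Pearson chi-square on a 2×2 contingency table (sex × group).

    Continuity correction off by default; Yates-corrected variant by flag.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(table, correction=correction)
    return GroupTestResult(float(res.statistic), float(res.pvalue),
                           "chi_square", tuple(int(v) for v in table.sum(axis=1)))


# ---------------------------------------------------------------------------
# Logistic scoring and ROC
# ---------------------------------------------------------------------------


def _records_frame(records: Sequence) -> pd.DataFrame:
    rows = []
    for r in records:
        ratio = np.nan
        if r.features is not None and getattr(r.features, "valid", True):
            ratio = r.features.ratio_1656_1623
        rows.append({"subject_id": r.subject_id, "y": int(r.is_positive),
                     "ratio": ratio, "age": r.age,
                     "sex": 1.0 if r.sex == "F" else 0.0})
    return pd.DataFrame(rows)


def fit_logistic_score(records: Sequence,
                       covariates: tuple = ("ratio", "age", "sex")) -> LogisticScore:
    """Maximum-likelihood logistic model: disease status ~ covariates.

    Sex is encoded F = 1, M = 0.  Subjects with missing covariates are
    excluded and counted.  Under perfect separation the ML fit diverges; the
    scores then fall back to the rank of −ratio (low ratio ⇒ misfolding),
    a monotone-equivalent score for ROC purposes, with an explicit warning.
    """
    if not covariates:
        raise ValueError("need at least one covariate")
    df = _records_frame(records)
    complete = df.dropna(subset=list(covariates))
    n_excluded = len(df) - len(complete)
    y = complete["y"].to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least two subjects per class")
    X = sm.add_constant(complete[list(covariates)].to_numpy(dtype=float))
    names = ("intercept", *covariates)

    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=Warning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("logistic fit did not converge")
        scores = np.asarray(fit.predict(X), dtype=float)
        coefficients = dict(zip(names, (float(b) for b in fit.params)))
    except Exception:
        fallback = True
        warnings.warn("perfect separation or non-convergence in logistic fit; "
                      "falling back to rank(-ratio) scores")
        key = "ratio" if "ratio" in covariates else covariates[0]
        vals = complete[key].to_numpy(dtype=float)
        scores = rankdata(-vals) / (len(vals) + 1.0)
        coefficients = {name: np.nan for name in names}
    return LogisticScore(scores=scores, truth=y, coefficients=coefficients,
                         fallback=fallback, n_excluded=n_excluded)


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via mid-rank structural components."""
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_ranks[:m] - pos_ranks) / n          # components over positives
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # components over negatives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc), float(var)


def roc_auc(scores: Sequence[float], truth: Sequence[int],
            ci_method: str = "delong", n_boot: int = 2000,
            seed: Optional[int] = None,
            coefficients: Optional[dict] = None) -> RocResult:
    """Empirical ROC curve and AUC with a 95% confidence interval.

    The trapezoidal AUC over the empirical ROC equals the normalized
    Mann–Whitney U statistic; the default CI is DeLong's, a seeded
    percentile bootstrap is available with ``ci_method="bootstrap"``.
    CI bounds are not clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    auc, var = _delong_auc_variance(pos, neg)
    if ci_method == "delong":
        half = 1.959963984540054 * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, pos.size, replace=True)
            q = rng.choice(neg, neg.size, replace=True)
            reps[b], _ = _delong_auc_variance(p, q)
        lo, hi = np.percentile(reps, [2.5, 97.5])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    fpr, tpr, _ = roc_curve(truth, scores)
    return RocResult(auc=auc, ci_low=float(lo), ci_high=float(hi),
                     fpr=fpr, tpr=tpr,
                     coefficients=coefficients or {}, ci_method=ci_method)


def covariate_only_auc(records: Sequence, seed: Optional[int] = None) -> RocResult:
    """ROC-AUC of the demographics-only model (age and sex, no read-out)."""
    score = fit_logistic_score(records, covariates=("age", "sex"))
    return roc_auc(score.scores, score.truth, coefficients=score.coefficients,
                   seed=seed)


# ---------------------------------------------------------------------------
# Small supporting computations
# ---------------------------------------------------------------------------


def albumin_norm_value(age: float) -> float:
    """Age-dependent Q_Alb norm value: 4 + age/15."""
    if not age > 0:
        raise ValueError("age must be positive")
    return 4.0 + age / 15.0


def qalb_positivity(age: float, q_alb: float) -> bool:
    """Blood–brain-barrier dysfunction flag: Q_Alb strictly above the
    age-dependent norm value."""
    return q_alb > albumin_norm_value(age)


def extraction_efficiency(original_conc: float, supernatant_conc: float) -> float:
    """Percent of analyte removed from the sample: 100·(orig − sup)/orig."""
    if not original_conc > 0:
        raise ValueError("original concentration must be positive")
    if supernatant_conc < 0:
        raise ValueError("supernatant concentration must be non-negative")
    eff = 100.0 * (original_conc - supernatant_conc) / original_conc
    if eff < 0:
        warnings.warn("supernatant exceeds original concentration; "
                      "possible dilution mismatch")
    return eff


def tht_verdict(scans, shift_tolerance_nm: float = 3.0,
                min_emission_factor: float = 20.0) -> tuple[float, float, bool]:
    """Thioflavin-T aggregation verdict.

    ``scans`` is a :class:`~irsyn.synthetic_data.ThTScans`-like object with
    excitation (410–460 nm) and emission (480–620 nm) scans plus a blank
    emission scan.  Returns (excitation peak shift from 413 nm, emission
    factor at 482 nm vs blank, aggregated flag).  Aggregation is confirmed
    when the excitation maximum sits within ±3 nm of 450 nm (intercalated
    ThT) and the 482 nm emission is at least 20× the blank.
    """
    ex_wl = np.asarray(scans.excitation_wl, dtype=float)
    ex = np.asarray(scans.excitation, dtype=float)
    em_wl = np.asarray(scans.emission_wl, dtype=float)
    em = np.asarray(scans.emission, dtype=float)
    blank = np.asarray(scans.blank_emission, dtype=float)
    if ex_wl.min() > 410 or ex_wl.max() < 460:
        raise ValueError("excitation scan must cover 410-460 nm")
    if em_wl.min() > 480 or em_wl.max() < 620:
        raise ValueError("emission scan must cover 480-620 nm")
    peak = float(ex_wl[int(np.argmax(ex))])
    at_482 = np.abs(em_wl - 482.0) <= 1.0
    blank_mean = float(blank[at_482].mean())
    if blank_mean <= 0:
        raise ValueError("blank emission nonpositive at 482 nm")
    factor = float(em[at_482].mean()) / blank_mean
    aggregated = (abs(peak - 450.0) <= shift_tolerance_nm
                  and factor >= min_emission_factor)
    return peak - 413.0, factor, aggregated
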