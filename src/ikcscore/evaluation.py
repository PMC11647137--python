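"""Evaluation statistics: ROC/AUC, Kaplan-Meier, log-rank, univariate Cox,
optimal survival cutoff, Spearman correlation, and PD-L1 / TMB comparator bins.

The log-rank machinery is implemented here directly (hypergeometric expected
counts and variances per event time) because the optimal-cutoff search needs
the standardized statistic at every admissible split of a continuous score;
Kaplan-Meier curves and Cox models are fitted with lifelines (Efron tie
handling for Cox, the default of modern survival software).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .core_io import ClinicalTable, ValidationError

logger = logging.getLogger("ikcscore")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and AUC of ``scores`` against binary ``labels`` (1 = positive).

    The AUC is computed by the rank (Mann-Whitney) formulation, so tied scores
    contribute half a concordant pair and the value is invariant to any
    strictly monotone transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels != 1]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("ROC requires both classes present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (pos.size * neg.size)
    fpr, tpr, thr = _sk_roc_curve(labels == 1, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# Survival: Kaplan-Meier, log-rank, Cox
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve: S(t) with at-risk counts at event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class SurvivalResult:
    km_curves: dict[str, KMCurve]
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    cox_p: float


def _check_survival(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size != events.size or times.size == 0:
        raise ValidationError("times and events must be equal-length and non-empty")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0 (censored) or 1 (event)")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator (censoring shrinks risk sets
    without introducing steps)."""
    times, events = _check_survival(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def _logrank_o_e_v(times, events, in_a: np.ndarray) -> tuple[float, float, float]:
    """Observed events, hypergeometric expectation and variance for group A."""
    event_times = np.unique(times[events == 1])
    o = e = v = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        o += d_a
        e += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return float(o), float(e), float(v)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    times, events = _check_survival(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValidationError(f"log-rank test requires exactly 2 non-empty groups, got {labels.size}")
    o, e, v = _logrank_o_e_v(times, events, groups == labels[0])
    if v == 0:
        return 0.0, 1.0
    chi2 = (o - e) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_univariate(times, events, covariate) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox proportional hazards fit (Efron ties, Wald 95% CI).

    Returns (hazard ratio per unit covariate, (ci_low, ci_high), p).
    """
    times, events = _check_survival(times, events)
    covariate = np.asarray(covariate, dtype=float)
    if np.unique(covariate).size == 1:
        raise ValidationError("constant covariate in Cox model")
    df = pd.DataFrame({"time": times, "event": events, "x": covariate})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9, "max_steps": 500})
    except ConvergenceError as err:
        raise ValidationError(f"Cox model failed to converge (perfect separation?): {err}") from err
    row = cph.summary.loc["x"]
    return (
        float(row["exp(coef)"]),
        (float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        float(row["p"]),
    )


def survival_by_group(times, events, groups) -> SurvivalResult:
    """KM curves per group, log-rank test, and Cox HR of group B vs group A.

    ``groups`` must take exactly two values; the HR is reported for the
    lexicographically *second* label relative to the first (so with labels
    "high"/"low" the HR is low-vs-high... pass an indicator to control the
    reference). Most callers use :func:`evaluate_profile`, which reports the
    HR of the high-score group explicitly.
    """
    times, events = _check_survival(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValidationError("survival comparison requires exactly 2 groups")
    chi2, p = logrank_test(times, events, groups)
    hr, ci, cox_p = cox_univariate(times, events, (groups == labels[1]).astype(float))
    curves = {
        str(lab): km_estimate(times[groups == lab], events[groups == lab]) for lab in labels
    }
    return SurvivalResult(curves, chi2, p, hr, ci[0], ci[1], cox_p)


def standardized_logrank(times, events, in_a: np.ndarray) -> float:
    """Standardized log-rank statistic (O - E)/sqrt(V) for membership ``in_a``."""
    times, events = _check_survival(times, events)
    o, e, v = _logrank_o_e_v(times, events, np.asarray(in_a, dtype=bool))
    if v == 0:
        return 0.0
    return (o - e) / np.sqrt(v)


def optimal_cutoff(scores, times, events, minprop: float = 0.1) -> float:
    """Maximally selected log-rank cutpoint for a continuous score.

    Scans the midpoints of consecutive sorted unique scores, keeping only
    splits that leave both groups with at least ``minprop`` of the samples,
    and returns the cutoff maximizing |standardized log-rank statistic|
    (ties resolved to the lower cutoff). The p-value at the selected cutoff is
    *not* corrected for the maximal selection and should be treated as
    exploratory.
    """
    scores = np.asarray(scores, dtype=float)
    times, events = _check_survival(times, events)
    if scores.size != times.size:
        raise ValidationError("scores and survival data must align")
    n = scores.size
    if n < int(np.ceil(1 / minprop)):
        raise ValidationError(f"need >= {int(np.ceil(1 / minprop))} samples for minprop={minprop}")
    uniq = np.unique(scores)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_group = minprop * n
    best_cut, best_stat = None, -np.inf
    for cut in candidates:  # ascending, so strict improvement keeps the lowest tie
        low = scores <= cut
        if low.sum() < min_group or (n - low.sum()) < min_group:
            continue
        stat = abs(standardized_logrank(times, events, ~low))
        if stat > best_stat + 1e-12:
            best_stat, best_cut = stat, cut
    if best_cut is None:
        raise ValidationError("no cutoff satisfies the minprop constraint")
    return float(best_cut)


# ---------------------------------------------------------------------------
# Correlation and comparator binnings
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks at ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman requires aligned vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pdl1_level(tps: float) -> int:
    """PD-L1 tumor proportion score binned: <1% -> 0, 1-49% -> 1, >=50% -> 2."""
    if not 0 <= tps <= 100:
        raise ValidationError(f"PD-L1 TPS {tps} outside [0, 100]")
    if tps < 1:
        return 0
    if tps < 50:
        return 1
    return 2


def pdl1_binary(tps: float) -> str:
    """PD-L1 positive (>=1%) vs negative (<1%)."""
    return "neg" if pdl1_level(tps) == 0 else "pos"


def tmb_group(tmb: float, cutoff: float = 10.0) -> str:
    """Tumor mutation burden group: high iff tmb >= cutoff (mut/Mb)."""
    if tmb < 0:
        raise ValidationError(f"negative TMB {tmb}")
    return "high" if tmb >= cutoff else "low"


# ---------------------------------------------------------------------------
# Whole-profile evaluation report
# ---------------------------------------------------------------------------


def evaluate_profile(
    profile: pd.DataFrame, clinical: ClinicalTable, minprop: float = 0.1
) -> dict:
    """Evaluate an IKC profile against clinical outcomes.

    Computes the response AUC of the IKC score, the optimal survival cutoff
    with the high-vs-low log-rank test and Cox HR, and — when the columns are
    available — comparator AUCs for PD-L1 (continuous, 3-level, binary) and
    TMB (continuous, 10 mut/Mb binary).
    """
    shared = profile.index.intersection(clinical.df.index)
    if shared.empty:
        raise ValidationError("profile and clinical table share no samples")
    profile = profile.loc[shared]
    clin = clinical.df.loc[shared]

    report: dict = {"n_samples": int(len(shared))}

    responder = clin["responder"]
    labeled = responder.notna()
    if labeled.sum() >= 4 and responder[labeled].nunique() == 2:
        y = (responder[labeled] == "R").astype(int).to_numpy()
        report["auc_ikc"] = roc_auc(profile.loc[labeled, "ikc_score"], y).auc
        for comparator, transform in (
            ("pdl1_tps", None),
            ("pdl1_level", lambda v: [pdl1_level(t) for t in v]),
            ("pdl1_binary", lambda v: [0 if pdl1_binary(t) == "neg" else 1 for t in v]),
            ("tmb", None),
            ("tmb_group", lambda v: [0 if tmb_group(t) == "low" else 1 for t in v]),
        ):
            source = comparator if comparator in clin else comparator.split("_")[0]
            src_col = {"pdl1_level": "pdl1_tps", "pdl1_binary": "pdl1_tps",
                       "tmb_group": "tmb"}.get(comparator, comparator)
            if src_col not in clin:
                continue
            have = labeled & clin[src_col].notna()
            if have.sum() < 4 or responder[have].nunique() < 2:
                continue
            vals = clin.loc[have, src_col].to_numpy(dtype=float)
            if transform is not None:
                vals = np.asarray(transform(vals), dtype=float)
            if np.unique(vals).size < 2:
                continue
            yv = (responder[have] == "R").astype(int).to_numpy()
            report[f"auc_{comparator}"] = roc_auc(vals, yv).auc

    if "pfs_time" in clin:
        surv = clin["pfs_time"].notna()
        if surv.sum() >= int(np.ceil(1 / minprop)):
            times = clin.loc[surv, "pfs_time"].to_numpy(dtype=float)
            events = clin.loc[surv, "pfs_event"].to_numpy(dtype=float)
            scores = profile.loc[surv, "ikc_score"].to_numpy(dtype=float)
            cutoff = optimal_cutoff(scores, times, events, minprop=minprop)
            high = scores > cutoff
            chi2, p = logrank_test(times, events, np.where(high, "high", "low"))
            report.update(
                cutoff=float(cutoff),
                n_high=int(high.sum()),
                n_low=int((~high).sum()),
                logrank_chi2=chi2,
                logrank_p=p,
            )
            try:
                hr, ci, cox_p = cox_univariate(times, events, high.astype(float))
                report.update(hr_high_vs_low=hr, hr_ci=[ci[0], ci[1]], cox_p=cox_p)
            except ValidationError as err:
                logger.warning("Cox HR unavailable: %s", err)
                report["cox_flag"] = "monotone_likelihood"

    if "tumor_purity" in clin:
        have = clin["tumor_purity"].notna()
        if have.sum() >= 3:
            rho, p = spearman(clin.loc[have, "tumor_purity"], profile.loc[have, "krt_score"])
            report["purity_krt_spearman_rho"] = rho
            report["purity_krt_spearman_p"] = p
    if "tmb" in clin:
        have = clin["tmb"].notna()
        if have.sum() >= 3:
            rho, p = spearman(clin.loc[have, "tmb"], profile.loc[have, "ikc_score"])
            report["tmb_ikc_spearman_rho"] = rho
            report["tmb_ikc_spearman_p"] = p
    return report
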