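"""Kaplan-Meier estimation, logrank and trend tests, landmark re-anchoring.

Progression-free survival (PFS) runs from the baseline blood draw to the
first documented progression or death, censored at the last assessment up
to 12 months.  Group comparisons use the logrank family: the k-sample
heterogeneity test (k-1 df) and, for ordered score categories, the 1-df
score-weighted trend statistic.  Follow-up draws are analyzed by landmark:
PFS is re-anchored at the draw among patients who were sampled and still
progression-free at that time.

Kaplan-Meier curves come from lifelines; the observed-minus-expected vector
and its hypergeometric covariance are computed here because the trend
statistic needs them explicitly (the k-group chi-square built from the same
machinery is cross-checked against lifelines in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .synthetic import PatientRecord


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be > 0, got {self.time}")
        if not self.group:
            raise ValueError("group label must be non-empty")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with at-risk/event bookkeeping per event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass(frozen=True)
class LandmarkSpec:
    visit: str
    landmark_time: float


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator (events before censorings at ties)."""
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    mask = tab["observed"].to_numpy() > 0
    t = tab.index.to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    return KMCurve(
        event_times=t,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(dtype=float)[mask],
        events=tab["observed"].to_numpy(dtype=float)[mask],
    )


def km_median(curve: KMCurve) -> Optional[float]:
    """Smallest time with survival <= 0.5, or None if never reached."""
    below = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def _oe_and_covariance(records: Sequence[SurvivalRecord], groups: Sequence[str]):
    """Observed-minus-expected event counts per group and their covariance.

    At each distinct event time with d events and n at risk, group g
    (n_g at risk, d_g events) contributes O_g - E_g = d_g - d * n_g / n and
    covariance V_gh = d (n - d) / (n - 1) * (delta_gh n_g n - n_g n_h) / n^2.
    """
    k = len(groups)
    gidx = {g: j for j, g in enumerate(groups)}
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    g = np.array([gidx[r.group] for r in records], dtype=int)

    oe = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in np.unique(t[e]):
        at_risk = t >= tt
        n = at_risk.sum()
        dying = e & (t == tt)
        d = dying.sum()
        n_g = np.bincount(g[at_risk], minlength=k).astype(float)
        d_g = np.bincount(g[dying], minlength=k).astype(float)
        oe += d_g - d * n_g / n
        if n > 1:
            scale = d * (n - d) / (n - 1)
            cov += scale * (np.diag(n_g) * n - np.outer(n_g, n_g)) / n**2
    return oe, cov


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, int, float]:
    """k-sample logrank heterogeneity test.

    Returns ``(chi-square statistic, df = k - 1, p)``.  With no events at
    all the statistic is 0 and p is 1.
    """
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("logrank_test requires at least two groups")
    oe, cov = _oe_and_covariance(records, groups)
    df = len(groups) - 1
    sub_oe, sub_cov = oe[:-1], cov[:-1, :-1]
    if not np.any(sub_cov):
        return 0.0, df, 1.0
    stat = float(sub_oe @ np.linalg.pinv(sub_cov) @ sub_oe)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def trend_test(records: Sequence[SurvivalRecord],
               group_order: Sequence[str],
               scores: Optional[Sequence[float]] = None) -> tuple[float, float]:
    """1-df score-weighted logrank trend test over ordered groups.

    Returns the signed z statistic (positive when later groups have excess
    events) and its two-sided normal p.  Default scores 0, 1, 2, ...
    """
    if len(group_order) < 3:
        raise ValueError("trend_test requires at least three ordered groups")
    if scores is None:
        scores = list(range(len(group_order)))
    s = np.asarray(scores, dtype=float)
    oe, cov = _oe_and_covariance(records, list(group_order))
    var = float(s @ cov @ s)
    if var <= 0:
        return 0.0, 1.0
    z = float(s @ oe) / np.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def build_landmark(cohort: Sequence[PatientRecord], spec: LandmarkSpec,
                   classifier: Callable[[PatientRecord, str], Optional[str]],
                   censor_horizon: float = 12.0) -> list[SurvivalRecord]:
    """Re-anchor PFS at a follow-up visit.

    Keeps only patients with a usable (status ok) sample at the visit whose
    censoring-capped PFS extends strictly beyond the landmark time; their
    time becomes ``pfs_time - landmark_time``.  ``classifier`` maps
    (patient, visit) to a group label, or None to exclude (e.g. score not
    determinable).
    """
    out: list[SurvivalRecord] = []
    for rec in cohort:
        panel = rec.samples.get(spec.visit)
        if panel is None or panel.status != "ok":
            continue
        t_cap = min(rec.pfs_time, censor_horizon)
        event = rec.pfs_event and rec.pfs_time <= censor_horizon
        t = t_cap - spec.landmark_time
        if t <= 0:
            continue  # progressed/censored on or before the sample date
        group = classifier(rec, spec.visit)
        if group is None:
            continue
        out.append(SurvivalRecord(rec.patient_id, t, event, group))
    return out


def ctc_change_category(baseline_elevated: bool, followup_elevated: bool) -> str:
    """Four-way CTC change category between baseline and a follow-up draw."""
    if baseline_elevated is None or followup_elevated is None:
        raise ValueError("both elevation flags must be defined")
    if baseline_elevated:
        return "high" if followup_elevated else "decrease"
    return "increase" if followup_elevated else "low"
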