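"""Survival machinery: KM closed forms, logrank vs independent references,
trend statistic behavior, landmark construction, CTC change categories."""

import math

import numpy as np
import pytest
from lifelines.statistics import multivariate_logrank_test

from ctceti.scoring import AliquotPanel
from ctceti.survival import (
    KMCurve,
    LandmarkSpec,
    SurvivalRecord,
    build_landmark,
    ctc_change_category,
    km_estimate,
    km_median,
    logrank_test,
    trend_test,
)
from ctceti.synthetic import PatientRecord


def _recs(times, events, group="g", start=0):
    return [SurvivalRecord(f"p{start + i}", float(t), bool(e), group)
            for i, (t, e) in enumerate(zip(times, events))]


def _naive_logrank_oe(records, groups):
    """Straight-from-definition O-E per group (independent reimplementation)."""
    oe = {g: 0.0 for g in groups}
    event_times = sorted({r.time for r in records if r.event})
    for tt in event_times:
        at_risk = [r for r in records if r.time >= tt]
        dying = [r for r in at_risk if r.event and r.time == tt]
        n, d = len(at_risk), len(dying)
        for g in groups:
            n_g = sum(r.group == g for r in at_risk)
            d_g = sum(r.group == g for r in dying)
            oe[g] += d_g - d * n_g / n
    return oe


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        curve = km_estimate(_recs([1, 2, 3, 4, 5], [1] * 5))
        assert np.allclose(curve.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km_median(curve) == 3.0

    def test_all_censored_survival_stays_at_one(self):
        curve = km_estimate(_recs([2, 4, 6], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert km_median(curve) is None

    def test_median_undefined_when_survival_stays_above_half(self):
        curve = KMCurve(event_times=np.array([1.0, 2.0]),
                        survival=np.array([0.9, 0.7]),
                        at_risk=np.array([10.0, 9.0]), events=np.array([1.0, 1.0]))
        assert km_median(curve) is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_simulated_exponential_median_recovered(self, rng):
        target = 6.9
        times = rng.exponential(target / math.log(2), size=200)
        curve = km_estimate(_recs(times, [1] * 200))
        assert abs(km_median(curve) - target) / target <= 0.15


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        recs = _recs([1, 2, 3, 4], [1, 1, 0, 1], "a") + \
               _recs([1, 2, 3, 4], [1, 1, 0, 1], "b", start=10)
        stat, df, p = logrank_test(recs)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_no_events_gives_p_one(self):
        recs = _recs([1, 2], [0, 0], "a") + _recs([3, 4], [0, 0], "b", start=10)
        stat, _, p = logrank_test(recs)
        assert stat == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_recs([1, 2], [1, 1]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_lifelines_chi_square(self, seed, k):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(60):
            g = i % k
            recs.append(SurvivalRecord(
                f"p{i}", float(rng.exponential(2 + 2 * g)) + 1e-3,
                bool(rng.random() < 0.8), f"g{g}"))
        stat, df, p = logrank_test(recs)
        ref = multivariate_logrank_test([r.time for r in recs],
                                        [r.group for r in recs],
                                        [r.event for r in recs])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)
        assert df == k - 1

    def test_invariant_to_group_relabeling(self, rng):
        recs = []
        for i in range(40):
            recs.append(SurvivalRecord(f"p{i}", float(rng.exponential(3)) + 1e-3,
                                       bool(rng.random() < 0.7), "ab"[i % 2]))
        stat1, _, _ = logrank_test(recs)
        swapped = [SurvivalRecord(r.patient_id, r.time, r.event,
                                  "b" if r.group == "a" else "a") for r in recs]
        stat2, _, _ = logrank_test(swapped)
        assert stat1 == pytest.approx(stat2, rel=1e-9)

    def test_oe_vector_matches_naive_reimplementation(self, rng):
        from ctceti.survival import _oe_and_covariance
        recs = []
        for i in range(25):
            recs.append(SurvivalRecord(f"p{i}", float(rng.integers(1, 8)),
                                       bool(rng.random() < 0.7), "abc"[i % 3]))
        groups = ["a", "b", "c"]
        oe, _ = _oe_and_covariance(recs, groups)
        naive = _naive_logrank_oe(recs, groups)
        assert np.allclose(oe, [naive[g] for g in groups])

    def test_detects_strong_hazard_ratio(self):
        """HR 3 with 100/arm: p < 0.01 in at least 19/20 seeded replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            recs = (_recs(rng.exponential(6.0, 100) + 1e-3, [1] * 100, "lo")
                    + _recs(rng.exponential(2.0, 100) + 1e-3, [1] * 100, "hi", start=200))
            _, _, p = logrank_test(recs)
            hits += p < 0.01
        assert hits >= 19

    def test_asymptotic_p_close_to_exact_permutation_p(self):
        """On a moderate instance the chi-square p tracks the permutation null."""
        rng = np.random.default_rng(5)
        times = np.concatenate([rng.exponential(4.0, 15), rng.exponential(2.0, 15)])
        events = rng.random(30) < 0.85
        labels = np.array(["a"] * 15 + ["b"] * 15)

        def stat_for(lab):
            recs = [SurvivalRecord(f"p{i}", float(t) + 1e-3, bool(e), g)
                    for i, (t, e, g) in enumerate(zip(times, events, lab))]
            return logrank_test(recs)[0]

        obs = stat_for(labels)
        p_asym = logrank_test([SurvivalRecord(f"p{i}", float(t) + 1e-3, bool(e), g)
                               for i, (t, e, g) in enumerate(zip(times, events, labels))])[2]
        perm_ge = 0
        n_perm = 5000
        for _ in range(n_perm):
            perm_ge += stat_for(rng.permutation(labels)) >= obs - 1e-12
        p_perm = perm_ge / n_perm
        assert abs(p_asym - p_perm) < 0.05


class TestTrend:
    def test_identical_ordered_groups_give_zero(self):
        recs = []
        for g in "abc":
            recs += _recs([1, 2, 3], [1, 1, 0], g, start=ord(g) * 10)
        z, p = trend_test(recs, ["a", "b", "c"])
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_reversing_group_order_flips_sign(self, rng):
        recs = []
        for gi, g in enumerate("abc"):
            times = rng.exponential(6.0 / (gi + 1), 30) + 1e-3
            recs += _recs(times, [1] * 30, g, start=gi * 100)
        z_fwd, _ = trend_test(recs, ["a", "b", "c"])
        z_rev, _ = trend_test(recs, ["c", "b", "a"])
        assert z_fwd == pytest.approx(-z_rev, rel=1e-9)

    def test_requires_three_groups(self):
        recs = _recs([1, 2], [1, 1], "a") + _recs([3, 4], [1, 1], "b", start=10)
        with pytest.raises(ValueError):
            trend_test(recs, ["a", "b"])

    def test_detects_monotone_hazards(self):
        """Hazards increasing across groups: trend found in >= 18/20 replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            recs = []
            for gi, (g, med) in enumerate([("a", 8.0), ("b", 5.0), ("c", 2.5)]):
                times = rng.exponential(med / math.log(2), 60) + 1e-3
                recs += _recs(times, [1] * 60, g, start=gi * 100)
            z, p = trend_test(recs, ["a", "b", "c"])
            hits += (p < 0.05) and (z > 0)
        assert hits >= 18


def _patient(pid, pfs_time, pfs_event, visits=("BL", "M1"), counts=(8, 8, 8, 8)):
    panel = AliquotPanel(counts, {"ER": 10.0, "BCL2": 10.0, "HER2": 10.0, "KI67": 10.0})
    return PatientRecord(patient_id=pid, latent_state="resistant",
                         samples={v: panel for v in visits},
                         pfs_time=pfs_time, pfs_event=pfs_event)


class TestLandmark:
    spec = LandmarkSpec(visit="M1", landmark_time=1.0)

    @staticmethod
    def classifier(rec, visit):
        return "grp"

    def test_progression_before_landmark_excluded(self):
        cohort = [_patient("a", 0.5, True)]
        assert build_landmark(cohort, self.spec, self.classifier) == []

    def test_missing_sample_excluded(self):
        cohort = [_patient("a", 6.0, True, visits=("BL",))]
        assert build_landmark(cohort, self.spec, self.classifier) == []

    def test_times_re_anchored(self):
        cohort = [_patient("a", 4.0, True)]
        out = build_landmark(cohort, self.spec, self.classifier)
        assert len(out) == 1
        assert out[0].time == pytest.approx(3.0) and out[0].event

    def test_event_on_sample_date_excluded(self):
        cohort = [_patient("a", 1.0, True)]
        assert build_landmark(cohort, self.spec, self.classifier) == []

    def test_counts_partition_cohort(self):
        cohort = [
            _patient("a", 0.5, True),                 # progressed before landmark
            _patient("b", 6.0, True, visits=("BL",)),  # no sample
            _patient("c", 4.0, True),                  # included
            _patient("d", 14.0, False),                # included, censored at 12
        ]
        out = build_landmark(cohort, self.spec, self.classifier)
        included = {r.patient_id for r in out}
        assert included == {"c", "d"}
        excluded_progress = [r for r in cohort
                             if "M1" in r.samples and min(r.pfs_time, 12.0) <= 1.0]
        excluded_no_sample = [r for r in cohort if "M1" not in r.samples]
        assert len(excluded_progress) + len(excluded_no_sample) + len(out) == len(cohort)

    def test_censoring_cap_applied_before_re_anchoring(self):
        out = build_landmark([_patient("d", 14.0, False)], self.spec, self.classifier)
        assert out[0].time == pytest.approx(11.0) and not out[0].event


class TestCtcChangeCategory:
    @pytest.mark.parametrize("bl, fu, cat", [
        (False, True, "increase"),
        (True, False, "decrease"),
        (False, False, "low"),
        (True, True, "high"),
    ])
    def test_four_way_mapping(self, bl, fu, cat):
        assert ctc_change_category(bl, fu) == cat

    def test_undefined_flag_rejected(self):
        with pytest.raises(ValueError):
            ctc_change_category(None, True)
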