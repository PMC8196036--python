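"""Cohort table I/O, point-table serialization, and the analysis pipeline.

The interchange format is a delimited text table, one row per patient-visit:

    patient_id, visit, aliquot1..aliquot4, pct_er, pct_bcl2, pct_her2,
    pct_ki67, status, pfs_months, pfs_event, event_is_death, death_mbc,
    reimaged_3mo

Marker percentages are empty when undetermined; patient-level outcome
fields repeat on every row of a patient.  Times are months (reals); no
dates are ever required.  Configuration is YAML (JSON accepted — every JSON
file is valid YAML).
"""

from __future__ import annotations

import json
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import rapid_progression as rp
from . import survival as surv
from .design import PowerSpec, StageDesign, simulate_rp_power, stage_alpha, stage_beta
from .retraining import RetrainConfig, eligible_from_cohort, ensemble_validate
from .scoring import (
    DEFAULT_POINT_TABLE,
    AliquotPanel,
    PointTable,
    compute_eti,
)
from .synthetic import CohortConfig, PatientRecord, generate_cohort

COHORT_COLUMNS = [
    "patient_id", "visit", "aliquot1", "aliquot2", "aliquot3", "aliquot4",
    "pct_er", "pct_bcl2", "pct_her2", "pct_ki67", "status",
    "pfs_months", "pfs_event", "event_is_death", "death_mbc", "reimaged_3mo",
]

VALID_VISITS = ("BL", "M1", "M2", "M3", "M12")

_PCT_COLS = {"ER": "pct_er", "BCL2": "pct_bcl2", "HER2": "pct_her2", "KI67": "pct_ki67"}


class CohortFormatError(ValueError):
    """A cohort file violates the table contract."""


def write_cohort(cohort: Sequence[PatientRecord], path) -> None:
    rows = []
    for rec in cohort:
        for visit, panel in rec.samples.items():
            row = {
                "patient_id": rec.patient_id,
                "visit": visit,
                "aliquot1": panel.counts[0], "aliquot2": panel.counts[1],
                "aliquot3": panel.counts[2], "aliquot4": panel.counts[3],
                "status": panel.status,
                "pfs_months": rec.pfs_time,
                "pfs_event": int(rec.pfs_event),
                "event_is_death": int(rec.event_is_death),
                "death_mbc": int(rec.death_due_to_mbc),
                "reimaged_3mo": int(rec.reimaged_at_3mo),
            }
            for marker, col in _PCT_COLS.items():
                pct = panel.marker_pct.get(marker)
                row[col] = "" if pct is None else pct
            rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "visit": str, "status": str},
                     float_precision="round_trip")
    if list(df.columns) != COHORT_COLUMNS:
        raise CohortFormatError(
            f"malformed header: expected {COHORT_COLUMNS}, got {list(df.columns)}")

    cohort: list[PatientRecord] = []
    for pid, sub in df.groupby("patient_id", sort=False):
        samples: dict[str, AliquotPanel] = {}
        first = sub.iloc[0]
        for i, row in sub.iterrows():
            if row["visit"] not in VALID_VISITS:
                raise CohortFormatError(
                    f"row {i + 2}: unknown visit {row['visit']!r} (column 'visit')")
            try:
                counts = tuple(int(row[f"aliquot{j}"]) for j in range(1, 5))
            except (TypeError, ValueError) as exc:
                raise CohortFormatError(
                    f"row {i + 2}: unparseable aliquot count ({exc})") from None
            marker_pct = {}
            for marker, col in _PCT_COLS.items():
                v = row[col]
                if not (isinstance(v, float) and math.isnan(v)) and v != "":
                    marker_pct[marker] = float(v)
            samples[row["visit"]] = AliquotPanel(
                counts=counts, marker_pct=marker_pct, status=row["status"])
        cohort.append(PatientRecord(
            patient_id=str(pid), latent_state="unknown", samples=samples,
            pfs_time=float(first["pfs_months"]), pfs_event=bool(int(first["pfs_event"])),
            event_is_death=bool(int(first["event_is_death"])),
            death_due_to_mbc=bool(int(first["death_mbc"])),
            reimaged_at_3mo=bool(int(first["reimaged_3mo"])),
        ))
    return cohort


def save_point_table(table: PointTable, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(table.to_dict(), fh, sort_keys=False)


def load_point_table(path) -> PointTable:
    with open(path) as fh:
        return PointTable.from_dict(yaml.safe_load(fh))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# pipeline


def score_cohort(cohort: Sequence[PatientRecord],
                 table: PointTable = DEFAULT_POINT_TABLE) -> pd.DataFrame:
    """Score every panel; returns a tidy patient-visit score table."""
    rows = []
    for rec in cohort:
        for visit, panel in rec.samples.items():
            res = compute_eti(panel, table)
            rows.append({
                "patient_id": rec.patient_id, "visit": visit,
                "avg_ctc": res.avg_ctc, "rounded_avg": res.rounded_avg,
                "elevated": res.elevated, "determined": res.determined,
                "enum_points": res.enum_points, "bio_score": res.bio_score,
                "total": res.total, "category": res.category,
                "status": res.status,
            })
    return pd.DataFrame(rows)


def _eti_classifier(table: PointTable):
    def classify(rec: PatientRecord, visit: str):
        panel = rec.samples.get(visit)
        if panel is None:
            return None
        res = compute_eti(panel, table)
        return res.category if res.determined else None
    return classify


def _ctc_classifier(table: PointTable):
    def classify(rec: PatientRecord, visit: str):
        panel = rec.samples.get(visit)
        if panel is None or panel.status != "ok":
            return None
        return "elevated" if compute_eti(panel, table).elevated else "not_elevated"
    return classify


def _survival_section(cohort, table, horizon: float) -> dict:
    section: dict = {}
    visits = {"BL": 0.0, "M1": 1.0, "M2": 2.0, "M3": 3.0}
    eti_cls = _eti_classifier(table)
    ctc_cls = _ctc_classifier(table)
    for visit, t0 in visits.items():
        spec = surv.LandmarkSpec(visit=visit, landmark_time=t0)
        entry: dict = {}
        for label, cls in (("ctc", ctc_cls), ("eti", eti_cls)):
            records = surv.build_landmark(cohort, spec, cls, censor_horizon=horizon)
            groups = sorted({r.group for r in records})
            medians = {}
            for g in groups:
                sub = [r for r in records if r.group == g]
                medians[g] = surv.km_median(surv.km_estimate(sub)) if sub else None
            res: dict = {"n": len(records), "median_pfs": medians}
            if len(groups) >= 2 and records:
                stat, df, p = surv.logrank_test(records)
                res["logrank"] = {"statistic": stat, "df": df, "p": p}
            if label == "eti" and all(g in groups for g in ("low", "intermediate", "high")):
                z, p = surv.trend_test(records, ["low", "intermediate", "high"])
                res["trend"] = {"z": z, "p": p}
            entry[label] = res
        section[visit] = entry
    return section


def _rp_section(cohort, table) -> dict:
    statuses = {rec.patient_id: rp.rp_status(rec) for rec in cohort}
    assessable = [rec for rec in cohort if statuses[rec.patient_id] != "unassessable"]
    n_rp = sum(statuses[rec.patient_id] == "rp" for rec in assessable)
    section: dict = {
        "n_cohort": len(cohort),
        "n_assessable": len(assessable),
        "overall": _rate_entry(n_rp, len(assessable)),
    }

    by_cat: dict[str, list[int]] = {}
    for rec in assessable:
        res = compute_eti(rec.samples["BL"], table)
        if not res.determined:
            continue
        x = by_cat.setdefault(res.category, [0, 0])
        x[0] += statuses[rec.patient_id] == "rp"
        x[1] += 1
    section["by_eti_category"] = {c: _rate_entry(*v) for c, v in sorted(by_cat.items())}

    order = [c for c in ("low", "intermediate", "high") if c in by_cat]
    if {"low", "high"} <= set(order):
        lo, hi = by_cat["low"], by_cat["high"]
        tab = [[hi[0], hi[1] - hi[0]], [lo[0], lo[1] - lo[0]]]
        odds, p = rp.fisher_exact_2x2(tab)
        section["fisher_high_vs_low"] = {"odds_ratio": odds, "p": p, "table": tab}
    if len(order) == 3:
        tab3 = [[by_cat[c][0], by_cat[c][1] - by_cat[c][0]] for c in order]
        section["fisher_3x2_p"] = rp.fisher_exact_rxc(tab3)
        z, p = rp.trend_test_proportions(
            [by_cat[c][0] for c in order], [by_cat[c][1] for c in order])
        section["trend"] = {"z": z, "p": p}
    elif len(order) < 3:
        section["note"] = ("fewer than three score categories observed; "
                           "3-category tests not applicable")
    return section


def _rate_entry(successes: int, trials: int) -> dict:
    if trials == 0:
        return {"successes": 0, "trials": 0, "rate": None, "ci95_pct": None}
    ci = rp.clopper_pearson(successes, trials)
    return {"successes": successes, "trials": trials,
            "rate": successes / trials, "ci95_pct": list(ci.percent_interval())}


def run_pipeline(config: Mapping | None = None, seed: int | None = None) -> dict:
    """Simulate (or load) -> score -> survival -> RP -> design [-> retrain].

    Returns the structured report; each stage's failure is re-raised with
    the stage name attached.
    """
    cfg = dict(config or {})
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg.get("seed", 0))

    table = DEFAULT_POINT_TABLE
    if "point_table" in cfg:
        table = (PointTable.from_dict(cfg["point_table"])
                 if isinstance(cfg["point_table"], Mapping)
                 else load_point_table(cfg["point_table"]))

    stage = "simulate"
    try:
        if "cohort_csv" in cfg:
            stage = "load"
            cohort = read_cohort(cfg["cohort_csv"])
            horizon = float(cfg.get("censor_horizon", 12.0))
        else:
            cc = CohortConfig(**{**cfg.get("cohort", {}), "seed": seed})
            cohort = generate_cohort(cc, table)
            horizon = cc.censor_horizon

        stage = "score"
        scores = score_cohort(cohort, table)
        tabulation = {
            visit: sub.groupby("category")["patient_id"].count().to_dict()
            for visit, sub in scores.groupby("visit")
        }

        stage = "survival"
        survival_report = _survival_section(cohort, table, horizon)

        stage = "rp"
        rp_report = _rp_section(cohort, table)

        stage = "design"
        d = StageDesign()
        design_report = {
            "n": d.n, "cutoff": d.cutoff, "p_null": d.p_null, "p_alt": d.p_alt,
            "alpha": stage_alpha(d), "beta": stage_beta(d),
        }
        if cfg.get("power", False):
            pw = simulate_rp_power(PowerSpec(seed=seed,
                                             reps=int(cfg.get("power_reps", 2000))))
            design_report["power"] = {"power": pw.power, "mc_ci": list(pw.mc_ci),
                                      "reps": pw.reps}

        report = {
            "seed": seed,
            "n_patients": len(cohort),
            "eti_tabulation": tabulation,
            "survival": survival_report,
            "rapid_progression": rp_report,
            "design": design_report,
        }

        if cfg.get("retrain", True):
            stage = "retrain"
            eligible = eligible_from_cohort(cohort)
            n = len(eligible)
            if n >= 10 and len({r.rp for r in eligible}) == 2:
                val_n = max(2, round(n * 10 / 32))
                rc = RetrainConfig(train_n=n - val_n, val_n=val_n, seed=seed,
                                   n_splits=int(cfg.get("retrain_splits", 500)))
                ens = ensemble_validate(eligible, rc)
                report["retrain"] = {
                    "n_eligible": n, "auc": ens.auc,
                    "importance_tally": dict(ens.importance_tally),
                    "n_splits": ens.n_splits,
                }
            else:
                report["retrain"] = {"n_eligible": n,
                                     "note": "too few eligible patients or degenerate outcome"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return report


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=2)
        fh.write("\n")
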