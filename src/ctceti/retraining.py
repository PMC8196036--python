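"""Bootstrap-ensemble retraining of the composite score.

Exploratory modeling of rapid progression (RP) on the patients with
elevated CTC (average >= 5/7.5 ml whole blood) asks whether the four marker
percentages add anything to CTC enumeration.  The procedure: repeatedly
split the eligible patients into training (n=22) and validation (n=10)
sets; inflate each training set to 500 observations by sampling with
replacement; fit one model (a classification tree, or a logistic
regression for comparison) per training set on five predictors — average
CTC count and percent ER, BCL2, HER2, Ki67; score the matching validation
set; average each patient's predicted probabilities over every split where
they landed in validation; summarize with an ROC curve/AUC and, for trees,
a tally of which variable was most important in each fit.

Models come from scikit-learn; the univariate logistic follow-up fits use
statsmodels (for coefficient standard errors and Wald p-values).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.tree import DecisionTreeClassifier

from .rapid_progression import rp_status
from .scoring import average_ctc
from .synthetic import PatientRecord

log = logging.getLogger(__name__)

PREDICTORS = ("avg_ctc", "pct_er", "pct_bcl2", "pct_her2", "pct_ki67")


@dataclass(frozen=True)
class EligibleRecord:
    """One patient eligible for retraining: elevated CTC, RP assessable."""

    patient_id: str
    avg_ctc: float
    pct_er: float
    pct_bcl2: float
    pct_her2: float
    pct_ki67: float
    rp: bool

    def features(self) -> np.ndarray:
        return np.array([self.avg_ctc, self.pct_er, self.pct_bcl2,
                         self.pct_her2, self.pct_ki67], dtype=float)


@dataclass(frozen=True)
class RetrainConfig:
    """Ensemble configuration (defaults: the published procedure's sizes)."""

    n_splits: int = 500
    inflate_to: int = 500
    train_n: int = 22
    val_n: int = 10
    model: str = "tree"
    min_leaf: int = 5
    max_depth: int | None = None
    max_features: int | None = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inflate_to < self.train_n:
            raise ValueError("inflate_to must be >= train_n")
        if self.model not in ("tree", "logistic"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class EnsembleResult:
    patient_ids: list[str]
    mean_probability: np.ndarray
    outcomes: np.ndarray
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    importance_tally: Mapping[str, int]
    n_splits: int


def eligible_from_cohort(cohort: Sequence[PatientRecord]) -> list[EligibleRecord]:
    """Extract retraining-eligible patients from a scored cohort.

    Eligibility: assessable for RP, baseline rounded average CTC >= 5, and
    all four marker percentages determined at baseline.
    """
    out = []
    for rec in cohort:
        status = rp_status(rec)
        if status == "unassessable":
            continue
        panel = rec.samples.get("BL")
        if panel is None or panel.status != "ok":
            continue
        avg, rounded = average_ctc(panel.counts)
        if rounded < 5:
            continue
        pcts = {m: panel.marker_pct.get(m) for m in ("ER", "BCL2", "HER2", "KI67")}
        if any(v is None for v in pcts.values()):
            continue
        out.append(EligibleRecord(
            patient_id=rec.patient_id, avg_ctc=avg,
            pct_er=pcts["ER"], pct_bcl2=pcts["BCL2"],
            pct_her2=pcts["HER2"], pct_ki67=pcts["KI67"],
            rp=(status == "rp"),
        ))
    return out


def make_splits(n_records: int, config: RetrainConfig, rng: np.random.Generator):
    """Yield (training multiset indices, validation indices) per split.

    Each split randomly partitions the records into train_n/val_n, then
    resamples the training part with replacement up to ``inflate_to``.
    """
    if n_records != config.train_n + config.val_n:
        raise ValueError(
            f"cohort size {n_records} != train_n + val_n = {config.train_n + config.val_n}")
    for _ in range(config.n_splits):
        perm = rng.permutation(n_records)
        train_idx = perm[: config.train_n]
        val_idx = perm[config.train_n:]
        inflated = rng.choice(train_idx, size=config.inflate_to, replace=True)
        yield inflated, val_idx


class _ConstantPredictor:
    """Fallback predictor when a training multiset has a single class."""

    def __init__(self, p: float):
        self.p = float(p)
        self.feature_importances_ = np.zeros(len(PREDICTORS))

    def predict_proba(self, X):
        out = np.empty((len(X), 2))
        out[:, 1] = self.p
        out[:, 0] = 1.0 - self.p
        return out


def fit_one_model(X: np.ndarray, y: np.ndarray, config: RetrainConfig,
                  random_state: int | None = None):
    """Fit one tree or logistic model on a training multiset.

    Single-class training data cannot support a classifier; a constant
    class-frequency predictor is returned with a logged warning.
    """
    if len(np.unique(y)) < 2:
        log.warning("single-class training set; returning constant predictor")
        return _ConstantPredictor(float(np.mean(y)))
    if config.model == "tree":
        clf = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=config.min_leaf,
            max_depth=config.max_depth, max_features=config.max_features,
            random_state=random_state)
    else:
        clf = LogisticRegression(penalty=None, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable logits are expected at n=22
        clf.fit(X, y)
    return clf


def ensemble_validate(records: Sequence[EligibleRecord],
                      config: RetrainConfig) -> EnsembleResult:
    """Run the full split/fit/validate ensemble.

    Per patient, the mean predicted RP probability over all splits where the
    patient fell in validation; ROC/AUC from those means; for trees, a tally
    over splits of the predictor with the largest impurity decrease.
    Deterministic given ``config.seed``.
    """
    X = np.array([r.features() for r in records])
    y = np.array([r.rp for r in records], dtype=int)
    n = len(records)

    rng = np.random.default_rng(config.seed)
    prob_sum = np.zeros(n)
    prob_cnt = np.zeros(n, dtype=int)
    tally = {p: 0 for p in PREDICTORS}

    for inflated, val_idx in make_splits(n, config, rng):
        seed_fit = int(rng.integers(0, 2**31 - 1))
        model = fit_one_model(X[inflated], y[inflated], config, random_state=seed_fit)
        probs = model.predict_proba(X[val_idx])[:, 1]
        prob_sum[val_idx] += probs
        prob_cnt[val_idx] += 1
        if config.model == "tree":
            imp = getattr(model, "feature_importances_", np.zeros(len(PREDICTORS)))
            tally[PREDICTORS[int(np.argmax(imp))]] += 1

    seen = prob_cnt > 0
    if not np.all(seen):
        log.warning("%d patient(s) never appeared in a validation set; excluded from ROC",
                    int((~seen).sum()))
    mean_prob = prob_sum[seen] / prob_cnt[seen]
    y_seen = y[seen]
    if len(np.unique(y_seen)) < 2:
        raise ValueError("AUC undefined: all validated patients share one outcome")
    fpr, tpr, _ = roc_curve(y_seen, mean_prob)
    auc = float(roc_auc_score(y_seen, mean_prob))
    return EnsembleResult(
        patient_ids=[r.patient_id for r, s in zip(records, seen) if s],
        mean_probability=mean_prob, outcomes=y_seen,
        roc_fpr=fpr, roc_tpr=tpr, auc=auc,
        importance_tally=tally, n_splits=config.n_splits)


def univariate_logistic(records: Sequence[EligibleRecord],
                        variable: str) -> tuple[float, float, float]:
    """Single-predictor logistic fit of RP: (coefficient, SE, Wald p).

    Raises on a constant predictor and flags complete separation (where the
    unpenalized MLE diverges) instead of returning an unstable fit.
    """
    if variable not in PREDICTORS:
        raise ValueError(f"variable must be one of {PREDICTORS}")
    x = np.array([getattr(r, variable) for r in records], dtype=float)
    y = np.array([r.rp for r in records], dtype=int)
    if np.ptp(x) == 0:
        raise ValueError(f"{variable} has no variation")
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        raise ValueError(f"complete separation on {variable}; unpenalized fit withheld")
    design = sm.add_constant(x)
    fit = sm.Logit(y, design).fit(disp=0)
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
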