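"""Rapid-progression endpoint and exact categorical statistics.

Rapid progression (RP) is objective radiographic progression, or death due
to metastatic breast cancer, within 3 months of the baseline draw; patients
without 3-month reimaging (and no qualifying event before then) are
unassessable and omitted.  Associations of RP with CTC and score categories
use Fisher's exact test (2x2 and its Freeman-Halton r x c generalization),
exact Clopper-Pearson binomial intervals for the printed rates, and the
Cochran-Armitage trend test across ordered categories.

Fisher 2x2 is scipy's; the Freeman-Halton test enumerates all tables with
the observed margins (scipy has no r x c exact test) using the two-sided
probability-mass rule: p sums the null probabilities of tables no more
probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .synthetic import PatientRecord

RP_WINDOW_MONTHS = 3.0

_REL_EPS = 1e-9  # tolerance when comparing table probabilities


def rp_status(patient: PatientRecord) -> str:
    """Classify a patient as ``rp``, ``no_rp`` or ``unassessable``.

    A qualifying event (progression, or death due to MBC) within 3 months
    is RP regardless of reimaging.  Otherwise 3-month reimaging is required
    to call no-RP; without it the patient is unassessable — even a non-MBC
    death inside the window does not qualify.
    """
    if patient.pfs_event and patient.pfs_time <= RP_WINDOW_MONTHS:
        if not patient.event_is_death or patient.death_due_to_mbc:
            return "rp"
    if patient.reimaged_at_3mo:
        return "no_rp"
    return "unassessable"


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        r = len(self.counts)
        if r < 2 or any(len(row) != len(self.counts[0]) for row in self.counts):
            raise ValueError("contingency table must be rectangular, at least 2x2")
        if len(self.counts[0]) < 2:
            raise ValueError("contingency table must have at least two columns")
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class BinomialCI:
    """Exact binomial point estimate with a central Clopper-Pearson interval."""

    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def proportion(self) -> float:
        return self.successes / self.trials

    def percent_interval(self) -> tuple[int, int]:
        """Bounds as whole percents for report formatting.

        Rounded half-up to one decimal and then half-up to an integer, i.e.
        as if read off a one-decimal report table (so 28.467 -> 28.5 -> 29).
        """

        def fmt(x: float) -> int:
            one_dp = math.floor(1000.0 * x + 0.5) / 10.0
            return int(math.floor(one_dp + 0.5))

        return fmt(self.lower), fmt(self.upper)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Exact central binomial confidence interval from Beta quantiles."""
    if trials < 1 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return BinomialCI(successes, trials, level, lower, upper)


def fisher_exact_2x2(table: ContingencyTable | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table.

    Returns ``(conditional odds ratio, p)``; a zero margin gives p = 1 and
    an undefined (NaN) odds ratio.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)


def _log_table_weight(cells: np.ndarray) -> np.ndarray:
    """log of prod 1/x! over cells (last axis pair-flattened)."""
    return -gammaln(cells + 1.0).sum(axis=-1)


@lru_cache(maxsize=100_000)
def _fisher_rx2_cached(rows: tuple[tuple[int, int], ...]) -> float:
    """Freeman-Halton p for an r x 2 table via vectorized enumeration.

    Conditional on all margins, P(table) is proportional to
    prod_i C(n_i, a_i) where n_i are row totals and a_i first-column cells.
    Enumerates the free cells a_1..a_{r-1} on a grid and sums probabilities
    <= the observed table's.
    """
    arr = np.asarray(rows, dtype=np.int64)
    n = arr.sum(axis=1)
    col1 = int(arr[:, 0].sum())

    def logc(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    # enumerate over free rows recursively but vectorize the innermost row
    r = len(n)
    log_obs = float(sum(logc(n[i], arr[i, 0]) for i in range(r)))

    total = 0.0
    extreme = 0.0

    def rec(i: int, remaining: int, log_w: float) -> None:
        nonlocal total, extreme
        if i == r - 2:
            # two rows left: vectorize a_i, a_{i+1} determined
            lo = max(0, remaining - n[i + 1])
            hi = min(n[i], remaining)
            if lo > hi:
                return
            a = np.arange(lo, hi + 1)
            lw = log_w + logc(n[i], a) + logc(n[i + 1], remaining - a)
            w = np.exp(lw)
            total += w.sum()
            extreme += w[lw <= log_obs + _REL_EPS].sum()
            return
        lo = max(0, remaining - int(n[i + 1:].sum()))
        hi = min(n[i], remaining)
        for a in range(lo, hi + 1):
            rec(i + 1, remaining - a, log_w + float(logc(n[i], a)))

    rec(0, col1, 0.0)
    return min(1.0, extreme / total)


def fisher_exact_rxc(table: ContingencyTable | Sequence[Sequence[int]],
                     max_tables: int = 5_000_000) -> float:
    """Freeman-Halton exact test for an r x c table (two-sided p).

    Enumerates every table with the observed margins; the p-value sums the
    multivariate-hypergeometric probabilities of tables no more probable
    than the observed one.  Raises if the enumeration would exceed
    ``max_tables`` (use a Monte-Carlo approximation for such tables).
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    r, c = arr.shape
    if c == 2:
        bound = int(np.prod(arr.sum(axis=1)[:-1] + 1))
        if bound > max_tables:
            raise ValueError(
                f"enumeration of ~{bound} tables exceeds max_tables={max_tables}; "
                "consider a Monte-Carlo p-value")
        return _fisher_rx2_cached(tuple(tuple(int(x) for x in row) for row in arr))
    if arr.shape[1] > arr.shape[0]:
        return fisher_exact_rxc(arr.T, max_tables=max_tables)

    row_tot = arr.sum(axis=1)
    col_tot = arr.sum(axis=0)
    bound = int(np.prod(row_tot[:-1] + 1) ** (c - 1))
    if bound > max_tables:
        raise ValueError(
            f"enumeration of up to ~{bound} tables exceeds max_tables={max_tables}; "
            "consider a Monte-Carlo p-value")

    log_obs = float(_log_table_weight(arr.reshape(-1)))
    total = 0.0
    extreme = 0.0

    def rec_rows(i: int, remaining_cols: np.ndarray, log_w: float) -> None:
        nonlocal total, extreme
        if i == r - 1:
            last = remaining_cols
            if np.any(last < 0) or last.sum() != row_tot[i]:
                return
            lw = log_w + float(_log_table_weight(last.astype(float)))
            w = math.exp(lw)
            total += w
            if lw <= log_obs + _REL_EPS:
                extreme += w
            return
        for row in _compositions(int(row_tot[i]), remaining_cols):
            rec_rows(i + 1, remaining_cols - row,
                     log_w + float(_log_table_weight(row.astype(float))))

    rec_rows(0, col_tot.copy(), 0.0)
    return min(1.0, extreme / total)


def _compositions(total: int, caps: np.ndarray):
    """All non-negative integer vectors summing to ``total`` with per-cell caps."""
    c = len(caps)

    def rec(i: int, remaining: int, acc: list[int]):
        if i == c - 1:
            if remaining <= caps[i]:
                yield np.array(acc + [remaining], dtype=np.int64)
            return
        lo = max(0, remaining - int(caps[i + 1:].sum()))
        hi = min(int(caps[i]), remaining)
        for v in range(lo, hi + 1):
            yield from rec(i + 1, remaining - v, acc + [v])

    yield from rec(0, total, [])


def trend_test_proportions(successes: Sequence[int], trials: Sequence[int],
                           scores: Sequence[float] | None = None) -> tuple[float, float]:
    """Cochran-Armitage trend test across ordered binomial categories.

    Returns the signed z statistic (positive for proportions increasing with
    the scores) and its two-sided normal p.  Default scores 0, 1, 2, ...
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if x.shape != n.shape or len(x) < 3:
        raise ValueError("at least three ordered categories required")
    if np.any(x < 0) or np.any(x > n) or np.any(n <= 0):
        raise ValueError("invalid success/trial counts")
    s = np.arange(len(x), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    N, X = n.sum(), x.sum()
    pbar = X / N
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    num = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(s**2 * n) - np.sum(s * n) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = num / math.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))
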