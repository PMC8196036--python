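"""CTC endocrine-therapy index (CTC-ETI) scoring.

The CTC-ETI is a composite score for ER-positive metastatic breast cancer
patients starting endocrine therapy.  A blood draw is split into four 7.5 ml
aliquots; circulating tumor cells (CTC) are enumerated in each.  The average
count maps to *enumeration points* (0/1/3/4 for <5, 5-10, 11-100, >100
CTC/7.5 ml whole blood).  When the average is >=5, the percent of CTC
staining positive (2+ or 3+) for each of four markers (ER, BCL2, HER2, Ki67)
maps to per-marker *Bio-Points* via three positivity categories (0%, 1-10%,
>10%); their sum is the *Bio-Score*.  The total,

    CTC-ETI = enumeration points + Bio-Score,

ranges 0-16 and is categorized low (0-3), intermediate (4-6), high (7-16).
Markers of endocrine sensitivity (ER, BCL2) earn fewer points the more
positive they are; resistance markers (HER2, Ki67) earn more.  The
per-marker point values live in a configurable :class:`PointTable`; the
shipped default satisfies every structural constraint of the published
algorithm (maximum total 16, ER weighted at least as heavily as any other
marker) but is an explicit stand-in, not a recovered supplementary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

MARKERS = ("ER", "BCL2", "HER2", "KI67")

#: markers whose positivity indicates endocrine sensitivity (points
#: non-increasing in positivity); the rest indicate resistance.
SENSITIVITY_MARKERS = ("ER", "BCL2")

MARKER_CATEGORIES = ("zero", "low", "high")

PANEL_STATUSES = ("ok", "qns", "preanalytic_error", "technical_failure")


@dataclass(frozen=True)
class AliquotPanel:
    """One blood draw: four aliquot CTC counts plus marker percentages.

    ``marker_pct`` maps marker name to percent of CTC staining positive
    (None = undetermined); it is only meaningful when the average count is
    >=5.  ``status`` other than ``ok`` marks the panel unusable (e.g. QNS,
    quantity not sufficient).
    """

    counts: tuple[int, int, int, int]
    marker_pct: Mapping[str, float | None] = field(default_factory=dict)
    status: str = "ok"

    def __post_init__(self) -> None:
        if len(self.counts) != 4:
            raise ValueError(f"exactly four aliquot counts required, got {len(self.counts)}")
        if any((not isinstance(c, (int,)) and not float(c).is_integer()) or c < 0 for c in self.counts):
            raise ValueError(f"aliquot counts must be non-negative integers: {self.counts}")
        if self.status not in PANEL_STATUSES:
            raise ValueError(f"unknown panel status {self.status!r}")
        for m, pct in self.marker_pct.items():
            if m not in MARKERS:
                raise ValueError(f"unknown marker {m!r}")
            if pct is not None and not (0.0 <= pct <= 100.0):
                raise ValueError(f"marker {m} percent {pct} outside [0, 100]")


@dataclass(frozen=True)
class PointTable:
    """Configurable mapping from categories to points.

    ``enum_cutpoints`` is an ordered sequence of ``(upper_bound, points)``
    applied to the rounded average count (upper bound inclusive; the last
    entry uses ``inf``).  ``marker_points`` maps marker -> positivity
    category -> points.  ``category_bounds`` maps score category to an
    inclusive ``(lo, hi)`` total-score range.
    """

    enum_cutpoints: tuple[tuple[float, int], ...] = ((4, 0), (10, 1), (100, 3), (math.inf, 4))
    marker_points: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "ER": {"zero": 4, "low": 2, "high": 0},
            "BCL2": {"zero": 2, "low": 1, "high": 0},
            "HER2": {"zero": 0, "low": 2, "high": 3},
            "KI67": {"zero": 0, "low": 1, "high": 3},
        }
    )
    category_bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"low": (0, 3), "intermediate": (4, 6), "high": (7, 16)}
    )

    @property
    def max_enum_points(self) -> int:
        return max(p for _, p in self.enum_cutpoints)

    @property
    def max_bio_score(self) -> int:
        return sum(max(pts.values()) for pts in self.marker_points.values())

    def to_dict(self) -> dict:
        return {
            "enum_cutpoints": [[b if math.isfinite(b) else None, p] for b, p in self.enum_cutpoints],
            "marker_points": {m: dict(v) for m, v in self.marker_points.items()},
            "category_bounds": {c: list(v) for c, v in self.category_bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PointTable":
        cuts = tuple(
            (math.inf if b is None else float(b), int(p)) for b, p in d["enum_cutpoints"]
        )
        return cls(
            enum_cutpoints=cuts,
            marker_points={m: dict(v) for m, v in d["marker_points"].items()},
            category_bounds={c: (int(v[0]), int(v[1])) for c, v in d["category_bounds"].items()},
        )


DEFAULT_POINT_TABLE = PointTable()


@dataclass(frozen=True)
class ETIResult:
    """Outcome of scoring one panel."""

    avg_ctc: float
    rounded_avg: int
    enum_points: int
    bio_points: Mapping[str, int]
    bio_score: int
    total: int
    category: str
    determined: bool
    elevated: bool
    status: str = "ok"


def average_ctc(counts: Sequence[int]) -> tuple[float, int]:
    """Average the four aliquot counts; round half-up to an integer.

    Returns ``(mean, rounded)``.  Half-up rounding (4.5 -> 5) is applied so
    the rounded value drives both the elevated/not-elevated call and the
    enumeration category.
    """
    if len(counts) != 4:
        raise ValueError(f"exactly four aliquot counts required, got {len(counts)}")
    if any(c < 0 for c in counts):
        raise ValueError(f"negative aliquot count in {tuple(counts)}")
    avg = sum(counts) / 4.0
    rounded = math.floor(avg + 0.5)
    return avg, rounded


def enumeration_points(rounded_avg: int, table: PointTable = DEFAULT_POINT_TABLE) -> int:
    """Map the rounded average CTC count to enumeration points."""
    if rounded_avg < 0:
        raise ValueError("rounded average must be non-negative")
    for upper, points in table.enum_cutpoints:
        if rounded_avg <= upper:
            return points
    raise ValueError("enumeration cutpoints do not cover the count")  # pragma: no cover


def marker_category(pct: float) -> str:
    """Positivity category for a marker percentage: zero (0%), low (0,10], high (>10)."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"marker percent {pct} outside [0, 100]")
    if pct == 0:
        return "zero"
    if pct <= 10:
        return "low"
    return "high"


def _category_for_total(total: int, table: PointTable) -> str:
    for cat, (lo, hi) in table.category_bounds.items():
        if lo <= total <= hi:
            return cat
    raise ValueError(f"total {total} outside every category bound")


def compute_eti(panel: AliquotPanel, table: PointTable = DEFAULT_POINT_TABLE) -> ETIResult:
    """Score one panel.

    A panel whose status is not ``ok``, or with >=5 average CTC but any
    undetermined marker, yields an undetermined result (``determined``
    False) — mirroring the protocol notion of an unsuccessful CTC-ETI
    determination.  With a rounded average below 5 the score is low with a
    Bio-Score of 0 regardless of the marker fields.
    """
    avg, rounded = average_ctc(panel.counts)
    elevated = rounded >= 5

    if panel.status != "ok":
        return ETIResult(avg, rounded, 0, {}, 0, 0, "low", determined=False,
                         elevated=elevated, status=panel.status)

    if not elevated:
        enum_pts = enumeration_points(rounded, table)
        return ETIResult(avg, rounded, enum_pts, {}, 0, enum_pts,
                         _category_for_total(enum_pts, table), determined=True,
                         elevated=False)

    pcts = {m: panel.marker_pct.get(m) for m in MARKERS}
    if any(v is None for v in pcts.values()):
        return ETIResult(avg, rounded, enumeration_points(rounded, table), {}, 0, 0,
                         "low", determined=False, elevated=True)

    enum_pts = enumeration_points(rounded, table)
    bio_points = {m: table.marker_points[m][marker_category(pcts[m])] for m in MARKERS}
    bio_score = sum(bio_points.values())
    total = enum_pts + bio_score
    return ETIResult(avg, rounded, enum_pts, bio_points, bio_score, total,
                     _category_for_total(total, table), determined=True, elevated=True)


def validate_point_table(table: PointTable) -> list[str]:
    """Check a point table against the algorithm's structural constraints.

    Returns a list of human-readable violations (empty = valid): enumeration
    points non-decreasing in count; sensitivity markers (ER, BCL2)
    non-increasing and resistance markers (HER2, Ki67) non-decreasing in
    positivity; maxima summing to 16; ER weighted at least as heavily as
    every other marker; category bounds tiling 0..16.
    """
    violations: list[str] = []

    bounds = [b for b, _ in table.enum_cutpoints]
    if sorted(bounds) != list(bounds) or len(set(bounds)) != len(bounds):
        violations.append("enumeration cutpoint bounds must be strictly increasing")
    pts = [p for _, p in table.enum_cutpoints]
    if any(b > a for a, b in zip(pts[1:], pts)):
        violations.append("enumeration points must be non-decreasing in CTC count")

    for m in MARKERS:
        if m not in table.marker_points:
            violations.append(f"marker {m} missing from marker_points")
            continue
        seq = [table.marker_points[m][c] for c in MARKER_CATEGORIES]
        if m in SENSITIVITY_MARKERS:
            if not all(a >= b for a, b in zip(seq, seq[1:])):
                violations.append(f"{m} points must be non-increasing in positivity")
        else:
            if not all(a <= b for a, b in zip(seq, seq[1:])):
                violations.append(f"{m} points must be non-decreasing in positivity")

    if all(m in table.marker_points for m in MARKERS):
        max_total = table.max_enum_points + table.max_bio_score
        if max_total != 16:
            violations.append(f"maximum total score is {max_total}, expected 16")
        er_max = max(table.marker_points["ER"].values())
        for m in MARKERS[1:]:
            if er_max < max(table.marker_points[m].values()):
                violations.append(f"ER must be weighted at least as heavily as {m} (overweighting)")

    covered = sorted(
        t for lo, hi in table.category_bounds.values() for t in range(lo, hi + 1)
    )
    if covered != list(range(17)):
        violations.append("category bounds must tile the totals 0..16 exactly once")

    return violations


def enumerate_score_combinations(table: PointTable = DEFAULT_POINT_TABLE):
    """Yield (enum_points, marker categories, total) over every combination.

    Exhausts the 4 enumeration categories crossed with 3^4 marker-positivity
    categories — the full discrete domain of the score when CTC are elevated.
    """
    from itertools import product

    enum_levels = [p for _, p in table.enum_cutpoints]
    for enum_pts, cats in product(enum_levels, product(MARKER_CATEGORIES, repeat=len(MARKERS))):
        bio = sum(table.marker_points[m][c] for m, c in zip(MARKERS, cats))
        yield enum_pts, dict(zip(MARKERS, cats)), enum_pts + bio


def max_total_score(table: PointTable = DEFAULT_POINT_TABLE) -> int:
    """Maximum attainable total score, by exhaustive enumeration."""
    return max(total for _, _, total in enumerate_score_combinations(table))
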