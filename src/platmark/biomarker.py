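"""Differential-marker screening and OR-rule composite classifier search.

The discovery procedure on a labelled cohort (drug-sensitive vs
drug-resistant) is:

1. *Screen*: for every binary marker, form the 2x2 table of group x
   positivity and keep markers with a two-sided Fisher exact p below alpha.
2. *Evaluate*: a classifier is a set of markers under the any-positive (OR)
   rule -- a patient tests positive when at least one member marker is
   present.  Performance is the confusion table against the clinical labels,
   with sensitivity TP/(TP+FN), specificity TN/(TN+FP), and the Fisher exact
   p of the resulting table.
3. *Search*: exhaustively enumerate all marker subsets up to ``max_size``
   (default 3) and rank by sensitivity, then specificity, then p, then
   smaller panels, then lexicographic marker names.

The OR rule maximizes sensitivity at the cost of specificity, the preferred
trade-off for a treatment-selection screen: false positives can be cleared by
follow-up testing, false negatives are simply missed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .cohort_io import Marker, MarkerMatrix, Patient
from .stats import Table2x2, fisher_exact_two_sided

__all__ = [
    "CombinationRule",
    "ConfusionCounts",
    "ClassifierSpec",
    "ScreenResult",
    "screen_markers",
    "evaluate_classifier",
    "search_combinations",
]

#: refuse enumeration beyond this many subsets; pre-screen candidates instead
MAX_COMBINATIONS = 1_000_000


class CombinationRule(str, enum.Enum):
    ANY_POSITIVE = "any_positive"  # the supported reproduction rule (union)
    ALL_POSITIVE = "all_positive"  # intersection; exploratory only


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int
    p_value: float

    @property
    def sensitivity(self) -> float:
        """TP/(TP+FN); NaN when the positive class is empty."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        """TN/(TN+FP); NaN when the negative class is empty."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan


@dataclass(frozen=True)
class ClassifierSpec:
    markers: frozenset  # of Marker
    rule: CombinationRule = CombinationRule.ANY_POSITIVE
    positive_class: str = "resistant"

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("classifier needs at least one marker")
        if self.positive_class not in ("resistant", "sensitive"):
            raise ValueError(f"unknown positive class {self.positive_class!r}")

    @property
    def sorted_markers(self) -> tuple:
        return tuple(sorted(self.markers, key=str))

    def __str__(self) -> str:
        return "/".join(str(m) for m in self.sorted_markers)


@dataclass(frozen=True)
class ScreenResult:
    marker: Marker
    count_resistant: int
    count_sensitive: int
    p_value: float
    direction: str  # "higher_in_resistant" | "higher_in_sensitive"


def _group_ids(cohort: Sequence[Patient]) -> tuple:
    resistant = [p.patient_id for p in cohort if p.group == "resistant"]
    sensitive = [p.patient_id for p in cohort if p.group == "sensitive"]
    return resistant, sensitive


def screen_markers(
    matrix: MarkerMatrix,
    cohort: Sequence[Patient],
    alpha: float = 0.05,
) -> list:
    """Markers whose positivity differs between groups at Fisher p < alpha.

    Output sorted by (p, marker label).  Requires both groups non-empty.
    """
    resistant, sensitive = _group_ids(cohort)
    if not resistant or not sensitive:
        raise ValueError("both response groups must be non-empty")
    missing = set(matrix.patients) - {p.patient_id for p in cohort}
    if missing:
        raise ValueError(f"matrix patients absent from cohort: {sorted(missing)}")
    results = []
    for marker in matrix.markers:
        pos = matrix.positives(marker)
        a = len(pos & set(resistant))
        c = len(pos & set(sensitive))
        table = Table2x2(a, len(resistant) - a, c, len(sensitive) - c)
        p = fisher_exact_two_sided(table).p_value
        if p < alpha:
            rate_r = a / len(resistant)
            rate_s = c / len(sensitive)
            results.append(
                ScreenResult(
                    marker=marker,
                    count_resistant=a,
                    count_sensitive=c,
                    p_value=p,
                    direction=(
                        "higher_in_resistant" if rate_r > rate_s else "higher_in_sensitive"
                    ),
                )
            )
    results.sort(key=lambda r: (r.p_value, str(r.marker)))
    return results


def evaluate_classifier(
    matrix: MarkerMatrix,
    spec: ClassifierSpec,
    cohort: Sequence[Patient],
) -> ConfusionCounts:
    """Confusion counts of a marker-set classifier against the group labels."""
    for marker in spec.markers:
        if str(marker) not in matrix.df.columns:
            raise KeyError(f"unknown marker {marker} in classifier {spec}")
    columns = [matrix.column(m) for m in spec.sorted_markers]
    if spec.rule is CombinationRule.ANY_POSITIVE:
        called = set()
        for col in columns:
            called |= set(col.index[col == 1])
    else:  # ALL_POSITIVE
        called = set(matrix.patients)
        for col in columns:
            called &= set(col.index[col == 1])
    resistant, sensitive = _group_ids(cohort)
    pos_ids = resistant if spec.positive_class == "resistant" else sensitive
    neg_ids = sensitive if spec.positive_class == "resistant" else resistant
    tp = sum(1 for pid in pos_ids if pid in called)
    fp = sum(1 for pid in neg_ids if pid in called)
    fn = len(pos_ids) - tp
    tn = len(neg_ids) - fp
    p = fisher_exact_two_sided(Table2x2(tp, fn, fp, tn)).p_value
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn, p_value=p)


def _rank_key(item: tuple) -> tuple:
    spec, counts = item
    sens = counts.sensitivity
    spec_ = counts.specificity
    return (
        -(sens if not math.isnan(sens) else -1.0),
        -(spec_ if not math.isnan(spec_) else -1.0),
        counts.p_value,
        len(spec.markers),
        tuple(str(m) for m in spec.sorted_markers),
    )


def search_combinations(
    matrix: MarkerMatrix,
    candidates: Sequence[Marker],
    cohort: Sequence[Patient],
    positive_class: str = "resistant",
    max_size: int = 3,
    rule: CombinationRule = CombinationRule.ANY_POSITIVE,
) -> list:
    """Exhaustively evaluate all candidate subsets of size 1..max_size.

    Returns the complete ranked list of (ClassifierSpec, ConfusionCounts),
    best first; deterministic in candidate order.
    """
    candidates = sorted(set(candidates), key=str)
    if not (1 <= max_size <= len(candidates)):
        raise ValueError(
            f"max_size must be in 1..{len(candidates)} (candidate count), got {max_size}"
        )
    total = sum(math.comb(len(candidates), k) for k in range(1, max_size + 1))
    if total > MAX_COMBINATIONS:
        raise ValueError(
            f"{total} combinations exceed the {MAX_COMBINATIONS} guard; "
            "pre-screen the candidate list (e.g. with screen_markers)"
        )
    ranked = []
    for k in range(1, max_size + 1):
        for subset in combinations(candidates, k):
            spec = ClassifierSpec(
                markers=frozenset(subset), rule=rule, positive_class=positive_class
            )
            ranked.append((spec, evaluate_classifier(matrix, spec, cohort)))
    ranked.sort(key=_rank_key)
    return ranked
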