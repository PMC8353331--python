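"""Shared table rendering: percentages to one decimal, p-values to three.

All user-facing tables (screen results, classifier tables, metric
comparisons) go through these formatters so the output style is uniform:
``57.1%`` for rates, ``0.019`` for p-values (p below 0.0005 prints as
``0.000``), ``NA`` for undefined quantities.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .biomarker import ClassifierSpec, ConfusionCounts, ScreenResult

__all__ = ["fmt_pct", "fmt_p", "screen_table", "classifier_table"]


def fmt_pct(fraction: float) -> str:
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return "NA"
    return f"{100.0 * fraction:.1f}%"


def fmt_p(p: float) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    return f"{p:.3f}"


def screen_table(results: Sequence[ScreenResult], n_resistant: int, n_sensitive: int) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "marker": str(r.marker),
                "gene": r.marker.gene,
                "event_class": r.marker.event_class.value,
                "n_resistant": r.count_resistant,
                "rate_resistant": fmt_pct(r.count_resistant / n_resistant),
                "n_sensitive": r.count_sensitive,
                "rate_sensitive": fmt_pct(r.count_sensitive / n_sensitive),
                "direction": r.direction,
                "p_value": fmt_p(r.p_value),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "gene", "event_class", "n_resistant", "rate_resistant",
            "n_sensitive", "rate_sensitive", "direction", "p_value",
        ],
    )


def classifier_table(ranked: Sequence[tuple]) -> pd.DataFrame:
    """Render (ClassifierSpec, ConfusionCounts) pairs in the classic
    No./Genes/TP/FN/FP/TN/Sensitivity/Specificity/p layout."""
    rows = []
    for i, (spec, counts) in enumerate(ranked, start=1):
        assert isinstance(spec, ClassifierSpec) and isinstance(counts, ConfusionCounts)
        rows.append(
            {
                "No.": i,
                "Genes": str(spec),
                "TP": counts.tp,
                "FN": counts.fn,
                "FP": counts.fp,
                "TN": counts.tn,
                "Sensitivity": fmt_pct(counts.sensitivity),
                "Specificity": fmt_pct(counts.specificity),
                "p value": fmt_p(counts.p_value),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["No.", "Genes", "TP", "FN", "FP", "TN", "Sensitivity", "Specificity", "p value"],
    )
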