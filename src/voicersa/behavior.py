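"""Forced-choice behavior: confusion tables and unbiased hit rates.

The unbiased hit rate for a category corrects raw accuracy for response
bias:

    Hu = (hits / trials presented) * (hits / responses given to the category)

Timeouts are tracked separately and excluded from both the hit count and
the response denominator (a timeout is neither a hit nor a response to any
category).  Hu scores are variance-stabilized with the arcsine transform
arcsin(sqrt(Hu)) before model fitting; the module exports a per-subject,
per-condition Hu table ready for any mixed-model tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionTable",
    "HuScore",
    "confusion_table",
    "unbiased_hit_rate",
    "arcsine_transform",
    "hu_table",
]


@dataclass
class ConfusionTable:
    """Stimulus-category x response-category trial counts plus timeouts."""

    counts: pd.DataFrame  # index: stimulus category; columns: response category
    timeouts: pd.Series

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any() or (self.timeouts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def categories(self) -> list:
        return list(self.counts.index)

    def trials_presented(self, category) -> int:
        """Responded + timed-out trials with this stimulus category."""
        return int(self.counts.loc[category].sum() + self.timeouts[category])

    def responses_given(self, category) -> int:
        """Trials (any stimulus) answered with this response category."""
        return int(self.counts[category].sum())

    def hits(self, category) -> int:
        return int(self.counts.loc[category, category])

    def percentages(self) -> pd.DataFrame:
        denom = self.counts.sum(axis=1) + self.timeouts
        return 100.0 * self.counts.div(denom, axis=0)


def confusion_table(trials: pd.DataFrame, categories=None) -> ConfusionTable:
    """Tabulate trial records into a confusion table.

    ``trials`` needs columns ``stimulus_category``, ``response_category``
    (missing/None on timeout) and optionally ``timeout``.  Row totals equal
    the trials presented per category; trial order is irrelevant.
    """
    frame = trials.copy()
    if "timeout" not in frame:
        frame["timeout"] = frame["response_category"].isna()
    cats = list(categories) if categories is not None else sorted(
        set(frame["stimulus_category"].dropna())
    )
    unknown = set(frame["stimulus_category"].dropna()) - set(cats)
    unknown |= set(frame.loc[~frame["timeout"], "response_category"].dropna()) - set(cats)
    if unknown:
        raise ValueError(f"unknown category labels: {sorted(unknown)}")

    counts = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    timeouts = pd.Series(0, index=cats, dtype=int)
    for _, row in frame.iterrows():
        s = row["stimulus_category"]
        if row["timeout"] or pd.isna(row["response_category"]):
            timeouts[s] += 1
        else:
            counts.loc[s, row["response_category"]] += 1
    return ConfusionTable(counts, timeouts)


@dataclass
class HuScore:
    """Unbiased hit rate for one category, with its ingredients."""

    category: str
    hu: float
    arcsine: float
    hits: int
    n_trials: int
    n_responses: int


def unbiased_hit_rate(table: ConfusionTable, category) -> HuScore:
    """Hu = (hits/trials presented) x (hits/responses to the category).

    Hu is 0 whenever there are no hits (including when the category was
    never chosen, where the precision factor is undefined but the hit count
    is necessarily 0 too).
    """
    n_trials = table.trials_presented(category)
    if n_trials == 0:
        raise ValueError(f"no trials presented for category {category!r}")
    hits = table.hits(category)
    n_resp = table.responses_given(category)
    hu = 0.0 if n_resp == 0 or hits == 0 else (hits / n_trials) * (hits / n_resp)
    return HuScore(str(category), hu, arcsine_transform(hu), hits, n_trials, n_resp)


def arcsine_transform(hu: float) -> float:
    """Variance-stabilizing arcsin(sqrt(x)) for a proportion in [0, 1]."""
    if not 0.0 <= hu <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    return math.asin(math.sqrt(hu))


def hu_table(trials: pd.DataFrame, categories=None,
             group_cols=("subject",)) -> pd.DataFrame:
    """Per-group (e.g. per-subject), per-category Hu table for export.

    Counts are pooled across runs within each group before the ratios are
    taken.  Columns: group keys, ``condition``, ``hu``, ``hu_arcsine``,
    ``hits``, ``n_trials``, ``n_responses``.
    """
    group_cols = [c for c in group_cols if c in trials.columns]
    rows = []
    grouped = trials.groupby(group_cols) if group_cols else [((), trials)]
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        table = confusion_table(sub, categories)
        for cat in table.categories:
            if table.trials_presented(cat) == 0:
                continue
            score = unbiased_hit_rate(table, cat)
            rows.append({**dict(zip(group_cols, key)), "condition": cat,
                         "hu": score.hu, "hu_arcsine": score.arcsine,
                         "hits": score.hits, "n_trials": score.n_trials,
                         "n_responses": score.n_responses})
    return pd.DataFrame(rows)
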