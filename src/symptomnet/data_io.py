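"""Item-response ingestion, dichotomization, and descriptive statistics.

Questionnaire items (PHQ-9 style) are ordinal with scores 0-3.  The
network pipeline operates on presence/absence: a score of 0 codes the
symptom as absent, any score of 1-3 as present.  This module reads the
subjects-by-items table from delimited text, applies that recoding, and
computes the group-wise descriptives (item means, SDs, absence/presence
percentages, total-score summaries, Mann-Whitney U, Cohen's d) reported
alongside such analyses, plus Cronbach's alpha for scale reliability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ItemResponseTable",
    "BinaryMatrix",
    "read_item_table",
    "dichotomize",
    "descriptive_stats",
    "mann_whitney_u",
    "cohens_d",
    "cronbach_alpha",
]

logger = logging.getLogger(__name__)

VALID_SCORES = (0, 1, 2, 3)


@dataclass(frozen=True)
class ItemResponseTable:
    """Ordinal questionnaire responses with a two-level group label.

    ``scores`` is an ``(n_subjects, n_items)`` integer matrix with
    entries in {0, 1, 2, 3}; ``group`` assigns each subject to one of at
    most two levels.
    """

    scores: np.ndarray
    items: tuple[str, ...]
    group: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        if not np.isin(scores, VALID_SCORES).all():
            bad = np.argwhere(~np.isin(scores, VALID_SCORES))[0]
            raise ValueError(
                f"score out of range {VALID_SCORES} at row {bad[0]}, "
                f"item column {bad[1]}"
            )
        if len(set(self.items)) != len(self.items):
            raise ValueError("item labels must be unique")
        if scores.shape[1] != len(self.items):
            raise ValueError("number of item labels must match columns")
        group = np.asarray(self.group)
        if group.shape != (scores.shape[0],):
            raise ValueError("group must have one label per subject")
        if len(np.unique(group)) > 2:
            raise ValueError("group must have at most two levels")
        object.__setattr__(self, "scores", scores.astype(np.int8))
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "group", group)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def group_levels(self) -> tuple:
        return tuple(pd.unique(self.group))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(self.items))
        df["group"] = self.group
        return df


@dataclass(frozen=True)
class BinaryMatrix:
    """Presence/absence recoding of an item-response table."""

    values: np.ndarray
    items: tuple[str, ...]
    group: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        if values.shape[1] != len(self.items):
            raise ValueError("number of item labels must match columns")
        group = np.asarray(self.group)
        if group.shape != (values.shape[0],):
            raise ValueError("group must have one label per subject")
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "group", group)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def group_levels(self) -> tuple:
        return tuple(pd.unique(self.group))

    def subset(self, mask: np.ndarray) -> "BinaryMatrix":
        return BinaryMatrix(self.values[mask], self.items, self.group[mask])

    def by_group(self) -> dict:
        return {
            lvl: self.values[self.group == lvl] for lvl in self.group_levels
        }


def read_item_table(
    path: str | Path,
    item_columns: Sequence[str],
    group_column: str,
    sep: str | None = None,
) -> ItemResponseTable:
    """Read a delimited subjects-by-items file into a validated table.

    Rows with any missing item score or group label are dropped; the
    count is logged and recorded on the returned table.  The delimiter
    is sniffed from the extension (``.tsv`` -> tab) unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in [*item_columns, group_column] if c not in df.columns]
    if missing_cols:
        raise KeyError(
            f"columns not found in {path.name}: {missing_cols}; "
            f"available: {list(df.columns)}"
        )
    sub = df[[*item_columns, group_column]]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d rows with missing entries", n_dropped)
    sub = sub.loc[complete]
    scores = sub[list(item_columns)].to_numpy()
    if not np.issubdtype(scores.dtype, np.number):
        raise ValueError("item columns must be numeric")
    if np.any(scores != scores.astype(int)):
        raise ValueError("item scores must be integers")
    return ItemResponseTable(
        scores=scores.astype(int),
        items=tuple(item_columns),
        group=sub[group_column].to_numpy(),
        n_dropped=n_dropped,
    )


def write_item_table(table: ItemResponseTable, path: str | Path) -> None:
    """Write a table as CSV (one row per subject, `group` column last)."""
    table.to_frame().to_csv(path, index=False)


def dichotomize(table: ItemResponseTable | BinaryMatrix) -> BinaryMatrix:
    """Recode scores to symptom presence: 0 -> absent, 1-3 -> present.

    Idempotent: applying it to an already-binary matrix returns an
    equal matrix.
    """
    if isinstance(table, BinaryMatrix):
        return BinaryMatrix(table.values.copy(), table.items, table.group)
    return BinaryMatrix(
        values=(table.scores > 0).astype(np.int8),
        items=table.items,
        group=table.group,
    )


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided, normal approximation).

    Returns the U statistic of the *first* sample (number of pairs where
    an `a` observation outranks a `b` observation, ties counting half)
    and the two-sided p-value with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled, (n-1)-weighted standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def cronbach_alpha(matrix: BinaryMatrix | ItemResponseTable) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item var) / total var)."""
    if isinstance(matrix, ItemResponseTable):
        X = matrix.scores.astype(float)
    else:
        X = matrix.values.astype(float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero")
    item_vars = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def descriptive_stats(matrix: BinaryMatrix) -> dict:
    """Group-wise item and total-score descriptives.

    Returns a dict with:

    ``per_item``
        DataFrame indexed by (group, item) with columns mean, sd,
        absence_pct, presence_pct, all on the binary scale.
    ``per_group``
        DataFrame indexed by group with total-score mean and sd.
    ``between``
        Mann-Whitney U (first group level's statistic), its p-value,
        and Cohen's d on total scores — present only with two groups.
    """
    levels = matrix.group_levels
    rows = []
    totals = {}
    for lvl in levels:
        X = matrix.values[matrix.group == lvl].astype(float)
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        for j, item in enumerate(matrix.items):
            rows.append(
                {
                    "group": lvl,
                    "item": item,
                    "mean": means[j],
                    "sd": sds[j],
                    "absence_pct": 100.0 * (1.0 - means[j]),
                    "presence_pct": 100.0 * means[j],
                }
            )
        totals[lvl] = X.sum(axis=1)
    per_item = pd.DataFrame(rows).set_index(["group", "item"])
    per_group = pd.DataFrame(
        {
            "total_mean": {lvl: t.mean() for lvl, t in totals.items()},
            "total_sd": {lvl: t.std(ddof=1) for lvl, t in totals.items()},
            "n": {lvl: len(t) for lvl, t in totals.items()},
        }
    )
    result = {"per_item": per_item, "per_group": per_group}
    if len(levels) == 2:
        t_a, t_b = totals[levels[0]], totals[levels[1]]
        u, p = mann_whitney_u(t_a, t_b)
        result["between"] = {
            "mann_whitney_u": u,
            "p_value": p,
            "cohens_d": cohens_d(t_a, t_b),
            "reference_group": levels[0],
        }
    else:
        logger.warning(
            "single group level: between-group statistics not computed"
        )
    return result
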