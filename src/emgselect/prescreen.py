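"""ANOVA prescreening of predictors before wrapper selection.

Each (channel, predictor) column gets a one-way ANOVA across movement
classes; a predictor whose class means are indistinguishable on most of its
channels (median p across channels above alpha) is dropped on *all*
channels, so the eliminated column count is always a multiple of the channel
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .features import FeatureMatrix, select_columns


@dataclass
class PrescreenResult:
    """Per-column p-values plus the whole-predictor elimination verdicts."""

    table: pd.DataFrame  # columns: channel, predictor, p, eliminated
    eliminated_predictors: list[str]
    alpha: float

    def column_mask(self, columns: pd.MultiIndex) -> np.ndarray:
        """Binary keep-mask aligned to a (channel, predictor) column index."""
        keep = ~columns.get_level_values("predictor").isin(self.eliminated_predictors)
        return keep.astype(int)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def anova_prescreen(m: FeatureMatrix, alpha: float = 0.05) -> PrescreenResult:
    """One-way ANOVA of every column across movement classes.

    Requires >= 2 classes with >= 2 rows each.  A predictor is eliminated
    when its median p-value across channels exceeds ``alpha``.
    """
    classes = m.classes
    uniq, counts = np.unique(classes, return_counts=True)
    if uniq.size < 2:
        raise DataError("ANOVA prescreen needs at least 2 classes")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise DataError(f"classes with fewer than 2 rows: {small}")
    groups = [m.values[classes == c] for c in uniq]
    # f_oneway vectorizes across columns
    _, pvals = stats.f_oneway(*groups, axis=0)
    pvals = np.atleast_1d(pvals)

    table = pd.DataFrame(
        {
            "channel": m.columns.get_level_values("channel"),
            "predictor": m.columns.get_level_values("predictor"),
            "p": pvals,
        }
    )
    med = table.groupby("predictor", sort=False)["p"].median()
    eliminated = med.index[med > alpha].tolist()
    table["eliminated"] = table["predictor"].isin(eliminated)
    return PrescreenResult(table=table, eliminated_predictors=eliminated, alpha=alpha)


def apply_prescreen(m: FeatureMatrix, result: PrescreenResult) -> FeatureMatrix:
    """Drop every channel-column of each eliminated predictor."""
    if not result.eliminated_predictors:
        return m
    return select_columns(m, result.column_mask(m.columns))
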