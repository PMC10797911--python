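"""Kaplan-Meier estimation and log-rank stratification by expressor status.

Cases are split into double-expressor (DE) and non-DE groups — positive for
both c-MYC and BCL2 at clinical thresholds — and their survival curves are
compared with the standard two-group log-rank test (chi-square, 1 df,
two-sided). A threshold grid sweeps both markers' cut-points over the
deciles and reports -log10(p) per cell; cells where either group is empty
are masked. The conventional significance mark is -log10(p) > 1.3, i.e.
p < 0.05. No multiple-testing correction is applied across grid cells: the
grid is a descriptive sweep, and its cells are strongly correlated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .stats import double_expressor

SIGNIFICANCE_NEG_LOG10_P = 1.3  # p < 0.05


def km_logrank(records: pd.DataFrame) -> tuple[float, float, dict]:
    """Two-group log-rank test plus fitted Kaplan-Meier curves.

    ``records`` needs columns time (>0), event (0/1) and group (two
    levels). Returns (chi_square, p_value, curves) where curves maps each
    group label to its fitted :class:`KaplanMeierFitter` (censoring marks
    available through lifelines' plotting).
    """
    for col in ("time", "event", "group"):
        if col not in records:
            raise ValueError(f"records missing column {col!r}")
    if (records["time"] <= 0).any():
        raise ValueError("times must be strictly positive")
    groups = records["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {list(groups)}")
    g0 = records[records["group"] == groups[0]]
    g1 = records[records["group"] == groups[1]]
    res = logrank_test(
        g0["time"], g1["time"], event_observed_A=g0["event"],
        event_observed_B=g1["event"],
    )
    curves = {}
    for label, g in ((groups[0], g0), (groups[1], g1)):
        kmf = KaplanMeierFitter(label=str(label))
        kmf.fit(g["time"], event_observed=g["event"])
        curves[label] = kmf
    return float(res.test_statistic), float(res.p_value), curves


@dataclasses.dataclass
class ThresholdGridResult:
    myc_thresholds: np.ndarray
    bcl2_thresholds: np.ndarray
    neg_log10_p: np.ndarray  # rows = myc, cols = bcl2; nan where masked
    mask: np.ndarray  # True where undefined (an empty group)

    def cell(self, t_myc: float, t_bcl2: float) -> float:
        i = int(np.flatnonzero(self.myc_thresholds == t_myc)[0])
        j = int(np.flatnonzero(self.bcl2_thresholds == t_bcl2)[0])
        return float(self.neg_log10_p[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.neg_log10_p,
            index=pd.Index(self.myc_thresholds, name="myc_threshold"),
            columns=pd.Index(self.bcl2_thresholds, name="bcl2_threshold"),
        )


def threshold_grid(
    scores: pd.DataFrame,
    records: pd.DataFrame,
    myc_grid=tuple(range(0, 100, 10)),
    bcl2_grid=tuple(range(0, 100, 10)),
) -> ThresholdGridResult:
    """-log10 log-rank p over a grid of double-expressor threshold pairs.

    ``scores`` holds one row per case with columns case_id, myc_score,
    bcl2_score; ``records`` holds case_id, time, event. Every case must
    have both. Cells where either the DE or non-DE group is empty are
    masked (nan), not zero.
    """
    myc_grid = np.asarray(myc_grid, dtype=float)
    bcl2_grid = np.asarray(bcl2_grid, dtype=float)
    if myc_grid.size == 0 or bcl2_grid.size == 0:
        raise ValueError("threshold grids must be non-empty")
    merged = records.merge(scores, on="case_id", how="inner", validate="1:1")
    if len(merged) != len(records):
        raise ValueError("every survival record needs both marker scores")
    neg_log10 = np.full((myc_grid.size, bcl2_grid.size), np.nan)
    mask = np.ones_like(neg_log10, dtype=bool)
    for i, tm in enumerate(myc_grid):
        for j, tb in enumerate(bcl2_grid):
            de = np.array(
                [
                    double_expressor(m, b, thresholds=(tm, tb))
                    for m, b in zip(merged["myc_score"], merged["bcl2_score"])
                ]
            )
            if de.all() or not de.any():
                continue
            rec = pd.DataFrame(
                {
                    "time": merged["time"],
                    "event": merged["event"],
                    "group": np.where(de, "DE", "non-DE"),
                }
            )
            _, p, _ = km_logrank(rec)
            neg_log10[i, j] = -np.log10(p)
            mask[i, j] = False
    return ThresholdGridResult(
        myc_thresholds=myc_grid,
        bcl2_thresholds=bcl2_grid,
        neg_log10_p=neg_log10,
        mask=mask,
    )
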