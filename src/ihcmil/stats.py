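"""Agreement and classification statistics for validating model scores.

Paired reference (pathologist / ground-truth) and model scores per case per
marker are compared with: Pearson correlation with a 1000-fold percentile
bootstrap CI, ICC(2,1) (two-way random effects, absolute agreement, single
measurement), sensitivity/specificity at clinical positivity thresholds
(c-MYC > 40%, BCL2 > 50%, strict inequality), double-expressor calls, and
Bland-Altman limits of agreement (mean difference ± 1.96 sample standard
deviations).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

CLINICAL_THRESHOLDS = {"c-MYC": 40.0, "BCL2": 50.0}


@dataclasses.dataclass
class BootstrapCI:
    low: float
    high: float


@dataclasses.dataclass
class AgreementReport:
    pearson_r: float
    pearson_ci: BootstrapCI
    icc: float
    icc_p: float
    sensitivity: float
    sensitivity_ci: BootstrapCI
    specificity: float
    specificity_ci: BootstrapCI
    bland_altman: tuple[float, float, float]  # mean_diff, lower_loa, upper_loa

    def to_dict(self) -> dict:
        md, lo, hi = self.bland_altman
        return {
            "pearson_r": self.pearson_r,
            "pearson_ci": [self.pearson_ci.low, self.pearson_ci.high],
            "icc": self.icc,
            "icc_p": self.icc_p,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": [self.sensitivity_ci.low, self.sensitivity_ci.high],
            "specificity": self.specificity,
            "specificity_ci": [self.specificity_ci.low, self.specificity_ci.high],
            "bland_altman": {"mean_diff": md, "loa_low": lo, "loa_high": hi},
        }


def pearson_with_ci(x, y, n_boot: int = 1000, seed: int = 0):
    """Sample Pearson r with a percentile bootstrap 95% CI.

    Resamples cases with replacement ``n_boot`` times; resamples where
    either variable is constant (r undefined) are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        boots.append(sps.pearsonr(xb, yb).statistic)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return r, float(lo), float(hi)


def icc_two_way_absolute(x, y) -> tuple[float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    The two score sources (reference, model) are the raters; returns the
    ICC and the p-value of its F test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(np.r_[x, y]) == 0:
        raise ValueError("degenerate variance: all scores identical")
    df = pd.DataFrame(
        {
            "targets": np.r_[np.arange(n), np.arange(n)],
            "raters": ["ref"] * n + ["model"] * n,
            "scores": np.r_[x, y],
        }
    )
    table = pg.intraclass_corr(
        df, targets="targets", raters="raters", ratings="scores"
    ).set_index("Type")
    # pingouin labels the two-way random absolute-agreement single-rater
    # form "ICC(A,1)" (older releases used "ICC2")
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    return float(row["ICC"]), float(row["pval"])


def classify_marker(score: float, marker: str, thresholds=None) -> bool:
    """Clinical positivity call: strictly above 40% (c-MYC) or 50% (BCL2)."""
    thresholds = thresholds or CLINICAL_THRESHOLDS
    if marker not in thresholds:
        raise ValueError(f"unknown marker {marker!r}")
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score must be in [0, 100], got {score}")
    return score > thresholds[marker]


def double_expressor(
    myc_score: float, bcl2_score: float, thresholds: tuple[float, float] = (40.0, 50.0)
) -> bool:
    """Double-expressor call: positive for BOTH markers at the thresholds.

    Thresholds are parameterized so the survival threshold grid can sweep
    them; the clinical default is (>40, >50).
    """
    if myc_score is None or bcl2_score is None:
        raise ValueError("both marker scores are required")
    t_myc, t_bcl2 = thresholds
    return (myc_score > t_myc) and (bcl2_score > t_bcl2)


def sens_spec(pred, truth, n_boot: int = 1000, seed: int = 0):
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with bootstrap CIs.

    Requires at least one true positive and one true negative case for the
    point estimates; bootstrap resamples cases, skipping resamples where a
    quantity is undefined.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if not truth.any():
        raise ValueError("no positive cases: sensitivity undefined")
    if truth.all():
        raise ValueError("no negative cases: specificity undefined")

    def _point(p, t):
        tp = (p & t).sum()
        fn = (~p & t).sum()
        tn = (~p & ~t).sum()
        fp = (p & ~t).sum()
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        return sens, spec

    sens, spec = _point(pred, truth)
    rng = np.random.default_rng(seed)
    n = len(pred)
    bs, bp = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        s, p = _point(pred[idx], truth[idx])
        if not np.isnan(s):
            bs.append(s)
        if not np.isnan(p):
            bp.append(p)
    s_lo, s_hi = np.percentile(bs, [2.5, 97.5])
    p_lo, p_hi = np.percentile(bp, [2.5, 97.5])
    return (
        float(sens),
        float(spec),
        BootstrapCI(float(s_lo), float(s_hi)),
        BootstrapCI(float(p_lo), float(p_hi)),
    )


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean paired difference and ± 1.96 sample-sd limits of agreement.

    Differences are x - y per case; sd uses the n-1 denominator. A
    zero-variance difference collapses both limits onto the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need n >= 2 paired observations")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def agreement_report(
    reference, model, marker: str = "c-MYC", n_boot: int = 1000, seed: int = 0
) -> AgreementReport:
    """Full agreement panel between reference and model scores for a marker."""
    reference = np.asarray(reference, dtype=float)
    model = np.asarray(model, dtype=float)
    r, r_lo, r_hi = pearson_with_ci(reference, model, n_boot=n_boot, seed=seed)
    icc, icc_p = icc_two_way_absolute(reference, model)
    truth = np.array([classify_marker(s, marker) for s in reference])
    pred = np.array([classify_marker(s, marker) for s in model])
    sens, spec, sens_ci, spec_ci = sens_spec(pred, truth, n_boot=n_boot, seed=seed)
    ba = bland_altman(reference, model)
    return AgreementReport(
        pearson_r=r,
        pearson_ci=BootstrapCI(r_lo, r_hi),
        icc=icc,
        icc_p=icc_p,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        bland_altman=ba,
    )
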