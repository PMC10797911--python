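"""Independent brute-force oracles used to cross-check the implementation.

Each function here recomputes a statistic from first principles (explicit
sums, ANOVA mean squares, event-time tables) without calling the package or
the library routine it checks.
"""

import math

import numpy as np


def pearson_formula(x, y):
    """Pearson r via the explicit covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def icc21_anova(x, y):
    """ICC(2,1) and its F-test p-value from two-way ANOVA mean squares."""
    from scipy.stats import f as f_dist

    M = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = M.shape
    grand = M.mean()
    ssr = k * ((M.mean(axis=1) - grand) ** 2).sum()  # rows (subjects)
    ssc = n * ((M.mean(axis=0) - grand) ** 2).sum()  # columns (raters)
    sst = ((M - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    F = msr / mse
    p = float(f_dist.sf(F, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def bland_altman_by_hand(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    md = d.sum() / n
    sd = math.sqrt(((d - md) ** 2).sum() / (n - 1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def sens_spec_counts(pred, truth):
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    tp = int((pred & truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    return tp / (tp + fn), tn / (tn + fp)


def logrank_by_hand(t1, e1, t2, e2):
    """Two-group log-rank chi-square via the observed-minus-expected sum
    over distinct event times (aggregated risk sets at ties)."""
    from scipy.stats import chi2

    times = np.r_[np.asarray(t1, float), np.asarray(t2, float)]
    events = np.r_[np.asarray(e1, int), np.asarray(e2, int)].astype(bool)
    grp = np.r_[np.zeros(len(t1)), np.ones(len(t2))].astype(bool)
    O = E = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        nj = at_risk.sum()
        n1 = (at_risk & grp).sum()
        dying = (times == t) & events
        dj = dying.sum()
        d1 = (dying & grp).sum()
        O += d1
        E += n1 * dj / nj
        if nj > 1:
            V += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    stat = (O - E) ** 2 / V
    return float(stat), float(chi2.sf(stat, 1))


def km_product_limit(times, events):
    """Kaplan-Meier survival at each distinct event time, by hand."""
    times = np.asarray(times, float)
    events = np.asarray(events, int).astype(bool)
    s = 1.0
    out = {}
    for t in np.unique(times[events]):
        n = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1.0 - d / n
        out[float(t)] = s
    return out


def gated_attention_by_hand(H, Wv, bv, Wu, bu, w, b):
    """Per-instance gated attention weights and pooled embedding, with
    explicit python loops (independent of the vectorized implementation)."""
    K = H.shape[0]
    scores = []
    for k in range(K):
        h = H[k]
        t = np.tanh(Wv @ h + bv)
        s = 1.0 / (1.0 + np.exp(-(Wu @ h + bu)))
        scores.append(float(w @ (t * s) + b))
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    tot = sum(exps)
    a = np.array([e / tot for e in exps])
    z = np.zeros(H.shape[1])
    for k in range(K):
        z = z + a[k] * H[k]
    return a, z
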