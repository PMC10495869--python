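"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths (and, where feasible,
numpy shortcuts) so that agreement is a genuine cross-check.
"""

import math


def brute_summaries(values, days, threshold):
    """Mean, sample SD, OLS slope, max |successive diff|, PAC — by loops."""
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return {"mean": mean, "sd": 0.0, "slope": 0.0,
                "max_change": 0.0, "pac": 0.0}
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    dbar = sum(days) / n
    sxx = sum((d - dbar) ** 2 for d in days)
    sxy = sum((d - dbar) * (v - mean) for d, v in zip(days, values))
    slope = sxy / sxx
    diffs = [abs(values[i + 1] - values[i]) for i in range(n - 1)]
    return {
        "mean": mean,
        "sd": sd,
        "slope": slope,
        "max_change": max(diffs),
        "pac": sum(1 for d in diffs if d >= threshold) / len(diffs),
    }


def pairwise_auc(labels, scores):
    """AUC by enumerating every positive-negative pair; ties count 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * pvalues[i] / rank_from_top)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def welch_closed_form(a, b):
    """Welch t statistic and Welch-Satterthwaite degrees of freedom."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
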