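"""Independent brute-force reference implementations used only by the tests.

Everything here is written from first principles (explicit loops, textbook
formulas) so it shares no code path with the package: the package goes through
scipy/statsmodels/sklearn, these do not.
"""

from __future__ import annotations

import math


def confusion_metrics(y_true, y_pred, classes):
    """Accuracy and one-vs-rest sensitivity/specificity by explicit counting."""
    n = len(y_true)
    correct = sum(1 for t, p in zip(y_true, y_pred) if t == p)
    sens, spec = {}, {}
    for c in classes:
        tp = fn = fp = tn = 0
        for t, p in zip(y_true, y_pred):
            if t == c and p == c:
                tp += 1
            elif t == c:
                fn += 1
            elif p == c:
                fp += 1
            else:
                tn += 1
        sens[c] = tp / (tp + fn) if tp + fn else float("nan")
        spec[c] = tn / (tn + fp) if tn + fp else float("nan")
    return correct / n, sens, spec


def pearson_r(x, y):
    """Pearson correlation from the covariance/variance definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def pearson_p(r, n):
    """Two-sided p for a Pearson r via the t-distribution with n-2 df."""
    from scipy.stats import t as t_dist  # distribution function only

    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(t_dist.sf(abs(t), n - 2))


def welch_p(a, b):
    """Two-sided Welch t-test p-value from the Welch-Satterthwaite formula."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * float(t_dist.sf(abs(t), df))


def benjamini_hochberg(p_values):
    """Step-up BH adjustment, returned in the input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        value = p_values[i] * m / rank_from_end
        running_min = min(running_min, value)
        adjusted[i] = min(1.0, running_min)
    return adjusted
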