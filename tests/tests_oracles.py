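"""Independent oracle implementations used by the acceptance tests.

Deliberately naive (loops, hand-rolled ranking) so they share no code
path with the package implementations they check.
"""

import numpy as np


def brute_force_mean_std(values, mask):
    """Two-pass per-compound mean and population std over retained members."""
    yhat, u = [], []
    for row, keep in zip(values, mask):
        v = [x for x, k in zip(row, keep) if k]
        if not v:
            yhat.append(np.nan)
            u.append(np.nan)
            continue
        m = sum(v) / len(v)
        yhat.append(m)
        if len(v) >= 2:
            u.append((sum((x - m) ** 2 for x in v) / len(v)) ** 0.5)
        else:
            u.append(np.nan)
    return np.array(yhat), np.array(u)


def rank_then_pearson(u, e):
    """Spearman ρ as Pearson correlation of hand-computed average ranks."""

    def avg_ranks(x):
        x = np.asarray(x, dtype=float)
        ranks = np.empty(len(x))
        order = np.argsort(x, kind="stable")
        sx = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    ru, re = avg_ranks(u), avg_ranks(e)
    return float(np.corrcoef(ru, re)[0, 1])
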