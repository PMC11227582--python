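"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives a quantity from first principles (per-index medians,
all-pairs minima, CDF-gap enumeration, hypergeometric enumeration,
grid-search least squares) without touching the implementation under test.
"""

import numpy as np
from scipy import stats


def oracle_rolling_median(x, w):
    if w % 2 == 0:
        w += 1
    h = w // 2
    n = len(x)
    return np.array([np.median(x[max(0, i - h):min(n, i + h + 1)])
                     for i in range(n)])


def oracle_nnd(a, b):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    return np.array([np.min(np.sqrt(((b - p) ** 2).sum(axis=1))) for p in a])


def oracle_ks_statistic(a, b):
    points = np.concatenate([a, b])
    return max(abs(np.mean(a <= x) - np.mean(b <= x)) for x in points)


def oracle_fisher_p(a, b, c, d):
    """Two-sided conditional p by enumeration over the hypergeometric support
    with fixed margins."""
    r1, n1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + n1 - n), min(r1, n1)
    pmf = {k: stats.hypergeom.pmf(k, n, n1, r1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


def oracle_exp_fit(t, x):
    """Grid-search exponential fit a*exp(-t/tau)+c: for each tau on a log
    grid solve the linear least squares in (a, c)."""
    best = None
    for tau in np.geomspace(1.0, 10 * (t[-1] - t[0]), 400):
        basis = np.column_stack([np.exp(-t / tau), np.ones_like(t)])
        coef, res, *_ = np.linalg.lstsq(basis, x, rcond=None)
        sse = res[0] if len(res) else np.sum((basis @ coef - x) ** 2)
        if best is None or sse < best[0]:
            best = (sse, coef[0], tau, coef[1])
    return best[1:]


def oracle_detect(z, rate, window_s=10.0, filter_k=2.0, peak_k=3.0,
                  min_sep_s=0.5):
    """Independent re-derivation of the MAD detector: recompute the threshold
    from its definition, scan every interior sample for strict local
    maximality (plateaus resolved to their first sample), then greedily keep
    larger peaks at the minimum separation."""
    r = z - oracle_rolling_median(z, int(round(window_s * rate)))
    mad1 = np.median(np.abs(r - np.median(r)))
    zf = z[r <= filter_k * mad1]
    m_f = np.median(zf)
    mad2 = np.median(np.abs(zf - m_f))
    thr = m_f + peak_k * mad2
    cand = [i for i in range(1, len(z) - 1)
            if z[i] > z[i - 1] and z[i] > thr
            and _next_differing(z, i) < z[i]]
    cand.sort(key=lambda i: (-z[i], i))
    accepted = []
    for i in cand:
        if all(abs(i - j) >= min_sep_s * rate for j in accepted):
            accepted.append(i)
    return sorted(accepted)


def _next_differing(z, i):
    j = i + 1
    while j < len(z) and z[j] == z[i]:
        j += 1
    return z[j] if j < len(z) else np.inf
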