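"""Independent brute-force oracles, deliberately coded in plain loop style.

These re-derive the normalization factors and test statistics from their
definitions, separately from the package implementation, so agreement is a
genuine dual-route check.
"""

import numpy as np


def bh_oracle(p):
    """Step-up BH by literal sorting: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def tmm_oracle(y, trim_M=0.30, trim_A=0.05):
    """Brute-force trimmed-mean-of-M factors on a strictly positive matrix.

    Assumes no exact ties in M or A (true for continuous random input).
    """
    y = np.asarray(y, float)
    n_rows, n_cols = y.shape
    N = [sum(y[:, k]) for k in range(n_cols)]
    p = np.array([[y[g, k] / N[k] for k in range(n_cols)] for g in range(n_rows)])
    q75 = [np.quantile(p[:, k], 0.75) for k in range(n_cols)]
    mean_q = sum(q75) / n_cols
    ref = min(range(n_cols), key=lambda k: abs(q75[k] - mean_q))
    logf = []
    for k in range(n_cols):
        if k == ref:
            logf.append(0.0)
            continue
        M = [np.log2(p[g, k] / p[g, ref]) for g in range(n_rows)]
        A = [0.5 * np.log2(p[g, k] * p[g, ref]) for g in range(n_rows)]
        v = [(1.0 - p[g, k]) / p[g, k] + (1.0 - p[g, ref]) / p[g, ref]
             for g in range(n_rows)]
        lo = int(np.floor(n_rows * trim_M)) + 1
        hi = n_rows + 1 - lo
        loA = int(np.floor(n_rows * trim_A)) + 1
        hiA = n_rows + 1 - loA
        rM = {g: r + 1 for r, g in enumerate(sorted(range(n_rows), key=lambda g: M[g]))}
        rA = {g: r + 1 for r, g in enumerate(sorted(range(n_rows), key=lambda g: A[g]))}
        keep = [g for g in range(n_rows) if lo <= rM[g] <= hi and loA <= rA[g] <= hiA]
        num = sum(M[g] / v[g] for g in keep)
        den = sum(1.0 / v[g] for g in keep)
        logf.append(num / den)
    f = np.power(2.0, logf)
    return f / np.exp(np.mean(np.log(f)))


def pooled_t_oracle(xa, xb):
    """Ordinary two-sample pooled-variance t statistic."""
    na, nb = len(xa), len(xb)
    va = np.var(xa, ddof=1)
    vb = np.var(xb, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (np.mean(xa) - np.mean(xb)) / np.sqrt(sp2 * (1 / na + 1 / nb))
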