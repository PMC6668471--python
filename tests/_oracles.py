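"""Independent brute-force oracles used to cross-check the package.

Everything here is written with explicit Python loops and two-pass means on
purpose: these routines must not share any code path with the vectorised
implementations they validate.
"""

import math


def brute_cov_corr(X, y):
    """Per-column sample covariance and Pearson correlation of X (list of
    rows) against y, via explicit two-pass loops."""
    n = len(y)
    p = len(X[0])
    covs, corrs = [], []
    my = sum(y) / n
    for j in range(p):
        xs = [X[i][j] for i in range(n)]
        mx = sum(xs) / n
        sxy = sum((xs[i] - mx) * (y[i] - my) for i in range(n))
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((v - my) ** 2 for v in y)
        covs.append(sxy / (n - 1))
        denom = math.sqrt(sxx * syy)
        corrs.append(sxy / denom if denom > 0 else float("nan"))
    return covs, corrs


def brute_retained(candidates, required_hot, excluded_cold, allowed_other):
    """Set-comprehension reimplementation of the A/B/C filters."""
    return {
        c.name
        for c in candidates
        if set(required_hot) <= set(c.hot_features)
        and not (set(c.cold_features) & set(excluded_cold))
        and set(c.other_features) <= set(allowed_other)
    }
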