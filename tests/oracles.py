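"""Independent oracles: deliberately naive implementations used only to
check the production code, sharing none of its machinery."""

import math


def exhaustive_dtw(test, ref):
    """Minimum accumulated cost and its path over *all* monotone warp
    paths, by plain recursion (no window, no memoization).  1-channel or
    multi-channel row sequences.  Exponential: lengths <= 8 only.

    Local cost uses sqrt(sum(d*d)) so the floating-point operations match
    the production kernel exactly.
    """

    def cost(i, j):
        d = 0.0
        ti, rj = test[i], ref[j]
        try:
            for a, b in zip(ti, rj):
                e = a - b
                d += e * e
        except TypeError:  # scalars
            e = ti - rj
            d = e * e
        return math.sqrt(d)

    def rec(i, j):
        c = cost(i, j)
        if i == 0 and j == 0:
            return c, [(0, 0)]
        best = math.inf
        best_path = None
        for pi, pj in ((i - 1, j - 1), (i - 1, j), (i, j - 1)):
            if pi >= 0 and pj >= 0:
                sub, sub_path = rec(pi, pj)
                if sub < best:
                    best, best_path = sub, sub_path
        return c + best, best_path + [(i, j)]

    return rec(len(test) - 1, len(ref) - 1)


def projected_distance_from_path(test, ref, path):
    """Mean per-test-sample Euclidean distance to the path-averaged
    reference, computed with plain Python lists."""
    n = len(test)
    sums = [None] * n
    counts = [0] * n
    for i, j in path:
        row = ref[j] if hasattr(ref[j], "__len__") else [ref[j]]
        if sums[i] is None:
            sums[i] = [0.0] * len(row)
        for k, v in enumerate(row):
            sums[i][k] += v
        counts[i] += 1
    total = 0.0
    for i in range(n):
        row = test[i] if hasattr(test[i], "__len__") else [test[i]]
        d = 0.0
        for k, v in enumerate(row):
            e = v - sums[i][k] / counts[i]
            d += e * e
        total += math.sqrt(d)
    return total / n


def welch_p_one_sided(x, y):
    """Closed-form one-sided Welch t-test p-value for mean(x) < mean(y),
    from first principles (mean, variance, Welch-Satterthwaite df,
    Student-t CDF via the regularized incomplete beta function)."""
    from scipy.special import betainc  # special function only, no stats

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    # P(T <= t) for Student-t with df degrees of freedom
    xbeta = df / (df + t * t)
    tail = 0.5 * betainc(df / 2.0, 0.5, xbeta)
    return tail if t < 0 else 1.0 - tail
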