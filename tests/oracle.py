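"""Independent brute-force oracle for interval slope screening.

Pure-Python exhaustive enumeration written directly from the defining
formulas (mean successive difference, closed-form intercept, 1 − SSE/SST),
kept free of any code shared with the package so it can referee the
vectorized implementation.
"""

import math


def literal_slope_sum(values, p, q):
    """Term-by-term mean of successive differences over positions [p, q]."""
    total = 0.0
    for k in range(p, q):
        total += values[k + 1] - values[k]
    return total / (q - p)


def brute_force_fits(cycles, values, min_window, slope_mode="endpoint"):
    """All window fits as (i, j, slope, bias, sse, r2) tuples."""
    m = len(cycles)
    fits = []
    for p in range(m - min_window + 1):
        for q in range(p + min_window - 1, m):
            xs = [float(c) for c in cycles[p : q + 1]]
            ys = [float(v) for v in values[p : q + 1]]
            n = len(xs)
            if slope_mode == "endpoint":
                slope = (ys[-1] - ys[0]) / (xs[-1] - xs[0])
            else:
                xbar = math.fsum(xs) / n
                sxx = math.fsum((x - xbar) ** 2 for x in xs)
                slope = math.fsum((x - xbar) * y for x, y in zip(xs, ys)) / sxx
            ybar = math.fsum(ys) / n
            xbar = math.fsum(xs) / n
            bias = ybar - slope * xbar
            sse = math.fsum((y - (slope * x + bias)) ** 2 for x, y in zip(xs, ys))
            sst = math.fsum((y - ybar) ** 2 for y in ys)
            r2 = 1.0 - sse / sst if sst > 0 else math.nan
            fits.append((int(xs[0]), int(xs[-1]), slope, bias, sse, r2))
    return fits


def brute_force_screen(
    cycles,
    values,
    r2_threshold=0.999,
    min_window=10,
    slope_mode="endpoint",
    require_positive_slope=True,
):
    """Exhaustive-search reference for screen_credible_slope.

    Returns (credible, best) where best is a fit tuple or None, using the
    same tie rules: maximal slope, then longer window, then smaller i.
    """
    fits = brute_force_fits(cycles, values, min_window, slope_mode)
    passing = [
        f
        for f in fits
        if not math.isnan(f[5])
        and f[5] > r2_threshold
        and (f[2] > 0 or not require_positive_slope)
    ]
    if passing:
        best = max(passing, key=lambda f: (f[2], f[1] - f[0], -f[0]))
        return True, best
    finite = [f for f in fits if not math.isnan(f[5])]
    if not finite:
        return False, None
    return False, max(finite, key=lambda f: (f[5], f[1] - f[0], -f[0]))
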