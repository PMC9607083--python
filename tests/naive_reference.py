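"""Naive reference implementations used as independent oracles in tests.

Everything here is written with explicit loops, closed-form two-parameter
least squares and cofactor matrix inversion — deliberately sharing no code
path with the package — so agreement is evidence of correctness rather than
of shared bugs.
"""

import math


def naive_rmse(truth, estimate):
    assert len(truth) == len(estimate)
    total = 0.0
    for a, b in zip(truth, estimate):
        total += (a - b) ** 2
    return math.sqrt(total / len(truth))


def naive_pearson(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)


def naive_profile(x):
    mean = sum(x) / len(x)
    out = []
    run = 0.0
    for v in x:
        run += v - mean
        out.append(run)
    return out


def _line_residuals(window):
    """Residuals of the least-squares line fitted against k = 0..s-1."""
    s = len(window)
    ks = list(range(s))
    mk = sum(ks) / s
    mw = sum(window) / s
    skk = sum((k - mk) ** 2 for k in ks)
    skw = sum((k - mk) * (w - mw) for k, w in zip(ks, window))
    slope = skw / skk
    intercept = mw - slope * mk
    return [w - (intercept + slope * k) for k, w in zip(ks, window)]


def naive_fluctuations(x, y, s):
    """(F2_dcca, F2_dfa_x, F2_dfa_y) by explicit window loops."""
    n = len(x)
    px = naive_profile(x)
    py = naive_profile(y)
    f_xy = f_xx = f_yy = 0.0
    for j in range(n - s + 1):
        rx = _line_residuals(px[j:j + s])
        ry = _line_residuals(py[j:j + s])
        f_xy += sum(a * b for a, b in zip(rx, ry)) / (s - 1)
        f_xx += sum(a * a for a in rx) / (s - 1)
        f_yy += sum(b * b for b in ry) / (s - 1)
    denom = n - s
    return f_xy / denom, f_xx / denom, f_yy / denom


def naive_dcca(x, y, s):
    f_xy, f_xx, f_yy = naive_fluctuations(x, y, s)
    return f_xy / math.sqrt(f_xx * f_yy)


def _inv2(m):
    (a, b), (c, d) = m
    det = a * d - b * c
    return [[d / det, -b / det], [-c / det, a / det]]


def _inv3(m):
    (a, b, c), (d, e, f), (g, h, i) = m
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    cof = [
        [e * i - f * h, -(b * i - c * h), b * f - c * e],
        [-(d * i - f * g), a * i - c * g, -(a * f - c * d)],
        [d * h - e * g, -(a * h - b * g), a * e - b * d],
    ]
    return [[cof[r][col] / det for col in range(3)] for r in range(3)]


def naive_dpcca(series, s):
    """Partial detrended cross-correlation of series[0], series[1] given the rest.

    Builds the DCCA coefficient matrix pairwise, inverts it with explicit
    2x2/3x3 cofactor formulas, and applies the partial-correlation readout.
    """
    m = len(series)
    assert m in (2, 3)
    rho = [[1.0] * m for _ in range(m)]
    for i in range(m):
        for j in range(i + 1, m):
            rho[i][j] = rho[j][i] = naive_dcca(series[i], series[j], s)
    c = _inv2(rho) if m == 2 else _inv3(rho)
    return -c[0][1] / math.sqrt(c[0][0] * c[1][1])


def naive_partial_from_pairwise(r_xy, r_xz, r_yz):
    """Textbook first-order partial correlation of (x, y) controlling z."""
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
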