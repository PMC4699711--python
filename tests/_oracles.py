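"""Independent reference implementations used only to check the package.

These are deliberately naive (double loops, flood fill, closed forms) and
were written against the definitions before the production code paths they
verify; they share no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_counts_bruteforce(x, m, r):
    """Ordered-pair SampEn match counts by exhaustive double loop.

    Templates i, j run over 0..N-m-1 (so every m-template has an m+1
    extension); matches use the strict Chebyshev criterion max|.| < r.
    """
    x = np.asarray(x, dtype=float)
    nt = len(x) - m
    b = a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return b, a


def sampen_bruteforce(x, m=3, r_frac=0.6):
    """-ln(A/B) from the brute-force counts; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return float("nan")
    b, a = sampen_counts_bruteforce(x, m, r_frac * sd)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def flood_fill_components(binary, connectivity):
    """Connected-component labeling by explicit flood fill.

    Returns a list of voxel-index sets, one per component, for 6/18/26
    connectivity in 3D.
    """
    binary = np.asarray(binary, dtype=bool)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    shape = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = set()
        while stack:
            v = stack.pop()
            comp.add(v)
            for dx, dy, dz in offsets:
                w = (v[0] + dx, v[1] + dy, v[2] + dz)
                if (
                    0 <= w[0] < shape[0]
                    and 0 <= w[1] < shape[1]
                    and 0 <= w[2] < shape[2]
                    and binary[w]
                    and not seen[w]
                ):
                    seen[w] = True
                    stack.append(w)
        components.append(comp)
    return components


def two_sample_t_pooled(a, b):
    """Classical pooled-variance two-sample t statistic (a minus b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def ols_residual_closed_form(y, design):
    """OLS residuals via the normal equations with an explicit inverse."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.inv(design.T @ design) @ design.T @ y
    return y - design @ beta
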