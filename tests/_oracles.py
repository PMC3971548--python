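"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: plain
Python loops over the textbook update equations, so they can arbitrate.
"""

import numpy as np


def fcm_bruteforce(values, centers, m=2.0, tol=1e-5, max_iter=300):
    """Textbook alternating-update fuzzy C-means, scalar loops only.

    Returns (centers, memberships, objective_trace).
    """
    values = [float(v) for v in values]
    centers = [float(c) for c in centers]
    n, k = len(values), len(centers)
    trace = []
    for _ in range(max_iter):
        u = [[0.0] * k for _ in range(n)]
        for i, x in enumerate(values):
            d2 = [(x - c) ** 2 for c in centers]
            if any(d == 0.0 for d in d2):
                hits = [j for j, d in enumerate(d2) if d == 0.0]
                for j in hits:
                    u[i][j] = 1.0 / len(hits)
                continue
            for j in range(k):
                u[i][j] = 1.0 / sum(
                    (d2[j] / d2[l]) ** (1.0 / (m - 1.0)) for l in range(k)
                )
        trace.append(
            sum(
                (u[i][j] ** m) * (values[i] - centers[j]) ** 2
                for i in range(n)
                for j in range(k)
            )
        )
        new_centers = []
        for j in range(k):
            num = sum((u[i][j] ** m) * values[i] for i in range(n))
            den = sum(u[i][j] ** m for i in range(n))
            new_centers.append(num / den if den > 0 else centers[j])
        shift = max(abs(a - b) for a, b in zip(new_centers, centers))
        centers = new_centers
        if shift < tol:
            break
    return np.array(centers), np.array(u), np.array(trace)


def dice_from_sets(a, b):
    """Dice coefficient from explicit voxel-index sets."""
    sa, sb = set(map(tuple, a)), set(map(tuple, b))
    if not sa and not sb:
        return float("nan")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def icc21_mean_squares(ref, auto):
    """ICC(2,1) from the explicit two-way mean squares (n subjects, k=2 raters)."""
    y = np.column_stack([np.asarray(ref, float), np.asarray(auto, float)])
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
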