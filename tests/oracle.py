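"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: contingency
tables are built by explicit Python loops and the two-locus regression is
solved through a pseudoinverse on the explicit design matrix.
"""

import numpy as np
from scipy import stats

MISSING = -1


def contingency_r2(x, y):
    """LD r^2 by explicit 2x2 contingency counting (nan if monomorphic)."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    n = len(pairs)
    if n == 0:
        return float("nan")
    n1 = sum(1 for a, _ in pairs if a == 1)
    n2 = sum(1 for _, b in pairs if b == 1)
    n11 = sum(1 for a, b in pairs if a == 1 and b == 1)
    if n1 in (0, n) or n2 in (0, n):
        return float("nan")
    num = (n * n11 - n1 * n2) ** 2
    den = n1 * (n - n1) * n2 * (n - n2)
    return num / den


def brute_second_order(g1, g2, q):
    """Second-order LD by enumerating the four two-locus classes directly.

    Returns (max_r2, per-pseudomarker list, best 1-based index; 0 if all
    four undefined).
    """
    rows = [(a, b, c) for a, b, c in zip(g1, g2, q)
            if MISSING not in (int(a), int(b), int(c))]
    qv = [c for _, _, c in rows]
    per = []
    for a0, b0 in ((0, 0), (0, 1), (1, 0), (1, 1)):
        ind = [1 if (a == a0 and b == b0) else 0 for a, b, _ in rows]
        per.append(contingency_r2(ind, qv))
    defined = [(k, v) for k, v in enumerate(per) if v == v]
    if not defined:
        return float("nan"), per, 0
    best_v = max(v for _, v in defined)
    best_k = min(k for k, v in defined if v == best_v)
    return best_v, per, best_k + 1


def ols_two_locus(y, g1, g2):
    """Normal-equations OLS of y on [1, a1, a2, a1*a2] with +1/-1 codes.

    Returns (beta (4,), se (4,), p (4,)) or None if the design is rank
    deficient or either locus monomorphic.
    """
    y = np.asarray(y, dtype=float)
    a1 = np.where(np.asarray(g1) == 0, 1.0, -1.0)
    a2 = np.where(np.asarray(g2) == 0, 1.0, -1.0)
    ok = (np.asarray(g1) != MISSING) & (np.asarray(g2) != MISSING) & ~np.isnan(y)
    y, a1, a2 = y[ok], a1[ok], a2[ok]
    n = y.size
    X = np.column_stack([np.ones(n), a1, a2, a1 * a2])
    if np.linalg.matrix_rank(X) < 4 or len(set(a1)) < 2 or len(set(a2)) < 2:
        return None
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - 4)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    p = 2 * stats.t.sf(np.abs(beta / se), n - 4)
    return beta, se, p


def random_triplet_dataset(rng, n_max=40, allow_missing=False):
    """A random 3-locus inbred dataset for oracle comparisons."""
    n = int(rng.integers(5, n_max + 1))
    p = rng.uniform(0.05, 0.95, size=3)
    codes = (rng.random((n, 3)) < p).astype(np.int8)
    if allow_missing:
        miss = rng.random((n, 3)) < 0.1
        codes[miss] = MISSING
    return codes
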