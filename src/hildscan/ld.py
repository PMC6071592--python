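"""Pairwise and second-order (high-order) linkage disequilibrium.

For inbred individuals a genotype column is a haplotype, so the LD between
two loci is the squared correlation of their 0/1 codes,

    r^2 = D^2 / (p_x (1 - p_x) p_y (1 - p_y)),   D = p_xy - p_x p_y,

computed from the 2x2 contingency counts of the pairwise-complete
individuals. All r^2 values in this module are evaluated with the exact
integer identity

    r^2 = (n * n11 - n1 * n2)^2 / (n1 (n - n1) n2 (n - n2)),

so results are reproducible to the last bit regardless of the (vectorized or
scalar) code path that produced the counts.

The second-order LD of a predictor pair (M1, M2) against a target Q recodes
the four two-locus genotypes AB / Ab / aB / ab as four one-vs-rest
bi-allelic pseudomarkers P1..P4 and takes the maximum pseudomarker-to-target
r^2. A monomorphic pseudomarker has no r^2 and is excluded from the max; if
all four are monomorphic the statistic is undefined (nan).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "LdValue",
    "PseudomarkerSet",
    "SecondOrderLD",
    "ld_r2",
    "make_pseudomarkers",
    "second_order_ld",
    "max_individual_r2",
    "pairwise_r2_matrix",
    "second_order_ld_batch",
]


class LdValue(NamedTuple):
    """An LD r^2 with the number of complete observations behind it."""

    r2: float
    n_used: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r2)


UNDEFINED = float("nan")


def _r2_from_counts(n11, n1, n2, n):
    """Exact r^2 from 2x2 contingency counts (vectorized, int64 inputs).

    nan where either margin is monomorphic. Valid for n < ~50,000 (int64
    overflow bound on (n*n11)^2).
    """
    n11 = np.asarray(n11, dtype=np.int64)
    n1 = np.asarray(n1, dtype=np.int64)
    n2 = np.asarray(n2, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    num = (n * n11 - n1 * n2) ** 2
    den = n1 * (n - n1) * n2 * (n - n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return r2


def ld_r2(x, y) -> LdValue:
    """Pairwise LD r^2 between two genotype columns (pairwise-complete).

    Returns an undefined value (``nan``) when either locus is monomorphic
    among the complete individuals; symmetric in its arguments.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("columns must have the same length")
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n == 0:
        return LdValue(UNDEFINED, 0)
    xb = x[ok] == 1
    yb = y[ok] == 1
    n1 = int(xb.sum())
    n2 = int(yb.sum())
    n11 = int((xb & yb).sum())
    return LdValue(float(_r2_from_counts(n11, n1, n2, n)), n)


@dataclass(frozen=True)
class PseudomarkerSet:
    """The four one-vs-rest recodings of a two-locus genotype.

    ``indicators`` is a 4 x n int8 array; row k is the indicator of the
    k-th two-locus class (P1={AB}, P2={Ab}, P3={aB}, P4={ab}, with A/B the
    major alleles, i.e. code 0). Individuals missing at either locus carry
    ``MISSING`` in all four rows. On complete individuals the four rows sum
    to one: the classes partition the sample.
    """

    indicators: np.ndarray
    source: tuple | None = None

    LABELS = ("AB", "Ab", "aB", "ab")

    def __getitem__(self, k: int) -> np.ndarray:
        return self.indicators[k]


def make_pseudomarkers(g1, g2, source=None) -> PseudomarkerSet:
    """Recode a predictor pair's two-locus genotypes as four pseudomarkers."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("columns must have the same length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    ind = np.full((4, g1.size), MISSING, dtype=np.int8)
    a = g1 == 1  # minor at locus 1
    b = g2 == 1
    ind[0, ok] = (~a & ~b)[ok]  # AB
    ind[1, ok] = (~a & b)[ok]   # Ab
    ind[2, ok] = (a & ~b)[ok]   # aB
    ind[3, ok] = (a & b)[ok]    # ab
    return PseudomarkerSet(ind, source)


class SecondOrderLD(NamedTuple):
    max_r2: LdValue
    per_pseudomarker: tuple
    best_index: int  # 1..4 (0 when all four pseudomarkers are undefined)


def second_order_ld(g1, g2, q) -> SecondOrderLD:
    """Second-order LD of predictor pair (g1, g2) to target q.

    Uses triplet-complete individuals. The statistic is the maximum defined
    pseudomarker-to-target r^2; ties break to the lowest pseudomarker index.
    Undefined (nan) if the target or all four pseudomarkers are monomorphic.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    q = np.asarray(q)
    if not (g1.shape == g2.shape == q.shape):
        raise ValueError("columns must have the same length")
    ok = (g1 != MISSING) & (g2 != MISSING) & (q != MISSING)
    n = int(ok.sum())
    if n == 0:
        empty = tuple(LdValue(UNDEFINED, 0) for _ in range(4))
        return SecondOrderLD(LdValue(UNDEFINED, 0), empty, 0)
    a = (g1[ok] == 1).astype(np.int64)
    b = (g2[ok] == 1).astype(np.int64)
    t = (q[ok] == 1).astype(np.int64)
    nq = int(t.sum())
    c1 = int(a.sum())
    c2 = int(b.sum())
    c12 = int((a & b).sum())
    c1q = int((a & t).sum())
    c2q = int((b & t).sum())
    c12q = int((a & b & t).sum())
    # class sizes and class-with-target counts for P1..P4
    nP = (n - c1 - c2 + c12, c2 - c12, c1 - c12, c12)
    nPQ = (nq - c1q - c2q + c12q, c2q - c12q, c1q - c12q, c12q)
    per = tuple(LdValue(float(_r2_from_counts(nPQ[k], nP[k], nq, n)), n) for k in range(4))
    best, best_r2 = 0, UNDEFINED
    for k in range(4):
        v = per[k].r2
        if not np.isnan(v) and (np.isnan(best_r2) or v > best_r2):
            best, best_r2 = k + 1, v
    return SecondOrderLD(LdValue(best_r2, n), per, best)


def max_individual_r2(q, predictors: GenotypeMatrix | np.ndarray):
    """Maximum single-predictor r^2 to a target column.

    Returns ``(LdValue, argmax_index)``; the argmax is the lowest index on
    ties, -1 when every pairwise r^2 is undefined.
    """
    codes = predictors.codes if isinstance(predictors, GenotypeMatrix) else np.asarray(predictors)
    if codes.ndim != 2 or codes.shape[1] == 0:
        raise ValueError("empty predictor panel")
    q = np.asarray(q)
    if not (codes == MISSING).any() and not (q == MISSING).any():
        r2 = pairwise_r2_matrix(q[:, None], codes)[0]
        n_used = q.size
    else:
        vals = [ld_r2(q, codes[:, j]) for j in range(codes.shape[1])]
        r2 = np.array([v.r2 for v in vals])
        n_used = max((v.n_used for v in vals), default=0)
    if np.all(np.isnan(r2)):
        return LdValue(UNDEFINED, n_used), -1
    best = int(np.nanargmax(r2))
    return LdValue(float(r2[best]), n_used), best


# ---------------------------------------------------------------------------
# Vectorized kernels (complete data): counts accumulate exactly in float32
# matmuls (integers < 2^24) and r^2 uses the same integer formula as ld_r2.
# ---------------------------------------------------------------------------

def _as_f32(codes) -> np.ndarray:
    a = np.asarray(codes)
    if (a == MISSING).any():
        raise ValueError("vectorized LD kernels require complete data")
    return np.ascontiguousarray(a, dtype=np.float32)


def pairwise_r2_matrix(A, B) -> np.ndarray:
    """All pairwise r^2 between columns of A (n x P) and B (n x T)."""
    Af = _as_f32(A)
    Bf = _as_f32(B)
    n = Af.shape[0]
    n11 = np.rint(Af.T @ Bf).astype(np.int64)
    n1 = Af.sum(axis=0).astype(np.int64)
    n2 = Bf.sum(axis=0).astype(np.int64)
    return _r2_from_counts(n11, n1[:, None], n2[None, :], n)


def _pseudo_r2_stack(c1, c2, c12, c1q, c2q, c12q, nq, n):
    """r^2 of the four pseudomarkers from triplet count statistics.

    All arguments broadcastable int64 arrays; returns array with a leading
    axis of length 4 (P1..P4 order).
    """
    nP = np.stack(np.broadcast_arrays(n - c1 - c2 + c12, c2 - c12, c1 - c12, c12))
    nPQ = np.stack(np.broadcast_arrays(nq - c1q - c2q + c12q, c2q - c12q, c1q - c12q, c12q))
    return _r2_from_counts(nPQ, nP, np.asarray(nq)[None, ...], np.asarray(n))


def _max_over_pseudomarkers(r2_stack):
    """(max_r2, best_index 1..4) over axis 0, nan-aware, lowest-index ties."""
    filled = np.where(np.isnan(r2_stack), -1.0, r2_stack)
    best = filled.argmax(axis=0)
    max_r2 = np.take_along_axis(filled, best[None, ...], axis=0)[0]
    all_nan = np.isnan(r2_stack).all(axis=0)
    out = np.where(all_nan, np.nan, max_r2)
    best_index = np.where(all_nan, 0, best + 1)
    return out, best_index


def second_order_ld_batch(A1, A2, Q):
    """Second-order LD for a batch of triplets (complete data).

    ``A1``, ``A2``, ``Q`` are n x B arrays whose b-th columns hold the two
    predictor columns and the target column of triplet b. Returns
    ``(max_r2 (B,), best_index (B,), per_pseudomarker (4, B))``.
    """
    g1 = _as_f32(A1)
    g2 = _as_f32(A2)
    qv = _as_f32(Q)
    n = g1.shape[0]
    g12 = g1 * g2
    c1 = np.rint(g1.sum(0)).astype(np.int64)
    c2 = np.rint(g2.sum(0)).astype(np.int64)
    nq = np.rint(qv.sum(0)).astype(np.int64)
    c12 = np.rint(g12.sum(0)).astype(np.int64)
    c1q = np.rint(np.einsum("ij,ij->j", g1, qv)).astype(np.int64)
    c2q = np.rint(np.einsum("ij,ij->j", g2, qv)).astype(np.int64)
    c12q = np.rint(np.einsum("ij,ij->j", g12, qv)).astype(np.int64)
    stack = _pseudo_r2_stack(c1, c2, c12, c1q, c2q, c12q, nq, n)
    max_r2, best = _max_over_pseudomarkers(stack)
    return max_r2, best, stack
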