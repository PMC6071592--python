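"""Two-locus statistical epistasis for inbred populations.

The model is the standard additive-by-additive regression for populations
with two homozygous genotype classes per locus,

    y = mu + a1*beta1 + a2*beta2 + (a1*a2)*beta12 + e,

where a1, a2 code the two homozygotes as +1 (major) / -1 (minor) and the
interaction code a1*a2 is their elementwise product (+1 for the AABB/aabb
classes, -1 for AAbb/aaBB). A nonzero beta12 is *statistical* epistasis: it
may reflect a functional interaction, but equally well high-order LD between
the marker pair and a single hidden causal locus.

The genome scan is the two-stage procedure common in practice: an ordinary
least-squares scan over all marker pairs without population-structure
control, followed by a linear-mixed-model refit (random polygenic effect
with genomic-kinship covariance, scalar REML on the eigen-rotated model) of
the pairs that pass the scan threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genotypes import MISSING, GenotypeMatrix, Phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "EpistasisFit",
    "TwoLocusEpistasis",
    "EpistasisScan",
    "encode_additive",
    "fit_two_locus_model",
    "epistasis_scan",
    "bonferroni_threshold",
    "n_pairs",
    "genomic_kinship",
    "refit_with_kinship",
]


def encode_additive(g) -> np.ndarray:
    """Map genotype codes to the +1/-1 design coding of the two-locus model.

    Major homozygote (code 0) -> +1, minor homozygote (code 1) -> -1,
    missing -> nan. The interaction code is the elementwise product of two
    encoded columns.
    """
    g = np.asarray(g)
    out = np.full(g.shape, np.nan)
    out[g == 0] = 1.0
    out[g == 1] = -1.0
    return out


@dataclass
class EpistasisFit:
    """Estimates and tests for one two-locus model fit."""

    intercept: float
    beta1: float
    beta2: float
    beta12: float
    se1: float
    se2: float
    se12: float
    p1: float
    p2: float
    p12: float
    n_used: int
    corrected: bool = False
    aliased: bool = False
    sigma2_g: float = 0.0
    sigma2_e: float = float("nan")

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta1, self.beta2, self.beta12])


def _y_values(y) -> np.ndarray:
    return y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)


def _design(y, g1, g2):
    yv = _y_values(y)
    a1 = encode_additive(g1)
    a2 = encode_additive(g2)
    ok = ~(np.isnan(yv) | np.isnan(a1) | np.isnan(a2))
    n = int(ok.sum())
    if n < 5:
        raise ValueError(f"only {n} complete observations (need >= 5)")
    a1, a2, yv = a1[ok], a2[ok], yv[ok]
    if np.all(a1 == a1[0]) or np.all(a2 == a2[0]):
        raise ValueError("both loci must be polymorphic among complete observations")
    X = np.column_stack([np.ones(n), a1, a2, a1 * a2])
    return X, yv, ok, n


def fit_two_locus_model(y, g1, g2) -> EpistasisFit:
    """OLS fit of the two-locus additive-by-additive model (uncorrected).

    ``y`` may be a :class:`Phenotype` (assumed aligned) or an array. Rows
    with a missing phenotype or genotype are dropped. A design made rank
    deficient by an empty two-locus genotype class is returned with the
    ``aliased`` flag set and undefined standard errors / p-values.
    """
    import statsmodels.api as sm

    X, yv, _, n = _design(y, g1, g2)
    if np.linalg.matrix_rank(X) < 4:
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        nan = float("nan")
        return EpistasisFit(beta[0], beta[1], beta[2], beta[3],
                            nan, nan, nan, nan, nan, nan,
                            n_used=n, aliased=True)
    res = sm.OLS(yv, X).fit()
    return EpistasisFit(
        intercept=float(res.params[0]),
        beta1=float(res.params[1]), beta2=float(res.params[2]), beta12=float(res.params[3]),
        se1=float(res.bse[1]), se2=float(res.bse[2]), se12=float(res.bse[3]),
        p1=float(res.pvalues[1]), p2=float(res.pvalues[2]), p12=float(res.pvalues[3]),
        n_used=n, corrected=False, sigma2_e=float(res.mse_resid),
    )


def bonferroni_threshold(alpha: float, n_tests) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def n_pairs(m: int) -> int:
    """Number of unordered marker pairs, C(m, 2)."""
    return comb(int(m), 2)


# ---------------------------------------------------------------------------
# genome scan (stage 1, OLS)
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    table: pd.DataFrame
    n_tests: int
    p_threshold: float
    n_aliased: int


_SCAN_COLUMNS = ["marker_i", "marker_j", "id_i", "id_j", "chrom_i", "pos_i",
                 "chrom_j", "pos_j", "beta1", "beta2", "beta12",
                 "se12", "p12", "n_used", "aliased"]


def epistasis_scan(y, G: GenotypeMatrix, p_threshold: float, keep_all: bool = False) -> ScanResult:
    """OLS interaction test for every unordered marker pair.

    Pairs with interaction p-value below ``p_threshold`` are returned sorted
    by p12 (``keep_all=True`` returns every testable pair). Pairs whose
    design is aliased by an empty two-locus class are counted and skipped.
    With complete data the per-pair OLS is solved from precomputed
    cross-product matrices; with missing data each pair is fitted on its
    pairwise-complete rows.
    """
    yv = _y_values(y)
    if yv.size != G.n:
        raise ValueError("phenotype and genotype matrix are not aligned")
    m = G.n_markers
    total = n_pairs(m)
    rows = []
    n_aliased = 0
    if not G.has_missing() and not np.isnan(yv).any():
        A = encode_additive(G.codes)
        n = G.n
        S = A.T @ A
        colsum = A.sum(axis=0)
        Ay = A.T @ yv
        Z = (A * yv[:, None]).T @ A  # Z[i, j] = sum(a_i a_j y)
        sy = float(yv.sum())
        yy = float(yv @ yv)
        df = n - 4
        iu, ju = np.triu_indices(m, k=1)
        for lo in range(0, iu.size, 200_000):
            ii = iu[lo:lo + 200_000]
            jj = ju[lo:lo + 200_000]
            si, sj, sij = colsum[ii], colsum[jj], S[ii, jj]
            # two-locus class counts; an empty class aliases a1*a2
            counts = np.stack([n + si + sj + sij, n + si - sj - sij,
                               n - si + sj - sij, n - si - sj + sij]) / 4.0
            ok = counts.min(axis=0) > 0.5
            n_aliased += int((~ok).sum())
            ii, jj = ii[ok], jj[ok]
            si, sj, sij = si[ok], sj[ok], sij[ok]
            B = ii.size
            if B == 0:
                continue
            XtX = np.empty((B, 4, 4))
            XtX[:, 0, 0] = XtX[:, 1, 1] = XtX[:, 2, 2] = XtX[:, 3, 3] = n
            XtX[:, 0, 1] = XtX[:, 1, 0] = XtX[:, 2, 3] = XtX[:, 3, 2] = si
            XtX[:, 0, 2] = XtX[:, 2, 0] = XtX[:, 1, 3] = XtX[:, 3, 1] = sj
            XtX[:, 0, 3] = XtX[:, 3, 0] = XtX[:, 1, 2] = XtX[:, 2, 1] = sij
            Xty = np.column_stack([np.full(B, sy), Ay[ii], Ay[jj], Z[ii, jj]])
            beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
            rss = np.clip(yy - np.einsum("bk,bk->b", beta, Xty), 0.0, None)
            sigma2 = rss / df
            cov33 = np.linalg.inv(XtX)[:, 3, 3]
            se12 = np.sqrt(np.clip(sigma2 * cov33, 0.0, None))
            with np.errstate(divide="ignore", invalid="ignore"):
                tval = np.where(se12 > 0, np.abs(beta[:, 3]) / np.where(se12 > 0, se12, 1.0), np.inf)
            p12 = 2.0 * stats.t.sf(tval, df)
            p12 = np.where((se12 == 0) & (beta[:, 3] == 0), 1.0, p12)
            sel = np.ones(B, dtype=bool) if keep_all else p12 < p_threshold
            for b in np.where(sel)[0]:
                rows.append(_scan_row(G, int(ii[b]), int(jj[b]), beta[b],
                                      float(se12[b]), float(p12[b]), n, False))
    else:
        for i in range(m - 1):
            for j in range(i + 1, m):
                try:
                    fit = fit_two_locus_model(yv, G.codes[:, i], G.codes[:, j])
                except ValueError:
                    n_aliased += 1
                    continue
                if fit.aliased:
                    n_aliased += 1
                    continue
                if keep_all or fit.p12 < p_threshold:
                    rows.append(_scan_row(G, i, j, fit.betas, fit.se12, fit.p12, fit.n_used, False))
    table = pd.DataFrame(rows, columns=_SCAN_COLUMNS).sort_values("p12", kind="mergesort").reset_index(drop=True)
    return ScanResult(table=table, n_tests=total, p_threshold=p_threshold, n_aliased=n_aliased)


def _scan_row(G, i, j, beta, se12, p12, n_used, aliased):
    mm = G.markers
    b = np.asarray(beta, dtype=float)
    b1, b2, b12 = (b[1], b[2], b[3]) if b.size == 4 else (b[0], b[1], b[2])
    return (i, j, mm.marker_id[i], mm.marker_id[j],
            mm.chromosome[i], int(mm.position[i]), mm.chromosome[j], int(mm.position[j]),
            float(b1), float(b2), float(b12), float(se12), float(p12), int(n_used), aliased)


# ---------------------------------------------------------------------------
# kinship and mixed-model refit (stage 2)
# ---------------------------------------------------------------------------

def genomic_kinship(G: GenotypeMatrix) -> np.ndarray:
    """Allele-sharing genomic kinship: Z Z' / m on column-standardized codes.

    Missing entries are mean-imputed per column for this computation only.
    Symmetric and positive semi-definite by construction.
    """
    if G.n < 2 or G.n_markers < 2:
        raise ValueError("kinship needs >= 2 individuals and >= 2 markers")
    X = G.codes.astype(float)
    X[G.codes == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return (Z @ Z.T) / Z.shape[1]


def _check_psd_eig(K, tol=1e-6):
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kinship matrix must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix must be symmetric")
    d, U = np.linalg.eigh(K)
    if d.min() < -tol * max(d.max(), 1.0):
        raise ValueError("kinship matrix is not positive semi-definite")
    return np.clip(d, 0.0, None), U


def _reml_neg_loglik(lam, W, z, d, df):
    w = 1.0 / (lam * d + 1.0)
    M = W.T @ (W * w[:, None])
    rhs = W.T @ (w * z)
    beta = np.linalg.solve(M, rhs)
    r = z - W @ beta
    q = float(r @ (w * r))
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0 or q <= 0:
        return np.inf, None
    nll = df * np.log(q / df) + float(np.sum(np.log(lam * d + 1.0))) + logdetM
    return nll, (beta, M, q / df)


def refit_with_kinship(y, g1, g2, K, fix_lambda: float | None = None) -> EpistasisFit:
    """Two-locus model with a random polygenic effect, cov sigma2_g * K.

    The model is rotated by the eigenvectors of K, leaving independent
    observations with variances sigma2_e * (lambda * d_i + 1) where
    lambda = sigma2_g / sigma2_e; REML profiles the likelihood over lambda
    by bounded scalar search (tolerance 1e-8 on log-lambda). Wald t-tests on
    the GLS estimates; ``fix_lambda=0`` reproduces the OLS fit exactly.
    """
    X, yv, ok, n = _design(y, g1, g2)
    K = np.asarray(K, dtype=float)
    if K.shape[0] != ok.size:
        raise ValueError("kinship matrix not aligned to phenotype/genotypes")
    d, U = _check_psd_eig(K[np.ix_(ok, ok)])
    if np.linalg.matrix_rank(X) < 4:
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        nan = float("nan")
        return EpistasisFit(*beta, nan, nan, nan, nan, nan, nan,
                            n_used=n, corrected=True, aliased=True)
    W = U.T @ X
    z = U.T @ yv
    df = n - 4

    if fix_lambda is not None:
        lam = float(fix_lambda)
    else:
        def obj(t):
            return _reml_neg_loglik(np.exp(t), W, z, d, df)[0]
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        if _reml_neg_loglik(0.0, W, z, d, df)[0] <= res.fun:
            lam = 0.0
    nll, fitted = _reml_neg_loglik(lam, W, z, d, df)
    if fitted is None:
        raise RuntimeError("mixed-model fit failed (degenerate rotated design)")
    beta, M, sigma2_e = fitted
    cov = sigma2_e * np.linalg.inv(M)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return EpistasisFit(
        intercept=float(beta[0]),
        beta1=float(beta[1]), beta2=float(beta[2]), beta12=float(beta[3]),
        se1=float(se[1]), se2=float(se[2]), se12=float(se[3]),
        p1=float(pvals[1]), p2=float(pvals[2]), p12=float(pvals[3]),
        n_used=n, corrected=True, sigma2_g=float(lam * sigma2_e),
        sigma2_e=float(sigma2_e),
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class TwoLocusEpistasis(BaseEstimator):
    """Estimator for the two-locus additive-by-additive model.

    ``fit(X, y)`` takes an n x 2 array (or GenotypeMatrix) of genotype codes
    for the marker pair. With ``kinship`` set, the fit is the
    kinship-corrected mixed model; otherwise plain OLS.
    """

    def __init__(self, kinship=None):
        self.kinship = kinship

    def fit(self, X, y):
        codes = X.codes if isinstance(X, GenotypeMatrix) else np.asarray(X)
        if codes.ndim != 2 or codes.shape[1] != 2:
            raise ValueError("X must have exactly two genotype columns")
        if self.kinship is None:
            res = fit_two_locus_model(y, codes[:, 0], codes[:, 1])
        else:
            res = refit_with_kinship(y, codes[:, 0], codes[:, 1], self.kinship)
        self.result_ = res
        self.intercept_ = res.intercept
        self.coef_ = res.betas
        self.se_ = np.array([res.se1, res.se2, res.se12])
        self.pvalues_ = np.array([res.p1, res.p2, res.p12])
        self.n_used_ = res.n_used
        self.corrected_ = res.corrected
        self.aliased_ = res.aliased
        return self

    def predict(self, X):
        codes = X.codes if isinstance(X, GenotypeMatrix) else np.asarray(X)
        a1 = encode_additive(codes[:, 0])
        a2 = encode_additive(codes[:, 1])
        return self.intercept_ + self.coef_[0] * a1 + self.coef_[1] * a2 + self.coef_[2] * a1 * a2


class EpistasisScan(BaseEstimator):
    """Two-stage exhaustive pairwise epistasis scan.

    Stage 1: OLS interaction test for all C(m, 2) marker pairs at a
    Bonferroni threshold (``alpha`` over all pairs by default, or an
    explicit ``n_tests`` for block-based corrections). Stage 2 (optional):
    each passing pair is refitted with a genomic-kinship mixed model.
    """

    def __init__(self, alpha: float = 0.05, n_tests: int | None = None,
                 p_threshold: float | None = None, kinship_refit: bool = True):
        self.alpha = alpha
        self.n_tests = n_tests
        self.p_threshold = p_threshold
        self.kinship_refit = kinship_refit

    def fit(self, G: GenotypeMatrix, y):
        yv = _y_values(y)
        if self.p_threshold is not None:
            thr = self.p_threshold
        else:
            thr = bonferroni_threshold(self.alpha, self.n_tests or n_pairs(G.n_markers))
        scan = epistasis_scan(yv, G, thr)
        table = scan.table.copy()
        if self.kinship_refit and len(table):
            K = genomic_kinship(G)
            self.kinship_ = K
            cols = {"beta12_corrected": [], "se12_corrected": [], "p12_corrected": [],
                    "sigma2_g": []}
            for _, row in table.iterrows():
                fit = refit_with_kinship(yv, G.codes[:, int(row.marker_i)],
                                         G.codes[:, int(row.marker_j)], K)
                cols["beta12_corrected"].append(fit.beta12)
                cols["se12_corrected"].append(fit.se12)
                cols["p12_corrected"].append(fit.p12)
                cols["sigma2_g"].append(fit.sigma2_g)
            for k, v in cols.items():
                table[k] = v
        self.results_ = table
        self.n_tests_ = scan.n_tests
        self.threshold_ = thr
        self.n_aliased_ = scan.n_aliased
        return self
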