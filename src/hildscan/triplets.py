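"""Exhaustive and sampled scans for high-order LD triplets.

A *triplet* is (predictor i, predictor j, target q): two genotyped markers
evaluated jointly against one hidden polymorphism. Each triplet gets a
cis/trans class from marker positions: a predictor is *cis* to the target
iff it lies on the same chromosome within ``window_bp`` (default 1 Mb,
inclusive); two / one / zero cis predictors give cis_cis / cis_trans /
trans_trans.

The scan mirrors the two-stage bookkeeping of window-based surveys:

1. targets already tagged well by a single predictor (max individual
   r^2 >= ``target_filter_r2``) are skipped and counted;
2. every unordered predictor pair is evaluated against each remaining
   target; records above ``keep_r2`` are retained and flagged *strong*
   above ``strong_r2``.

Observed per-class proportions from windows extrapolate to genome-wide
expected counts by multiplying with the total number of possible triplets
per class (:func:`count_possible_pairs`, :func:`extrapolate_genome`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import ld
from .genotypes import GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

CLASSES = ("cis_cis", "cis_trans", "trans_trans")

__all__ = [
    "CLASSES",
    "TripletScan",
    "TripletScanResult",
    "ExtrapolationEstimate",
    "classify_triplet",
    "scan_triplets",
    "count_possible_pairs",
    "extrapolate_genome",
    "sample_triplet_proportions",
]


def _is_cis(chrom_p, pos_p, chrom_t, pos_t, window_bp):
    """Vectorized cis test: same chromosome and |Δpos| <= window (inclusive)."""
    same = np.asarray(chrom_p).astype(str) == np.asarray(chrom_t).astype(str)
    near = np.abs(np.asarray(pos_p, dtype=np.int64) - np.asarray(pos_t, dtype=np.int64)) <= int(window_bp)
    return same & near


def classify_triplet(marker_map: MarkerMap, i: int, j: int, q: int, window_bp: int = 1_000_000) -> str:
    """Cis/trans class of a triplet whose three loci share one marker map."""
    n_cis = int(
        _is_cis(marker_map.chromosome[i], marker_map.position[i], marker_map.chromosome[q], marker_map.position[q], window_bp)
    ) + int(
        _is_cis(marker_map.chromosome[j], marker_map.position[j], marker_map.chromosome[q], marker_map.position[q], window_bp)
    )
    return CLASSES[2 - n_cis]


def _classify_counts(n_cis):
    """Map per-triplet cis-predictor counts {0,1,2} to class labels."""
    return np.array(CLASSES, dtype=object)[2 - np.asarray(n_cis)]


@dataclass
class TripletScanResult:
    """Outcome of an exhaustive triplet scan."""

    records: pd.DataFrame
    denominators: dict          # class -> evaluated (pair, target) triplets
    strong_counts: dict         # class -> triplets with r2 > strong_r2
    kept_counts: dict           # class -> triplets with r2 > keep_r2
    n_targets_evaluated: int
    n_targets_skipped: int
    n_pairs_total: int          # C(P, 2)
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "evaluated_triplets": pd.Series(self.denominators),
                "kept": pd.Series(self.kept_counts),
                "strong": pd.Series(self.strong_counts),
            }
        ).rename_axis("class")


_RECORD_COLUMNS = [
    "predictor_i", "predictor_j", "target",
    "predictor_i_id", "predictor_j_id", "target_id",
    "chrom_i", "pos_i", "chrom_j", "pos_j", "chrom_q", "pos_q",
    "r2_p1", "r2_p2", "r2_p3", "r2_p4",
    "second_order_r2", "best_pseudomarker", "max_individual_r2",
    "class", "strong",
]


def _max_individual_r2_per_target(P: GenotypeMatrix, T: GenotypeMatrix, chunk=512):
    """Max single-predictor r^2 for each target column (nan-aware)."""
    out = np.empty(T.n_markers)
    if P.has_missing() or T.has_missing():
        for t in range(T.n_markers):
            out[t] = ld.max_individual_r2(T.codes[:, t], P)[0].r2
        return out
    for lo in range(0, T.n_markers, chunk):
        hi = min(lo + chunk, T.n_markers)
        r2 = ld.pairwise_r2_matrix(T.codes[:, lo:hi], P.codes)
        all_nan = np.isnan(r2).all(axis=1)
        block = np.where(all_nan, np.nan, np.nanmax(np.where(np.isnan(r2), -1.0, r2), axis=1))
        out[lo:hi] = block
    return out


def scan_triplets(
    predictors: GenotypeMatrix,
    targets: GenotypeMatrix,
    keep_r2: float = 0.3,
    strong_r2: float = 0.6,
    target_filter_r2: float = 0.6,
    window_bp: int = 1_000_000,
    block_size: int = 512,
) -> TripletScanResult:
    """Exhaustively evaluate all (predictor pair, target) triplets.

    Panels must carry the same individuals in the same order (align first).
    Intended for window-sized panels; the cross-product is evaluated in
    blocks and only records above ``keep_r2`` are materialized.
    """
    if predictors.n != targets.n or not np.array_equal(predictors.individual_ids, targets.individual_ids):
        raise ValueError("predictor and target panels must carry the same individuals (align by id first)")
    P = predictors.n_markers
    if P < 2 or targets.n_markers == 0:
        raise ValueError("empty panel")

    max_ind = _max_individual_r2_per_target(predictors, targets)
    keep_targets = np.where(~(np.nan_to_num(max_ind, nan=np.inf) >= target_filter_r2))[0]
    n_skipped = targets.n_markers - keep_targets.size
    if n_skipped:
        logger.info("scan_triplets: %d of %d targets skipped (max individual r2 >= %g)",
                    n_skipped, targets.n_markers, target_filter_r2)

    pmap, tmap = predictors.markers, targets.markers
    denominators = {c: 0 for c in CLASSES}
    strong_counts = {c: 0 for c in CLASSES}
    kept_counts = {c: 0 for c in CLASSES}
    rows = []

    iu, ju = np.triu_indices(P, k=1)  # used by the slow path only
    fast = not (predictors.has_missing() or targets.has_missing())
    if fast:
        Af = np.ascontiguousarray(predictors.codes, dtype=np.float32)
        n = predictors.n
        s = np.rint(Af.sum(axis=0)).astype(np.int64)
        S = np.rint(Af.T @ Af).astype(np.int64)

    for t in keep_targets:
        cis = _is_cis(pmap.chromosome, pmap.position, tmap.chromosome[t], tmap.position[t], window_bp)
        c_q = int(cis.sum())
        denominators["cis_cis"] += comb(c_q, 2)
        denominators["cis_trans"] += c_q * (P - c_q)
        denominators["trans_trans"] += comb(P - c_q, 2)

        if fast:
            qf = np.ascontiguousarray(targets.codes[:, t], dtype=np.float32)
            nq = int(qf.sum())
            u = np.rint(Af.T @ qf).astype(np.int64)
            Sq = np.rint(Af.T @ (Af * qf[:, None])).astype(np.int64)
            for lo in range(0, P, block_size):
                hi = min(lo + block_size, P)
                stack = ld._pseudo_r2_stack(
                    s[lo:hi, None], s[None, :], S[lo:hi],
                    u[lo:hi, None], u[None, :], Sq[lo:hi], nq, n,
                )
                max_r2, best = ld._max_over_pseudomarkers(stack)
                jj_grid = np.arange(P)[None, :]
                ii_grid = np.arange(lo, hi)[:, None]
                sel = (jj_grid > ii_grid) & (np.nan_to_num(max_r2, nan=-1.0) > keep_r2)
                bi, bj = np.nonzero(sel)
                for a, b in zip(bi, bj):
                    i, j = lo + int(a), int(b)
                    _append_record(rows, predictors, targets, i, j, t,
                                   stack[:, a, b], float(max_r2[a, b]), int(best[a, b]),
                                   float(max_ind[t]), cis, strong_r2, window_bp,
                                   strong_counts, kept_counts)
        else:
            qcol = targets.codes[:, t]
            for i, j in zip(iu, ju):
                res = ld.second_order_ld(predictors.codes[:, i], predictors.codes[:, j], qcol)
                if res.max_r2.defined and res.max_r2.r2 > keep_r2:
                    per = np.array([v.r2 for v in res.per_pseudomarker])
                    _append_record(rows, predictors, targets, int(i), int(j), int(t),
                                   per, res.max_r2.r2, res.best_index,
                                   float(max_ind[t]), cis, strong_r2, window_bp,
                                   strong_counts, kept_counts)

    records = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    return TripletScanResult(
        records=records,
        denominators=denominators,
        strong_counts=strong_counts,
        kept_counts=kept_counts,
        n_targets_evaluated=int(keep_targets.size),
        n_targets_skipped=int(n_skipped),
        n_pairs_total=comb(P, 2),
        params=dict(keep_r2=keep_r2, strong_r2=strong_r2,
                    target_filter_r2=target_filter_r2, window_bp=window_bp),
    )


def _append_record(rows, predictors, targets, i, j, t, per_r2, max_r2, best,
                   max_ind_t, cis, strong_r2, window_bp, strong_counts, kept_counts):
    pmap, tmap = predictors.markers, targets.markers
    cls = CLASSES[2 - (int(cis[i]) + int(cis[j]))]
    strong = max_r2 > strong_r2
    kept_counts[cls] += 1
    if strong:
        strong_counts[cls] += 1
    rows.append((
        i, j, t,
        pmap.marker_id[i], pmap.marker_id[j], tmap.marker_id[t],
        pmap.chromosome[i], int(pmap.position[i]),
        pmap.chromosome[j], int(pmap.position[j]),
        tmap.chromosome[t], int(tmap.position[t]),
        float(per_r2[0]), float(per_r2[1]), float(per_r2[2]), float(per_r2[3]),
        float(max_r2), int(best), max_ind_t, cls, bool(strong),
    ))


class TripletScan(BaseEstimator):
    """Scikit-learn-style wrapper around :func:`scan_triplets`.

    Parameters mirror the scan thresholds; ``fit(predictors, targets)``
    runs the exhaustive scan and exposes the outcome as fitted attributes
    (``records_``, ``denominators_``, ``strong_counts_``, ...).
    """

    def __init__(self, keep_r2: float = 0.3, strong_r2: float = 0.6,
                 target_filter_r2: float = 0.6, window_bp: int = 1_000_000,
                 block_size: int = 512):
        self.keep_r2 = keep_r2
        self.strong_r2 = strong_r2
        self.target_filter_r2 = target_filter_r2
        self.window_bp = window_bp
        self.block_size = block_size

    def fit(self, predictors: GenotypeMatrix, targets: GenotypeMatrix):
        res = scan_triplets(
            predictors, targets,
            keep_r2=self.keep_r2, strong_r2=self.strong_r2,
            target_filter_r2=self.target_filter_r2,
            window_bp=self.window_bp, block_size=self.block_size,
        )
        self.result_ = res
        self.records_ = res.records
        self.denominators_ = res.denominators
        self.strong_counts_ = res.strong_counts
        self.kept_counts_ = res.kept_counts
        self.n_targets_evaluated_ = res.n_targets_evaluated
        self.n_targets_skipped_ = res.n_targets_skipped
        self.n_pairs_total_ = res.n_pairs_total
        return self


def count_possible_pairs(predictor_map: MarkerMap, target_map: MarkerMap,
                         window_bp: int = 1_000_000) -> dict:
    """Genome totals of possible (predictor pair, target) triplets per class.

    For each target with ``c`` cis predictors out of ``P``:
    cis_cis C(c,2), cis_trans c(P-c), trans_trans C(P-c,2). Python integers
    throughout (totals overflow int64 at genome scale).
    """
    P = len(predictor_map)
    w = int(window_bp)
    by_chrom = {}
    for c in np.unique(predictor_map.chromosome.astype(str)):
        sel = predictor_map.chromosome.astype(str) == c
        by_chrom[c] = np.sort(predictor_map.position[sel])
    totals = {c: 0 for c in CLASSES}
    tchrom = target_map.chromosome.astype(str)
    tpos = target_map.position
    for k in range(len(target_map)):
        pos = by_chrom.get(str(tchrom[k]))
        if pos is None:
            cq = 0
        else:
            lo = np.searchsorted(pos, tpos[k] - w, side="left")
            hi = np.searchsorted(pos, tpos[k] + w, side="right")
            cq = int(hi - lo)
        totals["cis_cis"] += comb(cq, 2)
        totals["cis_trans"] += cq * (P - cq)
        totals["trans_trans"] += comb(P - cq, 2)
    return totals


@dataclass
class ExtrapolationEstimate:
    """Genome-wide extrapolation of per-class strong-triplet counts.

    ``estimate = pooled proportion x genome total`` per class; the
    estimation error is the sample standard deviation of the per-window
    genome estimates (nan when only one window contributes).
    """

    observed: dict
    evaluated: dict
    proportion: dict
    genome_possible: dict
    estimate: dict
    error: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_strong": pd.Series(self.observed),
                "evaluated": pd.Series(self.evaluated),
                "proportion": pd.Series(self.proportion),
                "genome_possible": pd.Series({k: float(v) for k, v in self.genome_possible.items()}),
                "genome_estimate": pd.Series(self.estimate),
                "estimation_error": pd.Series(self.error),
            }
        ).rename_axis("class")


def extrapolate_genome(window_results, genome_totals: dict) -> ExtrapolationEstimate:
    """Extrapolate per-window (observed_strong, evaluated) counts genome-wide.

    ``window_results``: sequence of mappings class -> (observed, evaluated).
    Proportions are pooled (sum observed / sum evaluated) across windows;
    classes with zero pooled evaluated triplets are undefined (nan).
    """
    if not window_results:
        raise ValueError("at least one window result required")
    observed, evaluated, proportion, estimate, error = {}, {}, {}, {}, {}
    for cls in CLASSES:
        obs = [int(w[cls][0]) for w in window_results if cls in w]
        ev = [int(w[cls][1]) for w in window_results if cls in w]
        observed[cls] = sum(obs)
        evaluated[cls] = sum(ev)
        total = genome_totals.get(cls, 0)
        if evaluated[cls] == 0:
            proportion[cls] = float("nan")
            estimate[cls] = float("nan")
            error[cls] = float("nan")
            continue
        proportion[cls] = observed[cls] / evaluated[cls]
        estimate[cls] = proportion[cls] * total
        per_window = [o / e * total for o, e in zip(obs, ev) if e > 0]
        error[cls] = float(np.std(per_window, ddof=1)) if len(per_window) > 1 else float("nan")
    return ExtrapolationEstimate(observed, evaluated, proportion,
                                 dict(genome_totals), estimate, error)


def sample_triplet_proportions(
    predictors: GenotypeMatrix,
    targets: GenotypeMatrix,
    n_samples: int,
    seed: int,
    strong_r2: float = 0.6,
    target_filter_r2: float = 0.6,
    window_bp: int = 1_000_000,
    chunk: int = 20_000,
) -> pd.DataFrame:
    """Monte Carlo estimate of per-class strong-triplet proportions.

    Draws ``n_samples`` (predictor pair, target) triplets uniformly (targets
    restricted to those passing the individual-r^2 filter), evaluates the
    second-order LD of each, and tabulates per class how many exceed
    ``strong_r2``. An unbiased estimator of the exhaustive-scan proportions
    when the full cross-product is not computable.
    """
    if predictors.n != targets.n or not np.array_equal(predictors.individual_ids, targets.individual_ids):
        raise ValueError("predictor and target panels must carry the same individuals")
    if predictors.has_missing() or targets.has_missing():
        raise ValueError("sampled scans require complete data")
    P = predictors.n_markers
    max_ind = _max_individual_r2_per_target(predictors, targets)
    keep_targets = np.where(~(np.nan_to_num(max_ind, nan=np.inf) >= target_filter_r2))[0]
    if keep_targets.size == 0 or P < 2:
        raise ValueError("nothing to sample after target filtering")

    rng = np.random.default_rng(seed)
    pmap, tmap = predictors.markers, targets.markers
    At = np.ascontiguousarray(predictors.codes.T)
    Tt = np.ascontiguousarray(targets.codes.T)
    evaluated = {c: 0 for c in CLASSES}
    strong = {c: 0 for c in CLASSES}
    remaining = int(n_samples)
    while remaining > 0:
        b = min(chunk, remaining)
        remaining -= b
        ii = rng.integers(0, P, size=b)
        jj = rng.integers(0, P - 1, size=b)
        jj[jj >= ii] += 1  # uniform over unordered pairs, i != j
        qq = keep_targets[rng.integers(0, keep_targets.size, size=b)]
        max_r2, _, _ = ld.second_order_ld_batch(At[ii].T, At[jj].T, Tt[qq].T)
        cis_i = _is_cis(pmap.chromosome[ii], pmap.position[ii], tmap.chromosome[qq], tmap.position[qq], window_bp)
        cis_j = _is_cis(pmap.chromosome[jj], pmap.position[jj], tmap.chromosome[qq], tmap.position[qq], window_bp)
        cls_idx = 2 - (cis_i.astype(int) + cis_j.astype(int))
        hit = np.nan_to_num(max_r2, nan=-1.0) > strong_r2
        for k, c in enumerate(CLASSES):
            sel = cls_idx == k
            evaluated[c] += int(sel.sum())
            strong[c] += int((sel & hit).sum())
    out = pd.DataFrame({"evaluated": pd.Series(evaluated), "strong": pd.Series(strong)})
    out["proportion"] = np.where(out["evaluated"] > 0, out["strong"] / out["evaluated"], np.nan)
    return out.rename_axis("class")
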