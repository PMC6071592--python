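"""Synthetic inbred populations with controllable high-order LD structure.

Everything the scans consume can be generated here, at desk scale, with the
statistical features the analysis assumes:

* :func:`sample_population` — i.i.d. draws of whole haplotypes from a
  :class:`HaplotypeTable` (one haplotype per individual: wild inbred
  accessions carry no heterozygosity).
* :func:`simulate_mosaic_genome` — a background genome where each individual
  is a recombination mosaic of a small founder set, giving LD that decays
  with bp distance within chromosomes and independence across chromosomes.
* :func:`make_fig1_scenario` — the minimal phantom-epistasis construction:
  a single causal locus Q whose minor allele is carried exactly by the ab
  two-locus class of a marker pair, so neither marker tags Q well but one
  pseudomarker tags it perfectly.
* :func:`make_complex_locus_scenario` — a linkage block of four hidden
  effect loci (three trait-increasing, one trait-decreasing) in incomplete
  mutual LD, jointly tagged by one cis and one trans predictor far better
  than by any single marker.
* :func:`simulate_phenotype` — additive (optionally truly epistatic)
  phenotypes with Gaussian noise under a known generative truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap, Phenotype

__all__ = [
    "HaplotypeTable",
    "ArchitectureSpec",
    "sample_population",
    "make_marker_map",
    "simulate_mosaic_genome",
    "split_panels",
    "make_fig1_scenario",
    "make_complex_locus_scenario",
    "simulate_phenotype",
]


@dataclass
class HaplotypeTable:
    """K haplotypes over L loci with sampling frequencies."""

    haplotypes: np.ndarray       # K x L, codes 0/1
    frequencies: np.ndarray      # K, sums to 1
    markers: MarkerMap

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 1:
            raise ValueError("haplotypes must be a K x L matrix with K >= 1")
        if self.frequencies.size != self.haplotypes.shape[0]:
            raise ValueError("one frequency per haplotype required")
        if (self.frequencies < 0).any() or abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be nonnegative and sum to 1")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype length must equal marker map length")


@dataclass
class ArchitectureSpec:
    """Which loci drive the phenotype and how.

    ``effects`` are per-minor-allele effects in trait units; in
    ``true_epistasis`` mode an additional ``interaction_effect`` acts on the
    +1/-1 product code of the first two causal loci.
    """

    causal_indices: tuple
    effects: tuple
    noise_sd: float = 0.5
    mode: str = "single_locus"   # single_locus | linked_block | true_epistasis
    interaction_effect: float = 0.0

    def __post_init__(self):
        if len(self.causal_indices) != len(self.effects):
            raise ValueError("one effect per causal locus required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in {"single_locus", "linked_block", "true_epistasis"}:
            raise ValueError(f"unknown mode {self.mode!r}")


def sample_population(table: HaplotypeTable, n: int, seed: int) -> GenotypeMatrix:
    """Draw ``n`` inbred individuals i.i.d. from the haplotype distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.haplotypes.shape[0], size=n, p=table.frequencies)
    ids = np.array([f"ind{k:05d}" for k in range(n)], dtype=object)
    return GenotypeMatrix(table.haplotypes[idx], ids, table.markers)


def make_marker_map(n_markers: int, seed: int, n_chromosomes: int = 5,
                    chrom_length_bp: int = 30_000_000) -> MarkerMap:
    """Markers at uniform random positions on equal-length chromosomes."""
    rng = np.random.default_rng(seed)
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    chroms, poss = [], []
    for c in range(n_chromosomes):
        pos = np.unique(rng.integers(1, chrom_length_bp + 1, size=2 * per[c]))
        while pos.size < per[c]:  # rare at realistic densities
            pos = np.unique(np.concatenate([pos, rng.integers(1, chrom_length_bp + 1, size=per[c])]))
        pos = np.sort(rng.choice(pos, size=per[c], replace=False))
        chroms.extend([f"chr{c + 1}"] * per[c])
        poss.extend(pos.tolist())
    ids = [f"m{k:06d}" for k in range(n_markers)]
    return MarkerMap.from_arrays(ids, chroms, poss)


def simulate_mosaic_genome(markers: MarkerMap, n: int, seed: int,
                           n_founders: int = 20,
                           recomb_per_bp: float = 1e-6) -> GenotypeMatrix:
    """Background genome of founder-haplotype recombination mosaics.

    Founder alleles are Bernoulli with per-site frequencies drawn from a
    U-shaped Beta(0.5, 0.5) spectrum (resampled once if monomorphic among
    founders). Each individual, independently per chromosome, is a mosaic of
    founder haplotypes with crossover counts Poisson in physical distance,
    so LD-r^2 decays with bp distance on the 1/``recomb_per_bp`` scale and
    chromosomes are mutually independent. Monomorphic sample columns are
    retained; filter with :meth:`GenotypeMatrix.filter_maf`.
    """
    if recomb_per_bp < 0:
        raise ValueError("recomb_per_bp must be >= 0")
    rng = np.random.default_rng(seed)
    L = len(markers)
    p = rng.beta(0.5, 0.5, size=L)
    founders = (rng.random((n_founders, L)) < p).astype(np.int8)
    mono = founders.min(axis=0) == founders.max(axis=0)
    if mono.any():  # one resampling pass toward polymorphism among founders
        founders[:, mono] = (rng.random((n_founders, int(mono.sum()))) < 0.5).astype(np.int8)

    codes = np.empty((n, L), dtype=np.int8)
    chrom = markers.chromosome.astype(str)
    for c in np.unique(chrom):
        cols = np.where(chrom == c)[0]
        pos = markers.position[cols].astype(float)
        span = float(pos[-1] - pos[0]) if cols.size > 1 else 0.0
        for ind in range(n):
            n_x = rng.poisson(span * recomb_per_bp) if span > 0 else 0
            breaks = np.sort(rng.uniform(pos[0], pos[-1], size=n_x)) if n_x else np.empty(0)
            seg = np.searchsorted(breaks, pos, side="right")
            founder_per_seg = rng.integers(0, n_founders, size=n_x + 1)
            codes[ind, cols] = founders[founder_per_seg[seg], cols]
    ids = np.array([f"ind{k:05d}" for k in range(n)], dtype=object)
    return GenotypeMatrix(codes, ids, markers)


def split_panels(G: GenotypeMatrix, n_predictors: int, seed: int):
    """Randomly split markers into a predictor panel and a target panel.

    Emulates the chip-vs-sequencing setting: a random subset of markers is
    'genotyped' (predictors) and the rest are the hidden targets.
    """
    if n_predictors >= G.n_markers:
        raise ValueError("need at least one target marker")
    rng = np.random.default_rng(seed)
    pred_idx = np.sort(rng.choice(G.n_markers, size=n_predictors, replace=False))
    targ_idx = np.setdiff1d(np.arange(G.n_markers), pred_idx)
    return G.subset_markers(pred_idx), G.subset_markers(targ_idx)


def make_fig1_scenario(n_per_class: int, seed: int = 0, noise_sd: float = 0.0):
    """Perfect two-locus tagging of a hidden causal locus.

    Four equally sized two-locus classes AB / Ab / aB / ab of a marker pair
    (M1, M2); the causal minor allele at the hidden locus Q is carried by
    exactly the ab individuals. Neither marker alone tags Q (r^2 = 1/3 at
    equal class sizes) but pseudomarker P4 = {ab vs rest} tags it perfectly.
    The phenotype is the causal-allele indicator plus optional Gaussian
    noise, so the generative model is single-locus additive: any fitted
    interaction between M1 and M2 is statistical epistasis born of the
    second-order LD alone.

    Returns ``(GenotypeMatrix with markers M1, M2, Q, Phenotype)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    block = np.array([[0, 0, 0],   # columns M1, M2, Q
                      [0, 1, 0],
                      [1, 0, 0],
                      [1, 1, 1]], dtype=np.int8)
    codes = np.repeat(block, n_per_class, axis=0)
    n = codes.shape[0]
    markers = MarkerMap.from_arrays(
        ["M1", "M2", "Q"],
        ["chr2", "chr3", "chr2"],
        [10_100_000, 5_000_000, 10_500_000],
    )
    ids = np.array([f"ind{k:05d}" for k in range(n)], dtype=object)
    G = GenotypeMatrix(codes[:, markers.sort_order], ids, markers)
    y = codes[:, 2].astype(float)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return G, Phenotype(ids, y)


def simulate_phenotype(G: GenotypeMatrix, spec: ArchitectureSpec, seed: int) -> Phenotype:
    """Phenotype with additive signed effects at the causal loci + noise.

    Each carried minor allele at causal locus k adds ``effects[k]`` trait
    units. In ``true_epistasis`` mode an extra ``interaction_effect`` times
    the +1/-1 product code of the first two causal loci is added.
    """
    for k in spec.causal_indices:
        if not 0 <= k < G.n_markers:
            raise ValueError(f"causal index {k} out of range")
    rng = np.random.default_rng(seed)
    y = np.zeros(G.n)
    for k, b in zip(spec.causal_indices, spec.effects):
        y += float(b) * (G.codes[:, k] == 1)
    if spec.mode == "true_epistasis" and len(spec.causal_indices) >= 2:
        from .epistasis import encode_additive

        a1 = encode_additive(G.codes[:, spec.causal_indices[0]])
        a2 = encode_additive(G.codes[:, spec.causal_indices[1]])
        y += spec.interaction_effect * np.nan_to_num(a1 * a2)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=G.n)
    return Phenotype(G.individual_ids, y)


# --- complex (multi-allelic-like) locus ------------------------------------

# Haplotype classes over the loci in (chromosome, position) order:
# [trans predictor T, mGWA1, mGWA2, ins326, del53, cis predictor C]. The
# four predictor-pair genotype classes each decompose into sub-haplotypes so
# the hidden loci are in incomplete mutual LD and the predictor pair — but
# no single predictor — separates the extreme causal-allele combinations.
_COMPLEX_HAPLOTYPES = np.array(
    [
        # T  m1 m2 i326 d53 C
        [0, 0, 0, 0, 0, 0],  # AACC, no causal minors
        [0, 1, 0, 0, 0, 0],  # AACC, mGWA1
        [0, 0, 0, 0, 0, 1],  # AATT, no causal minors
        [0, 1, 0, 0, 0, 1],  # AATT, mGWA1
        [1, 0, 0, 0, 1, 0],  # GGCC, del53 (trait-decreasing)
        [1, 1, 0, 0, 1, 0],  # GGCC, del53 + mGWA1
        [1, 1, 1, 1, 0, 1],  # GGTT, mGWA1 + mGWA2 + ins326
        [1, 0, 1, 1, 0, 1],  # GGTT, mGWA2 + ins326
    ],
    dtype=np.int8,
)
_COMPLEX_FREQUENCIES = np.array([0.20, 0.12, 0.16, 0.12, 0.15, 0.07, 0.12, 0.06])
_CAUSAL_NAMES = ("mGWA1", "mGWA2", "ins326", "del53")
_TRANS_IDX, _CIS_IDX = 0, 5
DEFAULT_COMPLEX_SPEC = ArchitectureSpec(
    causal_indices=(1, 2, 3, 4),
    effects=(1.0, 1.0, 1.0, -1.0),
    noise_sd=0.5,
    mode="linked_block",
)


def make_complex_locus_scenario(n: int = 340, seed: int = 0,
                                spec: ArchitectureSpec = None,
                                n_background: int = 100):
    """A hidden four-locus linkage block tagged by a cis-trans predictor pair.

    One chromosome-2 block carries four linked hidden effect loci (mGWA1,
    mGWA2, ins326 trait-increasing; del53 trait-decreasing) in incomplete
    mutual LD. The genotyped panel holds a trans predictor on chromosome 1,
    a cis predictor ~100 kb from the block, and ``n_background`` independent
    neutral markers; the causal loci themselves are excluded. The haplotype
    frequencies make the predictor-pair classes order low (GGCC) /
    intermediate (AACC, AATT) / high (GGTT) in expected phenotype.

    Returns ``(panel GenotypeMatrix, Phenotype, truth DataFrame)`` where the
    truth table lists each individual's predictor-pair class and carrier
    status at the four hidden loci.
    """
    if spec is None:
        spec = DEFAULT_COMPLEX_SPEC
    if spec.mode != "linked_block":
        raise ValueError("complex-locus scenario requires mode='linked_block'")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    focal_map = MarkerMap.from_arrays(
        ["trans_pred", "mGWA1", "mGWA2", "ins326", "del53", "cis_pred"],
        ["chr1", "chr2", "chr2", "chr2", "chr2", "chr2"],
        [5_315_502, 10_700_000, 10_750_000, 10_800_000, 10_850_000, 10_928_720],
    )
    table = HaplotypeTable(_COMPLEX_HAPLOTYPES, _COMPLEX_FREQUENCIES, focal_map)
    focal = sample_population(table, n, seed=int(seeds[0]))
    y = simulate_phenotype(focal, spec, seed=int(seeds[1]))

    # neutral background markers, independent of the focal block
    bg_map = make_marker_map(n_background, seed=int(seeds[2]))
    bg_p = np.random.default_rng(int(seeds[3])).uniform(0.1, 0.9, size=n_background)
    bg_codes = (np.random.default_rng(int(seeds[3]) + 1).random((n, n_background)) < bg_p).astype(np.int8)

    pred_cols = [_TRANS_IDX, _CIS_IDX]
    panel_codes = np.column_stack([focal.codes[:, pred_cols], bg_codes])
    panel_map = MarkerMap.from_arrays(
        np.concatenate([focal_map.marker_id[pred_cols], bg_map.marker_id]),
        np.concatenate([focal_map.chromosome[pred_cols], bg_map.chromosome]),
        np.concatenate([focal_map.position[pred_cols], bg_map.position]),
    )
    panel = GenotypeMatrix(panel_codes[:, panel_map.sort_order], focal.individual_ids, panel_map)

    tcode = focal.codes[:, _TRANS_IDX]
    ccode = focal.codes[:, _CIS_IDX]
    class_label = np.array(["AA", "GG"], dtype=object)[tcode] + np.array(["CC", "TT"], dtype=object)[ccode]
    truth = pd.DataFrame({"individual_id": focal.individual_ids, "pair_class": class_label})
    for k, name in zip(spec.causal_indices, _CAUSAL_NAMES):
        truth[name] = focal.codes[:, k]
    return panel, y, truth
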