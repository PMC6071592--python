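"""Genotype matrices for inbred, bi-allelic populations.

The data model is deliberately minimal: a population of inbred (effectively
haploid) individuals is an ``n_individuals x n_markers`` matrix of codes

* ``0`` — homozygote for the major (more frequent) allele,
* ``1`` — homozygote for the minor allele,
* ``MISSING`` (``-1``) — no call.

Because the individuals are inbred, genotype frequencies equal allele
frequencies and genotype columns can be treated as haplotypes in all LD
arithmetic. Marker metadata (chromosome, 1-based bp position, alleles) lives
in a :class:`MarkerMap` kept sorted by (chromosome, position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Integer code for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1})


class EmptyPanelError(ValueError):
    """Raised when filtering removes every marker from a panel."""


@dataclass(frozen=True)
class MarkerMap:
    """Locations and alleles of the markers of a :class:`GenotypeMatrix`.

    Markers are sorted by (chromosome label, position); (chromosome,
    position) pairs must be unique and positions strictly positive
    (1-based, as in VCF).
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    allele_major: np.ndarray
    allele_minor: np.ndarray

    @classmethod
    def from_arrays(
        cls,
        marker_id,
        chromosome,
        position,
        allele_major=None,
        allele_minor=None,
    ) -> "MarkerMap":
        marker_id = np.asarray(marker_id, dtype=object)
        chromosome = np.asarray(chromosome, dtype=object)
        position = np.asarray(position, dtype=np.int64)
        m = marker_id.size
        if allele_major is None:
            allele_major = np.full(m, "A", dtype=object)
        if allele_minor is None:
            allele_minor = np.full(m, "a", dtype=object)
        allele_major = np.asarray(allele_major, dtype=object)
        allele_minor = np.asarray(allele_minor, dtype=object)
        if not (chromosome.size == position.size == m == allele_major.size == allele_minor.size):
            raise ValueError("marker map arrays must have equal length")
        if m and position.min() <= 0:
            raise ValueError("positions must be strictly positive (1-based)")
        order = np.lexsort((position, chromosome.astype(str)))
        mm = cls(
            marker_id=marker_id[order],
            chromosome=chromosome[order],
            position=position[order],
            allele_major=allele_major[order],
            allele_minor=allele_minor[order],
        )
        key = list(zip(mm.chromosome, mm.position))
        if len(set(key)) != m:
            raise ValueError("(chromosome, position) pairs must be unique")
        object.__setattr__(mm, "_order", order)
        return mm

    @property
    def sort_order(self) -> np.ndarray:
        """Permutation applied to the input arrays during construction."""
        return getattr(self, "_order", np.arange(len(self)))

    def __len__(self) -> int:
        return int(self.marker_id.size)

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        mm = MarkerMap(
            marker_id=self.marker_id[idx],
            chromosome=self.chromosome[idx],
            position=self.position[idx],
            allele_major=self.allele_major[idx],
            allele_minor=self.allele_minor[idx],
        )
        return mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "allele_major": self.allele_major,
                "allele_minor": self.allele_minor,
            }
        )


def compute_maf(g) -> float:
    """Minor-allele frequency of one genotype column.

    For inbred individuals the minor-homozygote frequency equals the minor
    allele frequency, so this is ``min(p, 1 - p)`` of the frequency of code 1
    among non-missing entries.
    """
    g = np.asarray(g)
    ok = g != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all-missing genotype column")
    p = float((g[ok] == 1).sum()) / n
    return min(p, 1.0 - p)


@dataclass
class GenotypeMatrix:
    """Inbred bi-allelic genotypes for ``n`` individuals at ``m`` markers."""

    codes: np.ndarray
    individual_ids: np.ndarray
    markers: MarkerMap

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-dimensional (individuals x markers)")
        if self.codes.shape[0] != self.individual_ids.size:
            raise ValueError("row count must equal number of individual ids")
        if self.codes.shape[1] != len(self.markers):
            raise ValueError("column count must equal marker map length")
        if len(set(self.individual_ids)) != self.individual_ids.size:
            raise ValueError("duplicated individual ids")
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    # spec field name alias
    @property
    def map(self) -> MarkerMap:
        return self.markers

    @property
    def n(self) -> int:
        """Sample size."""
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def column(self, k: int) -> np.ndarray:
        return self.codes[:, k]

    def maf(self) -> np.ndarray:
        """Per-column minor-allele frequency (nan for all-missing columns)."""
        ok = self.codes != MISSING
        n_ok = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_ok > 0, (self.codes == 1).sum(axis=0) / np.maximum(n_ok, 1), np.nan)
        out = np.minimum(p, 1.0 - p)
        out[n_ok == 0] = np.nan
        return out

    def filter_maf(self, maf_min: float, allow_empty: bool = False) -> "GenotypeMatrix":
        """Keep markers with MAF strictly greater than ``maf_min``.

        The threshold is strict: a marker at exactly the threshold is
        dropped ("MAF > t"). ``maf_min = 0`` keeps exactly the polymorphic
        markers.
        """
        maf = self.maf()
        keep = np.where(np.nan_to_num(maf, nan=-1.0) > maf_min)[0]
        n_drop = self.n_markers - keep.size
        if n_drop:
            logger.info("filter_maf(%g): dropped %d of %d markers", maf_min, n_drop, self.n_markers)
        if keep.size == 0 and not allow_empty:
            raise EmptyPanelError(f"no markers left after MAF > {maf_min} filter")
        return self.subset_markers(keep)

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(self.codes[:, idx], self.individual_ids, self.markers.subset(idx))

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(self.codes[idx], self.individual_ids[idx], self.markers)

    def align_to(self, ids) -> "GenotypeMatrix":
        """Reorder rows to match ``ids`` (all must be present)."""
        lookup = {i: k for k, i in enumerate(self.individual_ids)}
        try:
            idx = np.array([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"individual id not in genotype matrix: {e.args[0]!r}") from None
        return self.subset_individuals(idx)

    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def write_table(self, path, orientation: str = "markers_in_rows", sep: str = "\t") -> None:
        write_table(self, path, orientation=orientation, sep=sep)


@dataclass
class Phenotype:
    """One quantitative trait value per individual (arbitrary units)."""

    individual_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.individual_ids.size != self.values.size:
            raise ValueError("ids and values must have equal length")
        if len(set(self.individual_ids)) != self.individual_ids.size:
            raise ValueError("duplicated individual ids in phenotype")

    def __len__(self) -> int:
        return int(self.values.size)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.individual_ids, name="value")

    def write_table(self, path, sep: str = "\t") -> None:
        pd.DataFrame({"individual_id": self.individual_ids, "value": self.values}).to_csv(
            path, sep=sep, index=False
        )


def read_phenotype(path, sep=None) -> Phenotype:
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs two columns: id, value")
    return Phenotype(df.iloc[:, 0].astype(str).to_numpy(), df.iloc[:, 1].to_numpy(dtype=float))


def align(G: GenotypeMatrix, phen: Phenotype):
    """Join a genotype matrix with a phenotype on individual id.

    Returns ``(G_aligned, y)`` restricted to the shared individuals, in the
    genotype matrix's id order.
    """
    shared = [i for i in G.individual_ids if i in set(phen.individual_ids)]
    if not shared:
        raise ValueError("no shared individual ids between genotypes and phenotype")
    Ga = G.align_to(shared)
    y = phen.to_series().loc[shared].to_numpy()
    return Ga, y


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _orient_major(codes: np.ndarray, ref, alt):
    """Flip columns so code 0 is the major allele; return allele arrays."""
    m = codes.shape[1]
    major = np.asarray(ref, dtype=object).copy()
    minor = np.asarray(alt, dtype=object).copy()
    ok = codes != MISSING
    n_ok = np.maximum(ok.sum(axis=0), 1)
    p_alt = (codes == 1).sum(axis=0) / n_ok
    flip = p_alt > 0.5
    for j in np.where(flip)[0]:
        col = codes[:, j]
        swap = col != MISSING
        codes[swap, j] = 1 - col[swap]
        major[j], minor[j] = minor[j], major[j]
    return codes, major, minor


def read_vcf(path, maf_min: float = 0.0, het_policy: str = "missing") -> GenotypeMatrix:
    """Read inbred genotypes from a VCF (GT field, bi-allelic SNPs only).

    Heterozygous calls should be rare in inbred material; ``het_policy``
    decides their fate: ``missing`` (default) treats them as no-calls,
    ``drop_marker`` removes the whole marker, ``error`` raises. Markers with
    MAF not strictly greater than ``maf_min`` are dropped.
    """
    from cyvcf2 import VCF

    if het_policy not in {"missing", "drop_marker", "error"}:
        raise ValueError(f"unknown het_policy {het_policy!r}")

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    cols, mid, chrom, pos, ref, alt = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types)  # cyvcf2: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.full(gt.size, MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 1
        het = gt == 1
        if het.any():
            if het_policy == "error":
                raise ValueError(f"heterozygous call at {var.CHROM}:{var.POS}")
            if het_policy == "drop_marker":
                continue
            # het_policy == "missing": leave as MISSING
        cols.append(col)
        mid.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-bi-allelic-SNP records", n_skipped)
    if not cols:
        raise EmptyPanelError("no bi-allelic SNP records in VCF")
    codes = np.column_stack(cols)
    codes, major, minor = _orient_major(codes, ref, alt)
    mm = MarkerMap.from_arrays(mid, chrom, pos, major, minor)
    G = GenotypeMatrix(codes[:, mm.sort_order], samples, mm)
    return G.filter_maf(maf_min)


_META_ROWS = ("#chromosome", "#position", "#allele_major", "#allele_minor")


def write_table(G: GenotypeMatrix, path, orientation: str = "markers_in_rows", sep: str = "\t") -> None:
    """Write a genotype matrix as delimited text (codes 0/1, missing as NA)."""
    vals = G.codes.astype(object)
    vals[G.codes == MISSING] = "NA"
    if orientation == "markers_in_rows":
        df = G.markers.to_frame()
        body = pd.DataFrame(vals.T, columns=G.individual_ids)
        pd.concat([df.reset_index(drop=True), body.reset_index(drop=True)], axis=1).to_csv(
            path, sep=sep, index=False
        )
    elif orientation == "markers_in_columns":
        rows = []
        rows.append(["#chromosome"] + list(G.markers.chromosome))
        rows.append(["#position"] + [str(p) for p in G.markers.position])
        rows.append(["#allele_major"] + list(G.markers.allele_major))
        rows.append(["#allele_minor"] + list(G.markers.allele_minor))
        header = ["individual_id"] + list(G.markers.marker_id)
        with open(path, "w") as fh:
            fh.write(sep.join(header) + "\n")
            for r in rows:
                fh.write(sep.join(str(x) for x in r) + "\n")
            for i, ind in enumerate(G.individual_ids):
                fh.write(sep.join([str(ind)] + [str(v) for v in vals[i]]) + "\n")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


def _codes_from_strings(arr) -> np.ndarray:
    out = np.full(arr.shape, MISSING, dtype=np.int8)
    s = np.char.strip(arr.astype(str))
    out[s == "0"] = 0
    out[s == "1"] = 1
    bad = ~np.isin(s, ("0", "1", "NA", "nan", ""))
    if bad.any():
        raise ValueError(f"non {{0,1,NA}} genotype codes in table, e.g. {s[bad][0]!r}")
    return out


def read_table(path, orientation: str = "markers_in_rows", sep: str = "\t") -> GenotypeMatrix:
    """Read a genotype matrix written by :func:`write_table`."""
    if orientation == "markers_in_rows":
        df = pd.read_csv(path, sep=sep, dtype=str, comment=None)
        meta_cols = [c for c in ("marker_id", "chromosome", "position", "allele_major", "allele_minor") if c in df.columns]
        if "chromosome" not in meta_cols or "position" not in meta_cols:
            raise ValueError("table must carry chromosome and position columns")
        ind_ids = [c for c in df.columns if c not in meta_cols]
        codes = _codes_from_strings(df[ind_ids].to_numpy()).T  # individuals x markers
        mm = MarkerMap.from_arrays(
            df["marker_id"].to_numpy(object) if "marker_id" in df else np.arange(len(df)).astype(str),
            df["chromosome"].to_numpy(object),
            df["position"].to_numpy(np.int64),
            df["allele_major"].to_numpy(object) if "allele_major" in df else None,
            df["allele_minor"].to_numpy(object) if "allele_minor" in df else None,
        )
        return GenotypeMatrix(codes[:, mm.sort_order], np.asarray(ind_ids, dtype=object), mm)
    elif orientation == "markers_in_columns":
        df = pd.read_csv(path, sep=sep, dtype=str, header=0)
        first = df.iloc[:, 0].astype(str)
        meta = {name: df[first == name].iloc[0, 1:] for name in _META_ROWS if (first == name).any()}
        if "#chromosome" not in meta or "#position" not in meta:
            raise ValueError("table must carry #chromosome and #position rows")
        body = df[~first.str.startswith("#")]
        ind_ids = body.iloc[:, 0].astype(str).to_numpy(object)
        codes = _codes_from_strings(body.iloc[:, 1:].to_numpy())
        mm = MarkerMap.from_arrays(
            np.asarray(df.columns[1:], dtype=object),
            meta["#chromosome"].to_numpy(object),
            meta["#position"].to_numpy(np.int64),
            meta.get("#allele_major", pd.Series()).to_numpy(object) if "#allele_major" in meta else None,
            meta.get("#allele_minor", pd.Series()).to_numpy(object) if "#allele_minor" in meta else None,
        )
        return GenotypeMatrix(codes[:, mm.sort_order], ind_ids, mm)
    raise ValueError(f"unknown orientation {orientation!r}")


def subsample_individuals(G: GenotypeMatrix, n_sub: int, seed: int, maf_min: float = 0.0) -> GenotypeMatrix:
    """Uniform subsample of individuals without replacement, seeded.

    Columns are re-checked after subsampling: markers that became
    monomorphic (or fell at/below ``maf_min``) are dropped and logged.
    """
    if n_sub > G.n:
        raise ValueError(f"n_sub={n_sub} exceeds sample size n={G.n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(G.n, size=n_sub, replace=False))
    sub = G.subset_individuals(idx)
    return sub.filter_maf(maf_min)
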