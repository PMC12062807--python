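"""Genotype container, VCF/GFF3/sample-map IO, and site-level QC.

The central object is :class:`GenotypeMatrix`: an individuals x sites
matrix of alt-allele dosages (0/1/2, -1 for missing) with ordered site
and sample metadata.  QC follows the two-stage chain used for duck
resequencing panels: a biallelic/rare-allele/missingness pass
(minor-allele frequency >= 0.01, site missingness <= 0.9) followed by a
stricter MAF >= 0.05 and Hardy-Weinberg exact-test p >= 1e-6 pass over
all samples pooled.

Internal coordinates are 0-based half-open; VCF and GFF3 stay 1-based at
the file boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with site and sample metadata.

    Parameters
    ----------
    dosage : int8 ndarray, shape (n_samples, n_sites)
        Alt-allele count per genotype; -1 encodes missing.
    sites : DataFrame with columns chrom, pos (1-based), ref, alt,
        sorted by (chrom, pos) with no duplicate positions.
    samples : list of sample ids, matching dosage rows.
    chrom_lengths : optional chromosome lengths (bp); derived from the
        largest observed position when absent.
    """

    dosage: np.ndarray
    sites: pd.DataFrame
    samples: list[str]
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x sites)")
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)
        key = list(zip(self.sites["chrom"], self.sites["pos"]))
        if any(key[i] >= key[i + 1] for i in range(len(key) - 1)):
            raise ValueError("sites must be sorted by (chrom, pos) without duplicates")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_length(self, chrom: str) -> int:
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        pos = self.sites.loc[self.sites["chrom"] == chrom, "pos"]
        return int(pos.max())

    def site_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def positions0(self, chrom: str) -> np.ndarray:
        """0-based positions on one chromosome."""
        return self.sites.loc[self.sites["chrom"] == chrom, "pos"].to_numpy() - 1

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage[:, index],
            self.sites.iloc[np.asarray(index)].reset_index(drop=True),
            list(self.samples),
            self.chrom_lengths,
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        idx = [order[s] for s in ids]
        return GenotypeMatrix(self.dosage[idx, :], self.sites.copy(), list(ids), self.chrom_lengths)

    # --- per-site pooled counts -------------------------------------------------
    def called(self) -> np.ndarray:
        return (self.dosage != MISSING).sum(axis=0)

    def alt_counts(self) -> np.ndarray:
        d = self.dosage.astype(np.int64)
        return np.where(self.dosage == MISSING, 0, d).sum(axis=0)

    def het_counts(self) -> np.ndarray:
        return (self.dosage == 1).sum(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency over called alleles; NaN where no calls."""
        n = self.called()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.alt_counts() / (2.0 * n), np.nan)

    def minor_af(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)


class SampleMap:
    """sample_id -> (population, breed, type) assignment.

    ``population`` is the coarse wild/local/commercial grouping; ``breed``
    is free text; ``type`` is wild/egg/dual/meat (the egg vs dual split
    partitions the local population).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "population", "breed", "type"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sample map missing columns: {sorted(missing)}")
        if frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample map")
        self.frame = frame.reset_index(drop=True)
        self._by_id = self.frame.set_index("sample_id")

    def __len__(self) -> int:
        return len(self.frame)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.frame["population"]))

    def samples_in(self, population: str | None = None, type_: str | None = None) -> list[str]:
        f = self.frame
        if population is not None:
            f = f[f["population"] == population]
        if type_ is not None:
            f = f[f["type"] == type_]
        return list(f["sample_id"])

    def population_of(self, sample_id: str) -> str:
        return str(self._by_id.loc[sample_id, "population"])

    def subset(self, ids: list[str]) -> "SampleMap":
        keep = self.frame[self.frame["sample_id"].isin(set(ids))]
        return SampleMap(keep)

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SampleMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class SiteCounts:
    """Per-group, per-site genotype counts (the p_i, h_i, n_i of Fst).

    Arrays are shaped (n_groups, n_sites).
    """

    groups: list[str]
    n_called: np.ndarray
    alt_count: np.ndarray
    het_count: np.ndarray
    missing_count: np.ndarray

    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_called > 0, self.alt_count / (2.0 * self.n_called), np.nan)

    def het_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_called > 0, self.het_count / self.n_called, np.nan)

    def row(self, group: str) -> "SiteCounts":
        i = self.groups.index(group)
        return SiteCounts(
            [group],
            self.n_called[i : i + 1],
            self.alt_count[i : i + 1],
            self.het_count[i : i + 1],
            self.missing_count[i : i + 1],
        )


@dataclass
class GeneSet:
    """Gene intervals from GFF3, stored 0-based half-open."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
    )

    def __len__(self) -> int:
        return len(self.frame)


# ----------------------------------------------------------------------------
# VCF IO
# ----------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with GT fields into a GenotypeMatrix.

    Dosage is the alt-allele count of each diploid genotype.  Half-calls
    and non-diploid genotypes become missing.  Multi-allelic records are
    dropped (not split); duplicate (chrom, pos) records are an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    lengths: dict[str, int] = {}
    for name, ln in zip(vcf.seqnames, vcf.seqlens or []):
        lengths[name] = int(ln)

    rows = []
    meta = []
    seen: set[tuple[str, int]] = set()
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        key = (variant.CHROM, variant.POS)
        if key in seen:
            raise ValueError(f"duplicate position {key} in {path}")
        seen.add(key)
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2 or min(alleles) < 0:
                continue
            dos[i] = alleles[0] + alleles[1]
        rows.append(dos)
        meta.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    vcf.close()

    sites = pd.DataFrame(meta, columns=SITE_COLUMNS)
    dosage = np.vstack(rows).T if rows else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(dosage, sites, samples, lengths or None)


_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a GT-only VCFv4.2 file (deterministic byte output)."""
    lines = ["##fileformat=VCFv4.2", "##source=lsblscan"]
    for chrom in geno.chroms():
        lines.append(f"##contig=<ID={chrom},length={geno.chrom_length(chrom)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples))

    gt_idx = np.where(geno.dosage == MISSING, 3, geno.dosage).astype(np.int8)
    gts = _GT_STRINGS[gt_idx]  # (samples, sites)
    sites = geno.sites
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j in range(geno.n_sites):
            row = sites.iloc[j]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts[:, j])
                + "\n"
            )


# ----------------------------------------------------------------------------
# QC filters
# ----------------------------------------------------------------------------

def filter_biallelic(
    geno: GenotypeMatrix,
    min_minor_af: float = 0.01,
    max_missing_frac: float = 0.9,
) -> GenotypeMatrix:
    """First-stage site QC: polymorphic biallelic SNPs with MAF >= ``min_minor_af``
    (on called alleles) and missing fraction <= ``max_missing_frac``.
    """
    n = geno.called()
    maf = geno.minor_af()
    miss_frac = 1.0 - n / geno.n_samples
    with np.errstate(invalid="ignore"):
        keep = (n > 0) & (maf >= min_minor_af) & (maf > 0) & (miss_frac <= max_missing_frac)
    if not keep.any():
        warnings.warn("no sites pass the biallelic/MAF/missingness filter")
    return geno.take_sites(np.flatnonzero(keep))


def filter_maf_hwe(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Second-stage QC: drop sites with MAF < ``maf_min`` or Hardy-Weinberg
    exact-test p < ``hwe_p_min`` (test pooled over all samples).

    Both filters are strict "<": a site sitting exactly at either
    threshold is retained.
    """
    maf = geno.minor_af()
    n_hom_alt = (geno.dosage == 2).sum(axis=0)
    n_het = geno.het_counts()
    n_hom_ref = (geno.dosage == 0).sum(axis=0)
    pvals = hwe_exact_p_vector(n_hom_ref, n_het, n_hom_alt)
    with np.errstate(invalid="ignore"):
        keep = (maf >= maf_min) & (pvals >= hwe_p_min)
    keep &= ~np.isnan(maf)
    if not keep.any():
        warnings.warn("no sites pass the MAF/HWE filter")
    return geno.take_sites(np.flatnonzero(keep))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (plain, non-mid p).

    Conditions on the observed allele counts and sums the probabilities
    of every heterozygote count of the same parity whose probability does
    not exceed the observed configuration's.  An all-missing site is
    undefined; p = 1 is returned.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_alt + n_het  # alt allele count
    n_b = 2 * n_hom_ref + n_het

    # log P(het = h | allele counts) up to the common normalizer
    lg = math.lgamma

    def logw(h: int) -> float:
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        return h * math.log(2.0) - lg(hom_a + 1) - lg(h + 1) - lg(hom_b + 1)

    hets = range(n_a % 2, min(n_a, n_b) + 1, 2)
    logs = np.array([logw(h) for h in hets])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    obs = probs[(n_het - (n_a % 2)) // 2]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_exact_p_vector(n_hom_ref, n_het, n_hom_alt) -> np.ndarray:
    """Vector form of :func:`hwe_exact_p`, memoized on the count triple."""
    cache: dict[tuple[int, int, int], float] = {}
    out = np.empty(len(n_het), dtype=float)
    for j, key in enumerate(zip(n_hom_ref, n_het, n_hom_alt)):
        key = (int(key[0]), int(key[1]), int(key[2]))
        if key not in cache:
            cache[key] = hwe_exact_p(*key)
        out[j] = cache[key]
    return out


# ----------------------------------------------------------------------------
# GFF3 genes and grouped counts
# ----------------------------------------------------------------------------

def read_gff_genes(path) -> GeneSet:
    """Extract gene features from a GFF3 into half-open 0-based intervals.

    The gene id is taken from the ID attribute (falling back to Name);
    files without gene rows yield an empty set with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name") or [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    if not rows:
        warnings.warn(f"no gene features found in {path}")
        return GeneSet()
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if (frame["start"] >= frame["end"]).any():
        raise ValueError("gene with non-positive length after coordinate conversion")
    return GeneSet(frame)


def group_site_counts(
    geno: GenotypeMatrix,
    samplemap: SampleMap,
    grouping: dict[str, list[str]] | str = "population",
) -> SiteCounts:
    """Per-site genotype counts for each group of samples.

    ``grouping`` is either the name of a sample-map column whose values
    define groups, or an explicit {group: [sample ids]} mapping.
    """
    if isinstance(grouping, str):
        col = samplemap.frame[samplemap.frame["sample_id"].isin(set(geno.samples))]
        groups = {g: list(sub["sample_id"]) for g, sub in col.groupby(grouping, sort=False)}
    else:
        groups = grouping
    names = list(groups)
    order = {s: i for i, s in enumerate(geno.samples)}
    n_called = np.zeros((len(names), geno.n_sites), dtype=np.int64)
    alt = np.zeros_like(n_called)
    het = np.zeros_like(n_called)
    missing = np.zeros_like(n_called)
    for gi, name in enumerate(names):
        ids = groups[name]
        unknown = [s for s in ids if s not in order]
        if unknown:
            raise KeyError(f"samples not in matrix: {unknown[:3]}")
        block = geno.dosage[[order[s] for s in ids], :]
        called = block != MISSING
        n_called[gi] = called.sum(axis=0)
        alt[gi] = np.where(called, block, 0).sum(axis=0)
        het[gi] = (block == 1).sum(axis=0)
        missing[gi] = (~called).sum(axis=0)
    return SiteCounts(names, n_called, alt, het, missing)
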