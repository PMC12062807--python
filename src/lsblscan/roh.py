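"""Scanning-window detection of runs of homozygosity (ROH).

The algorithm mirrors the classic genotype-count scanning approach: a
50-SNP window slides one SNP at a time along each chromosome and is
called homozygous when it contains at most ``window_het`` heterozygous
and ``window_missing`` missing calls.  Each SNP's hit fraction is the
proportion of windows containing it that were called homozygous (the
denominator shrinks at chromosome edges to the windows that actually
exist).  SNPs at or above ``window_threshold`` are eligible; maximal
runs of consecutive eligible SNPs, split at inter-SNP gaps above
``gap_kb``, become segments and are kept when they meet the minimum SNP
count, minimum length, and SNP-density requirements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lsblscan.variants import MISSING, GenotypeMatrix, SampleMap


@dataclass
class RohParams:
    """Scanning parameters; defaults are the standard --homozyg set
    (window-snp 50, window-het 1, window-missing 5, window-threshold
    0.05, snp 50, density 500 kb/SNP, gap 1000 kb, min length 1000 kb)."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 50
    min_kb: float = 1000.0
    density_kb_per_snp: float = 500.0
    gap_kb: float = 1000.0

    def validate(self) -> None:
        if min(self.window_snp, self.window_het + 1, self.window_missing + 1, self.min_snp) < 1:
            raise ValueError("ROH counts must be positive")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")
        if min(self.min_kb, self.density_kb_per_snp, self.gap_kb) <= 0:
            raise ValueError("kb parameters must be positive")


@dataclass
class RohSegment:
    sample_id: str
    chrom: str
    start: int  # 1-based bp of first SNP in segment
    end: int  # 1-based bp of last SNP
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _eligible_snps(dos: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean eligibility per SNP on one chromosome (hit-fraction rule)."""
    s = dos.size
    w = params.window_snp
    if s < w:
        return np.zeros(s, dtype=bool)
    het = (dos == 1).astype(np.int64)
    mis = (dos == MISSING).astype(np.int64)
    hom_window = (_sliding_sum(het, w) <= params.window_het) & (
        _sliding_sum(mis, w) <= params.window_missing
    )
    n_windows = s - w + 1
    hcum = np.concatenate([[0], np.cumsum(hom_window)])
    idx = np.arange(s)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(n_windows, idx + 1)
    hits = hcum[hi] - hcum[lo]
    denom = hi - lo
    return hits / denom >= params.window_threshold


def detect_roh(
    dosage_row: np.ndarray,
    sites: pd.DataFrame,
    params: RohParams | None = None,
    sample_id: str = "",
) -> list[RohSegment]:
    """Call ROH segments for one individual.

    ``dosage_row`` is the individual's dosage vector over ``sites``
    (sorted by chrom, pos).  Chromosomes with fewer SNPs than the
    scanning window produce no calls.
    """
    params = params or RohParams()
    params.validate()
    segments: list[RohSegment] = []
    gap_bp = params.gap_kb * 1000.0
    for chrom, sub in sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        eligible = _eligible_snps(dosage_row[idx], params)
        # maximal runs of eligible SNPs, split at large gaps
        j = 0
        s = eligible.size
        while j < s:
            if not eligible[j]:
                j += 1
                continue
            k = j
            while k + 1 < s and eligible[k + 1] and pos[k + 1] - pos[k] <= gap_bp:
                k += 1
            seg = RohSegment(sample_id, str(chrom), int(pos[j]), int(pos[k]), k - j + 1)
            if (
                seg.n_snps >= params.min_snp
                and seg.length >= params.min_kb * 1000.0
                and seg.length / 1000.0 / seg.n_snps <= params.density_kb_per_snp
            ):
                segments.append(seg)
            j = k + 1
    return segments


def detect_roh_all(
    geno: GenotypeMatrix, params: RohParams | None = None
) -> list[RohSegment]:
    segs: list[RohSegment] = []
    for i, sample in enumerate(geno.samples):
        segs.extend(detect_roh(geno.dosage[i], geno.sites, params, sample))
    return segs


def validate_segment(
    seg: RohSegment,
    dosage_row: np.ndarray,
    sites: pd.DataFrame,
    params: RohParams,
) -> bool:
    """Independently re-check a called segment against every constraint:
    SNP count, length, density, internal gaps, and SNP eligibility."""
    sub = sites[(sites["chrom"] == seg.chrom)]
    idx = sub.index.to_numpy()
    pos = sub["pos"].to_numpy()
    inside = (pos >= seg.start) & (pos <= seg.end)
    n_snps = int(inside.sum())
    if n_snps != seg.n_snps or n_snps < params.min_snp:
        return False
    if seg.length < params.min_kb * 1000.0:
        return False
    if seg.length / 1000.0 / n_snps > params.density_kb_per_snp:
        return False
    if np.any(np.diff(pos[inside]) > params.gap_kb * 1000.0):
        return False
    eligible = _eligible_snps(dosage_row[idx], params)
    return bool(eligible[inside].all())


def segments_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.chrom, s.start, s.end, s.n_snps, s.length / 1000.0) for s in segments],
        columns=["sample_id", "chrom", "start", "end", "n_snps", "kb"],
    )


def roh_summary(
    segments: list[RohSegment], samplemap: SampleMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual (count, total kb, mean kb) and per-population
    (mean +/- sd segment length in kb) ROH summaries.

    Individuals with no segments appear with zeros.
    """
    frame = segments_frame(segments)
    per_ind_rows = []
    for sample in samplemap.frame["sample_id"]:
        sub = frame[frame["sample_id"] == sample]
        per_ind_rows.append(
            (
                sample,
                samplemap.population_of(sample),
                len(sub),
                float(sub["kb"].sum()),
                float(sub["kb"].mean()) if len(sub) else 0.0,
            )
        )
    per_ind = pd.DataFrame(
        per_ind_rows, columns=["sample_id", "population", "n_segments", "total_kb", "mean_kb"]
    )
    pop_rows = []
    pop_of = {s: samplemap.population_of(s) for s in samplemap.frame["sample_id"]}
    frame = frame.assign(population=frame["sample_id"].map(pop_of))
    for pop in samplemap.populations():
        lengths = frame.loc[frame["population"] == pop, "kb"].to_numpy()
        pop_rows.append(
            (
                pop,
                len(lengths),
                float(lengths.mean()) if lengths.size else 0.0,
                float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0,
            )
        )
    per_pop = pd.DataFrame(pop_rows, columns=["population", "n_segments", "mean_kb", "sd_kb"])
    return per_ind, per_pop
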