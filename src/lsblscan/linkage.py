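"""Genotype-dosage LD: pairwise r^2, decay curves, pruning, and Ne.

r^2 is the squared Pearson correlation of dosage vectors over
pairwise-complete individuals — the unphased-diploid measure the usual
LD-decay tools report.  Effective population size is recovered from
binned r^2 through Sved's relation E[r^2] = 1/(alpha + 4 N c): each
distance bin maps to a recombination fraction c (linear map, default
1 cM/Mb), its sample-size-adjusted mean r^2 (r^2 - 1/(2n)) is inverted
to Ne = (1/(4c)) (1/r^2_adj - alpha), and the bin's midpoint dates the
estimate at t = 1/(2c) generations ago.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lsblscan.variants import MISSING, GenotypeMatrix


def genotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    NaN when fewer than two complete pairs remain or either site is
    monomorphic among them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING) & (b != MISSING) & ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pair_r2_block(dos: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """Vectorized r^2 for many site pairs; dos is (samples, sites) with -1 missing."""
    a = dos[:, i_idx].astype(np.float64)
    b = dos[:, j_idx].astype(np.float64)
    ok = (a >= 0) & (b >= 0)
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    n = ok.sum(axis=0).astype(float)
    sa = a.sum(axis=0)
    sb = b.sum(axis=0)
    saa = (a * a).sum(axis=0)
    sbb = (b * b).sum(axis=0)
    sab = (a * b).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sab - sa * sb / n
        va = saa - sa * sa / n
        vb = sbb - sb * sb / n
        r2 = (cov * cov) / (va * vb)
    r2[(n < 2) | (va <= 0) | (vb <= 0)] = np.nan
    return r2


@dataclass
class LdBin:
    distance_low: int
    distance_high: int
    n_pairs: int
    mean_r2: float

    def midpoint(self) -> float:
        return 0.5 * (self.distance_low + self.distance_high)


def ld_decay(
    geno: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_width: int = 25_000,
    max_pairs_per_bin: int = 500_000,
    seed: int = 0,
    _chunk: int = 200_000,
) -> pd.DataFrame:
    """Mean r^2 by physical-distance bin over all intra-chromosome pairs.

    Pairs beyond ``max_pairs_per_bin`` per bin are subsampled with the
    given seed.  Empty bins are emitted with n_pairs 0 and NaN mean.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    pair_i: list[np.ndarray] = [[] for _ in range(n_bins)]
    pair_j: list[np.ndarray] = [[] for _ in range(n_bins)]
    for chrom in geno.chroms():
        offset = np.flatnonzero(geno.site_mask(chrom))
        pos = geno.sites.loc[offset, "pos"].to_numpy()
        if pos.size < 2:
            continue
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        counts = np.maximum(hi - np.arange(pos.size) - 1, 0)
        total = int(counts.sum())
        if total == 0:
            continue
        ii = np.repeat(np.arange(pos.size), counts)
        starts = np.cumsum(counts) - counts
        jj = np.arange(total) - starts[ii] + ii + 1
        d = pos[jj] - pos[ii]
        b = np.minimum((d - 1) // bin_width, n_bins - 1)
        order = np.argsort(b, kind="stable")
        bounds = np.searchsorted(b[order], np.arange(n_bins + 1))
        for bb in range(n_bins):
            sel = order[bounds[bb] : bounds[bb + 1]]
            if sel.size:
                pair_i[bb].append(offset[ii[sel]])
                pair_j[bb].append(offset[jj[sel]])
    rows = []
    for bb in range(n_bins):
        if pair_i[bb]:
            ii = np.concatenate(pair_i[bb])
            jj = np.concatenate(pair_j[bb])
            if ii.size > max_pairs_per_bin:
                sel = rng.choice(ii.size, size=max_pairs_per_bin, replace=False)
                ii, jj = ii[sel], jj[sel]
            vals = []
            for c0 in range(0, ii.size, _chunk):
                vals.append(_pair_r2_block(geno.dosage, ii[c0 : c0 + _chunk], jj[c0 : c0 + _chunk]))
            r2 = np.concatenate(vals)
            r2 = r2[~np.isnan(r2)]
        else:
            r2 = np.array([])
        rows.append(
            (
                int(edges[bb]),
                int(edges[bb + 1]),
                int(r2.size),
                float(r2.mean()) if r2.size else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["distance_low", "distance_high", "n_pairs", "mean_r2"])


def ld_prune(
    geno: GenotypeMatrix,
    window_snp: int = 50,
    step_snp: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy LD pruning (the --indep-pairwise 50 5 0.2 scheme).

    Within each 50-SNP window, while any retained pair has r^2 above the
    threshold, the member with the smaller MAF is removed (ties drop the
    later position); the window then slides by ``step_snp``.  Returns
    the sorted indices of retained sites.
    """
    maf = geno.minor_af()
    keep = np.ones(geno.n_sites, dtype=bool)
    for chrom in geno.chroms():
        idx_all = np.flatnonzero(geno.site_mask(chrom))
        for w0 in range(0, max(idx_all.size - 1, 1), step_snp):
            win = idx_all[w0 : w0 + window_snp]
            active = win[keep[win]]
            while active.size >= 2:
                r2m = _pairwise_r2_matrix(geno.dosage[:, active])
                np.fill_diagonal(r2m, 0.0)
                with np.errstate(invalid="ignore"):
                    viol = np.argwhere(np.triu(r2m > r2_max, k=1))
                if viol.size == 0:
                    break
                a, b = viol[0]
                sa, sb = active[a], active[b]
                if maf[sa] < maf[sb]:
                    drop = sa
                elif maf[sb] < maf[sa]:
                    drop = sb
                else:
                    drop = max(sa, sb)  # tie: drop the later position
                keep[drop] = False
                active = active[active != drop]
            if w0 + window_snp >= idx_all.size:
                break
    return np.flatnonzero(keep)


def _pairwise_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """r^2 between all site columns (missing handled pairwise-complete)."""
    s = dos.shape[1]
    x = dos.astype(np.float64)
    ok = x >= 0
    x = np.where(ok, x, 0.0)
    n = ok.T.astype(float) @ ok.astype(float)
    sx = x.T @ ok.astype(float)
    sxx = (x * x).T @ ok.astype(float)
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        vx = sxx - sx * sx / n  # var of row site over pair-complete with col site
        r2 = cov * cov / (vx * vx.T)
    r2[n < 2] = np.nan
    return r2


def ne_from_ld(
    bins: pd.DataFrame,
    n_samples: int,
    alpha: float = 1.0,
    map_rate: float = 1e-8,
) -> pd.DataFrame:
    """Sved-equation Ne per distance bin.

    c = map_rate x bin midpoint (1 cM/Mb by default); r^2 is first
    reduced by the 1/(2n) sampling term.  Bins whose adjusted r^2 is
    non-positive, or with c = 0 or no pairs, are masked.
    """
    rows = []
    for r in bins.itertuples():
        if r.n_pairs <= 0 or np.isnan(r.mean_r2):
            continue
        c = map_rate * 0.5 * (r.distance_low + r.distance_high)
        r2_adj = r.mean_r2 - 1.0 / (2.0 * n_samples)
        if c <= 0 or r2_adj <= 0:
            continue
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha)
        if ne <= 0:
            continue
        rows.append((1.0 / (2.0 * c), ne, int(r.distance_low), int(r.distance_high)))
    return pd.DataFrame(rows, columns=["t_generations", "Ne", "distance_low", "distance_high"])
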