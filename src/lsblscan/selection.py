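"""Weir-Cockerham Fst, LSBL selection scans, and candidate-region calling.

The site-level Fst estimator is the Weir & Cockerham (1984) variance
decomposition for r = 2 populations: per site, the among-population (a),
between-individual-within-population (b), and within-individual (c)
components are computed from sample sizes n_i, alt-allele frequencies
p_i, and observed heterozygote frequencies h_i; window Fst is the
ratio-of-sums sum(a) / sum(a + b + c) over the SNPs of a sliding window
(the "weighted" estimator; a mean-of-site-ratios column is also
emitted).

The locus-specific branch length (LSBL) resolves pairwise Fst into
per-branch contributions of a three-population star: for focal
population X against Y and Z,

    LSBL_X = (Fst_XY + Fst_XZ - Fst_YZ) / 2

so LSBL_X + LSBL_Y = Fst_XY identically.  Windows in the top quantile
(default 1%) of LSBL are candidate selection regions; overlapping or
abutting selected windows are merged, then rescanned on a finer grid
(default 10-kb window, 5-kb step).  The egg vs dual contrast instead
intersects top-quantile Fst windows with the tails of the
log2(pi_dual / pi_egg) ratio.

Negative per-window Fst values are retained by default: clamping to
zero would break the LSBL additive identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lsblscan.variants import GenotypeMatrix, SampleMap, SiteCounts, GeneSet, group_site_counts
from lsblscan.windows import aggregate_in_windows, make_track, same_grid, window_grid
from lsblscan.diversity import windowed_pi


# ----------------------------------------------------------------------------
# Weir-Cockerham (1984) two-population components
# ----------------------------------------------------------------------------

@dataclass
class FstComponents:
    """Per-site WC84 variance components for one population pair."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    valid: np.ndarray  # sites usable for the estimator

    def theta(self) -> np.ndarray:
        tot = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            th = self.a / tot
        return np.where(self.valid & (tot != 0), th, np.nan)


def wc_fst_site(counts1: SiteCounts, counts2: SiteCounts) -> FstComponents:
    """WC84 a, b, c components per site for two populations (r = 2).

    Sites where either population has no called individuals, where the
    mean sample size per population is 1 (the b component is undefined),
    or where both populations are fixed for the same allele, are marked
    invalid.
    """
    n1 = counts1.n_called[0].astype(float)
    n2 = counts2.n_called[0].astype(float)
    p1 = counts1.alt_freq()[0]
    p2 = counts2.alt_freq()[0]
    h1 = counts1.het_freq()[0]
    h2 = counts2.het_freq()[0]

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    valid = (n1 > 0) & (n2 > 0) & (n_bar > 1.0) & (n_c > 0)
    # both populations monomorphic for the same allele: no information
    mono_same = ((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1))
    valid &= ~mono_same
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    # components are O(p(1-p)); magnitudes at rounding-noise level are
    # exact cancellations (e.g. b at a fixed site) and are zeroed so that
    # degenerate ratios like the fixation theta = 1 come out exact
    for arr in (a, b, c):
        arr[np.abs(arr) < 1e-14] = 0.0
    return FstComponents(a, b, c, valid)


def windowed_fst(
    components: FstComponents,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    window: int = 50_000,
    step: int = 25_000,
) -> pd.DataFrame:
    """Window Fst as ratio-of-sums sum(a)/sum(a+b+c) on a sliding grid.

    The output track has a ``value`` column (ratio of sums) plus a
    ``mean_of_ratios`` column averaging per-site theta; windows with no
    usable sites (or a non-positive denominator) are NaN.
    """
    chroms = list(dict.fromkeys(sites["chrom"]))
    tot = components.a + components.b + components.c
    theta_site = components.theta()
    grids, ns, vals, mors = {}, {}, {}, {}
    for chrom in chroms:
        mask = (sites["chrom"] == chrom).to_numpy()
        pos0 = sites.loc[mask, "pos"].to_numpy() - 1
        use = components.valid[mask]
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(sites.loc[mask, "pos"].max())
        )
        grid = window_grid(length, window, step)
        p_use = pos0[use]
        n, s_a = aggregate_in_windows(p_use, components.a[mask][use], grid)
        _, s_tot = aggregate_in_windows(p_use, tot[mask][use], grid)
        th = theta_site[mask][use]
        th_ok = ~np.isnan(th)
        n_th, s_th = aggregate_in_windows(p_use[th_ok], th[th_ok], grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where((n > 0) & (s_tot > 0), s_a / s_tot, np.nan)
            m = np.where(n_th > 0, s_th / n_th, np.nan)
        grids[chrom], ns[chrom], vals[chrom], mors[chrom] = grid, n, v, m
    track = make_track(chroms, grids, ns, vals, "fst", window, step)
    track["mean_of_ratios"] = np.concatenate([mors[c] for c in chroms]) if chroms else []
    return track


def pairwise_window_fst(
    geno: GenotypeMatrix,
    samplemap: SampleMap,
    groups: tuple[str, str],
    grouping: str = "population",
    window: int = 50_000,
    step: int = 25_000,
) -> pd.DataFrame:
    """Convenience: grouped counts -> WC84 components -> window track."""
    counts = group_site_counts(geno, samplemap, grouping)
    comp = wc_fst_site(counts.row(groups[0]), counts.row(groups[1]))
    return windowed_fst(comp, geno.sites, geno.chrom_lengths, window, step)


# ----------------------------------------------------------------------------
# LSBL
# ----------------------------------------------------------------------------

def lsbl(
    fst_xy: pd.DataFrame,
    fst_xz: pd.DataFrame,
    fst_yz: pd.DataFrame,
    focal: str = "X",
) -> pd.DataFrame:
    """Locus-specific branch length of the focal population per window.

    LSBL_X = (Fst_XY + Fst_XZ - Fst_YZ) / 2.  The three tracks must
    share one window grid; a window masked in any input is masked in the
    output.  The pairwise Fst values are carried along as columns.
    """
    if not (same_grid(fst_xy, fst_xz) and same_grid(fst_xy, fst_yz)):
        raise ValueError("Fst tracks are not on the same window grid")
    track = fst_xy[["chrom", "start", "end"]].copy()
    xy = fst_xy["value"].to_numpy(dtype=float)
    xz = fst_xz["value"].to_numpy(dtype=float)
    yz = fst_yz["value"].to_numpy(dtype=float)
    track["n_snps"] = np.minimum.reduce(
        [fst_xy["n_snps"].to_numpy(), fst_xz["n_snps"].to_numpy(), fst_yz["n_snps"].to_numpy()]
    )
    track["value"] = (xy + xz - yz) / 2.0
    track["fst_xy"] = xy
    track["fst_xz"] = xz
    track["fst_yz"] = yz
    track.attrs.update(statistic=f"lsbl_{focal}", window=fst_xy.attrs.get("window"),
                       step=fst_xy.attrs.get("step"), focal=focal)
    return track


# ----------------------------------------------------------------------------
# candidate regions
# ----------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    peak: float
    n_windows: int
    genes: list[str] = field(default_factory=list)


def _merge_windows(selected: pd.DataFrame) -> list[CandidateRegion]:
    regions: list[CandidateRegion] = []
    for chrom, sub in selected.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur: CandidateRegion | None = None
        for r in sub.itertuples():
            if cur is not None and r.start <= cur.end:
                cur.end = max(cur.end, int(r.end))
                cur.peak = max(cur.peak, float(r.value))
                cur.n_windows += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = CandidateRegion(str(chrom), int(r.start), int(r.end), float(r.value), 1)
        if cur is not None:
            regions.append(cur)
    return regions


def top_quantile_regions(
    track: pd.DataFrame,
    q: float = 0.01,
    min_snps: int = 10,
) -> list[CandidateRegion]:
    """Merge the windows at or above the (1 - q) empirical quantile.

    Windows with fewer than ``min_snps`` usable SNPs (or masked values)
    are excluded from both the quantile computation and the selection;
    ties at the threshold are included.
    """
    usable = track[(track["n_snps"] >= min_snps) & track["value"].notna()]
    if usable.empty:
        return []
    threshold = float(np.quantile(usable["value"].to_numpy(), 1.0 - q))
    selected = usable[usable["value"] >= threshold]
    return _merge_windows(selected)


def regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.peak, r.n_windows, ",".join(r.genes)) for r in regions],
        columns=["chrom", "start", "end", "peak", "n_windows", "genes"],
    )


# ----------------------------------------------------------------------------
# fine rescan and the egg vs dual contrast
# ----------------------------------------------------------------------------

def fine_scan(
    geno: GenotypeMatrix,
    samplemap: SampleMap,
    region: CandidateRegion,
    focal: str,
    others: tuple[str, str],
    window: int = 10_000,
    step: int = 5_000,
    pad: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Recompute LSBL and per-population pi inside one region on a fine grid.

    The grid starts at the (padded) region start and steps by ``step``
    until the region end; pi tracks for the focal and both reference
    populations come on the identical grid.
    """
    lo = max(0, region.start - pad)
    hi = region.end + pad
    sel = (
        (geno.sites["chrom"] == region.chrom)
        & (geno.sites["pos"] - 1 >= lo)
        & (geno.sites["pos"] - 1 < hi)
    ).to_numpy()
    starts = np.arange(lo, hi, step, dtype=np.int64)
    grid = np.column_stack([starts, np.minimum(starts + window, hi)])

    pops = (focal,) + tuple(others)
    if not sel.any():
        empty = pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "value"])
        return empty, {p: empty.copy() for p in pops}

    sub = geno.take_sites(np.flatnonzero(sel))
    sub.chrom_lengths = None
    counts = group_site_counts(sub, samplemap, "population")

    def pair_track(g1: str, g2: str) -> pd.DataFrame:
        comp = wc_fst_site(counts.row(g1), counts.row(g2))
        pos0 = sub.sites["pos"].to_numpy() - 1
        use = comp.valid
        tot = comp.a + comp.b + comp.c
        n, s_a = aggregate_in_windows(pos0[use], comp.a[use], grid)
        _, s_tot = aggregate_in_windows(pos0[use], tot[use], grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where((n > 0) & (s_tot > 0), s_a / s_tot, np.nan)
        t = pd.DataFrame(
            {"chrom": region.chrom, "start": grid[:, 0], "end": grid[:, 1], "n_snps": n, "value": v}
        )
        t.attrs.update(statistic="fst", window=window, step=step)
        return t

    x, y, z = focal, others[0], others[1]
    track = lsbl(pair_track(x, y), pair_track(x, z), pair_track(y, z), focal=focal)

    pi_tracks: dict[str, pd.DataFrame] = {}
    from lsblscan.diversity import per_site_pi

    for pop in pops:
        pop_sub = sub.take_samples(samplemap.samples_in(pop))
        pi_site = per_site_pi(pop_sub)
        pos0 = pop_sub.sites["pos"].to_numpy() - 1
        ok = ~np.isnan(pi_site)
        n, s = aggregate_in_windows(pos0[ok], pi_site[ok], grid)
        span = (grid[:, 1] - grid[:, 0]).astype(float)
        t = pd.DataFrame(
            {
                "chrom": region.chrom,
                "start": grid[:, 0],
                "end": grid[:, 1],
                "n_snps": n,
                "value": s / span,
            }
        )
        t.attrs.update(statistic="pi", window=window, step=step)
        pi_tracks[pop] = t
    return track, pi_tracks


def pi_ratio_scan(
    pi_egg: pd.DataFrame,
    pi_dual: pd.DataFrame,
    fst_track: pd.DataFrame,
    q: float = 0.05,
    min_snps: int = 10,
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Selected regions from the top-q Fst / pi-ratio overlap.

    The ratio is log2(pi_dual / pi_egg) per window (masked where either
    pi is 0).  Egg-selected windows sit in the top q of the ratio AND
    the top q of Fst; dual-selected windows in the bottom q of the ratio
    AND the top q of Fst.  Each selected set is merged into regions.

    Ratio tails are strict (a window exactly at the quantile does not
    qualify), so a flat ratio — pi equal in both groups everywhere —
    selects nothing; the Fst threshold is inclusive, as elsewhere.
    """
    if not (same_grid(pi_egg, pi_dual) and same_grid(pi_egg, fst_track)):
        raise ValueError("tracks are not on the same window grid")
    pe = pi_egg["value"].to_numpy(dtype=float)
    pdl = pi_dual["value"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.log2(pdl / pe)
    ratio[(pe <= 0) | (pdl <= 0)] = np.nan

    fst = fst_track["value"].to_numpy(dtype=float)
    n_snps = np.minimum.reduce(
        [pi_egg["n_snps"].to_numpy(), pi_dual["n_snps"].to_numpy(), fst_track["n_snps"].to_numpy()]
    )
    usable = (n_snps >= min_snps) & ~np.isnan(ratio) & ~np.isnan(fst)
    if not usable.any():
        return [], []
    fst_thr = float(np.quantile(fst[usable], 1.0 - q))
    hi_thr = float(np.quantile(ratio[usable], 1.0 - q))
    lo_thr = float(np.quantile(ratio[usable], q))

    base = fst_track[["chrom", "start", "end"]].copy()
    base["n_snps"] = n_snps

    with np.errstate(invalid="ignore"):
        egg_mask = usable & (fst >= fst_thr) & (ratio > hi_thr)
        dual_mask = usable & (fst >= fst_thr) & (ratio < lo_thr)
    egg_sel = base[egg_mask].assign(value=ratio[egg_mask])
    dual_sel = base[dual_mask].assign(value=-ratio[dual_mask])
    return _merge_windows(egg_sel), _merge_windows(dual_sel)


def annotate_regions(regions: list[CandidateRegion], genes: GeneSet) -> list[CandidateRegion]:
    """Attach every gene whose half-open interval overlaps a region."""
    if len(genes) == 0:
        import warnings

        warnings.warn("empty gene set; regions left unannotated")
        return regions
    gf = genes.frame
    for region in regions:
        hit = gf[
            (gf["chrom"] == region.chrom)
            & (gf["start"] < region.end)
            & (gf["end"] > region.start)
        ]
        region.genes = list(hit["gene_id"])
    return regions
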