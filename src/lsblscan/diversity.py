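"""Heterozygosity, inbreeding F, and windowed nucleotide diversity.

Per-site expected heterozygosity is the plain 2p(1-p) (the usual
reporting convention for exact-test output); the individual inbreeding
coefficient's expected-homozygosity term carries the 2n/(2n-1)
small-sample correction, matching method-of-moments F estimators.  The
asymmetry is deliberate.

Windowed pi sums the unbiased per-site heterozygosity estimator
2 a (m - a) / (m (m - 1)) (a = alt allele count, m = called allele
count) over the SNPs of each sliding window and divides by the actual
window span in bp (the final window of a chromosome is truncated and
divided by its true span).  Zero-SNP windows are emitted with value 0 so
tracks stay aligned across statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lsblscan.variants import MISSING, GenotypeMatrix, SampleMap, SiteCounts
from lsblscan.windows import aggregate_in_windows, make_track, window_grid


def site_het(counts: SiteCounts) -> tuple[np.ndarray, np.ndarray]:
    """Observed and expected heterozygosity per site, per group.

    Ho = het / n_called; He = 2 p (1 - p).  Sites with no calls are NaN.
    """
    ho = counts.het_freq()
    p = counts.alt_freq()
    he = 2.0 * p * (1.0 - p)
    return ho, he


def individual_F(geno: GenotypeMatrix) -> pd.Series:
    """Method-of-moments inbreeding coefficient per individual.

    F = (O_hom - E_hom) / (L - E_hom) over the individual's called
    sites, with per-site expected homozygosity
    1 - 2 p (1 - p) * 2n/(2n - 1) computed from the full-sample allele
    frequency.  Individuals with no informative sites are NaN.
    """
    n = geno.called()
    p = geno.alt_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        e_het_site = 2.0 * p * (1.0 - p) * (2.0 * n / (2.0 * n - 1.0))
    e_het_site = np.where(n > 0, e_het_site, np.nan)

    called = geno.dosage != MISSING
    hom = called & (geno.dosage != 1)
    usable = called & ~np.isnan(e_het_site)[None, :]
    o_hom = (hom & usable).sum(axis=1).astype(float)
    l_called = usable.sum(axis=1).astype(float)
    e_hom = np.where(usable, 1.0 - e_het_site[None, :], 0.0).sum(axis=1)
    denom = l_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    return pd.Series(f, index=geno.samples, name="F")


def per_site_pi(geno: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site pairwise-difference estimator; NaN where < 2 alleles."""
    m = 2.0 * geno.called()
    a = geno.alt_counts().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * a * (m - a) / (m * (m - 1.0))
    return np.where(m >= 2, pi, np.nan)


def windowed_pi(
    geno: GenotypeMatrix,
    window: int = 50_000,
    step: int = 25_000,
    drop_empty: bool = False,
) -> pd.DataFrame:
    """Nucleotide diversity per sliding window (per-bp scale).

    Sites with fewer than two called alleles are skipped.  Windows with
    no SNPs carry value 0 (or are dropped with ``drop_empty``).
    """
    pi_site = per_site_pi(geno)
    chroms = geno.chroms()
    grids, n_snps, values = {}, {}, {}
    for chrom in chroms:
        mask = geno.site_mask(chrom)
        pos0 = geno.positions0(chrom)
        usable = ~np.isnan(pi_site[mask])
        grid = window_grid(geno.chrom_length(chrom), window, step)
        n, s = aggregate_in_windows(pos0[usable], pi_site[mask][usable], grid)
        span = (grid[:, 1] - grid[:, 0]).astype(float)
        grids[chrom] = grid
        n_snps[chrom] = n
        values[chrom] = s / span
    track = make_track(chroms, grids, n_snps, values, "pi", window, step)
    if drop_empty:
        track = track[track["n_snps"] > 0].reset_index(drop=True)
        track.attrs.update(statistic="pi", window=window, step=step)
    return track


def summarize_diversity(
    he_by_pop: dict[str, np.ndarray] | None = None,
    ho_by_pop: dict[str, np.ndarray] | None = None,
    pi_tracks: dict[str, pd.DataFrame] | None = None,
    f_by_pop: dict[str, pd.Series] | None = None,
    roh_lengths_by_pop: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Mean +/- sd per population for each diversity metric.

    He/Ho are summarized across sites, pi across windows, F across
    individuals, and ROH across segment lengths (kb).  Missing metrics
    are simply absent from the output; single-observation groups report
    sd 0 with a flag.
    """
    metrics: dict[str, dict[str, np.ndarray]] = {}
    if he_by_pop:
        metrics["He"] = he_by_pop
    if ho_by_pop:
        metrics["Ho"] = ho_by_pop
    if pi_tracks:
        metrics["Pi"] = {p: t.loc[t["n_snps"] > 0, "value"].to_numpy() for p, t in pi_tracks.items()}
    if f_by_pop:
        metrics["F"] = {p: s.to_numpy() for p, s in f_by_pop.items()}
    if roh_lengths_by_pop:
        metrics["ROH_kb"] = roh_lengths_by_pop
    rows = []
    for metric, by_pop in metrics.items():
        for pop, vals in by_pop.items():
            vals = np.asarray(vals, dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                rows.append((pop, metric, np.nan, np.nan, 0, True))
            else:
                rows.append(
                    (pop, metric, float(vals.mean()),
                     float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     int(vals.size), vals.size <= 1)
                )
    return pd.DataFrame(rows, columns=["population", "metric", "mean", "sd", "n", "degenerate"])


def population_diversity(
    geno: GenotypeMatrix,
    samplemap: SampleMap,
    window: int = 50_000,
    step: int = 25_000,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, pd.Series]]:
    """Convenience driver: He/Ho/pi/F for each population of the map.

    Returns the summary table plus per-population pi tracks and F series.
    """
    from lsblscan.variants import group_site_counts

    counts = group_site_counts(geno, samplemap, "population")
    ho, he = site_het(counts)
    he_by_pop, ho_by_pop, pi_tracks, f_by_pop = {}, {}, {}, {}
    for gi, pop in enumerate(counts.groups):
        he_by_pop[pop] = he[gi]
        ho_by_pop[pop] = ho[gi]
        sub = geno.take_samples(samplemap.samples_in(pop))
        pi_tracks[pop] = windowed_pi(sub, window, step)
        f_by_pop[pop] = individual_F(sub)
    summary = summarize_diversity(he_by_pop, ho_by_pop, pi_tracks, f_by_pop)
    return summary, pi_tracks, f_by_pop
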