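"""Weir-Cockerham Fst, LSBL identity, region calling, and the egg/dual scan."""

import numpy as np
import pandas as pd
import pytest

from lsblscan.selection import (
    CandidateRegion,
    annotate_regions,
    fine_scan,
    lsbl,
    pi_ratio_scan,
    top_quantile_regions,
    wc_fst_site,
    windowed_fst,
)
from lsblscan.variants import GeneSet, group_site_counts
from lsblscan.diversity import windowed_pi
from lsblscan.synthio import SimConfig, SweepWindow, simulate_three_pop
from tests.conftest import make_geno, make_map


def counts_pair(dos1, dos2):
    dos = np.vstack([dos1, dos2]).astype(np.int8)
    geno = make_geno(dos)
    ids1 = geno.samples[: len(dos1)]
    ids2 = geno.samples[len(dos1) :]
    sm = make_map(geno, ["wild"] * len(dos1) + ["local"] * len(dos2))
    c = group_site_counts(geno, sm, {"p1": ids1, "p2": ids2})
    return c.row("p1"), c.row("p2")


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Independent scalar evaluation of the WC84 two-population components."""
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def test_fst_complete_fixation_is_one():
    c1, c2 = counts_pair(np.zeros((5, 3)), np.full((4, 3), 2))
    comp = wc_fst_site(c1, c2)
    np.testing.assert_allclose(comp.theta(), 1.0)


def test_fst_all_heterozygous_is_zero():
    c1, c2 = counts_pair(np.ones((6, 2)), np.ones((6, 2)))
    comp = wc_fst_site(c1, c2)
    assert np.allclose(comp.a, 0.0, atol=1e-15)
    np.testing.assert_allclose(comp.theta(), 0.0, atol=1e-12)


def test_fst_components_hand_example():
    """pop1 = {AA, AA, Aa}, pop2 = {aa, aa, Aa}: a = 7/36, b = 0, c = 1/6,
    theta = 7/13 (hand evaluation of the variance components)."""
    c1, c2 = counts_pair(np.array([[0], [0], [1]]), np.array([[2], [2], [1]]))
    comp = wc_fst_site(c1, c2)
    assert comp.a[0] == pytest.approx(7 / 36, abs=1e-12)
    assert comp.b[0] == pytest.approx(0.0, abs=1e-12)
    assert comp.c[0] == pytest.approx(1 / 6, abs=1e-12)
    assert comp.theta()[0] == pytest.approx(7 / 13, abs=1e-12)


def test_fst_matches_oracle_on_random_tables():
    """Vectorized components equal the scalar WC84 oracle to 1e-10 on 1,000
    random two-population genotype count tables."""
    rng = np.random.default_rng(12)
    n_tables = 1000
    dos1 = rng.integers(0, 3, size=(8, n_tables)).astype(np.int8)
    dos2 = rng.integers(0, 3, size=(11, n_tables)).astype(np.int8)
    c1, c2 = counts_pair(dos1, dos2)
    comp = wc_fst_site(c1, c2)
    for j in rng.choice(n_tables, 250, replace=False):
        a, b, c = wc_oracle(
            c1.n_called[0, j], c1.alt_freq()[0, j], c1.het_freq()[0, j],
            c2.n_called[0, j], c2.alt_freq()[0, j], c2.het_freq()[0, j],
        )
        if not comp.valid[j]:
            continue
        assert comp.a[j] == pytest.approx(a, abs=1e-10)
        assert comp.b[j] == pytest.approx(b, abs=1e-10)
        assert comp.c[j] == pytest.approx(c, abs=1e-10)


def test_windowed_fst_ratio_of_sums():
    c1, c2 = counts_pair(
        np.array([[0, 0], [0, 1], [1, 0]]), np.array([[2, 1], [2, 2], [1, 2]])
    )
    sites = pd.DataFrame({"chrom": "chr1", "pos": [100, 200], "ref": "A", "alt": "C"})
    comp = wc_fst_site(c1, c2)
    track = windowed_fst(comp, sites, {"chr1": 1000}, window=1000, step=1000)
    expected = comp.a.sum() / (comp.a + comp.b + comp.c).sum()
    assert track["value"].iloc[0] == pytest.approx(expected, abs=1e-12)
    # mean-of-ratios column averages per-site theta
    assert track["mean_of_ratios"].iloc[0] == pytest.approx(np.nanmean(comp.theta()), abs=1e-12)


def test_fixation_window_fst_is_one():
    c1, c2 = counts_pair(np.zeros((5, 4)), np.full((5, 4), 2))
    sites = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30, 40], "ref": "A", "alt": "C"})
    track = windowed_fst(wc_fst_site(c1, c2), sites, {"chr1": 100}, 100, 100)
    assert track["value"].iloc[0] == pytest.approx(1.0)


def make_track(values, window=50_000):
    n = len(values)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * window,
            "end": (np.arange(n) + 1) * window,
            "n_snps": 20,
            "value": values,
        }
    )


def test_lsbl_direct_arithmetic():
    xy, xz, yz = make_track([0.3]), make_track([0.2]), make_track([0.1])
    t = lsbl(xy, xz, yz, focal="X")
    assert t["value"].iloc[0] == pytest.approx(0.2)


def test_lsbl_symmetric_star():
    v = 0.18
    t = lsbl(make_track([v] * 4), make_track([v] * 4), make_track([v] * 4))
    np.testing.assert_allclose(t["value"], v / 2)


def test_lsbl_additive_identity():
    """LSBL_X + LSBL_Y = Fst_XY and the three branches sum to half the
    pairwise total, per window, to 1e-12."""
    rng = np.random.default_rng(7)
    xy, xz, yz = (make_track(rng.uniform(-0.05, 0.6, 50)) for _ in range(3))
    lx = lsbl(xy, xz, yz)["value"].to_numpy()
    ly = lsbl(xy, yz, xz)["value"].to_numpy()
    lz = lsbl(xz, yz, xy)["value"].to_numpy()
    np.testing.assert_allclose(lx + ly, xy["value"], atol=1e-12)
    s = (xy["value"] + xz["value"] + yz["value"]) / 2
    np.testing.assert_allclose(lx + ly + lz, s, atol=1e-12)


def test_lsbl_rejects_grid_mismatch():
    with pytest.raises(ValueError, match="grid"):
        lsbl(make_track([0.1]), make_track([0.1, 0.2]), make_track([0.1]))


def test_top_quantile_counts_and_merge():
    """1,000 unmasked windows at q = 0.01 select 10 windows; overlapping
    selections merge."""
    rng = np.random.default_rng(5)
    vals = rng.permutation(1000) / 1000.0
    track = make_track(vals)
    regions = top_quantile_regions(track, q=0.01, min_snps=1)
    assert sum(r.n_windows for r in regions) == 10
    # explicit overlap merge: [0, 50k) and [25k, 75k)
    t2 = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 25_000], "end": [50_000, 75_000],
         "n_snps": 20, "value": [5.0, 6.0]}
    )
    background = make_track(np.linspace(0, 1, 200))
    background["start"] += 100_000
    background["end"] += 100_000
    full = pd.concat([t2, background], ignore_index=True)
    regions = top_quantile_regions(full, q=0.005, min_snps=1)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end, regions[0].peak) == (0, 75_000, 6.0)


def test_top_quantile_invariant_to_window_order():
    rng = np.random.default_rng(6)
    track = make_track(rng.uniform(0, 1, 400))
    shuffled = track.sample(frac=1, random_state=1).reset_index(drop=True)
    r1 = [(r.chrom, r.start, r.end) for r in top_quantile_regions(track, 0.05, 1)]
    r2 = [(r.chrom, r.start, r.end) for r in top_quantile_regions(shuffled, 0.05, 1)]
    assert sorted(r1) == sorted(r2)


def test_top_quantile_all_masked_is_empty():
    track = make_track([np.nan] * 10)
    assert top_quantile_regions(track, 0.01, 1) == []


def test_pi_ratio_arithmetic_and_null():
    pi_e = make_track([0.001] * 40)
    pi_d = make_track([0.002] * 40)
    with np.errstate(all="ignore"):
        ratio = np.log2(pi_d["value"] / pi_e["value"])
    assert ratio.iloc[0] == pytest.approx(1.0)
    # equal pi everywhere: the strict ratio tails select nothing
    fst = make_track(np.linspace(0, 0.5, 40))
    egg, dual = pi_ratio_scan(pi_e, pi_e.copy(), fst, q=0.05, min_snps=1)
    assert egg == [] and dual == []


def test_annotate_regions_overlap_semantics():
    genes = GeneSet(pd.DataFrame(
        {"gene_id": ["g1", "g2"], "chrom": "chr1",
         "start": [99, 99], "end": [200, 200], "strand": "+"}
    ))
    touching = CandidateRegion("chr1", 150, 300, 1.0, 1)
    abutting = CandidateRegion("chr1", 200, 300, 1.0, 1)
    spanning = CandidateRegion("chr1", 120, 160, 1.0, 1)
    annotate_regions([touching, abutting, spanning], genes)
    assert touching.genes == ["g1", "g2"]
    assert abutting.genes == []
    assert spanning.genes == ["g1", "g2"]


def test_fine_scan_grid_and_degenerate_region(small_sim):
    geno, sm, _ = small_sim
    region = CandidateRegion("chr1", 1_000_000, 1_100_000, 1.0, 2)
    track, pis = fine_scan(geno, sm, region, "commercial", ("local", "wild"))
    assert track["start"].iloc[0] == 1_000_000
    assert (np.diff(track["start"]) == 5_000).all()
    assert track["end"].max() == 1_100_000
    assert set(pis) == {"commercial", "local", "wild"}
    assert (pis["commercial"][["start", "end"]].values == track[["start", "end"]].values).all()
    tiny = CandidateRegion("chr1", 1_000_000, 1_004_000, 1.0, 1)
    t2, _ = fine_scan(geno, sm, tiny, "commercial", ("local", "wild"))
    assert len(t2) == 1


def test_lsbl_branch_drift_interpretation():
    """Drift confined to the commercial branch concentrates LSBL there."""
    from lsblscan.selection import pairwise_window_fst

    wins = []
    for seed in range(3):
        cfg = SimConfig(n_chrom=1, chrom_length_bp=5_000_000, n_sites=4000,
                        n_per_pop=15, f_wild=0.0, f_local=0.0, f_commercial=0.15,
                        n_founder_haplotypes=48, egg_dual_split=None, seed=seed)
        geno, sm, _ = simulate_three_pop(cfg)
        cl = pairwise_window_fst(geno, sm, ("commercial", "local"))
        cw = pairwise_window_fst(geno, sm, ("commercial", "wild"))
        lw = pairwise_window_fst(geno, sm, ("local", "wild"))
        l_com = np.nanmean(lsbl(cl, cw, lw, "commercial")["value"])
        l_loc = np.nanmean(lsbl(cl, lw, cw, "local")["value"])
        l_wld = np.nanmean(lsbl(cw, lw, cl, "wild")["value"])
        wins.append(l_com > l_loc and l_com > l_wld)
    assert all(wins)
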