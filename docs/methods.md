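# Methods

This note records the models, estimators, and numerical conventions
behind `lsblscan`, the choices made where the design was genuinely open,
and what the synthetic benchmark does and does not establish.

## The synthetic panel

The simulator emulates a three-population resequencing design — a wild
reference, a local (landrace) branch subdivided into egg-laying and
dual-purpose groups, and a commercial branch — at desk scale: by default
2 chromosomes × 25 Mb with 20,000 SNPs each and 36 diploids per
population. Site positions are drawn uniformly without replacement per
chromosome and sorted; density (0.8 SNP/kb) is high enough that 50-kb
windows hold ~40 SNPs and a 2-Mb tract ~1,600 SNPs.

**Allele frequencies.** Each site has an ancestral frequency
p ~ Uniform(0.05, 0.95). A population with drift coefficient F draws its
frequency from the Balding–Nichols distribution
Beta(p(1−F)/F, (1−p)(1−F)/F); F = 0 is handled as a special case
(the Beta is undefined) by copying p. Defaults are F = 0.05 / 0.10 /
0.20 for wild / local / commercial — orderings, not calibrated fits —
chosen to produce pairwise window Fst around 0.1–0.2, the range typical
of livestock breed contrasts. The egg/dual split re-applies
Balding–Nichols within the local branch (F = 0.05 per subgroup), a
two-level hierarchy mirroring the nested contrast.

**Linkage disequilibrium.** Each population (or local subgroup) has a
finite pool of founder haplotypes sampled site-wise from its
frequencies; a sampled haplotype is a copy-path over the pool, switching
to a uniformly drawn founder with probability `switch_rate` per bp
between adjacent sites (implemented in renewal form: the founder id at a
site is keyed by the most recent switch site, which keeps the random
stream fixed-size and runs sharing a seed locally coupled across
switch-rate values). Two consequences matter:

- the founder-pool size is itself a drift analog — background r² scales
  roughly as 1/K plus the 1/n sampling floor — so the default pools
  shrink from wild (64) to local (48) to commercial (16), reproducing
  the elevated LD of commercial breeds at every distance;
- `switch_rate` stands for recombination accumulated over the breed
  history, not a per-meiosis rate; the default 10⁻⁶/bp gives a visible
  r² decay over 0–500 kb. The differences among 10⁻⁸/10⁻⁷/10⁻⁶ at
  ≤ 10 kb are a few 10⁻⁴ in mean r², below desk-scale Monte-Carlo noise
  (~4 × 10⁻³ per paired seed); the monotonicity test therefore carries an
  explicit two-sigma margin for those steps and asserts the two-decade
  step to 10⁻⁴ strictly.

A true "no differentiation" null requires both F = 0 and a founder pool
large relative to the sample (the tests use 1,024 haplotypes); with a
small pool, founder resampling alone produces mean Fst ≈ 1/K − 1/2n.

**Injected signals.** A sweep overwrites the focal branch's frequencies
inside a window with `target_freq` before founder sampling (overlapping
sweeps on one branch are rejected); a homozygosity tract forces an
individual's two haplotypes identical over an interval. Chance
identity-by-descent can extend true homozygosity beyond a forced tract,
so recovery is scored against the realized het-free run containing the
tract. Missing genotypes are injected at a configurable rate (default 0)
to exercise the QC paths. All randomness comes from one seeded
generator with a documented draw order (positions, ancestral
frequencies, per-population frequencies in wild/local/egg/dual/
commercial order, founders then mosaics per pool, missingness last), so
output is byte-stable for a fixed seed.

**What the benchmark does not emulate:** real site-frequency spectra
(no rare-variant excess), mutation/genotyping error, recombination
hotspots, gene conversion, admixture between branches, or reference
bias. Passing recovery tests shows the estimators and the scan logic are
correct and well-powered under clean drift + sweep signals of the
configured strength; it does not certify power on real data.

## Estimators and conventions

**Coordinates.** Internal coordinates are 0-based half-open; VCF and
GFF3 are 1-based at the file boundary; all window tracks are BED-like.
Windows (default 50 kb / 25 kb; fine scan 10 kb / 5 kb) start at 0 and
the final window of a chromosome is truncated, with π divided by the
actual span. Zero-SNP windows are emitted with value 0 so tracks align
across statistics.

**QC.** Stage one keeps polymorphic biallelic SNPs with MAF ≥ 0.01 (on
called alleles) and missingness ≤ 0.9; multi-allelic records are dropped,
not split. Stage two removes MAF < 0.05 or Hardy–Weinberg exact p
< 10⁻⁶; both are strict "<", so sites exactly at a threshold survive.
The HWE test is the exact conditional (Wigginton-style) test with a
plain (non-mid) p, computed over all samples pooled — whether the
original filter was pooled or per-breed is not documented anywhere we
could check, so pooled is implemented and flagged as the assumption.
Per-site p-values are memoized on the genotype-count triple.

**Heterozygosity and F.** He is the plain 2p(1−p) and Ho the observed
het fraction, summarized across sites (the "±" spreads are sds across
sites; across-individuals is the other defensible convention). The
individual inbreeding coefficient is
F = (O_hom − E_hom)/(L − E_hom) with the unbiased per-site expectation
E_hom = 1 − 2p(1−p)·2n/(2n−1); the asymmetry (no correction in He, a
correction in F) is deliberate and mirrors common reporting practice.

**π.** Per site, the unbiased pairwise estimator
2a(m−a)/(m(m−1)) (a alt alleles among m called); per window, the sum
over SNPs divided by the window span in bp. Sites with fewer than two
called alleles are skipped.

**ROH.** The scanning algorithm: 50-SNP windows slide one SNP at a
time; a window is homozygous with ≤ 1 het and ≤ 5 missing calls; a
SNP's hit fraction uses as denominator only the windows that actually
contain it (shrinking at chromosome edges); eligible SNPs (fraction
≥ 0.05) form maximal runs split at gaps > 1,000 kb; segments must have
≥ 50 SNPs, ≥ 1,000 kb (the conventional default, since no explicit
minimum length accompanies the published flag set), and ≥ 1 SNP per
500 kb, with the density check applied to the final segment. Segment
ends are the first/last SNP positions (no trimming to the outermost
homozygous call); segment-level heterozygote count is unlimited, so an
occasional het absorbed by the window rule can sit inside a segment.
Chromosomes with fewer SNPs than the window produce no calls.

**LD and Ne.** r² is the squared Pearson correlation of dosages over
pairwise-complete individuals; undefined (masked) when fewer than two
complete pairs remain or a site is monomorphic among them. Decay curves
bin all intra-chromosome pairs by physical distance with a seeded
subsampling cap per bin (default 5 × 10⁵; means stabilize far below
that). Pruning follows the greedy 50-SNP-window / 5-SNP-step / r² > 0.2
scheme, removing the smaller-MAF member (tie: later position) until the
window is clean. Ne inverts Sved's E[r²] = 1/(α + 4Nc) per bin with
c = physical distance × 1 cM/Mb (configurable linear map), the
sample-size adjustment r² − 1/(2n) for unphased diploids, α = 1 by
default (2.2 selectable for the mutation-drift variant), and
t = 1/(2c); bins with non-positive adjusted r² are masked. Only the
Sved inversion with these stated options is promised — not numeric
parity with any particular Ne tool, whose binning and correction chains
are not restated here.

**Fst, LSBL, regions.** Site components a, b, c follow Weir &
Cockerham (1984) with r = 2 populations, using called sample sizes n_i,
alt frequencies p_i, and observed het frequencies h_i; sites where both
populations are fixed for the same allele, or with a degenerate sample
size, are excluded. Component magnitudes below 10⁻¹⁴ are zeroed — they
arise only from exact cancellations (e.g. b at a fixed site) and would
otherwise perturb degenerate ratios like θ = 1. Window Fst is the
ratio-of-sums Σa/Σ(a+b+c) ("weighted"); a mean-of-site-ratios column is
also emitted, since which variant feeds published LSBL values is
usually unstated. Negative window Fst is retained — clamping would break
the identity LSBL_X + LSBL_Y = Fst_XY, which is asserted to 10⁻¹² — and
windows need ≥ 10 usable SNPs (configurable) to enter quantile
computations. The top-quantile threshold is the empirical (1−q)
order-statistic quantile with ties included (≥); selected windows that
overlap or abut merge into regions carrying the peak value. Fine
rescans recompute Fst/LSBL/π on a 10-kb/5-kb grid aligned to the region
bounds. All merged top-quantile regions are rescanned by default; a
top-N peak selector reproduces the common practice of hand-picking a
few regions. The egg/dual contrast uses log₂(π_dual/π_egg) — the
orientation is this package's stated convention — with strict ratio
tails (a flat ratio selects nothing) intersected with inclusive top-q
Fst windows. Gene annotation attaches any gene whose half-open interval
intersects a region.

**Structure.** PCA imputes missing dosages to the site mean, centers by
2p and scales by √(2p(1−p)) (Patterson standardization; plain centering
available), eigendecomposes the sample covariance, and reports each
eigenvalue as a percentage of the positive-eigenvalue total; each
component is oriented so its largest-magnitude coordinate is positive.
IBS distance is 1 − mean shared-allele fraction over co-called sites
(pairs with none are masked). Neighbor-joining is Saitou–Nei with a
deterministic smallest-index tie-break; negative branch lengths are
floored at zero with the deficit shifted to the sister branch,
preserving path lengths, which match additive inputs to 10⁻⁹.

**Pipeline.** Per-stage seeds derive from the master seed and the stage
name via a CRC32 mix, so adding stages never perturbs earlier streams;
reruns are bit-stable. Sample-size equalization (the 72-per-population
device of the original design) takes a seeded per-population subsample
proportional by breed with largest-remainder rounding.

## Problem sizes

The test suite and the acceptance script run the study-scale
configuration (2 × 25 Mb × 20k SNPs, 3 × 36 diploids) for recovery
experiments — 20 seeds per scan in the tests, 10 in the script — and
smaller single-chromosome panels for ROH and LD properties. These sizes
were chosen so the full suite completes in about a minute while keeping
every recovery rate at or near 1; headline counts from 416-sample
panels (absolute SNP totals, per-population π magnitudes) are
scale-dependent and are checked as packaged-metadata consistency, not
recomputed.

## Known limitations

- The HWE pooling assumption (above) can over-filter strongly
  differentiated sites via the Wahlund effect; with the default
  simulated drift this removes ~8% of sites and does not affect sweep
  recovery, but a per-population option would be the next refinement.
- The IBS distance averages over each pair's complete cases; tools
  differ subtly in how missing pairs are weighted.
- LD-based Ne is reported per distance bin without cross-bin smoothing
  or a recombination map.
- The scanning ROH detector is genotype-count based; likelihood/HMM
  detectors behave differently at low SNP density.
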