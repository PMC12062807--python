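"""Three-population diploid SNP simulator with recoverable ground truth.

The generator emulates the wild / local / commercial design of a duck
resequencing panel.  Allele frequencies follow the Balding-Nichols
model: an ancestral frequency p ~ Uniform(0.05, 0.95) per site, and each
population's frequency drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) where F
is that branch's drift coefficient (F = 0 copies p unchanged).  Linkage
disequilibrium arises from a haplotype-mosaic process: each population
has a finite founder-haplotype pool sampled site-wise from its
frequencies, and every sampled haplotype is a copy-path over founders
that switches founder with probability ``switch_rate`` per bp.  A small
founder pool is the drift analog that inflates r^2; the switch rate sets
the LD decay scale (it stands for recombination accumulated over the
breed history, so it is orders of magnitude above the per-meiosis rate).

Selective sweeps are injected by overwriting the focal population's site
frequencies inside a window with ``target_freq`` before founder
sampling; runs of homozygosity by forcing an individual's two haplotypes
identical over a tract.  The egg vs dual split re-applies
Balding-Nichols within the local branch (a two-level hierarchy).

Randomness comes from one seeded numpy Generator; the draw order is
fixed (positions, ancestral freqs, per-population freqs in wild / local
/ egg / dual / commercial order, founders then mosaics per pool in that
same order, missingness last) so outputs are stable across versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from lsblscan.variants import GenotypeMatrix, SampleMap, SITE_COLUMNS

POPULATIONS = ("wild", "local", "commercial")


@dataclass
class SweepWindow:
    """A selective sweep: ``population`` may also be 'egg' or 'dual'."""

    population: str
    chrom: str
    start: int  # 0-based half-open bp
    end: int
    target_freq: float


@dataclass
class RohTract:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open bp
    end: int


@dataclass
class EggDualSplit:
    """Partition of the local population into egg-laying and dual-purpose
    subgroups, each drifted from the local branch by its own F."""

    egg_fraction: float = 0.5
    f_egg: float = 0.05
    f_dual: float = 0.05
    sweep_windows: list[SweepWindow] = field(default_factory=list)


@dataclass
class SimConfig:
    """Study-scale defaults: 2 chromosomes x 25 Mb x 20k SNPs, 36 diploids
    per population, branch drift (wild, local, commercial) = (0.05, 0.10,
    0.20), founder pools shrinking from wild to commercial."""

    n_chrom: int = 2
    chrom_length_bp: int = 25_000_000
    n_sites: int = 20_000
    n_per_pop: int | dict[str, int] = 36
    f_wild: float = 0.05
    f_local: float = 0.10
    f_commercial: float = 0.20
    n_founder_haplotypes: int | dict[str, int] = field(
        default_factory=lambda: {"wild": 64, "local": 48, "commercial": 16}
    )
    switch_rate: float = 1e-6
    sweep_windows: list[SweepWindow] = field(default_factory=list)
    roh_tracts: list[RohTract] = field(default_factory=list)
    egg_dual_split: EggDualSplit | None = field(default_factory=EggDualSplit)
    missing_rate: float = 0.0
    seed: int = 0

    def pop_size(self, pop: str) -> int:
        return self.n_per_pop[pop] if isinstance(self.n_per_pop, dict) else self.n_per_pop

    def founders(self, pop: str) -> int:
        k = self.n_founder_haplotypes
        return k[pop] if isinstance(k, dict) else k

    def drift(self, pop: str) -> float:
        return {"wild": self.f_wild, "local": self.f_local, "commercial": self.f_commercial}[pop]

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def validate(self) -> None:
        for pop in POPULATIONS:
            if not 0 <= self.drift(pop) < 1:
                raise ValueError(f"drift coefficient for {pop} must be in [0, 1)")
            if self.pop_size(pop) < 2:
                raise ValueError("n_per_pop must be >= 2")
            if self.founders(pop) < 2:
                raise ValueError("need >= 2 founder haplotypes")
        if self.egg_dual_split is not None:
            s = self.egg_dual_split
            if not 0 < s.egg_fraction < 1:
                raise ValueError("egg_fraction must be in (0, 1)")
            for f in (s.f_egg, s.f_dual):
                if not 0 <= f < 1:
                    raise ValueError("subgroup drift must be in [0, 1)")
        chroms = set(self.chrom_names())
        sweeps = list(self.sweep_windows)
        if self.egg_dual_split is not None:
            sweeps += self.egg_dual_split.sweep_windows
        by_pop: dict[str, list[SweepWindow]] = {}
        for sw in sweeps:
            if not 0.5 < sw.target_freq <= 1:
                raise ValueError("sweep target_freq must be in (0.5, 1]")
            if sw.chrom not in chroms:
                raise ValueError(f"sweep chromosome {sw.chrom} not simulated")
            if not 0 <= sw.start < sw.end <= self.chrom_length_bp:
                raise ValueError("sweep window outside chromosome bounds")
            by_pop.setdefault(sw.population, []).append(sw)
        for pop, ws in by_pop.items():
            ws = sorted(ws, key=lambda w: (w.chrom, w.start))
            for a, b in zip(ws, ws[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(f"overlapping sweep windows on the {pop} branch")
        for tr in self.roh_tracts:
            if tr.chrom not in chroms or not 0 <= tr.start < tr.end <= self.chrom_length_bp:
                raise ValueError("ROH tract outside simulated coordinates")


@dataclass
class SimTruth:
    """Ground truth of one simulation run, for parameter-recovery tests."""

    sites: pd.DataFrame  # chrom, pos (1-based)
    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]  # wild / local / egg / dual / commercial
    sweeps: list[SweepWindow]
    tracts: list[RohTract]
    seed: int


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0.0:
        return p.copy()
    ratio = (1.0 - f) / f
    return rng.beta(p * ratio, (1.0 - p) * ratio)


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions, uniform on [1, length], sorted."""
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _apply_sweeps(
    freq: np.ndarray, sweeps: list[SweepWindow], pop: str, sites: pd.DataFrame
) -> None:
    for sw in sweeps:
        if sw.population != pop:
            continue
        sel = (sites["chrom"] == sw.chrom) & (sites["pos"] - 1 >= sw.start) & (sites["pos"] - 1 < sw.end)
        freq[sel.to_numpy()] = sw.target_freq


def _mosaic_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,
    n_hap: int,
    chrom_slices: list[slice],
    positions: list[np.ndarray],
    switch_rate: float,
) -> np.ndarray:
    """Sample ``n_hap`` copy-path haplotypes over a founder pool."""
    n_founders, n_sites = founders.shape
    hap = np.empty((n_hap, n_sites), dtype=np.int8)
    for sl, pos in zip(chrom_slices, positions):
        gaps = np.diff(pos)
        p_switch = -np.expm1(-switch_rate * gaps)
        switches = rng.random((n_hap, gaps.size)) < p_switch
        # founder id is re-drawn at every switch; indexing the draw by the
        # site of the most recent switch (renewal form) keeps the stream
        # fixed-size, so runs sharing a seed stay locally coupled across
        # switch_rate values (their switch sets are nested)
        last_switch = np.zeros((n_hap, pos.size), dtype=np.int64)
        if pos.size > 1:
            site_idx = np.arange(1, pos.size)[None, :]
            np.maximum.accumulate(np.where(switches, site_idx, 0), axis=1,
                                  out=last_switch[:, 1:])
        draws = rng.integers(0, n_founders, size=(n_hap, pos.size))
        fid = draws[np.arange(n_hap)[:, None], last_switch]
        cols = np.arange(sl.start, sl.stop)
        hap[:, sl] = founders[fid, cols[None, :]]
    return hap


def simulate_three_pop(config: SimConfig) -> tuple[GenotypeMatrix, SampleMap, SimTruth]:
    """Simulate genotypes for the wild / local / commercial design.

    Returns the dosage matrix, the sample map (with the egg/dual split
    recorded as breed and type), and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names()

    # 1. site positions, per chromosome
    positions = [_draw_positions(rng, config.chrom_length_bp, config.n_sites) for _ in chroms]
    sites = pd.DataFrame(
        {
            "chrom": np.repeat(chroms, [p.size for p in positions]),
            "pos": np.concatenate(positions),
            "ref": "A",
            "alt": "C",
        }
    )[SITE_COLUMNS]
    n_sites = len(sites)
    offsets = np.cumsum([0] + [p.size for p in positions])
    chrom_slices = [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]

    # 2. ancestral and per-population frequencies
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    split = config.egg_dual_split
    pop_freqs: dict[str, np.ndarray] = {}
    for pop in POPULATIONS:
        pop_freqs[pop] = _balding_nichols(rng, anc, config.drift(pop))
        _apply_sweeps(pop_freqs[pop], config.sweep_windows, pop, sites)
        if pop == "local" and split is not None:
            for sub, f_sub in (("egg", split.f_egg), ("dual", split.f_dual)):
                pop_freqs[sub] = _balding_nichols(rng, pop_freqs["local"], f_sub)
                _apply_sweeps(pop_freqs[sub], config.sweep_windows, sub, sites)
                _apply_sweeps(pop_freqs[sub], split.sweep_windows, sub, sites)

    # 3. founder pools and mosaic individuals, in fixed pool order
    pools: list[tuple[str, str, str, np.ndarray]] = []  # (pop, breed, type, freq)
    if split is None:
        pools = [
            ("wild", "wild", "wild", pop_freqs["wild"]),
            ("local", "local", "dual", pop_freqs["local"]),
            ("commercial", "commercial", "meat", pop_freqs["commercial"]),
        ]
    else:
        pools = [
            ("wild", "wild", "wild", pop_freqs["wild"]),
            ("local", "local_egg", "egg", pop_freqs["egg"]),
            ("local", "local_dual", "dual", pop_freqs["dual"]),
            ("commercial", "commercial", "meat", pop_freqs["commercial"]),
        ]

    dosage_blocks = []
    sample_rows = []
    for pop, breed, type_, freq in pools:
        n_pop = config.pop_size(pop)
        if pop == "local" and split is not None:
            n_egg = int(round(split.egg_fraction * n_pop))
            n_ind = n_egg if type_ == "egg" else n_pop - n_egg
        else:
            n_ind = n_pop
        n_founders = config.founders(pop)
        founders = (rng.random((n_founders, n_sites)) < freq).astype(np.int8)
        hap = _mosaic_haplotypes(
            rng, founders, 2 * n_ind, chrom_slices, positions, config.switch_rate
        )
        start_idx = len(sample_rows)
        for i in range(n_ind):
            sample_rows.append((f"{breed}_{i:03d}", pop, breed, type_))
        dosage_blocks.append((hap, start_idx))

    # 4. assemble dosages, then force ROH tracts haplotype-identical
    samples = [r[0] for r in sample_rows]
    sample_index = {s: i for i, s in enumerate(samples)}
    dosage = np.empty((len(samples), n_sites), dtype=np.int8)
    haplotypes: dict[int, np.ndarray] = {}
    for hap, start_idx in dosage_blocks:
        n_ind = hap.shape[0] // 2
        dosage[start_idx : start_idx + n_ind] = hap[0::2] + hap[1::2]
        for i in range(n_ind):
            haplotypes[start_idx + i] = hap[2 * i]
    for tr in config.roh_tracts:
        if tr.sample_id not in sample_index:
            raise ValueError(f"ROH tract names unknown sample {tr.sample_id}")
        idx = sample_index[tr.sample_id]
        sel = (
            (sites["chrom"] == tr.chrom)
            & (sites["pos"] - 1 >= tr.start)
            & (sites["pos"] - 1 < tr.end)
        ).to_numpy()
        dosage[idx, sel] = 2 * haplotypes[idx][sel]

    # 5. missingness
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = -1

    geno = GenotypeMatrix(
        dosage,
        sites,
        samples,
        {c: config.chrom_length_bp for c in chroms},
    )
    samplemap = SampleMap(
        pd.DataFrame(sample_rows, columns=["sample_id", "population", "breed", "type"])
    )
    all_sweeps = list(config.sweep_windows)
    if split is not None:
        all_sweeps += list(split.sweep_windows)
    truth = SimTruth(
        sites=sites[["chrom", "pos"]].copy(),
        ancestral_freq=anc,
        pop_freqs=pop_freqs,
        sweeps=all_sweeps,
        tracts=list(config.roh_tracts),
        seed=config.seed,
    )
    return geno, samplemap, truth


# ----------------------------------------------------------------------------
# truth file round-trip
# ----------------------------------------------------------------------------

_TRUTH_HEADER = ["record", "chrom", "pos", "population", "start", "end", "value", "sample"]


def write_truth(truth: SimTruth, path) -> None:
    """Serialize a SimTruth to one long-format TSV (lossless round-trip)."""
    rows: list[list] = []
    rows.append(["seed", "", "", "", "", "", repr(int(truth.seed)), ""])
    for sw in truth.sweeps:
        rows.append(["sweep", sw.chrom, "", sw.population, sw.start, sw.end, repr(sw.target_freq), ""])
    for tr in truth.tracts:
        rows.append(["tract", tr.chrom, "", "", tr.start, tr.end, "", tr.sample_id])
    chrom = truth.sites["chrom"].to_numpy()
    pos = truth.sites["pos"].to_numpy()
    for j in range(len(truth.sites)):
        rows.append(["freq", chrom[j], pos[j], "ancestral", "", "", repr(float(truth.ancestral_freq[j])), ""])
    for pop, freq in truth.pop_freqs.items():
        for j in range(len(truth.sites)):
            rows.append(["freq", chrom[j], pos[j], pop, "", "", repr(float(freq[j])), ""])
    pd.DataFrame(rows, columns=_TRUTH_HEADER).to_csv(path, sep="\t", index=False)


def read_truth(path) -> SimTruth:
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "population": str, "sample": str},
        float_precision="round_trip",
    )
    seed_rows = frame[frame["record"] == "seed"]
    seed = int(seed_rows["value"].iloc[0]) if len(seed_rows) else 0
    sweeps = [
        SweepWindow(r.population, r.chrom, int(r.start), int(r.end), float(r.value))
        for r in frame[frame["record"] == "sweep"].itertuples()
    ]
    tracts = [
        RohTract(r.sample, r.chrom, int(r.start), int(r.end))
        for r in frame[frame["record"] == "tract"].itertuples()
    ]
    freqs = frame[frame["record"] == "freq"]
    anc = freqs[freqs["population"] == "ancestral"]
    sites = anc[["chrom", "pos"]].astype({"pos": int}).reset_index(drop=True)
    pop_freqs = {
        pop: sub["value"].astype(float).to_numpy()
        for pop, sub in freqs[freqs["population"] != "ancestral"].groupby("population", sort=False)
    }
    return SimTruth(
        sites=sites,
        ancestral_freq=anc["value"].astype(float).to_numpy(),
        pop_freqs=pop_freqs,
        sweeps=sweeps,
        tracts=tracts,
        seed=seed,
    )
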