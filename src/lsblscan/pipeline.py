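"""End-to-end driver: simulate/load -> QC -> diversity, ROH, LD,
structure -> Fst/LSBL/region scans -> report.

Every stage draws its randomness from a seed derived from the master
seed and the stage name (CRC32 mix), so adding a stage never perturbs
the streams of earlier ones; with fixed seeds the whole run is
bit-stable.  All outputs are TSV (tracks BED-like half-open), trees
Newick, genotypes VCFv4.2, plus a manifest echoing the configuration.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lsblscan import diversity, linkage, roh, selection, structure, synthio, variants
from lsblscan.windows import write_track

log = logging.getLogger("lsblscan")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: str = "lsblscan_out"
    vcf: str | None = None  # when None, simulate
    sample_map: str | None = None
    gff: str | None = None
    sim: synthio.SimConfig = field(default_factory=synthio.SimConfig)
    window: int = 50_000
    step: int = 25_000
    fine_window: int = 10_000
    fine_step: int = 5_000
    lsbl_q: float = 0.01
    egg_q: float = 0.05
    min_snps_per_window: int = 10
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    ld_max_dist: int = 500_000
    ld_bin_width: int = 25_000
    ld_max_pairs_per_bin: int = 100_000
    equalize_n: int | None = None
    pca_k: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (self.window >= self.step > 0 and self.fine_window >= self.fine_step > 0):
            raise ValueError("require window >= step > 0")
        for q in (self.lsbl_q, self.egg_q):
            if not 0 < q < 0.5:
                raise ValueError("quantiles must be in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            sweeps = [synthio.SweepWindow(**s) for s in sim_raw.pop("sweep_windows", [])]
            tracts = [synthio.RohTract(**t) for t in sim_raw.pop("roh_tracts", [])]
            split_raw = sim_raw.pop("egg_dual_split", "default")
            cfg.sim = synthio.SimConfig(**sim_raw, sweep_windows=sweeps, roh_tracts=tracts)
            if split_raw is None:
                cfg.sim.egg_dual_split = None
            elif split_raw != "default":
                sub_sweeps = [synthio.SweepWindow(**s) for s in split_raw.pop("sweep_windows", [])]
                cfg.sim.egg_dual_split = synthio.EggDualSplit(**split_raw, sweep_windows=sub_sweeps)
        return cfg


def equalize_samples(
    samplemap: variants.SampleMap, n: int = 72, seed: int = 0
) -> variants.SampleMap:
    """Seeded per-population subsample of size n, proportional by breed.

    Breed quotas use largest-remainder rounding; populations smaller
    than n are kept whole (with a warning).  Sampling within a breed is
    without replacement.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    frame = samplemap.frame
    for pop in samplemap.populations():
        sub = frame[frame["population"] == pop]
        if len(sub) <= n:
            if len(sub) < n:
                log.warning("population %s has only %d samples (< %d); keeping all", pop, len(sub), n)
            chosen.extend(sub["sample_id"])
            continue
        breeds = sub.groupby("breed", sort=True)["sample_id"].apply(list)
        counts = np.array([len(v) for v in breeds])
        exact = n * counts / counts.sum()
        quota = np.floor(exact).astype(int)
        remainder = exact - quota
        short = n - quota.sum()
        # largest remainders first; ties broken by larger breed, then name
        order = sorted(
            range(len(breeds)),
            key=lambda i: (-remainder[i], -counts[i], breeds.index[i]),
        )
        for i in order[:short]:
            quota[i] += 1
        for i, (breed, ids) in enumerate(breeds.items()):
            take = rng.choice(len(ids), size=quota[i], replace=False)
            chosen.extend(ids[t] for t in sorted(take))
    return samplemap.subset(chosen)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis skeleton; returns the report dictionary.

    Stage outputs are written under ``config.out_dir`` together with a
    manifest (stage, seed, output files).  A stage failure aborts with
    the failing stage named; earlier outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    report: dict = {}

    def record(stage: str, files: list[str], **info) -> None:
        manifest.append({"stage": stage, "seed": stage_seed(config.seed, stage), "files": files, **info})
        log.info("stage %-12s -> %s", stage, ", ".join(files) or "-")

    stage = "input"
    try:
        truth = None
        if config.vcf is None:
            sim = config.sim
            sim.seed = stage_seed(config.seed, "simulate")
            geno, samplemap, truth = synthio.simulate_three_pop(sim)
            variants.write_vcf(geno, out / "simulated.vcf")
            samplemap.write(out / "samples.tsv")
            synthio.write_truth(truth, out / "truth.tsv")
            record("simulate", ["simulated.vcf", "samples.tsv", "truth.tsv"],
                   n_samples=geno.n_samples, n_sites=geno.n_sites)
        else:
            geno = variants.read_vcf(config.vcf)
            samplemap = variants.SampleMap.read(config.sample_map)
            record("input", [], n_samples=geno.n_samples, n_sites=geno.n_sites)

        stage = "qc"
        geno = variants.filter_biallelic(geno)
        geno = variants.filter_maf_hwe(geno, config.maf_min, config.hwe_p_min)
        variants.write_vcf(geno, out / "qc.vcf")
        record("qc", ["qc.vcf"], n_sites=geno.n_sites)

        if config.equalize_n:
            stage = "equalize"
            samplemap = equalize_samples(samplemap, config.equalize_n, stage_seed(config.seed, "equalize"))
            geno = geno.take_samples(list(samplemap.frame["sample_id"]))
            record("equalize", [], n_samples=geno.n_samples)

        stage = "diversity"
        summary, pi_tracks, f_by_pop = diversity.population_diversity(
            geno, samplemap, config.window, config.step
        )
        stage_files = []
        for pop, track in pi_tracks.items():
            write_track(track, out / f"pi_{pop}.tsv")
            stage_files.append(f"pi_{pop}.tsv")

        stage = "roh"
        segments = roh.detect_roh_all(geno)
        roh.segments_frame(segments).to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        per_ind, per_pop = roh.roh_summary(segments, samplemap)
        per_ind.to_csv(out / "roh_individuals.tsv", sep="\t", index=False)
        roh_by_pop = {}
        frame = roh.segments_frame(segments)
        pop_of = {s: samplemap.population_of(s) for s in samplemap.frame["sample_id"]}
        for pop in samplemap.populations():
            roh_by_pop[pop] = frame.loc[frame["sample_id"].map(pop_of) == pop, "kb"].to_numpy()
        record("roh", ["roh_segments.tsv", "roh_individuals.tsv"], n_segments=len(segments))

        counts = variants.group_site_counts(geno, samplemap, "population")
        ho, he = diversity.site_het(counts)
        summary = diversity.summarize_diversity(
            {p: he[i] for i, p in enumerate(counts.groups)},
            {p: ho[i] for i, p in enumerate(counts.groups)},
            pi_tracks, f_by_pop, roh_by_pop,
        )
        summary.to_csv(out / "diversity_summary.tsv", sep="\t", index=False)
        record("diversity", stage_files + ["diversity_summary.tsv"])
        report["diversity"] = summary

        stage = "ld"
        ld_seed = stage_seed(config.seed, "ld")
        decay = {}
        for pop in samplemap.populations():
            sub = geno.take_samples(samplemap.samples_in(pop))
            decay[pop] = linkage.ld_decay(
                sub, config.ld_max_dist, config.ld_bin_width,
                config.ld_max_pairs_per_bin, ld_seed,
            )
            decay[pop].to_csv(out / f"ld_decay_{pop}.tsv", sep="\t", index=False)
            ne = linkage.ne_from_ld(decay[pop], sub.n_samples)
            ne.to_csv(out / f"ne_{pop}.tsv", sep="\t", index=False)
        record("ld", [f"ld_decay_{p}.tsv" for p in decay])
        report["ld_decay"] = decay

        stage = "structure"
        pca_res = structure.pca(geno, min(config.pca_k, geno.n_samples))
        pca_res.coords.to_csv(out / "pca_coords.tsv", sep="\t")
        pd.DataFrame(
            {"eigenvalue": pca_res.eigenvalues, "explained_pct": pca_res.explained_pct}
        ).to_csv(out / "pca_eigen.tsv", sep="\t", index=False)
        dist = structure.ibs_distance(geno)
        dist.to_csv(out / "ibs_distance.tsv", sep="\t")
        newick = structure.nj_tree(dist)
        (out / "nj_tree.nwk").write_text(newick + "\n")
        record("structure", ["pca_coords.tsv", "pca_eigen.tsv", "ibs_distance.tsv", "nj_tree.nwk"])
        report["pca_explained_pct"] = pca_res.explained_pct

        stage = "selection"
        pairs = {
            ("commercial", "local"): None,
            ("commercial", "wild"): None,
            ("local", "wild"): None,
        }
        for pair in list(pairs):
            t = selection.pairwise_window_fst(geno, samplemap, pair, "population",
                                              config.window, config.step)
            write_track(t, out / f"fst_{pair[0]}_{pair[1]}.tsv")
            pairs[pair] = t
        lsbl_tracks = {}
        for focal, y, z in (("commercial", "local", "wild"), ("local", "commercial", "wild")):
            xy = pairs[tuple(sorted((focal, y), key=["commercial", "local", "wild"].index))]
            xz = pairs[tuple(sorted((focal, z), key=["commercial", "local", "wild"].index))]
            yz = pairs[tuple(sorted((y, z), key=["commercial", "local", "wild"].index))]
            lt = selection.lsbl(xy, xz, yz, focal=focal)
            write_track(lt, out / f"lsbl_{focal}.tsv")
            lsbl_tracks[focal] = lt
        record("selection", [f"lsbl_{f}.tsv" for f in lsbl_tracks])

        stage = "regions"
        genes = variants.read_gff_genes(config.gff) if config.gff else None
        report["regions"] = {}
        for focal, lt in lsbl_tracks.items():
            regions = selection.top_quantile_regions(lt, config.lsbl_q, config.min_snps_per_window)
            if genes is not None:
                regions = selection.annotate_regions(regions, genes)
            selection.regions_frame(regions).to_csv(
                out / f"regions_{focal}.tsv", sep="\t", index=False
            )
            report["regions"][focal] = regions
            others = tuple(p for p in ("commercial", "local", "wild") if p != focal)[:2]
            fine_rows = []
            for ri, region in enumerate(regions):
                ft, fpis = selection.fine_scan(
                    geno, samplemap, region, focal, others,
                    config.fine_window, config.fine_step,
                )
                ft = ft.assign(region=ri)
                fine_rows.append(ft)
            if fine_rows:
                pd.concat(fine_rows, ignore_index=True).to_csv(
                    out / f"finescan_{focal}.tsv", sep="\t", index=False
                )
        record("regions", [f"regions_{f}.tsv" for f in lsbl_tracks])

        stage = "eggscan"
        egg_ids = samplemap.samples_in("local", "egg")
        dual_ids = samplemap.samples_in("local", "dual")
        if egg_ids and dual_ids:
            pi_egg = diversity.windowed_pi(geno.take_samples(egg_ids), config.window, config.step)
            pi_dual = diversity.windowed_pi(geno.take_samples(dual_ids), config.window, config.step)
            counts_ed = variants.group_site_counts(
                geno, samplemap, {"egg": egg_ids, "dual": dual_ids}
            )
            comp = selection.wc_fst_site(counts_ed.row("egg"), counts_ed.row("dual"))
            fst_ed = selection.windowed_fst(comp, geno.sites, geno.chrom_lengths,
                                            config.window, config.step)
            write_track(fst_ed, out / "fst_egg_dual.tsv")
            egg_regions, dual_regions = selection.pi_ratio_scan(
                pi_egg, pi_dual, fst_ed, config.egg_q, config.min_snps_per_window
            )
            if genes is not None:
                egg_regions = selection.annotate_regions(egg_regions, genes)
                dual_regions = selection.annotate_regions(dual_regions, genes)
            selection.regions_frame(egg_regions).to_csv(out / "regions_egg.tsv", sep="\t", index=False)
            selection.regions_frame(dual_regions).to_csv(out / "regions_dual.tsv", sep="\t", index=False)
            report["regions"]["egg"] = egg_regions
            report["regions"]["dual"] = dual_regions
            record("eggscan", ["fst_egg_dual.tsv", "regions_egg.tsv", "regions_dual.tsv"])

        if truth is not None and truth.sweeps:
            stage = "recovery"
            rows = []
            for sw in truth.sweeps:
                focal = {"egg": "egg", "dual": "dual"}.get(sw.population, sw.population)
                regions = report["regions"].get(focal, [])
                hit = any(
                    r.chrom == sw.chrom and r.start < sw.end and r.end > sw.start
                    for r in regions
                )
                rows.append((sw.population, sw.chrom, sw.start, sw.end, hit))
            rec = pd.DataFrame(rows, columns=["population", "chrom", "start", "end", "recovered"])
            rec.to_csv(out / "sweep_recovery.tsv", sep="\t", index=False)
            record("recovery", ["sweep_recovery.tsv"])
            report["sweep_recovery"] = rec
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    report["manifest"] = manifest
    return report
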