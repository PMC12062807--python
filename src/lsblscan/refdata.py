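"""Packaged reference metadata for the 416-duck resequencing panel.

Two small tables ship with the package: the cohort composition (22
breeds grouped into wild / local / commercial populations, with the
egg / dual / meat type of each breed) and the post-QC SNP count summary
(per-population and shared/unique counts).  They parameterize the
synthetic study design and provide consistency checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

def _load(name: str) -> pd.DataFrame:
    with resources.files("lsblscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def cohort_table() -> pd.DataFrame:
    """Breed-level cohort composition: population, breed, count, type."""
    return _load("duck_cohort.tsv")


def population_sizes() -> dict[str, int]:
    """Total individuals per population (wild 72, local 159, commercial 185)."""
    t = cohort_table()
    return {str(p): int(s) for p, s in t.groupby("population")["count"].sum().items()}


def snp_counts() -> dict[str, int]:
    t = _load("snp_counts.tsv")
    return {str(r.set): int(r.n_snps) for r in t.itertuples()}


def shared_snp_percentage() -> float:
    """Percentage of post-QC SNPs segregating in all three populations."""
    c = snp_counts()
    return 100.0 * c["shared"] / c["total"]
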