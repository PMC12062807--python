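"""VCF IO, QC filters, the Hardy-Weinberg exact test, and grouped counts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lsblscan.variants import (
    GenotypeMatrix,
    filter_biallelic,
    filter_maf_hwe,
    group_site_counts,
    hwe_exact_p,
    read_gff_genes,
    read_vcf,
    write_vcf,
)
from tests.conftest import make_geno, make_map


# ---------------------------------------------------------------- VCF IO

VCF_ONE_SITE = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td\te
chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\t./1
"""


def test_read_vcf_dosage_encoding(tmp_path):
    """GT 0/0, 0/1, 1/1 map to dosages 0, 1, 2; ./. and half-calls to missing."""
    path = tmp_path / "one.vcf"
    path.write_text(VCF_ONE_SITE)
    geno = read_vcf(path)
    assert geno.samples == list("abcde")
    assert geno.dosage[:, 0].tolist() == [0, 1, 2, -1, -1]
    assert geno.chrom_lengths == {"chr1": 1000}


def test_vcf_round_trip(tmp_path, small_sim):
    geno, _, _ = small_sim
    path = tmp_path / "rt.vcf"
    write_vcf(geno, path)
    back = read_vcf(path)
    assert back.samples == geno.samples
    assert np.array_equal(back.dosage, geno.dosage)
    assert back.sites[["chrom", "pos"]].equals(geno.sites[["chrom", "pos"]])


def test_read_vcf_rejects_duplicate_positions(tmp_path):
    bad = VCF_ONE_SITE + "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0\n"
    path = tmp_path / "dup.vcf"
    path.write_text(bad)
    with pytest.raises(ValueError, match="duplicate"):
        read_vcf(path)


# ---------------------------------------------------------------- QC chain

def test_filter_biallelic_thresholds():
    # 10 diploids: site0 MAF 0.005-equivalent is impossible; use 100 samples
    n = 100
    dos = np.zeros((n, 4), dtype=np.int8)
    dos[0, 0] = 1  # MAF 0.005 -> removed
    dos[:30, 1] = 1  # MAF 0.15 -> kept
    dos[:, 2] = 0  # monomorphic -> removed
    dos[:, 3] = -1
    dos[:4, 3] = 1  # 96% missing -> removed (0.96 > 0.9)
    geno = make_geno(dos)
    kept = filter_biallelic(geno)
    assert kept.sites["pos"].tolist() == [200]


def test_filter_maf_hwe_toy():
    """6-site toy: 2 low-MAF + 1 extreme HWE departure removed, 3 clean kept."""
    n = 50
    cols = []
    low1 = np.zeros(n, dtype=np.int8); low1[:2] = 1            # MAF 0.02
    low2 = np.zeros(n, dtype=np.int8); low2[0] = 2             # MAF 0.02
    hwe_bad = np.zeros(n, dtype=np.int8); hwe_bad[: n // 2] = 2  # no hets, p ~ 1e-14
    clean = np.array([0] * 12 + [1] * 26 + [2] * 12, dtype=np.int8)  # near-modal hets
    for c in (low1, low2, hwe_bad, clean, 2 - clean, np.roll(clean, 5)):
        cols.append(c)
    geno = make_geno(np.array(cols).T)
    kept = filter_maf_hwe(geno)
    assert kept.n_sites == 3
    assert hwe_exact_p(n // 2, 0, n // 2) < 1e-6


def test_maf_exactly_at_threshold_is_kept():
    n = 50  # MAF exactly 0.05: 5 alt alleles in 100
    col = np.zeros(n, dtype=np.int8)
    col[:5] = 1
    geno = make_geno(col[:, None])
    assert filter_maf_hwe(geno).n_sites == 1


def test_retained_sites_revalidate(small_sim):
    """Every site surviving the QC chain satisfies all thresholds when re-checked."""
    geno, _, _ = small_sim
    qc = filter_maf_hwe(filter_biallelic(geno))
    maf = qc.minor_af()
    assert (maf >= 0.05).all()
    hom_ref = (qc.dosage == 0).sum(axis=0)
    het = (qc.dosage == 1).sum(axis=0)
    hom_alt = (qc.dosage == 2).sum(axis=0)
    ps = [hwe_exact_p(a, b, c) for a, b, c in zip(hom_ref, het, hom_alt)]
    assert min(ps) >= 1e-6


# ---------------------------------------------------------------- HWE exact test

def hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Brute-force enumeration of the conditional heterozygote distribution,
    in exact integer arithmetic."""
    from fractions import Fraction

    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het
    nb = 2 * n_hom_ref + n_het
    weights = {}
    for h in range(na % 2, min(na, nb) + 1, 2):
        ha, hb = (na - h) // 2, (nb - h) // 2
        weights[h] = (
            2**h
            * math.factorial(n)
            // (math.factorial(ha) * math.factorial(h) * math.factorial(hb))
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


def test_hwe_modal_configuration_is_one():
    assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0, abs=1e-12)


def test_hwe_no_hets_matches_enumeration():
    assert hwe_exact_p(50, 0, 50) == pytest.approx(hwe_oracle(50, 0, 50), abs=1e-12)


def test_hwe_two_hets_only_two_configurations():
    assert hwe_exact_p(0, 2, 0) == pytest.approx(1.0, abs=1e-12)


def test_hwe_all_missing_site_returns_one():
    assert hwe_exact_p(0, 0, 0) == 1.0


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
)
def test_hwe_matches_enumeration_oracle(hr, het, ha):
    """Exact conditional p equals brute-force enumeration to 1e-12."""
    if hr + het + ha == 0:
        return
    assert hwe_exact_p(hr, het, ha) == pytest.approx(hwe_oracle(hr, het, ha), abs=1e-12)


# ---------------------------------------------------------------- GFF3 and counts

GFF = """##gff-version 3
chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=geneA
chr1\tsrc\texon\t100\t150\t.\t+\t.\tParent=geneA
chr2\tsrc\tgene\t500\t800\t.\t-\t.\tID=geneB
"""


def test_read_gff_genes_half_open(tmp_path):
    path = tmp_path / "g.gff3"
    path.write_text(GFF)
    genes = read_gff_genes(path)
    assert len(genes) == 2
    a = genes.frame.set_index("gene_id")
    assert (a.loc["geneA", "start"], a.loc["geneA", "end"]) == (99, 200)
    assert set(genes.frame["strand"]) == {"+", "-"}


def test_read_gff_no_genes(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("##gff-version 3\nchr1\tsrc\texon\t1\t10\t.\t+\t.\tID=x\n")
    with pytest.warns(UserWarning):
        genes = read_gff_genes(path)
    assert len(genes) == 0


def test_group_site_counts_partition_conservation():
    dos = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
    geno = make_geno(dos)
    sm = make_map(geno, ["wild", "wild", "local", "local"])
    counts = group_site_counts(geno, sm, {"g1": geno.samples[:2], "g2": geno.samples[2:]})
    assert counts.alt_count.sum(axis=0).tolist() == [4, 4]
    pooled = group_site_counts(geno, sm, {"all": geno.samples})
    assert np.array_equal(counts.alt_count.sum(axis=0), pooled.alt_count[0])
    assert np.array_equal(counts.n_called.sum(axis=0), pooled.n_called[0])


def test_group_site_counts_direct():
    dos = np.array([[0], [1], [2]], dtype=np.int8)
    geno = make_geno(dos)
    sm = make_map(geno, ["wild"] * 3)
    counts = group_site_counts(geno, sm, {"g": geno.samples})
    assert counts.n_called[0, 0] == 3
    assert counts.alt_count[0, 0] == 3
    assert counts.het_count[0, 0] == 1
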