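"""Window statistics, outlier flagging, region calling and SNP annotation."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from domescan import popgen
from domescan.popgen import (
    GeneModel,
    Window,
    annotate_snp_effects,
    call_signature_regions,
    classify_codon_change,
    flag_outlier_windows,
    make_windows,
    read_gff,
    read_vcf,
    ref_allele_frequency_profile,
    window_fst,
    window_pi,
    write_gff,
    write_vcf,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# windows

def test_make_windows_examples():
    ws = make_windows(100, 50, 25)
    assert [(w.start, w.end) for w in ws] == [(0, 50), (25, 75), (50, 100)]
    with pytest.warns(UserWarning):
        assert make_windows(49, 50, 25) == []
    tiling = make_windows(100, 25, 25)
    assert [(w.start, w.end) for w in tiling] == [
        (0, 25), (25, 50), (50, 75), (75, 100)
    ]


def test_make_windows_rejects_bad_step():
    with pytest.raises(ValueError):
        make_windows(100, 10, 20)


# ---------------------------------------------------------------------------
# nucleotide diversity

def test_window_pi_single_site_half_frequency():
    # 2 diploids = 4 allele copies, 2 ref / 2 alt, 100 bp window:
    # 4 of the 6 haplotype pairs differ -> (2/3)/100
    table = make_table([[1, 1]], positions=[10])
    pi, n = window_pi(table, ["S0", "S1"], Window("chr1", 0, 100))
    assert pi == pytest.approx((4 / 3 * 0.5) / 100, abs=1e-12)
    assert n == 1


def test_window_pi_monomorphic_zero():
    table = make_table([[0, 0], [2, 2]], positions=[5, 6])
    pi, _ = window_pi(table, ["S0", "S1"], Window("chr1", 0, 100))
    assert pi == 0.0


def test_window_pi_two_haplotypes_three_diffs():
    # one hom-ref and one hom-alt diploid -> per site all 4 copies 2/2 split;
    # emulate 2 haplotypes by a single diploid het at 3 sites with
    # min_called=2: mean pairwise difference 3 / 1000 bp
    table = make_table([[1], [1], [1]], positions=[1, 2, 3])
    pi, _ = window_pi(table, ["S0"], Window("chr1", 0, 1000), min_called=2)
    assert pi == pytest.approx(3 / 1000, abs=1e-12)


def test_window_pi_empty_window():
    table = make_table([[1, 1]], positions=[500])
    pi, n = window_pi(table, ["S0", "S1"], Window("chr1", 0, 100))
    assert (pi, n) == (0.0, 0)


def _pairwise_pi_oracle(haplotypes: np.ndarray, window_len: int) -> float:
    """Mean pairwise hamming distance among haplotypes, per bp."""
    n = len(haplotypes)
    pairs = list(itertools.combinations(range(n), 2))
    total = sum((haplotypes[i] != haplotypes[j]).sum() for i, j in pairs)
    return total / len(pairs) / window_len


@settings(derandomize=True, max_examples=60)
@given(
    n_dip=st.integers(2, 5),
    n_snps=st.integers(1, 100),
    seed=st.integers(0, 10_000),
)
def test_window_pi_matches_pairwise_oracle(n_dip, n_snps, seed):
    """Site-frequency pi equals brute-force mean pairwise haplotype diffs."""
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, (2 * n_dip, n_snps))
    geno = haps[0::2] + haps[1::2]          # random pairing into diploids
    window_len = n_snps + 10
    table = make_table(geno.T, positions=np.arange(1, n_snps + 1))
    pi, _ = window_pi(
        table, [f"S{i}" for i in range(n_dip)],
        Window("chr1", 0, window_len), min_called=2,
    )
    assert pi == pytest.approx(
        _pairwise_pi_oracle(haps, window_len), abs=1e-12
    )


def test_pi_translation_invariance():
    rng = np.random.default_rng(0)
    geno = rng.integers(0, 3, (20, 6))
    shift = 12_345
    t1 = make_table(geno, positions=np.arange(1, 21))
    t2 = make_table(geno, positions=np.arange(1, 21) + shift)
    g = [f"S{i}" for i in range(6)]
    p1, _ = window_pi(t1, g, Window("chr1", 0, 50))
    p2, _ = window_pi(t2, g, Window("chr1", shift, 50 + shift))
    assert p1 == p2


# ---------------------------------------------------------------------------
# Fst

@pytest.mark.parametrize("estimator", ["wc", "hudson"])
def test_fst_fixed_difference_is_one(estimator):
    geno = np.array([[2] * 10 + [0] * 10])   # alt-fixed vs ref-fixed
    table = make_table(geno)
    a = [f"S{i}" for i in range(10)]
    b = [f"S{i}" for i in range(10, 20)]
    fst, _ = window_fst(table, a, b, Window("chr1", 0, 10),
                        estimator=estimator, min_snps=1)
    assert fst == 1.0


def test_hudson_closed_form_negative():
    # p1 = p2 = 0.5 with n1 = n2 = 10 allele copies:
    # (0 - 2*0.25/9) / 0.5 = -1/9
    geno = np.array([[2, 2, 1, 0, 0, 2, 2, 1, 0, 0]])
    table = make_table(geno)
    a = [f"S{i}" for i in range(5)]
    b = [f"S{i}" for i in range(5, 10)]
    fst, _ = window_fst(table, a, b, Window("chr1", 0, 10),
                        estimator="hudson", min_snps=1)
    assert fst == pytest.approx(-1 / 9, abs=1e-12)


@pytest.mark.parametrize("estimator", ["wc", "hudson"])
def test_fst_never_exceeds_one(estimator):
    rng = np.random.default_rng(3)
    geno = rng.integers(0, 3, (50, 12))
    table = make_table(geno)
    a = [f"S{i}" for i in range(6)]
    b = [f"S{i}" for i in range(6, 12)]
    fst, _ = window_fst(table, a, b, Window("chr1", 0, 60),
                        estimator=estimator, min_snps=1)
    assert fst <= 1.0


def test_fst_undefined_below_min_snps():
    table = make_table(np.ones((3, 8), dtype=int))
    a, b = [f"S{i}" for i in range(4)], [f"S{i}" for i in range(4, 8)]
    fst, n = window_fst(table, a, b, Window("chr1", 0, 10), min_snps=10)
    assert np.isnan(fst) and n == 3


def test_fst_monomorphic_denominator_zero():
    table = make_table(np.zeros((12, 8), dtype=int))
    a, b = [f"S{i}" for i in range(4)], [f"S{i}" for i in range(4, 8)]
    fst, _ = window_fst(table, a, b, Window("chr1", 0, 20), min_snps=1)
    assert np.isnan(fst)


# ---------------------------------------------------------------------------
# outlier flagging and region calling

def _window_frame(fst_values, pi_values=None):
    n = len(fst_values)
    return pd.DataFrame(
        dict(
            contig=["chr1"] * n,
            start=np.arange(n) * 25_000,
            end=np.arange(n) * 25_000 + 50_000,
            n_snps=50,
            pi_dom=pi_values if pi_values is not None else np.linspace(0.001, 0.01, n),
            pi_wild=0.01,
            fst=fst_values,
        )
    )


def test_flag_counts_top_one_percent_of_200():
    rng = np.random.default_rng(1)
    fst = rng.permutation(np.linspace(0.01, 0.99, 200))
    stats, _ = flag_outlier_windows(_window_frame(fst), fst_top_q=0.01)
    assert stats["flag_fst"].sum() == 2


@settings(derandomize=True, max_examples=25)
@given(n=st.integers(30, 400), seed=st.integers(0, 999))
def test_flag_count_bounds_distinct_values(n, seed):
    rng = np.random.default_rng(seed)
    fst = rng.permutation(np.linspace(0, 1, n))
    stats, _ = flag_outlier_windows(_window_frame(fst), fst_top_q=0.01)
    k = stats["flag_fst"].sum()
    assert int(np.floor(0.01 * n)) <= k <= int(np.ceil(0.01 * n))


def test_identical_fst_none_flagged():
    stats, cut = flag_outlier_windows(_window_frame(np.full(50, 0.3)))
    assert stats["flag_fst"].sum() == 0          # strict inequality at ties
    assert np.isnan(cut["fst_sd"]) or cut["fst_sd"] == 0.0
    assert stats["z"].isna().all()


def test_flagging_requires_enough_windows():
    with pytest.raises(ValueError):
        flag_outlier_windows(_window_frame(np.linspace(0, 1, 10)))


def test_zscore_and_pz():
    fst = np.linspace(0.0, 1.0, 100)
    stats, cut = flag_outlier_windows(_window_frame(fst))
    z = (fst - fst.mean()) / fst.std(ddof=1)
    assert stats["z"].to_numpy() == pytest.approx(z)
    assert ((stats["p_z"] >= 0) & (stats["p_z"] <= 1)).all()


def test_adjacent_flagged_windows_merge_into_one_region():
    fst = np.full(100, 0.1)
    fst[40], fst[41] = 0.9, 0.95
    pi = np.full(100, 0.01)
    pi[40], pi[41] = 1e-5, 2e-5
    stats, _ = flag_outlier_windows(_window_frame(fst, pi), fst_top_q=0.03,
                                    pi_low_q=0.05)
    regions = call_signature_regions(stats, step=25_000)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (40 * 25_000 + 1, 41 * 25_000 + 50_000)
    assert r.max_fst == 0.95 and r.min_focal_pi == 1e-5


def test_regions_do_not_merge_across_contigs():
    fst = np.full(60, 0.1)
    fst[10] = fst[40] = 0.9
    pi = np.full(60, 0.01)
    pi[10] = pi[40] = 1e-5
    stats, _ = flag_outlier_windows(_window_frame(fst, pi), fst_top_q=0.05)
    stats.loc[30:, "contig"] = "chr2"
    regions = call_signature_regions(stats, step=25_000)
    assert len(regions) == 2
    assert {r.contig for r in regions} == {"chr1", "chr2"}


def test_no_double_flag_no_regions():
    # high fst coincides with HIGH pi here, so no window carries both flags
    stats, _ = flag_outlier_windows(_window_frame(np.linspace(0, 1, 100),
                                                  np.linspace(0.001, 0.01, 100)))
    assert call_signature_regions(stats, step=25_000) == []


# ---------------------------------------------------------------------------
# allele-frequency profile

def test_profile_mixed_genotypes():
    table = make_table([[0, 1, 2]], positions=[50])
    prof = ref_allele_frequency_profile(table, ["S0", "S1", "S2"], "chr1", 0, 100)
    assert prof["ref_allele_freq"].iloc[0] == pytest.approx(0.5)
    assert prof["ref_hom_freq"].iloc[0] == pytest.approx(1 / 3)


def test_profile_all_hom_ref_and_all_missing():
    table = make_table([[0, 0, 0], [-1, -1, -1]], positions=[10, 20])
    prof = ref_allele_frequency_profile(table, ["S0", "S1", "S2"], "chr1", 0, 100)
    assert prof["ref_allele_freq"].iloc[0] == 1.0
    assert prof["ref_hom_freq"].iloc[0] == 1.0
    assert np.isnan(prof["ref_allele_freq"].iloc[1])
    assert prof["n_called"].iloc[1] == 0


# ---------------------------------------------------------------------------
# VCF round trip

def test_vcf_write_read_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    geno = rng.integers(-1, 3, (30, 6))
    table = make_table(geno, positions=np.arange(10, 40),
                       contig_length=1000)
    path = tmp_path / "t.vcf"
    write_vcf(table, path)
    back = read_vcf(path)
    assert back.samples == table.samples
    np.testing.assert_array_equal(back.genotypes, table.genotypes)
    np.testing.assert_array_equal(back.positions, table.positions)
    assert back.contig_lengths == {"chr1": 1000}


def test_read_vcf_skips_multiallelic_and_indels(tmp_path):
    path = tmp_path / "m.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tX\tY\n"
        "chr1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        "chr1\t20\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        "chr1\t30\t.\tAT\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        "chr1\t40\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\n"
    )
    table = read_vcf(path)
    assert table.n_snps == 2
    assert table.n_skipped == 2
    assert table.genotypes[1, 0] == -1      # missing preserved


# ---------------------------------------------------------------------------
# SNP effect annotation

def _mini_gene(strand="+", contig="chr1"):
    # reference: 10 bp pad + 2 codons + pad
    #   + strand CDS bases 10..16: ATG GCT
    pad = "T" * 10
    cds = "ATGGCT"
    ref = {contig: pad + cds + "T" * 10}
    gene = GeneModel("g1", contig, strand, [(10, 16)])
    return ref, gene


def test_synonymous_plus_strand():
    ref, gene = _mini_gene("+")
    # GCT -> GCC at the codon's 3rd base (genomic pos 16, 1-based)
    table = make_table([[1, 1]], positions=[16], ref=["T"], alt=["C"])
    effects, counts = annotate_snp_effects(table, [gene], ref)
    assert effects[0].effect_class == "synonymous"
    assert effects[0].aa_change is None
    assert counts["g1"] == 0


def test_nonsynonymous_atg_to_ata():
    ref, gene = _mini_gene("+")
    table = make_table([[1, 1]], positions=[13], ref=["G"], alt=["A"])
    effects, counts = annotate_snp_effects(table, [gene], ref)
    assert effects[0].effect_class == "non-synonymous"
    assert effects[0].aa_change == "M->I"
    assert counts["g1"] == 1


def test_intergenic_snp_non_coding():
    ref, gene = _mini_gene("+")
    table = make_table([[1, 1]], positions=[3], ref=["T"], alt=["A"])
    effects, _ = annotate_snp_effects(table, [gene], ref)
    assert effects[0].effect_class == "non-coding"
    assert effects[0].gene_id is None


def test_minus_strand_codon_reconstruction():
    # mRNA ATGGCT on the minus strand = genomic segment revcomp(ATGGCT) = AGCCAT
    ref = {"chr1": "T" * 10 + "AGCCAT" + "T" * 10}
    gene = GeneModel("g1", "chr1", "-", [(10, 16)])
    # mRNA 3rd base (codon ATG, offset 2) sits at genomic pos 13 (0-based),
    # base C; genomic C->T is mRNA G->A: ATG -> ATA, M->I
    table = make_table([[1, 1]], positions=[14], ref=["C"], alt=["T"])
    effects, _ = annotate_snp_effects(table, [gene], ref)
    assert effects[0].effect_class == "non-synonymous"
    assert effects[0].aa_change == "M->I"


def test_stop_gain_reported_nonsynonymous():
    # TGG (W) -> TGA (*): 3rd base G->A
    ref = {"chr1": "T" * 10 + "TGG" + "T" * 10}
    gene = GeneModel("g1", "chr1", "+", [(10, 13)])
    table = make_table([[1, 1]], positions=[13], ref=["G"], alt=["A"])
    effects, _ = annotate_snp_effects(table, [gene], ref)
    assert effects[0].effect_class == "non-synonymous"
    assert effects[0].aa_change == "W->*"


def test_cds_not_multiple_of_three_skipped():
    ref = {"chr1": "T" * 30}
    gene = GeneModel("g1", "chr1", "+", [(10, 14)])
    table = make_table([[1, 1]], positions=[12], ref=["T"], alt=["A"])
    with pytest.warns(UserWarning, match="not divisible by 3"):
        effects, counts = annotate_snp_effects(table, [gene], ref)
    assert effects[0].effect_class == "non-coding"
    assert counts == {}


def test_classify_codon_change_table():
    assert classify_codon_change("GCT", 2, "C") == ("synonymous", None)
    assert classify_codon_change("ATG", 2, "A") == ("non-synonymous", "M->I")


def test_gff_round_trip(tmp_path):
    genes = [
        GeneModel("gA", "chr1", "+", [(100, 400)]),
        GeneModel("gB", "chr1", "-", [(600, 900), (950, 1250)]),
    ]
    path = tmp_path / "g.gff3"
    write_gff(genes, path, {"chr1": 2000})
    back = {g.gene_id: g for g in read_gff(path)}
    for g in genes:
        assert back[g.gene_id].cds == g.cds
        assert back[g.gene_id].strand == g.strand
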