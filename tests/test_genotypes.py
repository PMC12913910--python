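"""Filter cascade exactness, orientation convention and dosage utilities."""

import numpy as np
import pytest

from wildgwas.genotypes import (DosageMatrix, FilterConfig, filter_sites,
                                impute_mean, read_vcf, records_from_dosage,
                                replicate_error_rate)

N = 52  # individuals in the constructed fixtures


def make_vcf(tmp_path, rows, n=N, with_dp=True):
    """Write a minimal VCF; each row is (chrom,pos,ref,alt,[(gt,dp),...])."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">']
    if with_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">')
    for chrom in dict.fromkeys(r[0] for r in rows):
        lines.append(f"##contig=<ID={chrom}>")
    samples = [f"ind{i}" for i in range(n)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    fmt = "GT:DP" if with_dp else "GT"
    for chrom, pos, ref, alt, cells in rows:
        cell_s = [f"{gt}:{dp}" if with_dp else gt for gt, dp in cells]
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\t{fmt}\t"
                     + "\t".join(cell_s))
    path = tmp_path / "fixture.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path


def cells(gts, dp=25):
    return [(g, dp) for g in gts]


def clean_site(chrom, pos, n_het=20):
    gts = ["0/1"] * n_het + ["0/0"] * (N - n_het)
    return (chrom, pos, "A", "C", cells(gts))


def test_filter_log_counts_planted_violations_exactly(tmp_path):
    rows = [
        clean_site("100", 7),
        ("101", 5, "AT", "A", cells(["0/0"] * N)),            # indel
        ("102", 9, "A", "C,G", cells(["0/0"] * N)),           # tri-allelic
        # minor allele count 3 of 104 -> MAF 0.0288 < 0.03
        ("103", 11, "A", "C", cells(["0/1"] * 3 + ["0/0"] * (N - 3))),
        # 6 of 52 missing -> 11.5% > 10%
        ("104", 2, "A", "C", cells(["./."] * 6 + ["0/1"] * 20
                                   + ["0/0"] * (N - 26))),
        clean_site("105", 3),
    ]
    dm, log = filter_sites(read_vcf(make_vcf(tmp_path, rows)))
    assert log.n_input == 6 and log.n_output == 2
    assert log.removed == {"indel_or_multiallelic": 2, "missingness": 1,
                           "maf": 1}
    assert set(dm.locus_ids) == {"100:7", "105:3"}


def test_maf_boundary_arithmetic(tmp_path):
    # minor count 4 of 104 = 0.0385 kept; 3 of 104 = 0.0288 removed
    rows = [("1", 1, "A", "C", cells(["0/1"] * 4 + ["0/0"] * (N - 4))),
            ("2", 1, "A", "C", cells(["0/1"] * 3 + ["0/0"] * (N - 3)))]
    dm, log = filter_sites(read_vcf(make_vcf(tmp_path, rows)))
    assert list(dm.locus_ids) == ["1:1"] and log.removed["maf"] == 1


def test_missingness_boundary(tmp_path):
    # 5/52 = 9.6% retained; 6/52 = 11.5% removed
    keep = ("1", 1, "A", "C", cells(["./."] * 5 + ["0/1"] * 20
                                    + ["0/0"] * (N - 25)))
    drop = ("2", 1, "A", "C", cells(["./."] * 6 + ["0/1"] * 20
                                    + ["0/0"] * (N - 26)))
    dm, log = filter_sites(read_vcf(make_vcf(tmp_path, [keep, drop])))
    assert list(dm.locus_ids) == ["1:1"] and log.removed["missingness"] == 1


def test_depth_mask_uses_two_times_mean(tmp_path):
    # mean DP 27.5 -> genotypes with DP > 55 (and < 5) masked
    gts = ["0/1"] * 20 + ["0/0"] * (N - 20)
    c = [(g, 27) for g in gts]
    c[0] = ("0/1", 60)   # above 2x mean -> masked
    c[1] = ("0/1", 3)    # below 5x -> masked
    rows = [("1", 1, "A", "C", c), clean_site("2", 1)]
    dm, log = filter_sites(read_vcf(make_vcf(tmp_path, rows)))
    assert log.genotypes_depth_masked == 2
    expected_mean = np.mean([27] * (N - 2) + [60, 3] + [25] * N)
    assert log.mean_depth == pytest.approx(expected_mean)
    col = dm.values[:, list(dm.locus_ids).index("1:1")]
    assert np.isnan(col[0]) and np.isnan(col[1])


def test_minor_allele_orientation_and_tie(tmp_path):
    rows = [
        # ALT freq 0.4 -> ALT minor: dosage counts ALT
        ("1", 1, "A", "C", cells(["1/1"] * 16 + ["0/1"] * 10
                                 + ["0/0"] * (N - 26))),
        # ALT freq 0.6 -> REF minor: dosage counts REF
        ("2", 1, "A", "C", cells(["1/1"] * 26 + ["0/1"] * 10
                                 + ["0/0"] * (N - 36))),
        # exact tie 0.5 -> ALT chosen by convention
        ("3", 1, "A", "C", cells(["0/1"] * N)),
    ]
    dm, _ = filter_sites(read_vcf(make_vcf(tmp_path, rows)))
    idx = {l: i for i, l in enumerate(dm.locus_ids)}
    assert dm.values[:, idx["1:1"]].mean() == pytest.approx(42 / 104)
    assert dm.values[:, idx["2:1"]].mean() == pytest.approx(42 / 104)
    assert dm.minor_is_alt[idx["1:1"]] and not dm.minor_is_alt[idx["2:1"]]
    assert dm.minor_is_alt[idx["3:1"]]


def test_cascade_idempotent(small_cohort):
    geno, _, _ = small_cohort
    dm1, log1 = filter_sites(records_from_dosage(geno))
    assert sum(log1.removed.values()) == 0
    dm2, log2 = filter_sites(records_from_dosage(dm1))
    assert np.array_equal(dm1.values, dm2.values, equal_nan=True)
    assert sum(log2.removed.values()) == 0


def test_dosage_complement_sums_to_one(small_cohort):
    geno, _, _ = small_cohort
    obs = ~np.isnan(geno.values)
    assert np.allclose(geno.values[obs] + (1 - geno.values[obs]), 1.0)


def test_zero_surviving_loci_raises(tmp_path):
    rows = [("1", 1, "AT", "A", cells(["0/0"] * N))]
    with pytest.raises(ValueError, match="no loci survived"):
        filter_sites(read_vcf(make_vcf(tmp_path, rows)))


def test_replicate_error_rate():
    vals = np.zeros((3, 300))
    vals[1, :3] = 0.5                      # replicate differs at 3 loci
    dm = DosageMatrix(vals, [f"t{i}:1" for i in range(300)],
                      ["a", "b", "c"])
    rates = replicate_error_rate(dm, [("a", "b"), ("a", "c")])
    assert rates[("a", "b")] == pytest.approx(0.01)
    assert rates[("a", "c")] == 0.0
    with pytest.raises(KeyError):
        replicate_error_rate(dm, [("a", "zz")])


def test_replicate_error_rate_disjoint_missingness_errors():
    vals = np.array([[0.0, np.nan], [np.nan, 0.5]])  # rows = individuals
    dm = DosageMatrix(vals, ["t1:1", "t2:1"], ["a", "b"])
    with pytest.raises(ValueError, match="no comparable loci"):
        replicate_error_rate(dm, [("a", "b")])


def test_impute_mean_properties(rng):
    vals = rng.choice([0.0, 0.5, 1.0], size=(30, 40))
    dm = DosageMatrix(vals.copy(), [f"t{i}:1" for i in range(40)],
                      [f"i{i}" for i in range(30)])
    assert np.array_equal(impute_mean(dm), vals)  # no missing -> identity
    vals2 = vals.copy()
    vals2[0, 0] = np.nan
    dm2 = DosageMatrix(vals2, dm.locus_ids, dm.individual_ids)
    out = impute_mean(dm2)
    assert np.allclose(np.nanmean(vals2, axis=0), out.mean(axis=0),
                       atol=1e-12)
    obs = ~np.isnan(vals2)
    assert np.array_equal(out[obs], vals2[obs])


def test_impute_mean_half_split():
    vals = np.array([[0.0], [1.0], [np.nan], [0.0], [1.0]])
    dm = DosageMatrix(vals, ["t:1"], list("abcde"))
    assert impute_mean(dm)[2, 0] == pytest.approx(0.5)
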