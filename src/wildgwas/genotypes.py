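"""VCF input, the SNP filter cascade and the minor-allele dosage matrix.

The central genotype object is :class:`DosageMatrix`: individuals x loci with
entries 0 (homozygous for the major allele), 0.5 (heterozygote), 1 (homozygous
for the minor allele) and NaN for missing calls.  Loci are ddRAD SNPs named
``tag:pos`` where ``tag`` is the assembled ddRADtag (short contig) and ``pos``
the position of the SNP within it.

The filter cascade mirrors a conservative reduced-representation workflow:

1. drop indels and sites with more than two alleles;
2. mask individual genotypes whose read depth is below ``min_depth`` or above
   ``max_depth_factor`` times the mean depth (mean taken over all unmasked
   genotype depths before masking);
3. drop sites with more than ``max_missing`` missing calls;
4. drop sites with minor allele frequency below ``min_maf``.

Genotype-level (rather than site-level) depth masking is the conservative
reading of per-genotype min/max depth filters and matches VCFtools semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "DosageMatrix",
    "FilterConfig",
    "FilterLog",
    "VcfRecords",
    "read_vcf",
    "filter_sites",
    "records_from_dosage",
    "replicate_error_rate",
    "impute_mean",
]


@dataclass
class DosageMatrix:
    """Individuals x loci minor-allele dosage matrix.

    Attributes
    ----------
    values : ndarray of shape (n_individuals, n_loci)
        Entries in {0, 0.5, 1} or NaN for missing.
    locus_ids : ndarray of str
        ``tag:pos`` identifiers.
    individual_ids : ndarray of str
    minor_is_alt : ndarray of bool or None
        Per-locus record of which VCF allele was counted as minor.
    """

    values: np.ndarray
    locus_ids: np.ndarray
    individual_ids: np.ndarray
    minor_is_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, L = self.values.shape
        if len(self.individual_ids) != n or len(self.locus_ids) != L:
            raise ValueError("id lengths do not match matrix shape")
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 0.5, 1.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 0.5, 1} or NaN")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-locus minor allele frequency over non-missing calls."""
        f = np.nanmean(self.values, axis=0)
        return np.minimum(f, 1.0 - f)

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=0)

    @property
    def tags(self) -> np.ndarray:
        """ddRADtag identifier (``tag`` part of ``tag:pos``) per locus."""
        return np.array([str(l).split(":")[0] for l in self.locus_ids], dtype=object)

    def imputed(self) -> np.ndarray:
        """Return a complete copy with missing entries set to the locus mean."""
        return impute_mean(self)

    def subset_loci(self, locus_ids) -> "DosageMatrix":
        idx = {l: i for i, l in enumerate(self.locus_ids)}
        missing = [l for l in locus_ids if l not in idx]
        if missing:
            raise KeyError(f"unknown loci: {missing[:5]}")
        cols = [idx[l] for l in locus_ids]
        mia = None if self.minor_is_alt is None else self.minor_is_alt[cols]
        return DosageMatrix(self.values[:, cols], self.locus_ids[cols],
                            self.individual_ids, mia)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.individual_ids,
                     columns=self.locus_ids).to_csv(path, sep="\t",
                                                    index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "DosageMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), np.array(df.columns, dtype=object),
                   np.array(df.index.astype(str), dtype=object))


@dataclass
class FilterConfig:
    """Thresholds for the four-rule SNP filter cascade."""

    min_depth: int = 5
    max_depth_factor: float = 2.0
    max_missing: float = 0.10
    min_maf: float = 0.03

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.max_depth_factor <= 0 or self.min_maf <= 0:
            raise ValueError("filter thresholds must be positive")
        if not 0 < self.max_missing < 1:
            raise ValueError("max_missing must be in (0, 1)")


@dataclass
class FilterLog:
    """Loci removed per rule, in application order."""

    n_input: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=dict)
    genotypes_depth_masked: int = 0
    mean_depth: float = float("nan")

    def check(self) -> None:
        if self.n_input - sum(self.removed.values()) != self.n_output:
            raise AssertionError("FilterLog counts are inconsistent")

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"n_input": self.n_input, "n_output": self.n_output,
                       "removed": self.removed,
                       "genotypes_depth_masked": self.genotypes_depth_masked,
                       "mean_depth": self.mean_depth}, fh, indent=2)


@dataclass
class VcfRecords:
    """Raw genotype records: one row per VCF site, prior to filtering."""

    chrom: np.ndarray          # tag identifier per site
    pos: np.ndarray            # within-tag position
    ref: np.ndarray
    alt: np.ndarray            # object array of tuples of ALT alleles
    gt: np.ndarray             # sites x individuals ALT-allele count, -1 missing
    dp: np.ndarray | None      # sites x individuals depth, -1 missing; None if absent
    sample_ids: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def locus_ids(self) -> np.ndarray:
        return np.array([f"{c}:{p}" for c, p in zip(self.chrom, self.pos)],
                        dtype=object)


def read_vcf(path) -> VcfRecords:
    """Read a VCF 4.x file into :class:`VcfRecords`.

    GT is required; DP is optional.  Half-calls and missing genotypes map to
    missing.  Raises ``ValueError`` with the record number on malformed input.
    """
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    chrom, pos, ref, alt, gt_rows, dp_rows = [], [], [], [], [], []
    any_dp = False
    for i, var in enumerate(vcf):
        try:
            g = np.array([a[:2] for a in var.genotypes], dtype=int)
        except Exception as exc:  # pragma: no cover - cyvcf2 already validates
            raise ValueError(f"malformed genotype at record {i + 1}") from exc
        missing = (g < 0).any(axis=1)
        counts = np.where(missing, -1, (g > 0).sum(axis=1))
        dp = var.format("DP")
        if dp is not None:
            any_dp = True
            d = dp[:, 0].astype(np.int64)
            d[d < 0] = -1
        else:
            d = np.full(len(samples), -1, dtype=np.int64)
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(tuple(var.ALT))
        gt_rows.append(counts)
        dp_rows.append(d)
    if not gt_rows:
        raise ValueError(f"no records in VCF {path}")
    return VcfRecords(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        gt=np.vstack(gt_rows),
        dp=np.vstack(dp_rows) if any_dp else None,
        sample_ids=samples,
    )


def _is_snp(ref: str, alts: tuple) -> bool:
    return len(ref) == 1 and all(len(a) == 1 and a in "ACGT" for a in alts)


def filter_sites(records: VcfRecords, cfg: FilterConfig | None = None):
    """Apply the filter cascade; return ``(DosageMatrix, FilterLog)``.

    Dosages in the output count the empirically minor allele (the less
    frequent allele among non-missing calls; exact ties break toward ALT).
    """
    cfg = cfg or FilterConfig()
    if records.n_sites == 0:
        raise ValueError("no records to filter")
    log = FilterLog(n_input=records.n_sites)

    # rule 1: biallelic SNPs only
    keep = np.array([len(a) == 1 and _is_snp(r, a)
                     for r, a in zip(records.ref, records.alt)])
    log.removed["indel_or_multiallelic"] = int((~keep).sum())
    gt = records.gt[keep].astype(float)
    gt[gt < 0] = np.nan
    dp = records.dp[keep].astype(float) if records.dp is not None else None
    ids = records.locus_ids[keep]

    # rule 2: per-genotype depth mask
    if dp is not None:
        observed = ~np.isnan(gt) & (dp >= 0)
        mean_dp = float(dp[observed].mean()) if observed.any() else float("nan")
        log.mean_depth = mean_dp
        bad = observed & ((dp < cfg.min_depth)
                          | (dp > cfg.max_depth_factor * mean_dp))
        log.genotypes_depth_masked = int(bad.sum())
        gt[bad] = np.nan

    # rule 3: site missingness
    miss = np.isnan(gt).mean(axis=1)
    keep3 = miss <= cfg.max_missing
    log.removed["missingness"] = int((~keep3).sum())
    gt, ids = gt[keep3], ids[keep3]

    # rule 4: minor allele frequency
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(gt, axis=1) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep4 = maf >= cfg.min_maf
    log.removed["maf"] = int((~keep4).sum())
    gt, ids, alt_freq = gt[keep4], ids[keep4], alt_freq[keep4]

    if gt.shape[0] == 0:
        log.n_output = 0
        log.check()
        raise ValueError(f"no loci survived filtering: {log}")

    # orient to minor allele; tie at 0.5 breaks toward ALT
    minor_is_alt = alt_freq <= 0.5
    dosage = np.where(minor_is_alt[:, None], gt / 2.0, 1.0 - gt / 2.0)
    log.n_output = gt.shape[0]
    log.check()
    dm = DosageMatrix(dosage.T, ids, records.sample_ids, minor_is_alt)
    return dm, log


def records_from_dosage(dm: DosageMatrix) -> VcfRecords:
    """Re-express a dosage matrix as records (minor allele written as ALT).

    Depth information is not reconstructed, so the depth rule is a no-op on
    the result; used to check that the cascade is idempotent.
    """
    tags, positions = [], []
    for lid in dm.locus_ids:
        tag, _, p = str(lid).rpartition(":")
        tags.append(tag)
        positions.append(int(p))
    gt = dm.values.T * 2.0
    gt = np.where(np.isnan(gt), -1, gt).astype(np.int64)
    L = dm.n_loci
    return VcfRecords(
        chrom=np.array(tags, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * L, dtype=object),
        alt=np.array([("C",)] * L, dtype=object),
        gt=gt,
        dp=None,
        sample_ids=dm.individual_ids,
    )


def replicate_error_rate(dm: DosageMatrix, replicate_pairs) -> dict:
    """Fraction of discordant dosages between technical replicate columns.

    For each ``(id_a, id_b)`` pair, the rate is computed over loci called in
    both replicates.  Error rates under 1% are typical of a clean ddRAD run.
    """
    index = {str(i): k for k, i in enumerate(dm.individual_ids)}
    out = {}
    for a, b in replicate_pairs:
        if a not in index or b not in index:
            raise KeyError(f"unknown individual in pair ({a}, {b})")
        va, vb = dm.values[index[a]], dm.values[index[b]]
        both = ~np.isnan(va) & ~np.isnan(vb)
        if not both.any():
            raise ValueError(f"no comparable loci for pair ({a}, {b})")
        out[(a, b)] = float((va[both] != vb[both]).mean())
    return out


def impute_mean(dm: DosageMatrix) -> np.ndarray:
    """Locus-mean imputation of missing dosages; observed entries untouched."""
    vals = dm.values.copy()
    miss = np.isnan(vals)
    if not miss.any():
        return vals
    if miss.all(axis=0).any():
        raise ValueError("cannot impute a locus with no observed calls")
    means = np.nanmean(vals, axis=0)
    idx = np.where(miss)
    vals[idx] = means[idx[1]]
    return vals
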