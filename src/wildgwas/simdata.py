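"""Synthetic ddRAD cohorts with a planted genetic architecture for growth.

The generator emulates a small wild-population design: ~52 diploid
individuals from 3 sites x 3 plots, ~5,000 biallelic ddRAD SNPs (MAF >= 0.03,
<= 10% missingness), weak latent population structure, and a handful of
mutually correlated causal loci that individually explain ~15-30% of
log-growth variation and jointly ~50%.  Growth rates span roughly 0.12-0.46
cm/day over a 79-day monitoring window and are emitted as hole-punch
distances so the phenotype module's elongation-rate arithmetic is exercised
end to end.

Model
-----
Neutral locus ``l`` has ancestral minor-allele frequency ``p_l`` drawn from
``maf_range``; individual ``i`` carries dosage ``Bin(2, p_il)/2`` with
``logit(p_il) = logit(p_l) + w * u_i . f_l`` where ``u`` (individuals x K)
and ``f`` (K x loci) are standard normal and ``w`` = ``latent_geno_weight``.
The logistic-scale perturbation guarantees valid frequencies at any ``w``.

Causal loci are drawn conditional on a shared standard-normal liability
``h``: dosage ``Bin(2, sigmoid(logit(p_l) + a_l h))/2`` with ``a_l``
calibrated by quadrature so that ``cor(g_l, h) = rho`` with

    rho^2 = (per_locus_r2 / joint_r2 - 1/m) / (1 - 1/m),   m = n_causal.

The phenotype's genetic score ``S`` is the standardized sum of standardized
causal dosages; then ``cor(g_l, S)^2 ~ rho^2 + (1 - rho^2)/m`` and
log-growth ``y = sqrt(joint_r2) * S + noise`` realizes both the per-locus
and the joint coefficient of determination.  The noise is orthogonalized
against the causal dosages (and the leading latent factor) so the joint R^2
is exact up to range clipping.  Mutual correlation of the causal loci is the
point: it lets five loci each explain ~25% of variation while jointly
explaining ~50%.

Missingness is missing-completely-at-random, truncated so no locus exceeds
the 10% filter ceiling.  Read depths are negative-binomial around
``mean_depth``; depths for missing calls fall below the 5x floor, so the
emitted cohort passes the default filter cascade unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .genotypes import DosageMatrix

__all__ = ["SimConfig", "SimTruth", "generate_genotypes",
           "generate_phenotype", "write_cohort", "simulate_cohort"]

_MAX_MISSING = 0.10  # filter ceiling the generator guarantees


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic cohort."""

    n_individuals: int = 52
    n_loci: int = 5000
    n_sites: int = 3
    n_plots_per_site: int = 3
    maf_range: tuple = (0.05, 0.5)
    k_latent: int = 1
    latent_geno_weight: float = 0.25
    latent_pheno_r2: float = 0.0
    n_causal: int = 5
    per_locus_r2: float = 0.25
    joint_r2: float = 0.5
    missing_rate: float = 0.05
    mean_depth: float = 27.5
    growth_range: tuple = (0.12, 0.46)
    days: float = 79.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_loci", "n_sites", "n_plots_per_site"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if hi < 0.03:
            raise ValueError(
                "infeasible maf_range: upper bound below the 0.03 MAF filter")
        if not 0 <= self.missing_rate < _MAX_MISSING:
            raise ValueError("missing_rate must be in [0, 0.10)")
        if self.k_latent < 0 or self.latent_geno_weight < 0:
            raise ValueError("latent structure parameters must be >= 0")
        g_lo, g_hi = self.growth_range
        if not 0 < g_lo < g_hi:
            raise ValueError("growth_range must be increasing and positive")
        if self.days <= 0:
            raise ValueError("days must be positive")
        if not 0 <= self.per_locus_r2 < 1 or not 0 <= self.joint_r2 < 1:
            raise ValueError("R2 targets must be in [0, 1)")
        joint = (self.joint_r2 if (self.n_causal and self.per_locus_r2 > 0)
                 else 0.0)
        if joint + self.latent_pheno_r2 >= 1:
            raise ValueError("joint_r2 + latent_pheno_r2 must be < 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, recomputable from emitted data."""

    causal_locus_ids: list = field(default_factory=list)
    causal_effects: list = field(default_factory=list)
    latent_scores: np.ndarray | None = None
    realized_per_locus_r2: list = field(default_factory=list)
    realized_joint_r2: float = float("nan")
    causal_rho: float = float("nan")
    liability: np.ndarray | None = None

    def to_json(self, path) -> None:
        obj = {
            "causal_locus_ids": [str(x) for x in self.causal_locus_ids],
            "causal_effects": [float(x) for x in self.causal_effects],
            "latent_scores": None if self.latent_scores is None
            else np.asarray(self.latent_scores).tolist(),
            "realized_per_locus_r2": [float(x) for x in self.realized_per_locus_r2],
            "realized_joint_r2": float(self.realized_joint_r2),
            "causal_rho": float(self.causal_rho),
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        obj = json.loads(Path(path).read_text())
        ls = obj.get("latent_scores")
        return cls(causal_locus_ids=obj["causal_locus_ids"],
                   causal_effects=obj["causal_effects"],
                   latent_scores=None if ls is None else np.asarray(ls),
                   realized_per_locus_r2=obj["realized_per_locus_r2"],
                   realized_joint_r2=obj["realized_joint_r2"],
                   causal_rho=obj.get("causal_rho", float("nan")))


def _causal_rho(cfg: SimConfig) -> float:
    """Target correlation between each causal dosage and the shared liability."""
    m = cfg.n_causal
    if m <= 1:
        return 0.0
    lo = cfg.joint_r2 / m
    if not lo <= cfg.per_locus_r2 <= cfg.joint_r2:
        raise ValueError(
            f"per_locus_r2={cfg.per_locus_r2} incompatible with "
            f"joint_r2={cfg.joint_r2} at n_causal={m}; feasible range is "
            f"[{lo:.4f}, {cfg.joint_r2:.4f}]")
    rho2 = (cfg.per_locus_r2 / cfg.joint_r2 - 1.0 / m) / (1.0 - 1.0 / m)
    return float(np.sqrt(rho2))


# 40-node Gauss-Hermite rule for expectations over N(0, 1)
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(40)
_GH_X = _GH_X * np.sqrt(2.0)
_GH_W = _GH_W / np.sqrt(np.pi)


def _cor_dosage_liability(a: float, p: float) -> float:
    """cor(g, h) for g ~ Bin(2, sigmoid(logit(p) + a h))/2, h ~ N(0, 1)."""
    pi = expit(logit(p) + a * _GH_X)
    mean = float(_GH_W @ pi)
    cov = float(_GH_W @ (pi * _GH_X))
    # var(g) = E[pi (1-pi)]/2 (binomial part) + var(pi) (liability part)
    var = float(_GH_W @ (pi * (1 - pi))) / 2.0 + float(_GH_W @ (pi - mean) ** 2)
    return cov / np.sqrt(var) if var > 0 else 0.0


def _calibrate_slope(p: float, rho: float) -> float:
    if rho <= 0:
        return 0.0
    hi = 25.0
    if _cor_dosage_liability(hi, p) < rho:
        raise ValueError(
            f"target causal correlation rho={rho:.3f} unreachable at "
            f"allele frequency {p:.3f}")
    return brentq(lambda a: _cor_dosage_liability(a, p) - rho, 0.0, hi)


def _mask_missing(rng, n: int, rate: float):
    """MCAR missing index set, truncated at the 10% filter ceiling."""
    cap = int(np.floor(_MAX_MISSING * n))
    k = min(rng.binomial(n, rate), cap) if rate > 0 else 0
    return rng.choice(n, size=k, replace=False) if k else np.empty(0, int)


def _passes(dosage: np.ndarray) -> bool:
    obs = dosage[~np.isnan(dosage)]
    if obs.size == 0:
        return False
    f = obs.mean()
    return 0.03 <= min(f, 1 - f)


def generate_genotypes(cfg: SimConfig):
    """Draw a dosage matrix with latent structure and planted causal loci.

    Returns ``(DosageMatrix, SimTruth)``.  Every emitted locus passes the
    default MAF/missingness filters; locus IDs follow the ``tag:pos``
    convention with at least one pair of SNPs sharing a ddRADtag.
    """
    rng = np.random.default_rng(cfg.seed)
    n, L, k = cfg.n_individuals, cfg.n_loci, cfg.k_latent
    u = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    rho = _causal_rho(cfg) if (cfg.n_causal and cfg.per_locus_r2 > 0) else 0.0

    cols, base_freqs = [], []
    for _ in range(500):
        if len(cols) >= L:
            break
        b = max(L - len(cols), 256)
        p = rng.uniform(*cfg.maf_range, size=b)
        eta = logit(p)[None, :]
        if k:
            f = rng.standard_normal((k, b))
            eta = eta + cfg.latent_geno_weight * (u @ f)
        counts = rng.binomial(2, expit(np.broadcast_to(eta, (n, b))))
        dosage = counts / 2.0
        for j in range(b):
            col = dosage[:, j].copy()
            col[_mask_missing(rng, n, cfg.missing_rate)] = np.nan
            if _passes(col):
                cols.append(col)
                base_freqs.append(p[j])
                if len(cols) == L:
                    break
    else:
        raise ValueError("could not generate enough loci passing the MAF "
                         "filter; widen maf_range")

    values = np.column_stack(cols)
    base_freqs = np.asarray(base_freqs)

    # ddRADtag IDs: ~2% of SNPs share a tag with the previous one
    tags = np.empty(L, dtype=object)
    tag_pool = rng.choice(np.arange(10_000, 400_000), size=L, replace=False)
    positions = np.empty(L, dtype=int)
    t = 0
    for j in range(L):
        share = j > 0 and rng.random() < 0.02
        if not share:
            t += 1
        tags[j] = str(tag_pool[t])
        positions[j] = rng.integers(1, 141)
    if len(set(tags)) == L and L > 1:   # guarantee at least one shared pair
        tags[1] = tags[0]
    # make tag:pos unique
    seen: dict = {}
    locus_ids = []
    for tag, pos in zip(tags, positions):
        while (tag, pos) in seen:
            pos = pos % 140 + 1
        seen[(tag, pos)] = True
        locus_ids.append(f"{tag}:{pos}")
    locus_ids = np.array(locus_ids, dtype=object)

    truth = SimTruth(latent_scores=u, causal_rho=rho)
    if cfg.n_causal and cfg.per_locus_r2 > 0:
        if cfg.n_causal > L:
            raise ValueError("n_causal exceeds n_loci")
        h = rng.standard_normal(n)
        causal_idx = rng.choice(L, size=cfg.n_causal, replace=False)
        for j in causal_idx:
            p_j = base_freqs[j]
            a = _calibrate_slope(p_j, rho)
            for attempt in range(60):
                counts = rng.binomial(2, expit(logit(p_j) + a * h))
                col = counts / 2.0
                col[_mask_missing(rng, n, cfg.missing_rate)] = np.nan
                if _passes(col):
                    break
                if attempt == 40:   # stubborn low-frequency locus: re-draw p
                    p_j = rng.uniform(max(cfg.maf_range[0], 0.15), 0.5)
                    a = _calibrate_slope(p_j, rho)
            else:
                raise RuntimeError("failed to plant a causal locus")
            values[:, j] = col
        truth.liability = h
        truth.causal_locus_ids = [str(locus_ids[j]) for j in
                                  sorted(causal_idx)]

    # orient every column to the empirically minor allele (ties keep ALT)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(values, axis=0)
    minor_is_alt = freq <= 0.5
    values = np.where(minor_is_alt[None, :], values, 1.0 - values)

    ind_ids = np.array([f"kelp_{i + 1:03d}" for i in range(n)], dtype=object)
    dm = DosageMatrix(values, locus_ids, ind_ids, minor_is_alt)
    return dm, truth


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate (constant) vector in phenotype build")
    return (v - v.mean()) / sd


def generate_phenotype(geno: DosageMatrix, truth: SimTruth,
                       cfg: SimConfig) -> pd.DataFrame:
    """Build the growth phenotype from the planted causal loci.

    Returns a phenotype table with columns ``id, site, plot, distance_cm,
    days, growth_rate, log_growth, scaled_growth``.  Site and plot labels are
    assigned round-robin with zero site effect.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    n = geno.n_individuals
    imputed = geno.imputed()
    q = cfg.joint_r2 if (truth.causal_locus_ids and cfg.per_locus_r2 > 0) else 0.0
    c = cfg.latent_pheno_r2

    basis = [np.ones(n)]
    y = np.zeros(n)
    if q > 0:
        idx = [list(geno.locus_ids).index(l) for l in truth.causal_locus_ids]
        G_sel = imputed[:, idx]
        Z = np.column_stack([_standardize(G_sel[:, j])
                             for j in range(G_sel.shape[1])])
        # minor-allele orientation may have flipped a column's sign relative
        # to the shared liability; re-align so the score adds coherently
        ref = truth.liability if truth.liability is not None else Z[:, 0]
        signs = np.array([1.0 if np.dot(Z[:, j], ref) >= 0 else -1.0
                          for j in range(Z.shape[1])])
        S = _standardize((Z * signs).sum(axis=1))
        basis.extend(G_sel.T)
        y = y + np.sqrt(q) * S
    if c > 0:
        if truth.latent_scores is None or truth.latent_scores.shape[1] == 0:
            raise ValueError("latent_pheno_r2 > 0 requires k_latent >= 1")
        u1 = truth.latent_scores[:, 0]
        Q, _ = np.linalg.qr(np.column_stack(basis))
        u1o = u1 - Q @ (Q.T @ u1)
        basis.append(u1)
        y = y + np.sqrt(c) * _standardize(u1o)
    e = rng.standard_normal(n)
    Q, _ = np.linalg.qr(np.column_stack(basis))
    e = e - Q @ (Q.T @ e)
    y = y + np.sqrt(max(1.0 - q - c, 0.0)) * _standardize(e)
    y = _standardize(y)

    g_lo, g_hi = cfg.growth_range
    mu = (np.log10(g_lo) + np.log10(g_hi)) / 2.0
    sigma = (np.log10(g_hi) - np.log10(g_lo)) / 6.0
    rate = np.clip(10 ** (mu + sigma * y), g_lo, g_hi)
    log_growth = np.log10(rate)

    site = np.array([f"S{i % cfg.n_sites + 1}" for i in range(n)])
    plot = np.array([f"S{i % cfg.n_sites + 1}-P"
                     f"{(i // cfg.n_sites) % cfg.n_plots_per_site + 1}"
                     for i in range(n)])
    pheno = pd.DataFrame({
        "id": geno.individual_ids,
        "site": site,
        "plot": plot,
        "distance_cm": 5.0 + rate * cfg.days,
        "days": cfg.days,
        "growth_rate": rate,
        "log_growth": log_growth,
        "scaled_growth": _standardize(log_growth),
    })

    if q > 0:
        r2s, betas = [], []
        for j in range(G_sel.shape[1]):
            g = G_sel[:, j]
            r = np.corrcoef(g, log_growth)[0, 1]
            r2s.append(float(r * r))
            betas.append(float(np.cov(g, log_growth)[0, 1] / np.var(g, ddof=1)))
        truth.realized_per_locus_r2 = r2s
        truth.causal_effects = betas
        X = np.column_stack([np.ones(n), G_sel])
        resid = log_growth - X @ np.linalg.lstsq(X, log_growth, rcond=None)[0]
        tss = ((log_growth - log_growth.mean()) ** 2).sum()
        truth.realized_joint_r2 = float(1.0 - (resid ** 2).sum() / tss)
    return pheno


def write_cohort(geno: DosageMatrix, pheno: pd.DataFrame, truth: SimTruth,
                 outdir, cfg: SimConfig | None = None) -> dict:
    """Write VCF + phenotype CSV + truth JSON; returns the paths.

    Depths (FORMAT/DP) are negative-binomial around ``cfg.mean_depth``,
    clipped into the default depth-filter window for observed calls and
    below the 5x floor for missing calls, so re-reading the VCF through the
    filter cascade reproduces the dosage matrix exactly.
    """
    cfg = cfg or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    n, L = geno.values.shape
    minor_is_alt = (geno.minor_is_alt if geno.minor_is_alt is not None
                    else np.ones(L, dtype=bool))

    # negative binomial via gamma-poisson, dispersion 10
    lam = rng.gamma(10.0, cfg.mean_depth / 10.0, size=(n, L))
    dp = rng.poisson(lam)
    dp = np.clip(dp, 5, int(np.floor(1.8 * cfg.mean_depth)))
    dp[np.isnan(geno.values)] = rng.integers(0, 5, size=int(np.isnan(geno.values).sum()))

    vcf_path = outdir / "cohort.vcf"
    tags = [str(l).rpartition(":")[0] for l in geno.locus_ids]
    pos = [str(l).rpartition(":")[2] for l in geno.locus_ids]
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=wildgwas.simdata\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for tag in dict.fromkeys(tags):
            fh.write(f"##contig=<ID={tag},length=140>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in geno.individual_ids) + "\n")
        for j in range(L):
            alt_dosage = (geno.values[:, j] if minor_is_alt[j]
                          else 1.0 - geno.values[:, j])
            cells = []
            for i in range(n):
                d = alt_dosage[i]
                gt = "./." if np.isnan(d) else gt_map[round(float(d), 1)]
                cells.append(f"{gt}:{dp[i, j]}")
            fh.write(f"{tags[j]}\t{pos[j]}\t{geno.locus_ids[j]}\tA\tC\t.\t.\t"
                     f".\tGT:DP\t" + "\t".join(cells) + "\n")

    pheno_path = outdir / "phenotype.csv"
    pheno[["id", "site", "plot", "distance_cm", "days"]].to_csv(
        pheno_path, index=False)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    return {"vcf": vcf_path, "phenotype": pheno_path, "truth": truth_path}


def simulate_cohort(cfg: SimConfig | None = None):
    """Convenience wrapper: genotypes + phenotype in one call."""
    cfg = cfg or SimConfig()
    geno, truth = generate_genotypes(cfg)
    pheno = generate_phenotype(geno, truth, cfg)
    return geno, pheno, truth
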