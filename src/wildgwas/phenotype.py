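"""Field growth phenotype: elongation rate, transforms and cohort checks.

The phenotype is the lamina elongation rate of tagged kelp measured with the
hole-punch method: a hole punched 5 cm above the meristem moves distally as
new tissue is produced, so the rate is (measured distance - 5 cm) / days in
cm/day.  The analysis phenotype is its log10 transform (growth rates are
right-skewed), z-scored over the cohort.

Cohort-level checks mirror a standard wild-GWAS sanity battery: Shapiro-Wilk
normality before/after transform, one-way ANOVA across sites and across
plots nested in sites, a VanRaden genomic relationship matrix, and a Mantel
test of growth differences against genomic relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import DosageMatrix

__all__ = [
    "elongation_rate",
    "transform_growth",
    "load_phenotype",
    "phenotype_table",
    "site_anova",
    "relatedness_matrix",
    "mantel_growth_vs_relatedness",
]

HOLE_OFFSET_CM = 5.0


def elongation_rate(distance_cm, days, offset_cm: float = HOLE_OFFSET_CM):
    """Lamina elongation rate in cm/day: (distance - offset) / days.

    ``distance_cm`` is the measured hole-to-meristem distance; the hole was
    punched ``offset_cm`` above the meristem, so it cannot sit below that
    mark.  Vectorized over arrays.
    """
    distance_cm = np.asarray(distance_cm, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("days must be positive")
    if np.any(distance_cm < offset_cm):
        raise ValueError(
            f"distance below the {offset_cm} cm punch offset: the hole "
            "cannot regress toward the meristem")
    out = (distance_cm - offset_cm) / days
    return float(out) if out.ndim == 0 else out


@dataclass
class NormalityReport:
    """Shapiro-Wilk W and p for raw and log10-transformed rates."""

    w_raw: float
    p_raw: float
    w_log: float
    p_log: float


def transform_growth(rates, ids=None):
    """log10-transform and z-score growth rates; report normality.

    Returns ``(log_growth, scaled_growth, NormalityReport)``.  Raises on
    non-positive rates (naming the individual) and on a constant vector,
    where the z-score is undefined.
    """
    rates = np.asarray(rates, dtype=float)
    if ids is None:
        ids = np.arange(len(rates))
    bad = np.where(~(rates > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive growth rate for individual "
                         f"{ids[bad[0]]!r}")
    if np.ptp(rates) == 0:
        raise ValueError("all growth rates identical: z-scoring undefined")
    log_growth = np.log10(rates)
    scaled = (log_growth - log_growth.mean()) / log_growth.std()
    w_raw, p_raw = stats.shapiro(rates)
    w_log, p_log = stats.shapiro(log_growth)
    report = NormalityReport(float(w_raw), float(p_raw),
                             float(w_log), float(p_log))
    return log_growth, scaled, report


def phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Complete a raw field table (id, site, plot, distance_cm, days).

    Adds ``growth_rate``, ``log_growth`` and ``scaled_growth`` columns.
    """
    df = df.copy()
    df["growth_rate"] = elongation_rate(df["distance_cm"], df["days"])
    log_growth, scaled, _ = transform_growth(df["growth_rate"].to_numpy(),
                                             ids=df["id"].to_numpy())
    df["log_growth"] = log_growth
    df["scaled_growth"] = scaled
    return df


def load_phenotype(path) -> pd.DataFrame:
    """Read a phenotype CSV (``id,site,plot,distance_cm,days``) and derive
    the analysis columns."""
    df = pd.read_csv(path)
    required = {"id", "site", "plot", "distance_cm", "days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    return phenotype_table(df)


def _one_way(values: np.ndarray, labels: np.ndarray):
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two members")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def site_anova(pheno: pd.DataFrame) -> dict:
    """One-way ANOVA of log growth across sites and across plots in sites.

    Returns ``{"site": (F, p), "plot": (F, p)}``.  Plot labels are treated
    as nested (site-plot combinations form the groups).
    """
    y = pheno["log_growth"].to_numpy()
    site = pheno["site"].to_numpy()
    plot = (pheno["site"].astype(str) + "/" + pheno["plot"].astype(str)).to_numpy()
    return {"site": _one_way(y, site), "plot": _one_way(y, plot)}


def relatedness_matrix(geno: DosageMatrix) -> pd.DataFrame:
    """VanRaden method-1 genomic relationship matrix.

    With allele dosage d in [0, 2] (twice the stored minor-allele fraction)
    and per-locus frequency p_l: A = W W' / (2 sum_l p_l (1 - p_l)) with
    W_il = d_il - 2 p_l.  Monomorphic loci contribute nothing and are
    skipped.  Missing dosages are mean-imputed first.
    """
    d = 2.0 * geno.imputed()
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci monomorphic: relatedness undefined")
    W = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    A = (W @ W.T) / denom
    ids = [str(i) for i in geno.individual_ids]
    return pd.DataFrame(A, index=ids, columns=ids)


def mantel_growth_vs_relatedness(A: pd.DataFrame, pheno: pd.DataFrame,
                                 n_perm: int = 9999, seed: int = 0):
    """Mantel test of pairwise growth differences vs genomic distance.

    Genomic distance is ``max(A) - A`` (a monotone decreasing transform of
    relatedness, keeping the sign of r interpretable); growth distance is
    ``|log_growth_i - log_growth_j|``.  The statistic is the Pearson
    correlation over off-diagonal pairs; significance is two-sided from
    permutations of individual labels of the genetic matrix.
    Returns ``(r, p)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    ids = [str(i) for i in pheno["id"]]
    if list(A.index) != ids:
        raise ValueError("individual order of A and phenotype must match")
    Av = A.to_numpy()
    Dg = Av.max() - Av
    y = pheno["log_growth"].to_numpy()
    Dy = np.abs(y[:, None] - y[None, :])
    n = len(y)
    iu = np.triu_indices(n, k=1)

    def corr(perm):
        m = Dg[np.ix_(perm, perm)]
        return float(np.corrcoef(m[iu], Dy[iu])[0, 1])

    r_obs = corr(np.arange(n))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(corr(rng.permutation(n))) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)
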