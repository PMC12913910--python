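"""Cross-method integration: concordance, permutation null, polygenic score.

The multi-method battery deliberately trades single-method power for
robustness: a locus is trusted in proportion to how many independent
engines flag it.  Concordance classes are

* GWAS at the relaxed FDR < 0.10 threshold,
* ridge LFMM at FDR < 0.05,
* RDA loading outliers at |z| > 2.5 SD,

with loci classified none / single / double / triple and collapsed to
ddRADtag regions (SNPs sharing the ``tag`` part of ``tag:pos`` are linked
markers on one assembled contig, not independent signals).

The phenotype-randomization null reruns the GWAS + FDR scan on permuted
growth values to give an empirical distribution of discovery counts — the
small-sample guard against over-interpreting a handful of hits.

The polygenic model refits the ridge LFMM restricted to the selected loci,
builds a z-scaled per-individual score from the per-locus coefficients, and
reports the coefficient of determination of observed scaled growth on the
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .genotypes import DosageMatrix
from .gwas import gwas_scan, fdr_qvalues
from .lfmm import lfmm_ridge

__all__ = ["ConcordanceReport", "NullCountDistribution", "PolygenicScore",
           "concordance", "randomization_null", "per_locus_r2",
           "site_interaction_ancova", "polygenic_fit"]


@dataclass
class ConcordanceReport:
    """Per-locus method flags, concordance classes and tag regions."""

    table: pd.DataFrame                 # flags + class per locus
    regions: pd.DataFrame               # tag-collapsed flagged regions

    def loci_in_class(self, cls: str) -> list:
        return list(self.table.index[self.table["concordance"] == cls])

    @property
    def double_or_more(self) -> list:
        return list(self.table.index[
            self.table["concordance"].isin(["double", "triple"])])

    @property
    def triple(self) -> list:
        return self.loci_in_class("triple")


def concordance(gwas_res: pd.DataFrame, lfmm_res: pd.DataFrame,
                rda_res: pd.DataFrame) -> ConcordanceReport:
    """Classify every locus by which detection methods flag it.

    Inputs are the per-locus result frames of the three engines, indexed by
    locus; the locus universes must match.  GWAS contributes at the relaxed
    q < 0.10 threshold, LFMM at q < 0.05, RDA via its candidate flag.
    """
    idx = gwas_res.index
    if not (idx.equals(lfmm_res.index) and idx.equals(rda_res.index)):
        raise ValueError("the three result tables cover different loci")
    flags = pd.DataFrame({
        "gwas_q10": gwas_res["sig_q10"].fillna(False).astype(bool),
        "lfmm_q05": lfmm_res["sig_q05"].astype(bool),
        "rda": rda_res["candidate"].astype(bool),
    }, index=idx)
    n_methods = flags.sum(axis=1)
    flags["n_methods"] = n_methods
    flags["concordance"] = pd.cut(
        n_methods, bins=[-1, 0, 1, 2, 3],
        labels=["none", "single", "double", "triple"]).astype(str)

    flagged = flags[n_methods > 0].copy()
    flagged["tag"] = [str(l).split(":")[0] for l in flagged.index]
    order = {"single": 1, "double": 2, "triple": 3}
    rows = []
    for tag, grp in flagged.groupby("tag"):
        best = max(grp["concordance"], key=lambda c: order[c])
        rows.append({"tag": tag, "n_loci": len(grp),
                     "members": ",".join(map(str, grp.index)),
                     "best_class": best})
    regions = (pd.DataFrame(rows).set_index("tag")
               if rows else pd.DataFrame(columns=["n_loci", "members",
                                                  "best_class"]))
    return ConcordanceReport(table=flags, regions=regions)


@dataclass
class NullCountDistribution:
    """Discovery counts across phenotype permutations."""

    counts: np.ndarray
    n_iter: int
    observed: int
    seed: int
    fdr_method: str
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        self.summary = {
            "frac_le_1": float((c <= 1).mean()),
            "frac_zero": float((c == 0).mean()),
            "frac_ge_observed": float((c >= self.observed).mean()),
        }


def randomization_null(geno, pheno, n_iter: int = 1000, seed: int = 0,
                       fdr_method: str = "storey",
                       q_threshold: float = 0.05) -> NullCountDistribution:
    """Permute growth across individuals and count GWAS discoveries.

    Genotypes stay fixed; each iteration permutes ``log_growth``, reruns the
    per-SNP scan with the same FDR method as the observed analysis (mixing
    methods between observed and null is refused by construction), and
    counts loci at q below ``q_threshold``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    G = geno.imputed() if isinstance(geno, DosageMatrix) else np.asarray(geno)
    y = (pheno["log_growth"].to_numpy() if isinstance(pheno, pd.DataFrame)
         else np.asarray(pheno, dtype=float))
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    obs = int((gwas_scan(G, y, fdr_method=fdr_method)["q"]
               < q_threshold).sum())
    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter, dtype=int)
    for b in range(n_iter):
        res = gwas_scan(G, rng.permutation(y), fdr_method=fdr_method)
        counts[b] = int((res["q"] < q_threshold).sum())
    return NullCountDistribution(counts=counts, n_iter=n_iter, observed=obs,
                                 seed=seed, fdr_method=fdr_method)


def per_locus_r2(geno, pheno, loci=None) -> pd.Series:
    """Squared Pearson correlation between dosage and log growth per locus.

    Equals the coefficient of determination of the simple linear model of
    growth on allele state.  Missing dosages are mean-imputed.
    """
    if isinstance(geno, DosageMatrix):
        dm = geno if loci is None else geno.subset_loci(loci)
        G = dm.imputed()
        ids = dm.locus_ids
    else:
        G = np.asarray(geno, dtype=float)
        ids = np.arange(G.shape[1]) if loci is None else loci
    y = (pheno["log_growth"].to_numpy() if isinstance(pheno, pd.DataFrame)
         else np.asarray(pheno, dtype=float))
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    num = (Gc.T @ yc) ** 2
    den = (Gc * Gc).sum(axis=0) * float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, num / den, np.nan)
    return pd.Series(r2, index=pd.Index(ids, name="locus_id"), name="r2")


def site_interaction_ancova(geno, pheno, loci) -> pd.DataFrame:
    """Per-locus ANCOVA of log growth on site, dosage and their interaction.

    Fits ``log_growth ~ C(site) + dosage + C(site):dosage`` per locus and
    reports the interaction F test alongside the main-effect terms.  A locus
    is flagged inestimable when some site carries a single genotype class.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if pheno["site"].nunique() < 2:
        raise ValueError("ANCOVA needs at least two sites")
    dm = geno.subset_loci(loci) if isinstance(geno, DosageMatrix) else None
    G = dm.imputed() if dm is not None else np.asarray(geno, dtype=float)
    ids = dm.locus_ids if dm is not None else list(loci)
    rows = []
    for j, lid in enumerate(ids):
        df = pd.DataFrame({"y": pheno["log_growth"].to_numpy(),
                           "site": pheno["site"].to_numpy(),
                           "dosage": G[:, j]})
        estimable = bool((df.groupby("site")["dosage"].nunique() >= 2).all())
        row = {"locus_id": lid, "estimable": estimable}
        if estimable:
            fit = smf.ols("y ~ C(site) + dosage + C(site):dosage", df).fit()
            an = sm.stats.anova_lm(fit, typ=2)
            row.update(
                interaction_F=float(an.loc["C(site):dosage", "F"]),
                interaction_p=float(an.loc["C(site):dosage", "PR(>F)"]),
                site_F=float(an.loc["C(site)", "F"]),
                site_p=float(an.loc["C(site)", "PR(>F)"]),
                dosage_F=float(an.loc["dosage", "F"]),
                dosage_p=float(an.loc["dosage", "PR(>F)"]),
            )
        else:
            row.update({k: np.nan for k in
                        ("interaction_F", "interaction_p", "site_F",
                         "site_p", "dosage_F", "dosage_p")})
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus_id")


class PolygenicScore(BaseEstimator):
    """Polygenic prediction from a selected locus set.

    Refits the ridge LFMM restricted to the selected loci, takes the
    per-locus coefficients as weights, and scores individuals by the
    z-scaled weighted dosage sum.  ``score`` returns the in-sample R^2 of
    observed scaled growth regressed on the predicted score.

    Parameters
    ----------
    K : int
        Latent factors retained in the restricted refit (default 0: with a
        small selected panel the factors would absorb the signal itself).
    lam : float
        Ridge penalty of the refit.
    method : {"lfmm", "ridge"}
        "lfmm" (default) takes the per-locus coefficients of the restricted
        ridge LFMM (genotypes regressed on the trait); "ridge" is the
        alternative orientation, a joint ridge regression of the trait on
        the selected dosages.
    """

    def __init__(self, K: int = 0, lam: float = 1e-5, method: str = "lfmm"):
        self.K = K
        self.lam = lam
        self.method = method

    def fit(self, X, y):
        if isinstance(X, DosageMatrix):
            X = X.imputed()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("selected locus set must be non-empty")
        y = np.asarray(y, dtype=float).ravel()
        self._mean_ = X.mean(axis=0)
        Xc = X - self._mean_
        yc = y - y.mean()
        if self.method == "lfmm":
            self.coef_ = lfmm_ridge(Xc, yc, K=self.K, lam=self.lam).B
        elif self.method == "ridge":
            m = X.shape[1]
            self.coef_ = np.linalg.solve(
                Xc.T @ Xc + self.lam * np.eye(m), Xc.T @ yc)
        else:
            raise ValueError(f"unknown polygenic method {self.method!r}")
        raw = (X - self._mean_) @ self.coef_
        self._score_mean_, self._score_sd_ = raw.mean(), raw.std()
        if self._score_sd_ == 0:
            raise ValueError("degenerate polygenic score (zero variance)")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if isinstance(X, DosageMatrix):
            X = X.imputed()
        raw = (np.asarray(X, dtype=float) - self._mean_) @ self.coef_
        return (raw - self._score_mean_) / self._score_sd_

    def score(self, X, y):
        """R^2 of observed scaled growth on the predicted score (with its
        OLS F-test p-value available via :meth:`score_with_p`)."""
        return self.score_with_p(X, y)[0]

    def score_with_p(self, X, y):
        pred = self.predict(X)
        y = np.asarray(y, dtype=float).ravel()
        obs = (y - y.mean()) / y.std()
        r = np.corrcoef(pred, obs)[0, 1]
        r2 = float(r * r)
        n = len(y)
        f = r2 / max(1.0 - r2, 1e-300) * (n - 2)
        p = float(stats.f.sf(f, 1, n - 2))
        return r2, p


def polygenic_fit(geno, pheno, selected_loci, K: int = 0,
                  lam: float = 1e-5, method: str = "lfmm") -> dict:
    """Fit and evaluate the polygenic model on the selected loci.

    Returns a dict with the per-locus coefficients, per-individual predicted
    scaled scores, the in-sample R^2 against observed scaled growth and the
    F-test p-value of that fit.
    """
    if len(selected_loci) < 1:
        raise ValueError("selected locus set is empty")
    dm = (geno.subset_loci(selected_loci) if isinstance(geno, DosageMatrix)
          else None)
    X = dm.imputed() if dm is not None else np.asarray(geno, dtype=float)
    y = (pheno["log_growth"].to_numpy() if isinstance(pheno, pd.DataFrame)
         else np.asarray(pheno, dtype=float))
    model = PolygenicScore(K=K, lam=lam, method=method).fit(X, y)
    pred = model.predict(X)
    r2, p = model.score_with_p(X, y)
    return {"loci": list(selected_loci), "coef": model.coef_,
            "predicted": pred, "r2": r2, "p": p, "model": model}
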