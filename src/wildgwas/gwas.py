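"""Per-SNP linear-model association (GWAS) with FDR control.

Each locus is tested independently with ordinary least squares of log growth
on minor-allele dosage, y = mu + beta * g, giving a t statistic on n - 2
degrees of freedom.  No kinship or structure adjustment is applied here:
this scan is deliberately the naive engine of the multi-method battery (the
ridge LFMM handles confounding).  Multiple testing is controlled with
q-values — Storey's procedure with a smoother-estimated pi0 by default,
falling back to Benjamini-Hochberg when pi0 estimation is unstable — and
loci are flagged at the two working thresholds FDR < 0.05 and FDR < 0.1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genotypes import DosageMatrix

__all__ = ["GwasScan", "gwas_scan", "fdr_qvalues"]

_P_FLOOR = 1e-300


def fdr_qvalues(p, method: str = "storey", return_info: bool = False):
    """q-values for a vector of p-values.

    ``method='storey'`` estimates the null proportion pi0 with the cubic
    smoother over the lambda grid 0.05..0.95 and multiplies BH-style
    step-up values by pi0; it falls back to Benjamini-Hochberg (pi0 = 1)
    when the input is small (m < 100) or the estimate is non-positive.
    ``method='bh'`` is plain Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown FDR method {method!r}")

    m = p.size
    pi0 = 1.0
    used = "bh"
    if method == "storey" and m >= 100:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0_hat = float(np.polyval(coef, lam[-1]))
        if pi0_hat > 0:
            pi0 = min(pi0_hat, 1.0)
            used = "storey"

    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)

    if used == "bh":  # identical to statsmodels' BH; keep the library route
        q = multipletests(p, method="fdr_bh")[1]
    info = {"method": used, "pi0": pi0, "m": m}
    return (q, info) if return_info else q


def _as_matrix(geno) -> np.ndarray:
    if isinstance(geno, DosageMatrix):
        return geno.values
    if isinstance(geno, pd.DataFrame):
        return geno.to_numpy(dtype=float)
    return np.asarray(geno, dtype=float)


def _as_y(pheno) -> np.ndarray:
    if isinstance(pheno, pd.DataFrame):
        return pheno["log_growth"].to_numpy(dtype=float)
    return np.asarray(pheno, dtype=float)


def gwas_scan(geno, pheno, fdr_method: str = "storey") -> pd.DataFrame:
    """Vectorized per-locus OLS of phenotype on dosage.

    Accepts a :class:`DosageMatrix` (NaN entries handled per locus by
    complete-case arithmetic) or a plain array, and a phenotype table (uses
    its ``log_growth`` column) or a numeric vector.  Returns a DataFrame
    with ``beta, se, t, p, q, sig_q05, sig_q10`` indexed by locus.
    """
    G = _as_matrix(geno)
    y = _as_y(pheno)
    n, L = G.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match individuals")
    if n < 3:
        raise ValueError("need at least 3 individuals")

    mask = ~np.isnan(G)
    Gz = np.where(mask, G, 0.0)
    n_l = mask.sum(axis=0).astype(float)
    if np.any(n_l < 3):
        raise ValueError("a locus has fewer than 3 observed genotypes")
    sum_g = Gz.sum(axis=0)
    sum_gg = (Gz * Gz).sum(axis=0)
    sum_y = mask.T.astype(float) @ y
    sum_yy = mask.T.astype(float) @ (y * y)
    sum_gy = Gz.T @ y
    Sxx = sum_gg - sum_g ** 2 / n_l
    Sxy = sum_gy - sum_g * sum_y / n_l
    Syy = sum_yy - sum_y ** 2 / n_l

    degenerate = Sxx <= 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance loci skipped",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(degenerate, np.nan, Sxy / np.where(degenerate, 1, Sxx))
        sse = np.maximum(Syy - beta * Sxy, 0.0)
        df = n_l - 2
        sigma2 = sse / df
        se = np.sqrt(sigma2 / np.where(degenerate, 1, Sxx))
        t = np.where(se > 0, beta / np.where(se > 0, se, 1), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, _P_FLOOR, 1.0)
    p[degenerate] = np.nan

    ok = ~degenerate
    q = np.full(L, np.nan)
    if ok.any():
        q[ok] = fdr_qvalues(p[ok], method=fdr_method)
    if isinstance(geno, DosageMatrix):
        idx = geno.locus_ids
    elif isinstance(geno, pd.DataFrame):
        idx = geno.columns
    else:
        idx = np.arange(L)
    res = pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p, "q": q},
                       index=pd.Index(idx, name="locus_id"))
    res["sig_q05"] = res["q"] < 0.05
    res["sig_q10"] = res["q"] < 0.10
    res["degenerate"] = degenerate
    return res


class GwasScan(BaseEstimator):
    """Per-SNP OLS association scan as a scikit-learn style estimator.

    Parameters
    ----------
    fdr_method : {"storey", "bh"}
        Multiple-testing correction applied to the per-locus p-values.

    Attributes
    ----------
    results_ : DataFrame with beta, se, t, p, q and significance flags.
    fdr_info_ : dict describing the correction actually applied.
    """

    def __init__(self, fdr_method: str = "storey"):
        self.fdr_method = fdr_method

    def fit(self, X, y):
        self.results_ = gwas_scan(X, y, fdr_method=self.fdr_method)
        ok = ~self.results_["degenerate"]
        _, self.fdr_info_ = fdr_qvalues(self.results_.loc[ok, "p"],
                                        method=self.fdr_method,
                                        return_info=True)
        self.n_features_in_ = self.results_.shape[0]
        return self
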