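"""Redundancy analysis (RDA) outlier scan with growth as the constraint.

RDA is constrained ordination: the centered genotype matrix is projected
onto the predictor (here a single variable, scaled log growth), and the
constrained axes are the principal axes of the fitted values.  With one
predictor there is exactly one constrained axis; the fitted matrix
G-hat = P_x G_c has rank 1 and its right singular vector holds the per-SNP
loadings, which are then proportional to the per-locus covariance between
dosage and growth.  Candidate growth-associated SNPs are those whose
loading lies more than 2.5 standard deviations from the mean loading — the
conventional outlier screen for constrained-ordination genome scans.

Genotypes are centered but not scaled by default (the convention of the
classic constrained-ordination implementation); per-locus unit scaling is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genotypes import DosageMatrix

__all__ = ["RdaScan", "RdaResult", "rda_scan", "rda_candidates"]


@dataclass
class RdaResult:
    """Constrained-axis scores and per-SNP loadings."""

    axis_scores: np.ndarray     # individuals on constrained axis 1
    loadings: np.ndarray        # per-locus loading on axis 1
    locus_ids: np.ndarray
    variance_explained: float   # fraction of total genotype SS on the axis
    mean_loading: float = float("nan")
    sd_loading: float = float("nan")

    def __post_init__(self) -> None:
        self.mean_loading = float(np.mean(self.loadings))
        self.sd_loading = float(np.std(self.loadings))

    def to_frame(self, sd_cut: float = 2.5) -> pd.DataFrame:
        z = (self.loadings - self.mean_loading) / self.sd_loading
        return pd.DataFrame(
            {"loading": self.loadings, "loading_z": z,
             "candidate": np.abs(z) > sd_cut},
            index=pd.Index(self.locus_ids, name="locus_id"))


def rda_scan(geno, x, scale_loci: bool = False) -> RdaResult:
    """RDA of genotypes on a single (centered) predictor.

    The rank-1 structure is used directly: loadings are the normalized
    vector of per-locus covariances with the predictor, axis scores are the
    site scores of the fitted matrix, and the axis is oriented so its
    correlation with ``x`` is non-negative.
    """
    if isinstance(geno, DosageMatrix):
        G = geno.imputed()
        locus_ids = geno.locus_ids
    else:
        G = np.asarray(geno, dtype=float)
        locus_ids = np.arange(G.shape[1])
    if np.isnan(G).any():
        raise ValueError("RDA requires complete (imputed) genotypes")
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != G.shape[0]:
        raise ValueError("predictor length does not match individuals")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    x = x - x.mean()
    G_c = G - G.mean(axis=0)
    if scale_loci:
        sd = G_c.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("cannot scale zero-variance loci")
        G_c = G_c / sd

    xhat = x / np.linalg.norm(x)
    c = G_c.T @ xhat                    # per-locus covariance * n (up to x scale)
    s1 = np.linalg.norm(c)
    if s1 == 0:
        raise ValueError("genotypes are orthogonal to the predictor")
    loadings = c / s1
    axis_scores = xhat * s1             # fitted-site scores on axis 1
    # orientation: correlation(axis_scores, x) >= 0 holds by construction;
    # flip both factors if numerical sign convention ever reverses it
    if np.dot(axis_scores, x) < 0:      # pragma: no cover - defensive
        axis_scores, loadings = -axis_scores, -loadings
    total_ss = float((G_c * G_c).sum())
    return RdaResult(axis_scores=axis_scores, loadings=loadings,
                     locus_ids=np.asarray(locus_ids, dtype=object),
                     variance_explained=float(s1 ** 2 / total_ss))


def rda_candidates(res: RdaResult, sd_cut: float = 2.5) -> pd.DataFrame:
    """Loci whose loading deviates more than ``sd_cut`` SD from the mean.

    Returns the per-locus frame restricted to candidates, with the margin
    ``|z| - sd_cut`` for ranking.
    """
    if sd_cut < 0:
        raise ValueError("sd_cut must be >= 0")
    df = res.to_frame(sd_cut=sd_cut)
    df["margin"] = np.abs(df["loading_z"]) - sd_cut
    return df[df["candidate"]]


class RdaScan(BaseEstimator):
    """RDA outlier scan as a scikit-learn style estimator.

    Parameters
    ----------
    sd_cut : float
        Loading z-score cutoff for candidate status (default 2.5).
    scale_loci : bool
        Scale loci to unit variance before the ordination (default False).

    Attributes
    ----------
    result_ : :class:`RdaResult`
    results_ : per-locus DataFrame (loading, loading_z, candidate).
    candidates_ : index of candidate loci.
    """

    def __init__(self, sd_cut: float = 2.5, scale_loci: bool = False):
        self.sd_cut = sd_cut
        self.scale_loci = scale_loci

    def fit(self, X, y):
        self.result_ = rda_scan(X, y, scale_loci=self.scale_loci)
        self.results_ = self.result_.to_frame(sd_cut=self.sd_cut)
        self.candidates_ = self.results_.index[self.results_["candidate"]]
        self.n_features_in_ = len(self.results_)
        return self
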