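"""Concordance algebra, permutation null, per-locus R2, ANCOVA, polygenic."""

import numpy as np
import pandas as pd
import pytest

from wildgwas.genotypes import DosageMatrix
from wildgwas.integrate import (PolygenicScore, concordance, per_locus_r2,
                                polygenic_fit, randomization_null,
                                site_interaction_ancova)
from wildgwas.simdata import SimConfig, simulate_cohort


def _frames(universe, gwas_set, lfmm_set, rda_set):
    idx = pd.Index(universe, name="locus_id")
    gw = pd.DataFrame({"sig_q10": [l in gwas_set for l in universe]},
                      index=idx)
    lf = pd.DataFrame({"sig_q05": [l in lfmm_set for l in universe]},
                      index=idx)
    rd = pd.DataFrame({"candidate": [l in rda_set for l in universe]},
                      index=idx)
    return gw, lf, rd


def test_concordance_set_algebra():
    uni = ["t1:1", "t2:1", "t3:1", "t4:1"]
    rep = concordance(*_frames(uni, {"t1:1", "t2:1", "t3:1"},
                               {"t2:1", "t3:1"}, {"t3:1"}))
    assert rep.loci_in_class("triple") == ["t3:1"]
    assert rep.loci_in_class("double") == ["t2:1"]
    assert rep.loci_in_class("single") == ["t1:1"]
    assert rep.loci_in_class("none") == ["t4:1"]
    # classes partition the universe
    assert sorted(sum((rep.loci_in_class(c) for c in
                       ("none", "single", "double", "triple")), [])) == \
        sorted(uni)


def test_concordance_disjoint_sets_no_overlap():
    uni = ["a:1", "b:1", "c:1"]
    rep = concordance(*_frames(uni, {"a:1"}, {"b:1"}, {"c:1"}))
    assert rep.double_or_more == [] and rep.triple == []


def test_tag_collapsing_links_same_ddradtag():
    uni = ["55183:7", "55183:146", "9:1"]
    rep = concordance(*_frames(uni, set(uni[:2]), set(uni[:2]),
                               set(uni[:2])))
    assert list(rep.regions.index) == ["55183"]
    assert rep.regions.loc["55183", "n_loci"] == 2
    assert rep.regions.loc["55183", "best_class"] == "triple"


def test_concordance_universe_mismatch_errors():
    gw, lf, rd = _frames(["a:1", "b:1"], set(), set(), set())
    rd2 = rd.iloc[:1]
    with pytest.raises(ValueError, match="different loci"):
        concordance(gw, lf, rd2)


def test_randomization_null_determinism_and_summary(null_cohort):
    geno, pheno, _ = null_cohort
    n1 = randomization_null(geno, pheno, n_iter=100, seed=3,
                            fdr_method="bh")
    n2 = randomization_null(geno, pheno, n_iter=100, seed=3,
                            fdr_method="bh")
    assert np.array_equal(n1.counts, n2.counts)
    s = n1.summary
    assert s["frac_zero"] <= s["frac_le_1"] <= 1.0
    assert 0.0 <= s["frac_ge_observed"] <= 1.0
    with pytest.raises(ValueError, match="n_iter"):
        randomization_null(geno, pheno, n_iter=10)
    with pytest.raises(ValueError, match="constant"):
        randomization_null(geno, pheno.assign(log_growth=1.0), n_iter=100)


def test_randomization_null_invariant_to_individual_relabeling(null_cohort):
    """The null count distribution depends only on the (g, y) pairing
    multiset, so jointly relabeling individuals leaves its mean unmoved
    beyond Monte-Carlo noise."""
    geno, pheno, _ = null_cohort
    rng = np.random.default_rng(1)
    perm = rng.permutation(geno.n_individuals)
    geno_p = DosageMatrix(geno.values[perm], geno.locus_ids,
                          geno.individual_ids[perm])
    pheno_p = pheno.iloc[perm].reset_index(drop=True)
    a = randomization_null(geno, pheno, n_iter=100, seed=5, fdr_method="bh")
    b = randomization_null(geno_p, pheno_p, n_iter=100, seed=5,
                           fdr_method="bh")
    assert abs(a.summary["frac_zero"] - b.summary["frac_zero"]) < 0.1


def test_per_locus_r2_oracle():
    g = np.array([0, 0, 0.5, 0.5, 1, 1])
    y = np.array([1.0, 1.2, 2.0, 2.2, 3.0, 3.2])
    r2 = per_locus_r2(g[:, None], y)
    assert r2.iloc[0] == pytest.approx(np.corrcoef(g, y)[0, 1] ** 2,
                                       abs=1e-12)
    # perfectly collinear
    assert per_locus_r2(y[:, None], y).iloc[0] == pytest.approx(1.0)


def test_per_locus_r2_null_expectation(rng):
    n, L = 52, 4000
    G = rng.choice([0, 0.5, 1.0], size=(n, L))
    y = rng.normal(size=n)
    r2 = per_locus_r2(G, y)
    assert r2.mean() == pytest.approx(1 / (n - 1), rel=0.2)


def _ancova_cohort(rng, slopes, n_per_site=18):
    sites = np.repeat(["S1", "S2", "S3"], n_per_site)
    g = rng.choice([0, 0.5, 1.0], size=len(sites))
    y = np.zeros(len(sites))
    for s, b in zip(("S1", "S2", "S3"), slopes):
        m = sites == s
        y[m] = b * g[m] + rng.normal(scale=0.3, size=m.sum())
    pheno = pd.DataFrame({"id": [f"i{k}" for k in range(len(sites))],
                          "site": sites, "plot": "P1", "log_growth": y})
    return g[:, None], pheno


def test_ancova_detects_slope_reversal():
    rng = np.random.default_rng(2)
    hits = 0
    for _ in range(20):
        G, pheno = _ancova_cohort(rng, slopes=(1.0, 1.0, -1.0))
        res = site_interaction_ancova(G, pheno, loci=[0])
        hits += res["interaction_p"].iloc[0] < 0.05
    assert hits >= 16   # power > 0.8


def test_ancova_null_not_anticonservative():
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(30):
        G, pheno = _ancova_cohort(rng, slopes=(0.5, 0.5, 0.5))
        ps.append(site_interaction_ancova(G, pheno,
                                          loci=[0])["interaction_p"].iloc[0])
    assert (np.array(ps) < 0.05).mean() <= 0.15
    assert np.mean(ps) > 0.3


def test_ancova_single_site_errors_and_inestimable_flag():
    rng = np.random.default_rng(4)
    G, pheno = _ancova_cohort(rng, slopes=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="two sites"):
        site_interaction_ancova(G, pheno.assign(site="S1"), loci=[0])
    G2 = G.copy()
    G2[pheno["site"] == "S2", 0] = 0.5   # one genotype class in S2
    res = site_interaction_ancova(G2, pheno, loci=[0])
    assert not res["estimable"].iloc[0]
    assert np.isnan(res["interaction_p"].iloc[0])


def test_polygenic_single_locus_identity(default_cohort):
    geno, pheno, truth = default_cohort
    lid = truth.causal_locus_ids[0]
    poly = polygenic_fit(geno, pheno, [lid])
    r2 = per_locus_r2(geno, pheno, [lid]).iloc[0]
    assert poly["r2"] == pytest.approx(r2, abs=1e-10)


def test_polygenic_perfect_prediction():
    rng = np.random.default_rng(5)
    g = rng.choice([0, 0.5, 1.0], size=60)
    y = 2.0 * g + 1.0                      # growth exactly linear in dosage
    poly = polygenic_fit(g[:, None], pd.DataFrame({"log_growth": y}), [0])
    assert poly["r2"] == pytest.approx(1.0)


def test_polygenic_joint_beats_best_single(default_cohort):
    geno, pheno, truth = default_cohort
    poly = polygenic_fit(geno, pheno, truth.causal_locus_ids)
    singles = per_locus_r2(geno, pheno, truth.causal_locus_ids)
    assert poly["r2"] >= singles.max() - 1e-9
    assert 0.0 <= poly["r2"] <= 1.0
    assert poly["p"] < 1e-3


def test_polygenic_ridge_orientation(default_cohort):
    """The alternative trait-on-dosages ridge refit agrees with the default
    orientation up to the single-locus identity and gives a joint R2 at
    least as large in-sample."""
    geno, pheno, truth = default_cohort
    lid = truth.causal_locus_ids[0]
    r2 = per_locus_r2(geno, pheno, [lid]).iloc[0]
    single = polygenic_fit(geno, pheno, [lid], method="ridge")
    assert single["r2"] == pytest.approx(r2, abs=1e-8)
    joint_lfmm = polygenic_fit(geno, pheno, truth.causal_locus_ids)
    joint_ridge = polygenic_fit(geno, pheno, truth.causal_locus_ids,
                                method="ridge")
    assert joint_ridge["r2"] >= joint_lfmm["r2"] - 1e-9
    with pytest.raises(ValueError, match="unknown polygenic"):
        polygenic_fit(geno, pheno, [lid], method="lasso")


def test_polygenic_empty_selection_errors(default_cohort):
    geno, pheno, _ = default_cohort
    with pytest.raises(ValueError, match="empty"):
        polygenic_fit(geno, pheno, [])


def test_polygenic_estimator_predict_shape(default_cohort):
    geno, pheno, truth = default_cohort
    X = geno.subset_loci(truth.causal_locus_ids).imputed()
    y = pheno["log_growth"].to_numpy()
    est = PolygenicScore().fit(X, y)
    pred = est.predict(X)
    assert pred.shape == (geno.n_individuals,)
    assert abs(pred.mean()) < 1e-10 and abs(pred.std() - 1) < 1e-10
    assert est.score(X, y) == pytest.approx(polygenic_fit(
        geno, pheno, truth.causal_locus_ids)["r2"], abs=1e-12)
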