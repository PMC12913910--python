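"""Configuration-driven orchestration of the full association pipeline.

``run_all`` ties the stages together: VCF filtering, phenotype preparation
and checks, the three association engines, cross-method integration, the
phenotype-randomization null and the polygenic model, writing every stage's
tabular output under the configured directory.  A single global seed fans
out to per-stage child seeds through a counter-based scheme
(``SeedSequence([seed, stage_counter])``) so stages can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phenotype as phen
from .genotypes import FilterConfig, filter_sites, read_vcf
from .gwas import GwasScan
from .integrate import (concordance, per_locus_r2, polygenic_fit,
                        randomization_null, site_interaction_ancova)
from .lfmm import LfmmRidge
from .rda import RdaScan

__all__ = ["RunConfig", "run_all", "report", "child_seed"]


def child_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2^31."""
    return int(np.random.SeedSequence([int(seed), int(stage)])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; YAML round-trippable.

    Defaults match the study conventions of the workflow this package
    implements: depth window 5x to 2x mean, <= 10% missingness, MAF >= 0.03,
    FDR thresholds 0.05 (strict) and 0.1 (relaxed), RDA cutoff +/- 2.5 SD,
    1000 randomization iterations.
    """

    vcf: str = ""
    phenotype: str = ""
    outdir: str = "results"
    filter: FilterConfig = field(default_factory=FilterConfig)
    complete_case_gwas: bool = False
    fdr_method: str = "storey"
    gwas_q_strict: float = 0.05
    gwas_q_relaxed: float = 0.10
    lfmm_k: object = "auto"
    lfmm_lambda: float = 1e-5
    lfmm_q: float = 0.05
    rda_sd_cut: float = 2.5
    rda_scale: bool = False
    null_iterations: int = 1000
    mantel_permutations: int = 9999
    polygenic_k: int = 0
    polygenic_method: str = "lfmm"
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterConfig(**d["filter"])
        return cls(**d)


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def run_all(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; returns the result bundle.

    Stages abort with the stage name and cause on error.  Rerunning with the
    same config and seed is bit-identical for every deterministic stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg}

    log = logging.getLogger("wildgwas")
    log.setLevel(logging.INFO)
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)
        h.close()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    if not any(type(h) is logging.StreamHandler for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    log.info("run started: seed=%s vcf=%s", cfg.seed, cfg.vcf)

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
                log.info("stage %s ok", name)
                return result
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}"
                                   ) from exc
        return wrap

    # --- genotypes -------------------------------------------------------
    records = stage("read_vcf")(lambda: read_vcf(cfg.vcf))
    dm, flog = stage("filter")(lambda: filter_sites(records, cfg.filter))
    flog.to_json(out / "filter_log.json")
    bundle["dosage"] = dm
    bundle["filter_log"] = flog

    # --- phenotype -------------------------------------------------------
    pheno = stage("phenotype")(lambda: phen.load_phenotype(cfg.phenotype))
    pheno = pheno.set_index("id").loc[[str(i) for i in dm.individual_ids]
                                      ].reset_index()
    _, _, normality = phen.transform_growth(pheno["growth_rate"].to_numpy(),
                                            ids=pheno["id"].to_numpy())
    anova = stage("site_anova")(lambda: phen.site_anova(pheno))
    A = stage("relatedness")(lambda: phen.relatedness_matrix(dm))
    _write_tsv(A, out / "relatedness.tsv")
    mantel_r, mantel_p = stage("mantel")(lambda: phen.mantel_growth_vs_relatedness(
        A, pheno, n_perm=cfg.mantel_permutations, seed=child_seed(cfg.seed, 1)))
    bundle.update(pheno=pheno, normality=normality, anova=anova,
                  relatedness=A, mantel=(mantel_r, mantel_p))

    y = pheno["log_growth"].to_numpy()
    x = pheno["scaled_growth"].to_numpy()
    G = dm.values if cfg.complete_case_gwas else dm.imputed()

    # --- three association engines --------------------------------------
    gw = stage("gwas")(lambda: GwasScan(fdr_method=cfg.fdr_method)
                       .fit(pd_matrix(G, dm), y))
    _write_tsv(gw.results_, out / "gwas.tsv")
    lf = stage("lfmm")(lambda: LfmmRidge(K=cfg.lfmm_k, lam=cfg.lfmm_lambda,
                                         fdr_method=cfg.fdr_method,
                                         seed=child_seed(cfg.seed, 2)).fit(dm, x))
    if cfg.lfmm_k == "auto":
        log.warning("LFMM K chosen automatically (K=%d); K is the main "
                    "reproducibility lever of this method — set lfmm_k "
                    "explicitly to pin it", lf.K_)
    log.info("lfmm: K=%d gif=%.3f", lf.K_, lf.gif_)
    lf_out = lf.results_.copy()
    _write_tsv(lf_out, out / "lfmm.tsv")
    rd = stage("rda")(lambda: RdaScan(sd_cut=cfg.rda_sd_cut,
                                      scale_loci=cfg.rda_scale).fit(dm, x))
    _write_tsv(rd.results_, out / "rda.tsv")
    bundle.update(gwas=gw, lfmm=lf, rda=rd)

    # --- integration -----------------------------------------------------
    conc = stage("concordance")(lambda: concordance(gw.results_, lf.results_,
                                                    rd.results_))
    _write_tsv(conc.table, out / "concordance.tsv")
    _write_tsv(conc.regions, out / "regions.tsv")
    null = stage("randomization_null")(lambda: randomization_null(
        dm, pheno, n_iter=cfg.null_iterations, seed=child_seed(cfg.seed, 3),
        fdr_method=cfg.fdr_method, q_threshold=cfg.gwas_q_strict))
    pd.DataFrame({"count": null.counts}).to_csv(out / "null_counts.csv",
                                                index=False)
    (out / "null_summary.json").write_text(json.dumps(
        {**null.summary, "observed": null.observed,
         "n_iter": null.n_iter}, indent=2))
    bundle.update(concordance=conc, null=null)

    flagged = list(conc.table.index[conc.table["n_methods"] > 0])
    r2 = per_locus_r2(dm, pheno, flagged) if flagged else pd.Series(dtype=float)
    if len(r2):
        _write_tsv(r2.to_frame(), out / "per_locus_r2.tsv")
    triple = conc.triple
    ancova = (site_interaction_ancova(dm, pheno, triple) if triple
              else pd.DataFrame())
    if len(ancova):
        _write_tsv(ancova, out / "ancova.tsv")
    selected = conc.double_or_more
    poly = None
    if selected:
        poly = stage("polygenic")(lambda: polygenic_fit(
            dm, pheno, selected, K=cfg.polygenic_k, lam=cfg.lfmm_lambda,
            method=cfg.polygenic_method))
        pd.DataFrame({"id": pheno["id"],
                      "observed_scaled": pheno["scaled_growth"],
                      "predicted_scaled": poly["predicted"]}).to_csv(
            out / "polygenic.csv", index=False)
    bundle.update(per_locus_r2=r2, ancova=ancova, polygenic=poly)

    cfg.to_yaml(out / "config_used.yaml")
    summary = report(bundle)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    bundle["summary"] = summary
    log.info("run complete: outputs under %s", out)
    log.removeHandler(handler)
    handler.close()
    return bundle


def pd_matrix(G: np.ndarray, dm) -> pd.DataFrame:
    """Wrap a genotype array with locus ids so results stay indexed."""
    return pd.DataFrame(G, columns=dm.locus_ids)


def report(bundle: dict) -> dict:
    """Human-readable summary of a result bundle (JSON-serializable)."""
    cfg: RunConfig = bundle["config"]
    gw, lf, rd = bundle["gwas"], bundle["lfmm"], bundle["rda"]
    conc, null = bundle["concordance"], bundle["null"]
    counts = conc.table["concordance"].value_counts().to_dict()
    summary = {
        "seed": cfg.seed,
        "n_individuals": int(bundle["dosage"].n_individuals),
        "n_loci": int(bundle["dosage"].n_loci),
        "filter": {"removed": bundle["filter_log"].removed,
                   "mean_depth": bundle["filter_log"].mean_depth},
        "normality": dataclasses.asdict(bundle["normality"]),
        "anova": {k: {"F": v[0], "p": v[1]}
                  for k, v in bundle["anova"].items()},
        "mantel": {"r": bundle["mantel"][0], "p": bundle["mantel"][1]},
        "gwas": {"n_q05": int(gw.results_["sig_q05"].sum()),
                 "n_q10": int(gw.results_["sig_q10"].sum()),
                 "fdr": gw.fdr_info_},
        "lfmm": {"K": int(lf.K_), "lambda": cfg.lfmm_lambda,
                 "gif": float(lf.gif_),
                 "n_q05": int(lf.results_["sig_q05"].sum())},
        "rda": {"n_candidates": int(rd.results_["candidate"].sum()),
                "sd_cut": cfg.rda_sd_cut,
                "variance_explained": float(rd.result_.variance_explained)},
        "concordance": {k: int(counts.get(k, 0))
                        for k in ("single", "double", "triple")},
        "n_regions": int(len(conc.regions)),
        "null": {**null.summary, "observed": null.observed,
                 "n_iter": null.n_iter},
    }
    if bundle.get("polygenic"):
        summary["polygenic"] = {"n_loci": len(bundle["polygenic"]["loci"]),
                                "r2": bundle["polygenic"]["r2"],
                                "p": bundle["polygenic"]["p"]}
    return summary
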