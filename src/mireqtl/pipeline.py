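"""End-to-end orchestration: normalize -> expand -> filter -> associate ->
FDR -> risk -> reports.

:func:`run_pipeline` executes the stages in order on the input tables,
writes TSV result tables shaped like the study's report tables
(genotype-stratified N / mean / % zero expression with raw and FDR
p-values; paired tumor/normal comparisons; per-SNP genotype-class odds
ratios) and returns a manifest that, together with the config and seed it
records, suffices to reproduce the run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .assoc import (
    BootstrapSpec,
    bh_fdr,
    bootstrap_trend_p,
    differential_trend,
    genotype_class_summary,
    paired_bootstrap_ttest,
)
from .filters import FilterParams, apply_cascade
from .nomenclature import expand_pairs
from .preprocess import expression_prevalence, log2_transform, normalization_report, normalize
from .risk import fit_logistic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_synthetic_pipeline", "summarize_significance",
           "significant_fraction"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    expression_tumor: str
    expression_normal: str
    genotypes: str
    covariates: str
    pairs: str
    out_dir: str = "results"
    filter_params: FilterParams = field(default_factory=FilterParams)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    log2_offset: float = 1.0
    #: normalization strata: "site_by_tissue" (per-site within each tissue)
    #: or "site" (per-site, tissues pooled is not meaningful here since the
    #: two tissues live in separate matrices; "site" normalizes each matrix
    #: by site labels only)
    strata_mode: str = "site_by_tissue"
    alpha: float = 0.05
    run_risk: bool = True
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fp = FilterParams(**raw.pop("filter_params", {}))
        bs = BootstrapSpec(**raw.pop("bootstrap", {}))
        cfg = cls(filter_params=fp, bootstrap=bs, **raw)
        for key in ("expression_tumor", "expression_normal", "genotypes", "covariates", "pairs"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {key} = {p!r} does not exist")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _strata(covariates: pd.DataFrame, samples: pd.Index) -> pd.Series:
    if "site" in covariates.columns:
        return covariates["site"].reindex(samples)
    return pd.Series("all", index=samples)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- load -----------------------------------------------------------
    expr_t_raw = mio.read_expression(config.expression_tumor)
    expr_n_raw = mio.read_expression(config.expression_normal)
    genotypes = mio.read_genotypes(config.genotypes)
    covariates = mio.read_covariates(config.covariates)
    pairs_raw = mio.read_pairs(config.pairs)

    # ---- normalize (stratified 75th-percentile scaling) ------------------
    norm_t = normalize(expr_t_raw, _strata(covariates, expr_t_raw.columns),
                       log2_offset=config.log2_offset)
    norm_n = normalize(expr_n_raw, _strata(covariates, expr_n_raw.columns),
                       log2_offset=config.log2_offset)
    normalization_report(expr_t_raw, norm_t).to_csv(out / "normalization_tumor.tsv", sep="\t")
    normalization_report(expr_n_raw, norm_n).to_csv(out / "normalization_normal.tsv", sep="\t")
    log2_t = log2_transform(norm_t)
    log2_n = log2_transform(norm_n)

    # ---- expand + filter --------------------------------------------------
    catalog = list(expr_n_raw.index)
    expanded = expand_pairs(pairs_raw, catalog)
    retained, report = apply_cascade(
        expanded, norm_n.values, norm_t.values, genotypes, config.filter_params
    )
    report.to_frame().to_csv(out / "cascade_report.tsv", sep="\t", index=False)
    report.drops.to_csv(out / "cascade_drops.tsv", sep="\t", index=False)
    logger.info("pair cascade:\n%s", report.log_block())

    # individuals with all data types
    samples = [
        s for s in covariates.index
        if s in log2_n.columns and s in log2_t.columns and s in genotypes.columns
    ]
    cov_model = covariates.loc[samples, ["age", "sex", "center"]]
    seed_seq = np.random.SeedSequence(config.bootstrap.seed)
    n_tests = max(len(retained), 1)
    child_seeds = seed_seq.generate_state(3 * n_tests + 3) % (2**31)

    # ---- stage 1: non-tumor trend / stage 2: differential trend ----------
    nontumor_rows, diff_rows = [], []
    for k, (_, pair) in enumerate(retained.iterrows()):
        snp, mirna = pair["snp_id"], pair["mirna_name"]
        g = genotypes.loc[snp, samples].astype("float64")
        keep = g.notna().to_numpy()
        g_arr = g.to_numpy(dtype=float)[keep]
        cov_k = cov_model.iloc[keep]
        y_n = log2_n.loc[mirna, samples].to_numpy()[keep]
        y_t = log2_t.loc[mirna, samples].to_numpy()[keep]
        sig_n = norm_n.values.loc[mirna, samples].to_numpy()[keep]
        sig_t = norm_t.values.loc[mirna, samples].to_numpy()[keep]

        spec_nt = BootstrapSpec(config.bootstrap.n_boot, int(child_seeds[3 * k]),
                                config.bootstrap.two_sided, config.bootstrap.method)
        res_nt = bootstrap_trend_p(y_n, g_arr, cov_k, spec_nt)
        cls_n = genotype_class_summary(sig_n, g_arr)
        row = {"snp_id": snp, "gene_labels": pair.get("gene_labels", ""),
               "mirna_name": mirna, "beta": res_nt["beta"], "p_raw": res_nt["p_raw"],
               "n": res_nt["n"]}
        for code in (0, 1, 2):
            row[f"n_{code}"] = cls_n.loc[code, "n"]
            row[f"mean_{code}"] = cls_n.loc[code, "mean"]
            row[f"pct_zero_{code}"] = cls_n.loc[code, "pct_zero"]
        nontumor_rows.append(row)

        spec_df = BootstrapSpec(config.bootstrap.n_boot, int(child_seeds[3 * k + 1]),
                                config.bootstrap.two_sided, config.bootstrap.method)
        res_df = differential_trend(y_t, y_n, g_arr, cov_k, spec_df)
        cls_d = genotype_class_summary(sig_t - sig_n, g_arr)
        drow = {"snp_id": snp, "gene_labels": pair.get("gene_labels", ""),
                "mirna_name": mirna, "beta": res_df["beta"], "p_raw": res_df["p_raw"],
                "n": res_df["n"]}
        for code in (0, 1, 2):
            drow[f"n_{code}"] = cls_d.loc[code, "n"]
            drow[f"mean_diff_{code}"] = cls_d.loc[code, "mean"]
        g_codes = g_arr
        for code in (0, 1, 2):
            m = g_codes == code
            drow[f"pct_zero_tumor_{code}"] = float(100 * (sig_t[m] == 0).mean()) if m.any() else np.nan
            drow[f"pct_zero_normal_{code}"] = float(100 * (sig_n[m] == 0).mean()) if m.any() else np.nan
        diff_rows.append(drow)

    nontumor = pd.DataFrame(nontumor_rows)
    diff = pd.DataFrame(diff_rows)
    if len(nontumor):
        nontumor["q_fdr"] = bh_fdr(nontumor["p_raw"].to_numpy())
        diff["q_fdr"] = bh_fdr(diff["p_raw"].to_numpy())
    nontumor.to_csv(out / "trend_nontumor.tsv", sep="\t", index=False)
    diff.to_csv(out / "trend_differential.tsv", sep="\t", index=False)

    # ---- paired tumor vs non-tumor t-tests per retained miRNA ------------
    paired_rows = []
    for k, mirna in enumerate(sorted(retained["mirna_name"].unique())):
        y_t = log2_t.loc[mirna, samples].to_numpy()
        y_n = log2_n.loc[mirna, samples].to_numpy()
        spec_pt = BootstrapSpec(config.bootstrap.n_boot,
                                int(child_seeds[3 * n_tests + 2] + k) % (2**31),
                                config.bootstrap.two_sided, config.bootstrap.method)
        r = paired_bootstrap_ttest(y_t, y_n, spec_pt, mirna_name=mirna)
        sig_t = norm_t.values.loc[mirna, samples]
        sig_n = norm_n.values.loc[mirna, samples]
        paired_rows.append({
            "mirna_name": mirna, "mean_tumor": float(sig_t.mean()),
            "pct_zero_tumor": float(100 * (sig_t == 0).mean()),
            "mean_normal": float(sig_n.mean()),
            "pct_zero_normal": float(100 * (sig_n == 0).mean()),
            "t_stat": r.t_stat, "p_value": r.p_value, "n": r.n,
            "degenerate": r.degenerate,
        })
    paired = pd.DataFrame(paired_rows)
    paired.to_csv(out / "paired_tumor_normal.tsv", sep="\t", index=False)

    # ---- stage 3: risk models for SNPs significant in stage 1 or 2 -------
    sig_snps = summarize_significance(
        {"nontumor": nontumor, "differential": diff}, alpha=config.alpha
    )
    status = covariates["status"] if "status" in covariates.columns else None
    risk_rows = []
    if status is not None and config.run_risk:
        risk_samples = covariates.index[covariates["status"].notna()]
        for snp in sig_snps["significant_snps"]:
            if snp not in genotypes.index:
                continue
            cols = [s for s in risk_samples if s in genotypes.columns]
            g = genotypes.loc[snp, cols]
            rr = fit_logistic(
                status.loc[cols], g, covariates.loc[cols, ["age", "sex", "center"]],
                snp_id=snp,
            )
            risk_rows.append({
                "snp_id": snp,
                "controls_0": rr.counts.loc[0, "controls"], "cases_0": rr.counts.loc[0, "cases"],
                "controls_1": rr.counts.loc[1, "controls"], "cases_1": rr.counts.loc[1, "cases"],
                "or_het": rr.or_het, "ci_het_low": rr.ci_het[0], "ci_het_high": rr.ci_het[1],
                "controls_2": rr.counts.loc[2, "controls"], "cases_2": rr.counts.loc[2, "cases"],
                "or_hom": rr.or_hom, "ci_hom_low": rr.ci_hom[0], "ci_hom_high": rr.ci_hom[1],
                "separation": rr.separation,
            })
    risk_table = pd.DataFrame(risk_rows)
    risk_table.to_csv(out / "risk_odds_ratios.tsv", sep="\t", index=False)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.bootstrap.seed,
        "n_samples_analyzed": len(samples),
        "cascade": [list(t) for t in report.stage_counts],
        "n_pairs_tested": len(retained),
        "significance": {k: v for k, v in sig_snps.items() if k != "significant_snps"},
        "significant_snps": sorted(sig_snps["significant_snps"]),
        "outputs": {
            "normalization_tumor": str(out / "normalization_tumor.tsv"),
            "normalization_normal": str(out / "normalization_normal.tsv"),
            "cascade_report": str(out / "cascade_report.tsv"),
            "trend_nontumor": str(out / "trend_nontumor.tsv"),
            "trend_differential": str(out / "trend_differential.tsv"),
            "paired_tumor_normal": str(out / "paired_tumor_normal.tsv"),
            "risk_odds_ratios": str(out / "risk_odds_ratios.tsv"),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def summarize_significance(results: dict[str, pd.DataFrame], alpha: float = 0.05) -> dict:
    """Tally raw- and FDR-significant pairs and the unique significant
    SNPs across the non-tumor and differential analyses.

    ``results`` maps analysis name -> table with columns ``snp_id``,
    ``p_raw`` and optionally ``q_fdr``. The significant fraction is the
    number of unique raw-significant SNPs over the number of tested pairs.
    """
    if not results:
        raise ValueError("no result tables supplied")
    out: dict = {}
    union: set = set()
    n_tested = 0
    for name, table in results.items():
        if len(table) == 0:
            out[f"n_raw_sig_{name}"] = 0
            out[f"n_fdr_sig_{name}"] = 0
            continue
        raw_sig = table[table["p_raw"] < alpha]
        out[f"n_raw_sig_{name}"] = int(len(raw_sig))
        if "q_fdr" in table.columns:
            out[f"n_fdr_sig_{name}"] = int((table["q_fdr"] < alpha).sum())
        union |= set(raw_sig["snp_id"])
        n_tested = max(n_tested, len(table))
    out["n_unique_significant_snps"] = len(union)
    out["n_tested_pairs"] = n_tested
    out["significant_fraction_pct"] = significant_fraction(len(union), n_tested)
    out["significant_snps"] = union
    return out


def significant_fraction(n_unique_significant: int, n_tested: int) -> float:
    """Percentage of tested pairs whose SNP was significantly associated
    with expression, as printed in study summaries (one decimal)."""
    if n_tested <= 0:
        return 0.0
    return round(100.0 * n_unique_significant / n_tested, 1)


def run_synthetic_pipeline(
    out_dir: str | Path,
    config: "SyntheticConfig | None" = None,
    run_overrides: dict | None = None,
) -> dict:
    """Generate a synthetic cohort, write it to disk, and run the full
    pipeline on the files — the one-command smoke path."""
    from .simulate import SyntheticConfig, generate_cohort

    out_dir = Path(out_dir)
    cohort = generate_cohort(config or SyntheticConfig())
    files = cohort.to_dir(out_dir / "inputs")
    overrides = run_overrides or {}
    run_cfg = RunConfig(
        expression_tumor=files["expression_tumor"],
        expression_normal=files["expression_normal"],
        genotypes=files["genotypes"],
        covariates=files["covariates"],
        pairs=files["pairs"],
        out_dir=str(out_dir / "results"),
        **overrides,
    )
    return run_pipeline(run_cfg)
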