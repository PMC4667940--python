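"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a paired tumor / non-tumor miRNA microarray study
nested in a case-control design:

* genotypes drawn independently per SNP at Hardy-Weinberg proportions for
  a minor allele frequency sampled from ``maf_range``;
* covariates: age ~ Normal(65, 9.5) truncated to [30, 79], sex (2 levels),
  study center, and a per-individual tumor site (proximal/distal) that also
  serves as the normalization stratum;
* latent log2 expression per miRNA and tissue:

      l = intercept + beta_g * g + delta_tumor * t + gamma_gxt * g * t
          + covariate terms + Normal(0, sigma)

  with ``t`` = 1 for tumor tissue; signal = max(2**l - offset, 0), and a
  hurdle process zeroes each measurement independently with probability
  ``pi_zero`` (zero-inflation is generated independently of the latent
  value so the generating effects stay interpretable);
* case/control status from a logistic model whose per-minor-allele odds
  ratio ``risk_or_per_allele`` acts on one designated causal SNP; the
  linear predictor is centered so roughly half the cohort are cases.

SNP ``i`` is paired with miRNA ``i``; ``beta_g``, ``gamma_gxt`` and
``risk_or_per_allele`` may be scalars (every pair) or per-pair sequences,
so a single planted signal among nulls is one array away. The generating
truth for every pair is recorded in ``SyntheticCohort.truth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_genotypes", "generate_cohort"]


@dataclass
class SyntheticConfig:
    """Generating parameters for a synthetic paired-tissue cohort."""

    n_individuals: int = 344
    n_snps: int = 20
    n_mirnas: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: log2-expression change per minor allele (scalar or per-pair sequence)
    beta_g: float | np.ndarray = 0.5
    #: log2 tumor shift common to all individuals
    delta_tumor: float = 1.0
    #: genotype x tumor interaction on the log2 scale (scalar or per-pair)
    gamma_gxt: float | np.ndarray = 0.0
    #: probability a measurement is zeroed by the hurdle process
    pi_zero: float = 0.2
    #: per-covariate log2 slopes on expression
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.005, "sex": 0.1, "center": 0.1, "site": 0.0}
    )
    #: odds ratio per minor allele of the causal SNP for case status
    risk_or_per_allele: float | np.ndarray = 1.3
    #: residual SD of log2 expression
    sigma: float = 1.0
    seed: int = 13
    centers: tuple[str, ...] = ("utah", "kaiser")
    #: index of the SNP driving case status (scalar risk_or) — ignored when
    #: risk_or_per_allele is a per-SNP sequence
    causal_snp: int = 0
    #: per-miRNA baseline log2 intercept range
    intercept_range: tuple[float, float] = (3.0, 10.0)
    signal_offset: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.pi_zero < 1.0:
            raise ValueError("pi_zero must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("n_individuals", "n_snps", "n_mirnas"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the truth table behind it."""

    genotypes: pd.DataFrame  # SNP x individual, Int64 codes
    covariates: pd.DataFrame  # individual x (age, sex, center, site)
    expression_tumor: pd.DataFrame  # miRNA x individual, signal scale
    expression_normal: pd.DataFrame
    status: pd.Series  # 1 case / 0 control
    pairs: pd.DataFrame  # snp_id, gene_labels, mirna_name
    truth: pd.DataFrame  # per-pair generating parameters
    config: SyntheticConfig

    def to_dir(self, path: str | Path) -> dict[str, str]:
        """Write the cohort in the pipeline's input formats; returns the
        file map."""
        from . import io as mio

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        files = {
            "expression_tumor": str(path / "expression_tumor.tsv"),
            "expression_normal": str(path / "expression_normal.tsv"),
            "genotypes": str(path / "genotypes.tsv"),
            "covariates": str(path / "covariates.tsv"),
            "pairs": str(path / "pairs.csv"),
            "truth": str(path / "truth.tsv"),
        }
        mio.write_expression(self.expression_tumor, files["expression_tumor"])
        mio.write_expression(self.expression_normal, files["expression_normal"])
        mio.write_genotypes(self.genotypes, files["genotypes"])
        cov = self.covariates.copy()
        cov["status"] = self.status
        mio.write_covariates(cov, files["covariates"])
        mio.write_pairs(self.pairs, files["pairs"])
        self.truth.to_csv(files["truth"], sep="\t", index=False)
        return files


def generate_genotypes(
    n: int, maf: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` additive genotype codes at Hardy-Weinberg proportions
    ((1-maf)^2, 2 maf (1-maf), maf^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    return rng.choice(3, size=n, p=p)


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw >= low) & (draw <= high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _per_pair(value, n_pairs: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_pairs, float(arr))
    if arr.shape != (n_pairs,):
        raise ValueError(f"{name} must be a scalar or length-{n_pairs} sequence")
    return arr


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``; bit-reproducible
    for a fixed seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    individuals = [f"S{i:04d}" for i in range(n)]
    snps = [f"rs{900000 + i}" for i in range(config.n_snps)]
    mirnas = [f"hsa-miR-{9000 + i}-5p" for i in range(config.n_mirnas)]

    # covariates
    age = _truncated_normal(rng, 65.0, 9.5, 30.0, 79.0, n)
    sex = rng.choice(["male", "female"], size=n)
    center = rng.choice(list(config.centers), size=n)
    site = rng.choice(["proximal", "distal"], size=n)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "center": center, "site": site},
        index=pd.Index(individuals, name="sample_id"),
    )

    # genotypes
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    G = np.vstack([generate_genotypes(n, maf, rng) for maf in mafs])
    genotypes = pd.DataFrame(G, index=pd.Index(snps, name="snp_id"), columns=individuals).astype(
        "Int64"
    )

    # pairs: snp_i <-> mirna_i
    n_pairs = min(config.n_snps, config.n_mirnas)
    beta_g = _per_pair(config.beta_g, n_pairs, "beta_g")
    gamma = _per_pair(config.gamma_gxt, n_pairs, "gamma_gxt")
    pairs = pd.DataFrame(
        {
            "snp_id": snps[:n_pairs],
            "gene_labels": [f"GENE{i}" for i in range(n_pairs)],
            "mirna_name": mirnas[:n_pairs],
        }
    )

    eff = config.covariate_effects
    cov_term = (
        eff.get("age", 0.0) * (age - age.mean())
        + eff.get("sex", 0.0) * (sex == "female").astype(float)
        + eff.get("center", 0.0) * (center != config.centers[0]).astype(float)
        + eff.get("site", 0.0) * (site == "distal").astype(float)
    )

    intercepts = rng.uniform(*config.intercept_range, size=config.n_mirnas)
    expr = {}
    for tissue, t_flag in (("normal", 0.0), ("tumor", 1.0)):
        latent = np.empty((config.n_mirnas, n))
        for j in range(config.n_mirnas):
            g_j = G[j].astype(float) if j < n_pairs else np.zeros(n)
            b_j = beta_g[j] if j < n_pairs else 0.0
            c_j = gamma[j] if j < n_pairs else 0.0
            latent[j] = (
                intercepts[j]
                + b_j * g_j
                + config.delta_tumor * t_flag
                + c_j * g_j * t_flag
                + cov_term
                + rng.normal(0.0, config.sigma, size=n)
            )
        signal = np.maximum(np.exp2(latent) - config.signal_offset, 0.0)
        zero_mask = rng.random(signal.shape) < config.pi_zero
        signal[zero_mask] = 0.0
        expr[tissue] = pd.DataFrame(
            signal, index=pd.Index(mirnas, name="mirna"), columns=individuals
        )

    # case/control status
    risk_or = _per_pair(config.risk_or_per_allele, config.n_snps, "risk_or_per_allele") \
        if np.ndim(config.risk_or_per_allele) else None
    if risk_or is None:
        log_or = np.zeros(config.n_snps)
        log_or[config.causal_snp] = np.log(float(config.risk_or_per_allele))
    else:
        log_or = np.log(risk_or)
    risk_cov = 0.02 * (age - age.mean()) + 0.1 * (sex == "female") + 0.1 * (
        center != config.centers[0]
    )
    lin = G.T.astype(float) @ log_or + risk_cov
    lin = lin - lin.mean()  # baseline set for a balanced case-control mix
    prob = 1.0 / (1.0 + np.exp(-lin))
    status = pd.Series(
        (rng.random(n) < prob).astype(int), index=covariates.index, name="status"
    )

    truth = pd.DataFrame(
        {
            "snp_id": snps[:n_pairs],
            "mirna_name": mirnas[:n_pairs],
            "maf": mafs[:n_pairs],
            "beta_g": beta_g,
            "gamma_gxt": gamma,
            "delta_tumor": config.delta_tumor,
            "risk_or_per_allele": np.exp(log_or[:n_pairs]),
            "pi_zero": config.pi_zero,
            "sigma": config.sigma,
        }
    )

    return SyntheticCohort(
        genotypes=genotypes,
        covariates=covariates,
        expression_tumor=expr["tumor"],
        expression_normal=expr["normal"],
        status=status,
        pairs=pairs,
        truth=truth,
        config=config,
    )
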