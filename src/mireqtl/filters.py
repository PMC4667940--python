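"""SNP-miRNA pair filtering cascade and the Hardy-Weinberg exact test.

After expansion of generic miRNA names, candidate pairs pass through four
ordered filters; each record that fails is attributed to the *first* stage
it fails, so per-stage drop counts plus survivors always sum to the input
count:

1. ``expressed_anywhere`` - the miRNA shows signal > 0 in at least one
   colon sample (either tissue by default; configurable to non-tumor only);
2. ``genotype_available`` - the SNP has genotype data for at least one
   individual (optionally also not on a pre-supplied QC exclusion list);
3. ``polymorphic`` - the SNP has at least ``min_minor_carriers``
   individuals carrying the minor allele and does not depart from
   Hardy-Weinberg equilibrium at ``hwe_alpha`` (exact test);
4. ``prevalent`` - the miRNA is expressed in at least
   ``min_expression_prevalence`` of non-tumor samples (default 5%).

The HWE test is the exact conditional test: given the observed allele
counts, every heterozygote count of the right parity is enumerated and the
two-sided p-value sums the probabilities of all configurations no more
likely than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterParams", "CascadeReport", "hwe_exact_test", "apply_cascade"]


@dataclass
class FilterParams:
    """Thresholds of the pair-filter cascade."""

    min_expression_prevalence: float = 0.05
    min_minor_carriers: int = 2
    hwe_alpha: float = 1e-4
    require_genotype: bool = True
    #: "expressed anywhere" uses both tissues when True, non-tumor only otherwise
    expression_any_tissue: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_expression_prevalence <= 1.0:
            raise ValueError("min_expression_prevalence must lie in [0, 1]")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must lie in (0, 1)")
        if self.min_minor_carriers < 0:
            raise ValueError("min_minor_carriers must be non-negative")


STAGES = ("expressed_anywhere", "genotype_available", "polymorphic", "prevalent")


@dataclass
class CascadeReport:
    """Ordered per-stage retention counts and per-record drop reasons."""

    stage_counts: list[tuple[str, int, int]]  # (stage, n_in, n_out)
    drops: pd.DataFrame  # columns: snp_id, mirna_name, stage, reason

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "n_in", "n_out"])

    def log_block(self) -> str:
        """Human-readable flow summary mirroring the study-flow diagram."""
        lines = []
        for stage, n_in, n_out in self.stage_counts:
            lines.append(f"{stage:>20s}: {n_in:5d} -> {n_out:5d}  (dropped {n_in - n_out})")
        return "\n".join(lines)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    ``n_aa``/``n_ab``/``n_bb`` are genotype counts (common homozygote,
    heterozygote, rare homozygote). Enumerates every heterozygote count
    compatible with the observed allele counts and sums the conditional
    probabilities that do not exceed that of the observed configuration.
    Monomorphic samples have a single attainable configuration and p = 1.
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped individual is required")
    # allele counts; work with the rarer allele
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0

    # log P(het = h | allele counts) up to a common constant:
    #   log n! - log n_hom_rare! - log n_hom_common! - log h! + h log 2
    # where hom_rare = (n_rare - h)/2, hom_common = n - h - hom_rare
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hs) // 2
    hom_common = n - hs - hom_rare
    logp = (
        hs * math.log(2.0)
        - _lgamma_arr(hs + 1)
        - _lgamma_arr(hom_rare + 1)
        - _lgamma_arr(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_ab
    p_obs = probs[hs == obs]
    if p_obs.size == 0:  # inconsistent het parity cannot occur with valid counts
        raise ValueError(f"genotype counts {counts} inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def minor_allele_carriers(g: pd.Series | np.ndarray) -> int:
    """Number of individuals carrying at least one copy of the minor allele.

    Codes count copies of the *coded* allele; if the coded allele is in
    fact the major one in this sample, carriers of the other allele are
    counted instead.
    """
    arr = pd.Series(g).dropna().astype(int).to_numpy()
    if arr.size == 0:
        return 0
    coded_copies = arr.sum()
    if coded_copies <= arr.size:  # coded allele is the minor allele
        return int((arr > 0).sum())
    return int((arr < 2).sum())


def genotype_counts(g: pd.Series | np.ndarray) -> tuple[int, int, int]:
    arr = pd.Series(g).dropna().astype(int).to_numpy()
    return int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum())


def apply_cascade(
    pairs: pd.DataFrame,
    expr_normal: pd.DataFrame,
    expr_tumor: pd.DataFrame,
    genotypes: pd.DataFrame,
    params: FilterParams | None = None,
    snp_exclusion_list: set[str] | None = None,
) -> tuple[pd.DataFrame, CascadeReport]:
    """Run the four-stage filter over an expanded pair catalog.

    ``expr_normal``/``expr_tumor`` are signal-scale matrices (miRNA x
    sample); ``genotypes`` is SNP x individual with nullable codes. The
    expression and genotype sample sets must overlap. Returns the
    surviving pairs and a :class:`CascadeReport`.
    """
    params = params or FilterParams()
    snp_exclusion_list = snp_exclusion_list or set()

    expr_samples = set(expr_normal.columns) | set(expr_tumor.columns)
    if not expr_samples & set(genotypes.columns):
        raise ValueError("expression and genotype sample sets are disjoint")

    # per-miRNA / per-SNP stage verdicts, computed once
    any_expr = (expr_normal > 0).any(axis=1)
    if params.expression_any_tissue:
        any_expr = any_expr | (expr_tumor > 0).any(axis=1).reindex(any_expr.index, fill_value=False)
    prevalence = (expr_normal > 0).mean(axis=1)

    def expressed_anywhere(mirna: str) -> bool:
        return bool(any_expr.get(mirna, False))

    def genotype_available(snp: str) -> bool:
        if not params.require_genotype:
            return True
        if snp in snp_exclusion_list:
            return False
        return snp in genotypes.index and genotypes.loc[snp].notna().any()

    def polymorphic(snp: str) -> bool:
        if snp not in genotypes.index or genotypes.loc[snp].notna().sum() == 0:
            return True  # no genotype data to test (require_genotype=False path)
        g = genotypes.loc[snp]
        if minor_allele_carriers(g) < params.min_minor_carriers:
            return False
        return hwe_exact_test(*genotype_counts(g)) >= params.hwe_alpha

    def prevalent(mirna: str) -> bool:
        return bool(prevalence.get(mirna, 0.0) >= params.min_expression_prevalence)

    current = pairs.reset_index(drop=True)
    stage_counts: list[tuple[str, int, int]] = []
    drop_records: list[dict] = []

    checks = {
        "expressed_anywhere": lambda row: expressed_anywhere(row["mirna_name"]),
        "genotype_available": lambda row: genotype_available(row["snp_id"]),
        "polymorphic": lambda row: polymorphic(row["snp_id"]),
        "prevalent": lambda row: prevalent(row["mirna_name"]),
    }
    reasons = {
        "expressed_anywhere": "miRNA not expressed in any colon sample",
        "genotype_available": "SNP lacks genotype data",
        "polymorphic": "SNP monomorphic/under-polymorphic or fails HWE",
        "prevalent": "miRNA below non-tumor expression prevalence threshold",
    }
    for stage in STAGES:
        if stage == "genotype_available" and not params.require_genotype:
            stage_counts.append((stage, len(current), len(current)))
            continue
        keep = current.apply(checks[stage], axis=1) if len(current) else pd.Series(dtype=bool)
        n_in = len(current)
        dropped = current[~keep] if n_in else current
        for _, row in dropped.iterrows():
            drop_records.append(
                {"snp_id": row["snp_id"], "mirna_name": row["mirna_name"],
                 "stage": stage, "reason": reasons[stage]}
            )
        current = current[keep].reset_index(drop=True) if n_in else current
        stage_counts.append((stage, n_in, len(current)))

    drops = pd.DataFrame(drop_records, columns=["snp_id", "mirna_name", "stage", "reason"])
    report = CascadeReport(stage_counts=stage_counts, drops=drops)
    return current, report
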