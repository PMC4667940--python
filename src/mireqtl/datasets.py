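"""Worked-example inputs: printed summary tables from a published
colon-cancer case-control study of miRNA-related SNPs.

These are *inputs*, not fixtures: the study released per-genotype
case/control counts and per-analysis lists of significant SNPs in its
printed tables, and the worked examples recompute crude odds ratios and
the significant-SNP fraction from them. Individual-level data were never
deposited, so these printed tallies are the only public anchor for the
risk arithmetic.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "casecontrol_counts",
    "significant_snps_nontumor",
    "significant_snps_differential",
    "N_PAIRS_TESTED",
]

#: pairs evaluated in the study's final analysis stage
N_PAIRS_TESTED = 327

# per-genotype case/control counts for the three SNPs the study reported
# as risk-associated; columns follow the 0/1/2 additive coding with 0 the
# common homozygote referent
_COUNTS = [
    # snp, controls_0, cases_0, controls_1, cases_1, controls_2, cases_2
    ("rs8176318", 560, 484, 504, 504, 109, 127),  # BRCA1 3' UTR
    ("rs276466", 720, 642, 385, 419, 68, 54),  # IL22RA2 3' UTR
    ("rs8905", 928, 836, 234, 256, 11, 23),  # PRKAR1A 3' UTR
]


def casecontrol_counts() -> pd.DataFrame:
    """Printed genotype-class case/control counts (one row per SNP)."""
    return pd.DataFrame(
        _COUNTS,
        columns=[
            "snp_id",
            "controls_0", "cases_0",
            "controls_1", "cases_1",
            "controls_2", "cases_2",
        ],
    ).set_index("snp_id")


# SNPs the study reported as raw-significant (p < 0.05) in each analysis;
# two SNPs (rs1057560, rs2910164) were significant in both
_NONTUMOR = [
    "rs10406069", "rs1053047", "rs1053667", "rs12232826", "rs1378940",
    "rs1527423", "rs1559931", "rs16848494", "rs17703261", "rs17797090",
    "rs1943676", "rs4404254", "rs720607", "rs7628626", "rs7683093",
    "rs7911488", "rs8176318", "rs8679", "rs9874", "rs999885",
    "rs1057560", "rs2910164",
]
_DIFFERENTIAL = [
    "rs10508445", "rs1062707", "rs11068503", "rs1332793", "rs13505",
    "rs17281995", "rs2043556", "rs2228043", "rs2270841", "rs2288024",
    "rs2298209", "rs2344843", "rs2693737", "rs276466", "rs2909339",
    "rs353292", "rs353293", "rs8905", "rs9304994",
    "rs1057560", "rs2910164",
]


def significant_snps_nontumor() -> list[str]:
    """SNPs significantly associated with non-tumor expression (raw p)."""
    return list(_NONTUMOR)


def significant_snps_differential() -> list[str]:
    """SNPs significantly associated with tumor/non-tumor differential
    expression (raw p)."""
    return list(_DIFFERENTIAL)
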