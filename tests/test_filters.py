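import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mireqtl.filters import (
    CascadeReport,
    FilterParams,
    apply_cascade,
    genotype_counts,
    hwe_exact_test,
    minor_allele_carriers,
)


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration of the conditional het-count
    distribution; independent of the implementation under test."""
    n = n_aa + n_ab + n_bb
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n_rare == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hr = (n_rare - h) // 2
        hc = n - h - hr
        num = (
            Fraction(math.factorial(n), math.factorial(hr) * math.factorial(hc) * math.factorial(h))
            * 2**h
        )
        return Fraction(num, math.comb(2 * n, n_rare))

    probs = {h: prob(h) for h in range(n_rare % 2, n_rare + 1, 2)}
    p_obs = probs[n_ab]
    return float(sum(v for v in probs.values() if v <= p_obs))


@pytest.mark.parametrize("counts", [(0, 0, 50), (50, 0, 0), (1, 0, 0)])
def test_hwe_monomorphic_p_one(counts):
    assert hwe_exact_test(*counts) == 1.0


def test_hwe_matches_enumeration_oracle():
    cases = [(25, 50, 25), (10, 5, 10), (30, 40, 5), (3, 1, 3), (0, 2, 0), (57, 14, 1)]
    for c in cases:
        assert hwe_exact_test(*c) == pytest.approx(hwe_oracle(*c), rel=1e-9)


def test_hwe_extreme_het_deficit_excluded():
    p = hwe_exact_test(50, 0, 50)
    assert p < 1e-4
    assert p == pytest.approx(hwe_oracle(50, 0, 50), rel=1e-9)


def test_hwe_rejects_bad_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    n_aa=st.integers(min_value=0, max_value=40),
    n_ab=st.integers(min_value=0, max_value=40),
    n_bb=st.integers(min_value=0, max_value=40),
)
def test_hwe_property_valid_probability_and_oracle(n_aa, n_ab, n_bb):
    if n_aa + n_ab + n_bb == 0:
        return
    p = hwe_exact_test(n_aa, n_ab, n_bb)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(hwe_oracle(n_aa, n_ab, n_bb), rel=1e-9)


def test_minor_allele_carriers_handles_flipped_coding():
    assert minor_allele_carriers(np.array([0, 0, 1, 2])) == 2
    # coded allele is the major one: minor carriers are those NOT homozygote-coded
    assert minor_allele_carriers(np.array([2, 2, 2, 1, 0])) == 2
    assert genotype_counts(np.array([0, 1, 1, 2])) == (1, 2, 1)


# ---------------------------------------------------------------------------
# cascade


def _planted_fixture():
    """20 pairs with disjoint planted per-stage failures:
    4 unexpressed anywhere, 3 missing genotypes, 2 monomorphic,
    5 below 5% non-tumor prevalence -> 20 -> 16 -> 13 -> 11 -> 6."""
    rng = np.random.default_rng(77)
    n = 60
    samples = [f"S{i}" for i in range(n)]
    mirnas = [f"hsa-miR-{100 + i}-5p" for i in range(20)]
    snps = [f"rs{i}" for i in range(20)]
    pairs = pd.DataFrame({"snp_id": snps, "gene_labels": "", "mirna_name": mirnas})

    expr_n = pd.DataFrame(
        rng.uniform(1, 100, size=(20, n)), index=mirnas, columns=samples
    )
    expr_t = pd.DataFrame(
        rng.uniform(1, 100, size=(20, n)), index=mirnas, columns=samples
    )
    # stage 1: miRNAs 0-3 silent everywhere
    expr_n.iloc[0:4] = 0.0
    expr_t.iloc[0:4] = 0.0
    # stage 4: miRNAs 4-8 expressed in tumor but in <5% of non-tumor samples
    expr_n.iloc[4:9] = 0.0
    expr_n.iloc[4:9, 0] = 50.0  # 1/60 ~ 1.7% < 5%

    geno = pd.DataFrame(
        rng.choice([0, 1, 2], p=[0.5, 0.4, 0.1], size=(20, n)),
        index=snps, columns=samples,
    ).astype("Int64")
    # stage 2: SNPs 9-11 lack genotype data entirely
    geno = geno.drop(index=[f"rs{i}" for i in (9, 10, 11)])
    # stage 3: SNPs 12-13 monomorphic
    geno.loc["rs12"] = 0
    geno.loc["rs13"] = 0
    return pairs, expr_n, expr_t, geno


def test_cascade_counts_match_planted_fixture():
    pairs, expr_n, expr_t, geno = _planted_fixture()
    retained, report = apply_cascade(pairs, expr_n, expr_t, geno, FilterParams())
    flow = [(s, i, o) for s, i, o in report.stage_counts]
    assert flow == [
        ("expressed_anywhere", 20, 16),
        ("genotype_available", 16, 13),
        ("polymorphic", 13, 11),
        ("prevalent", 11, 6),
    ]
    assert len(retained) == 6


def test_cascade_independent_per_record_audit():
    """Each record's fate re-derived from scratch, without the cascade."""
    pairs, expr_n, expr_t, geno = _planted_fixture()
    params = FilterParams()
    retained, report = apply_cascade(pairs, expr_n, expr_t, geno, params)

    audited_stage = {}
    for _, row in pairs.iterrows():
        snp, mir = row["snp_id"], row["mirna_name"]
        expressed = (expr_n.loc[mir] > 0).any() or (expr_t.loc[mir] > 0).any()
        has_geno = snp in geno.index and geno.loc[snp].notna().any()
        if has_geno:
            g = geno.loc[snp].dropna().astype(int).to_numpy()
            carriers = min((g > 0).sum(), (g < 2).sum())
            poly = carriers >= params.min_minor_carriers and hwe_oracle(
                int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
            ) >= params.hwe_alpha
        else:
            poly = True
        prevalent = (expr_n.loc[mir] > 0).mean() >= params.min_expression_prevalence
        if not expressed:
            audited_stage[(snp, mir)] = "expressed_anywhere"
        elif not has_geno:
            audited_stage[(snp, mir)] = "genotype_available"
        elif not poly:
            audited_stage[(snp, mir)] = "polymorphic"
        elif not prevalent:
            audited_stage[(snp, mir)] = "prevalent"

    reported = {
        (r["snp_id"], r["mirna_name"]): r["stage"] for _, r in report.drops.iterrows()
    }
    assert reported == audited_stage
    assert len(report.drops) + len(retained) == len(pairs)
    # exactly one recorded reason per dropped record
    assert not report.drops.duplicated(subset=["snp_id", "mirna_name"]).any()


def test_cascade_identity_with_degenerate_thresholds():
    pairs, expr_n, expr_t, geno = _planted_fixture()
    # restore complete data
    rng = np.random.default_rng(5)
    expr_n.iloc[:, :] = rng.uniform(1, 10, expr_n.shape)
    expr_t.iloc[:, :] = rng.uniform(1, 10, expr_t.shape)
    geno = pd.DataFrame(
        rng.choice([0, 1, 2], p=[0.5, 0.4, 0.1], size=(20, expr_n.shape[1])),
        index=pairs["snp_id"], columns=expr_n.columns,
    ).astype("Int64")
    params = FilterParams(
        min_expression_prevalence=0.0, min_minor_carriers=0, hwe_alpha=1e-300
    )
    retained, report = apply_cascade(pairs, expr_n, expr_t, geno, params)
    assert len(retained) == len(pairs)
    assert all(n_in == n_out for _, n_in, n_out in report.stage_counts)


def test_first_failure_attribution():
    """A record failing both the expression and the prevalence stage is
    attributed to the first."""
    pairs, expr_n, expr_t, geno = _planted_fixture()
    _, report = apply_cascade(pairs, expr_n, expr_t, geno, FilterParams())
    # miRNAs 0-3 fail stage 1 (silent everywhere) and would also fail
    # stage 4 (zero non-tumor prevalence)
    for i in range(4):
        stage = report.drops.loc[
            report.drops["mirna_name"] == f"hsa-miR-{100 + i}-5p", "stage"
        ]
        assert list(stage) == ["expressed_anywhere"]


def test_cascade_deterministic():
    pairs, expr_n, expr_t, geno = _planted_fixture()
    r1 = apply_cascade(pairs, expr_n, expr_t, geno, FilterParams())
    r2 = apply_cascade(pairs, expr_n, expr_t, geno, FilterParams())
    pd.testing.assert_frame_equal(r1[0], r2[0])
    assert r1[1].stage_counts == r2[1].stage_counts
    pd.testing.assert_frame_equal(r1[1].drops, r2[1].drops)


def test_disjoint_sample_sets_error():
    pairs, expr_n, expr_t, geno = _planted_fixture()
    geno.columns = [f"X{i}" for i in range(geno.shape[1])]
    with pytest.raises(ValueError, match="disjoint"):
        apply_cascade(pairs, expr_n, expr_t, geno, FilterParams())


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FilterParams(min_expression_prevalence=1.5)
    with pytest.raises(ValueError):
        FilterParams(hwe_alpha=0.0)


def test_report_serialization_roundtrip(tmp_path):
    pairs, expr_n, expr_t, geno = _planted_fixture()
    _, report = apply_cascade(pairs, expr_n, expr_t, geno, FilterParams())
    frame = report.to_frame()
    assert list(frame.columns) == ["stage", "n_in", "n_out"]
    assert "expressed_anywhere" in report.log_block()
    assert isinstance(report, CascadeReport)
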