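"""Stratified 75th-percentile scaling normalization and log2 transform.

Microarray signal levels differ between samples for purely technical
reasons (array, RNA input, spatial position). The normalization used here
rescales every sample so that, within its stratum (tumor site by default),
its 75th signal percentile equals the stratum's median of pre-scaling 75th
percentiles:

    factor_j = median_{k in stratum(j)}( q75_k ) / q75_j

Scaled values are ``signal_j * factor_j``. The operation is idempotent and
scale-equivariant within a stratum. Percentiles use linear interpolation
between order statistics. Downstream tests run on ``log2(signal + offset)``
with a configurable offset (default 1.0) so zero-signal measurements stay
finite; descriptive means are reported on the normalized, non-log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "compute_scaling_factors",
    "apply_normalization",
    "normalize",
    "log2_transform",
    "expression_prevalence",
    "normalization_report",
]

QUANTILE = 0.75


@dataclass
class NormalizedMatrix:
    """A normalized miRNA x sample signal matrix with its provenance."""

    values: pd.DataFrame
    scaling_factors: pd.Series
    strata: pd.Series
    log2_offset: float = 1.0
    quantile: float = QUANTILE
    _extras: dict = field(default_factory=dict, repr=False)


def _q75(matrix: pd.DataFrame, quantile: float) -> pd.Series:
    return matrix.quantile(quantile, axis=0, interpolation="linear")


def compute_scaling_factors(
    signal: pd.DataFrame, strata: pd.Series, quantile: float = QUANTILE
) -> pd.Series:
    """Per-sample multipliers: stratum median of 75th percentiles over the
    sample's own 75th percentile."""
    missing = [s for s in signal.columns if s not in strata.index]
    if missing:
        raise ValueError(f"samples without a stratum label: {missing}")
    strata = strata.reindex(signal.columns)
    q = _q75(signal, quantile)
    zero = q.index[q <= 0].tolist()
    if zero:
        raise ValueError(
            f"cannot normalize: sample(s) {zero} have a {quantile:.0%} percentile of 0"
        )
    medians = q.groupby(strata).transform("median")
    factors = medians / q
    factors.name = "scaling_factor"
    return factors


def apply_normalization(
    signal: pd.DataFrame,
    factors: pd.Series,
    strata: pd.Series | None = None,
    log2_offset: float = 1.0,
    quantile: float = QUANTILE,
) -> NormalizedMatrix:
    """Multiply each sample (column) by its scaling factor."""
    sig_set, fac_set = set(signal.columns), set(factors.index)
    if sig_set != fac_set:
        raise ValueError(
            "factor/sample mismatch: "
            f"missing factors for {sorted(sig_set - fac_set)}, "
            f"extra factors for {sorted(fac_set - sig_set)}"
        )
    if (factors <= 0).any():
        bad = factors.index[factors <= 0].tolist()
        raise ValueError(f"non-positive scaling factors for samples {bad}")
    factors = factors.reindex(signal.columns)
    if strata is None:
        strata = pd.Series("all", index=signal.columns)
    values = signal * factors
    return NormalizedMatrix(
        values=values,
        scaling_factors=factors,
        strata=strata.reindex(signal.columns),
        log2_offset=log2_offset,
        quantile=quantile,
    )


def normalize(
    signal: pd.DataFrame,
    strata: pd.Series | None = None,
    log2_offset: float = 1.0,
    quantile: float = QUANTILE,
) -> NormalizedMatrix:
    """Convenience: compute factors and apply them in one call."""
    if strata is None:
        strata = pd.Series("all", index=signal.columns)
    factors = compute_scaling_factors(signal, strata, quantile)
    return apply_normalization(signal, factors, strata, log2_offset, quantile)


def log2_transform(matrix: NormalizedMatrix | pd.DataFrame, offset: float | None = None) -> pd.DataFrame:
    """``log2(signal + offset)``; the offset must be positive when zeros
    are present."""
    if isinstance(matrix, NormalizedMatrix):
        values = matrix.values
        offset = matrix.log2_offset if offset is None else offset
    else:
        values = matrix
        offset = 1.0 if offset is None else offset
    if offset < 0:
        raise ValueError("log2 offset must be non-negative")
    if offset == 0 and (values <= 0).any().any():
        raise ValueError("zero/negative signal values require a positive log2 offset")
    return np.log2(values + offset)


def expression_prevalence(values: pd.DataFrame | NormalizedMatrix) -> pd.Series:
    """Per-miRNA proportion of samples with signal > 0.

    ``1 - prevalence`` is the '% zero expression' descriptor reported in
    result tables.
    """
    if isinstance(values, NormalizedMatrix):
        values = values.values
    prev = (values > 0).mean(axis=1)
    prev.name = "prevalence"
    return prev


def normalization_report(before: pd.DataFrame, norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-sample TSV-ready report: stratum, q75 before/after, factor."""
    q_before = _q75(before, norm.quantile)
    q_after = _q75(norm.values, norm.quantile)
    return pd.DataFrame(
        {
            "stratum": norm.strata,
            "q75_before": q_before,
            "q75_after": q_after,
            "scaling_factor": norm.scaling_factors,
        }
    ).rename_axis("sample")
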