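"""Case-control risk models: crude 2x2 odds ratios and genotype-class
logistic regression.

Genotypes are coded as two indicators (heterozygote, rare homozygote)
against the common-homozygote referent, the standard codominant
parameterisation of case-control genotype tables. Adjusted odds ratios and
Wald 95% confidence intervals come from a binomial GLM fit by iteratively
reweighted least squares (IRLS), adjusting for age (continuous, years),
sex, and study center (unordered factor). A per-allele trend model (the
additive code entered as a single numeric term) is available as an
alternative.

The crude odds ratio from a 2x2 table uses the Woolf (log) interval,
exp(log OR +/- 1.96 * sqrt(sum of reciprocal cells)), with the
Haldane-Anscombe +0.5 continuity correction when any cell is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CrudeOR", "RiskResult", "crude_or", "fit_logistic"]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class CrudeOR:
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied
    undefined: bool = False  # a comparison group had no observations at all


@dataclass
class RiskResult:
    """Genotype-class odds ratios for one SNP."""

    snp_id: str
    counts: pd.DataFrame  # index genotype 0/1/2, columns controls/cases
    or_het: float
    ci_het: tuple[float, float]
    or_hom: float
    ci_hom: tuple[float, float]
    crude_het: CrudeOR | None = None
    crude_hom: CrudeOR | None = None
    separation: bool = False
    deviance_history: list[float] = field(default_factory=list)
    converged: bool = True
    n: int = 0


def crude_or(
    controls_ref: int, cases_ref: int, controls_alt: int, cases_alt: int
) -> CrudeOR:
    """Crude odds ratio of the alternative group vs the referent with a
    Woolf 95% CI."""
    cells = [controls_ref, cases_ref, controls_alt, cases_alt]
    if any(c < 0 for c in cells):
        raise ValueError(f"negative cell count in {cells}")
    if (controls_alt == 0 and cases_alt == 0) or (controls_ref == 0 and cases_ref == 0):
        return CrudeOR(np.nan, np.nan, np.nan, undefined=True)
    corrected = any(c == 0 for c in cells)
    a = np.array(cells, dtype=float)
    if corrected:
        a = a + 0.5
    c_ref, k_ref, c_alt, k_alt = a
    or_ = (k_alt * c_ref) / (c_alt * k_ref)
    se = np.sqrt((1.0 / a).sum())
    log_or = np.log(or_)
    return CrudeOR(
        or_=float(or_),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        corrected=corrected,
    )


def _genotype_indicators(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (g == 1).astype(float), (g == 2).astype(float)


def fit_logistic(
    status: np.ndarray | pd.Series,
    g: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "",
    model: str = "indicator",
    tol: float = 1e-8,
    maxiter: int = 50,
) -> RiskResult:
    """Genotype-class logistic regression for case/control status.

    ``model='indicator'`` fits heterozygote and rare-homozygote indicators
    against the common-homozygote referent; ``model='trend'`` fits the
    additive 0/1/2 code as a single term (its OR reported under
    ``or_het``). Individuals with missing genotype are dropped. Complete
    separation is flagged and the affected CI suppressed.
    """
    status_arr = np.asarray(pd.Series(status, dtype="float64"), dtype=float)
    g_arr = np.asarray(pd.Series(g, dtype="float64"), dtype=float)
    ok = ~(np.isnan(status_arr) | np.isnan(g_arr))
    status_arr, g_arr = status_arr[ok], g_arr[ok]
    cov = covariates.iloc[ok] if covariates is not None else None
    if set(np.unique(status_arr)) - {0.0, 1.0}:
        raise ValueError("status must be coded 0 (control) / 1 (case)")
    if np.unique(status_arr).size < 2:
        raise ValueError("both cases and controls are required")

    counts = pd.DataFrame(
        {
            "controls": [int(((g_arr == c) & (status_arr == 0)).sum()) for c in (0, 1, 2)],
            "cases": [int(((g_arr == c) & (status_arr == 1)).sum()) for c in (0, 1, 2)],
        },
        index=pd.Index([0, 1, 2], name="genotype"),
    )

    cols = [np.ones_like(g_arr)]
    names = ["intercept"]
    if model == "trend":
        cols.append(g_arr)
        names.append("genotype")
        term_idx = {"het": 1, "hom": None}
    elif model == "indicator":
        het, hom = _genotype_indicators(g_arr)
        term_idx = {}
        if het.sum() > 0:
            cols.append(het)
            names.append("het")
            term_idx["het"] = len(cols) - 1
        else:
            term_idx["het"] = None
        if hom.sum() > 0:
            cols.append(hom)
            names.append("hom")
            term_idx["hom"] = len(cols) - 1
        else:
            term_idx["hom"] = None
    else:
        raise ValueError("model must be 'indicator' or 'trend'")

    if cov is not None and len(cov.columns):
        enc = pd.get_dummies(cov, drop_first=True, dtype=float)
        for c in enc.columns:
            cols.append(enc[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is not full rank; check covariate coding")

    params, bse, mu, dev_history, converged = _irls_logistic(X, status_arr, tol, maxiter)

    separation = bool(
        np.abs(params).max() > 15.0 or np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10)
    )

    def term(key: str) -> tuple[float, tuple[float, float]]:
        j = term_idx.get(key)
        if j is None:
            return np.nan, (np.nan, np.nan)
        beta = float(params[j])
        se = float(bse[j])
        if separation:
            return float(np.exp(beta)), (np.nan, np.nan)
        # cap the exponent: an absurd SE (near-empty class) yields an inf
        # bound without overflow noise
        return float(np.exp(beta)), (
            float(np.exp(min(beta - _Z95 * se, 700.0))),
            float(np.exp(min(beta + _Z95 * se, 700.0))),
        )

    or_het, ci_het = term("het")
    or_hom, ci_hom = term("hom")

    crude_het = crude_hom = None
    if model == "indicator":
        crude_het = crude_or(
            counts.loc[0, "controls"], counts.loc[0, "cases"],
            counts.loc[1, "controls"], counts.loc[1, "cases"],
        )
        crude_hom = crude_or(
            counts.loc[0, "controls"], counts.loc[0, "cases"],
            counts.loc[2, "controls"], counts.loc[2, "cases"],
        )

    return RiskResult(
        snp_id=snp_id,
        counts=counts,
        or_het=or_het,
        ci_het=ci_het,
        or_hom=or_hom,
        ci_hom=ci_hom,
        crude_het=crude_het,
        crude_hom=crude_hom,
        separation=separation,
        deviance_history=dev_history,
        converged=converged,
        n=int(len(status_arr)),
    )


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # Bernoulli log-likelihood in the numerically stable logit form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, tol: float, maxiter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Logistic maximum likelihood by iteratively reweighted least squares.

    Newton steps with step-halving whenever a full step would increase the
    deviance, so the recorded deviance trace is non-increasing. Converges
    when the relative change in log-likelihood drops below ``tol``.
    Returns (params, Wald SEs, fitted probabilities, deviance history,
    converged flag).
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(y, eta)
    deviances = [-2.0 * ll]
    converged = False
    for _ in range(maxiter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        # working response z = eta + (y - mu) / w; solve weighted LS
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.pinv(xtw @ X) @ (xtw @ z)
        step = beta_new - beta
        scale = 1.0
        ll_new = _log_likelihood(y, X @ (beta + scale * step))
        halvings = 0
        while ll_new < ll and halvings < 30:
            scale *= 0.5
            halvings += 1
            ll_new = _log_likelihood(y, X @ (beta + scale * step))
        beta = beta + scale * step
        eta = X @ beta
        deviances.append(-2.0 * ll_new)
        rel_change = abs(ll_new - ll) / (abs(ll) + 1e-300)
        ll = ll_new
        if rel_change < tol:
            converged = True
            break
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, bse, mu, deviances, converged
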