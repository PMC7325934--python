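"""Negative-binomial differential abundance between contamination levels.

The test asks, per feature, whether mean abundance differs across groups
(reference vs low/medium/high contamination): counts are TMM-normalized,
a common NB dispersion is estimated by method of moments across features,
and a likelihood-ratio test compares the group-means model against the
intercept-only model, with p from a chi-square on (groups - 1) degrees of
freedom.  P-values are Benjamini-Hochberg adjusted and flagged at FDR
0.05.  Log2 fold-changes are reported for each non-reference group
relative to the reference, on normalized group means with pseudocount 0.5.

This is an independent NB-LRT implementation with a single common
dispersion, not an empirical-Bayes tagwise-shrinkage fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialResult",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_fit_and_test",
    "bh_fdr",
]


def tmm_factors(
    table: pd.DataFrame,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors per sample.

    The reference sample is the column whose upper-quartile fraction is
    closest to the mean upper-quartile fraction; M (log ratio) and A
    (average log expression) values over features positive in both samples
    are doubly trimmed and combined by precision weights.  Factors are
    rescaled to multiply to 1 in geometric mean.
    """
    y = table.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    uq = np.array([np.quantile(col[col > 0], 0.75) for col in y.T]) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = y[:, ref_idx]
    nref = lib[ref_idx]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_idx:
            continue
        obs = y[:, j]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            continue
        o, r = obs[keep], ref[keep]
        m = np.log2((o / lib[j]) / (r / nref))
        a = 0.5 * np.log2((o / lib[j]) * (r / nref))
        w = (lib[j] - o) / (lib[j] * o) + (nref - r) / (nref * r)
        if np.allclose(m, m[0], atol=1e-10):
            factors[j] = 2 ** m[0]
            continue
        m_lo, m_hi = np.quantile(m, [log_ratio_trim, 1 - log_ratio_trim])
        a_lo, a_hi = np.quantile(a, [abs_expr_trim, 1 - abs_expr_trim])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not sel.any():
            sel = np.ones_like(m, dtype=bool)
        factors[j] = 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.columns, name="tmm_factor")


def _normalized_counts(table: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    lib = table.sum(axis=0)
    eff = lib * factors
    return table / eff * eff.mean()


def estimate_common_dispersion(normalized: pd.DataFrame) -> float:
    """Method-of-moments common NB dispersion across features.

    Per feature, ``phi = (var - mean) / mean^2``; the common value is the
    median over features with positive mean, floored at 1e-8.
    """
    z = normalized.to_numpy(dtype=float)
    mu = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    ok = mu > 0
    phi = (v[ok] - mu[ok]) / mu[ok] ** 2
    if phi.size == 0:
        return 1e-8
    return float(max(np.median(phi), 1e-8))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB2 log-likelihood per feature row, gamma-extended to non-integer y."""
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-10)
    return np.sum(
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=1,
    )


def nb_fit_and_test(
    table: pd.DataFrame,
    groups: pd.Series,
    reference_level: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature NB likelihood-ratio test across groups, with BH-FDR.

    ``groups`` maps sample id to group label.  Returns a DataFrame with one
    row per feature: per-contrast log2 fold-change (each non-reference
    group vs the reference), the LRT p-value, BH-adjusted p-value and a
    significance flag at ``alpha``.
    """
    groups = groups.loc[table.columns]
    labels = groups.unique().tolist()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if reference_level is None:
        reference_level = "reference" if "reference" in labels else labels[0]
    if reference_level not in labels:
        raise ValueError(f"unknown reference level {reference_level!r}")

    factors = tmm_factors(table)
    norm = _normalized_counts(table, factors)
    phi = estimate_common_dispersion(norm)

    z = norm.to_numpy(dtype=float)
    nonzero = z.sum(axis=1) > 0
    grand = z.mean(axis=1, keepdims=True)
    mu_null = np.broadcast_to(grand, z.shape)
    mu_alt = np.empty_like(z)
    group_means: dict[str, np.ndarray] = {}
    for g in labels:
        cols = np.asarray(groups == g)
        gm = z[:, cols].mean(axis=1)
        group_means[g] = gm
        mu_alt[:, cols] = gm[:, None]

    lr = 2.0 * (_nb_loglik(z, mu_alt, phi) - _nb_loglik(z, mu_null, phi))
    lr = np.maximum(lr, 0.0)
    pvals = chi2.sf(lr, df=len(labels) - 1)
    pvals[~nonzero] = 1.0

    out = pd.DataFrame(index=table.index)
    for g in labels:
        if g == reference_level:
            continue
        lfc = np.log2((group_means[g] + 0.5) / (group_means[reference_level] + 0.5))
        lfc[~nonzero] = 0.0
        out[f"log2fc_{g}_vs_{reference_level}"] = lfc
    out["p_value"] = pvals
    out["fdr"] = bh_fdr(pvals)
    out["significant"] = out["fdr"] <= alpha
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
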