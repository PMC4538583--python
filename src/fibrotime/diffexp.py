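"""Consensus negative-binomial exact differential-expression testing.

A gene is called differentially expressed between two PD groups only when two
flavors of an NB exact test agree: one using a single *common* dispersion for
all genes, one using a *trended* per-gene dispersion.  Requiring agreement of
two differently-parameterized tests mirrors the practice of intersecting the
calls of two independent count-based DE methods.

The exact test conditions on the total count of both groups after scaling the
samples to a common depth.  Writing K_A and K_B for the group sums on that
common scale, K_g is modelled as the sum of m_g i.i.d. NB variables with mean
``mu`` and variance ``mu + alpha mu^2``, i.e. NB with mean ``m_g mu`` and
variance ``m_g mu + alpha (m_g mu)^2 / m_g``.  The two-sided p-value is the
total conditional probability of all splits (a, T - a) of T = K_A + K_B that
are no more probable than the observed one:

    p = sum_{Pr(a) <= Pr(obs)} Pr(a) / sum_a Pr(a)

At ``alpha = 0`` this reduces to the conditional binomial (Poisson) exact
test.  DEG calls: *standard* requires FDR < 0.05 under both flavors;
*strict* requires FDR < 0.01 under both flavors and |log2FC| > 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

#: conditional totals above this are enumerated only within +/- 8 conditional
#: SDs of the mode (and around the observed split); truncation error < 1e-8
ENUMERATION_CUTOFF = 5000
_TIE_RTOL = 1e-12


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed on all-positive genes only).

    s_j = median_i k_ij / geomean_i over genes with positive counts in every
    sample; reported unnormalized.
    """
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in every sample")
    logc = np.log(counts.loc[pos].to_numpy(dtype=float))
    log_ratio = logc - logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratio, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclasses.dataclass
class DispersionModel:
    """Per-gene NB dispersions under one of two flavors.

    ``common``: every gene shares the median of the positive per-gene
    method-of-moments estimates.  ``trended``: a least-squares fit of the MoM
    estimates against 1/mean, floored per gene at its own MoM estimate.
    """

    flavor: str
    per_gene: pd.Series
    alpha_common: float | None = None
    trend_coef: tuple | None = None

    def alpha_for(self, gene) -> float:
        return float(self.per_gene.loc[gene])


def _mom_dispersion(counts: pd.DataFrame, sf: pd.Series, groups) -> tuple:
    """Per-gene MoM dispersion on normalized counts.

    Uses the grand mean and the pooled within-group variance, so group mean
    differences do not inflate the estimate.
    """
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    ss = np.zeros(norm.shape[0])
    dof = 0
    for lab in labels:
        cols = norm[:, groups == lab]
        if cols.shape[1] < 2:
            raise ValueError("dispersion estimation needs >= 2 replicates per group")
        ss += cols.shape[1] * np.var(cols, axis=1, ddof=0)
        dof += cols.shape[1] - 1
    var = ss / dof
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(mean > 0, (var - mean) / np.square(mean), 0.0)
    return np.maximum(mom, 0.0), mean


def estimate_dispersion(
    counts: pd.DataFrame, sf: pd.Series, flavor: str, groups=None
) -> DispersionModel:
    """Estimate NB dispersions, flavor ``common`` or ``trended``."""
    if flavor not in ("common", "trended"):
        raise ValueError(f"unknown dispersion flavor {flavor!r}")
    if groups is None:
        groups = np.zeros(counts.shape[1], dtype=int)
        if counts.shape[1] < 2:
            raise ValueError("dispersion estimation needs >= 2 replicates")
    mom, mean = _mom_dispersion(counts, sf, groups)
    if flavor == "common":
        positive = mom[mom > 0]
        alpha = float(np.median(positive)) if positive.size else 0.0
        per_gene = pd.Series(alpha, index=counts.index)
        return DispersionModel(flavor="common", per_gene=per_gene, alpha_common=alpha)
    # trended: least squares of MoM against 1/mean, per-gene floored at MoM
    ok = mean > 0
    x = 1.0 / mean[ok]
    design = np.column_stack([np.ones(x.size), x])
    coef, *_ = np.linalg.lstsq(design, mom[ok], rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    with np.errstate(divide="ignore"):
        fit = np.where(mean > 0, a0 + a1 / mean, 0.0)
    per_gene = pd.Series(np.maximum(np.maximum(mom, fit), 0.0), index=counts.index)
    return DispersionModel(
        flavor="trended", per_gene=per_gene, trend_coef=(a0, a1)
    )


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of an NB (or Poisson when var <= mean) with given mean/variance."""
    k = np.asarray(k, dtype=float)
    if var <= mean * (1.0 + 1e-12):
        return k * np.log(mean) - mean - gammaln(k + 1.0)
    r = mean * mean / (var - mean)
    logp = np.log(r) - np.log(r + mean)
    log1mp = np.log(mean) - np.log(r + mean)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1.0) + r * logp + k * log1mp


def _exact_nb_p_from_sums(ka: int, kb: int, ma: int, mb: int, alpha: float) -> float:
    T = ka + kb
    if T == 0:
        return 1.0
    mu = T / (ma + mb)
    mean_a, mean_b = ma * mu, mb * mu
    var_a = mean_a + alpha * mean_a**2 / ma
    var_b = mean_b + alpha * mean_b**2 / mb
    lo, hi = 0, T
    if T > ENUMERATION_CUTOFF:
        cond_sd = np.sqrt(var_a * var_b / (var_a + var_b))
        mode = T * ma / (ma + mb)
        lo = int(min(max(0, np.floor(mode - 8 * cond_sd)), ka))
        hi = int(max(min(T, np.ceil(mode + 8 * cond_sd)), ka))
    a = np.arange(lo, hi + 1)
    logw = _nb_logpmf(a, mean_a, var_a) + _nb_logpmf(T - a, mean_b, var_b)
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[ka - lo]
    p = float(w[w <= w_obs * (1.0 + _TIE_RTOL)].sum() / w.sum())
    return min(p, 1.0)


def exact_nb_test(group_a, group_b, sf_a, sf_b, alpha: float) -> float:
    """Two-sided NB exact p-value for a difference between two count groups.

    Counts are scaled by their size factors, rounded to the common scale, and
    the conditional distribution of the group-A sum given the total is
    enumerated.  Returns 1.0 for an all-zero (untestable) gene.
    """
    if alpha < 0:
        raise ValueError("dispersion alpha must be >= 0")
    ga = np.asarray(group_a, dtype=float)
    gb = np.asarray(group_b, dtype=float)
    if (ga < 0).any() or (gb < 0).any():
        raise ValueError("counts must be non-negative")
    qa = np.rint(ga / np.asarray(sf_a, dtype=float))
    qb = np.rint(gb / np.asarray(sf_b, dtype=float))
    return _exact_nb_p_from_sums(
        int(qa.sum()), int(qb.sum()), len(qa), len(qb), alpha
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deg(
    result: pd.DataFrame,
    fdr_standard: float = 0.05,
    fdr_strict: float = 0.01,
    lfc_strict: float = 1.0,
) -> pd.DataFrame:
    """Consensus DEG flags: both flavors must pass each FDR threshold.

    ``deg_standard``: fdr_common < 0.05 and fdr_trended < 0.05.
    ``deg_strict``: both FDRs < 0.01 and |log2FC| strictly > 1.
    """
    out = result.copy()
    out["deg_standard"] = (out["fdr_common"] < fdr_standard) & (
        out["fdr_trended"] < fdr_standard
    )
    out["deg_strict"] = (
        (out["fdr_common"] < fdr_strict)
        & (out["fdr_trended"] < fdr_strict)
        & (out["log2fc"].abs() > lfc_strict)
    )
    return out


def run_comparison(
    cm,
    cell_line: str,
    pd_from,
    pd_to,
    fdr_standard: float = 0.05,
    fdr_strict: float = 0.01,
    lfc_strict: float = 1.0,
) -> pd.DataFrame:
    """Full two-group comparison between two PDs of one cell line.

    Returns one row per gene: normalized group means, log2FC (pseudocount
    0.5), p and BH-FDR under both dispersion flavors, consensus DEG flags,
    and an ``untestable`` flag for all-zero genes.
    """
    meta = cm.sample_meta
    samples_a = meta[(meta["cell_line"] == cell_line) & (meta["pd"] == pd_from)].index
    samples_b = meta[(meta["cell_line"] == cell_line) & (meta["pd"] == pd_to)].index
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError(f"no samples for {cell_line} PD {pd_from} vs {pd_to}")
    counts = cm.counts[list(samples_a) + list(samples_b)]
    sf = estimate_size_factors(counts)
    groups = np.array([0] * len(samples_a) + [1] * len(samples_b))
    disp_common = estimate_dispersion(counts, sf, "common", groups)
    disp_trended = estimate_dispersion(counts, sf, "trended", groups)

    arr = counts.to_numpy(dtype=float)
    sf_arr = sf.to_numpy()
    q = np.rint(arr / sf_arr[None, :])
    ka = q[:, groups == 0].sum(axis=1).astype(np.int64)
    kb = q[:, groups == 1].sum(axis=1).astype(np.int64)
    ma, mb = int((groups == 0).sum()), int((groups == 1).sum())

    alpha_t = disp_trended.per_gene.to_numpy()
    alpha_c = disp_common.alpha_common
    n_genes = arr.shape[0]
    p_common = np.empty(n_genes)
    p_trended = np.empty(n_genes)
    for i in range(n_genes):
        p_common[i] = _exact_nb_p_from_sums(ka[i], kb[i], ma, mb, alpha_c)
        p_trended[i] = _exact_nb_p_from_sums(ka[i], kb[i], ma, mb, float(alpha_t[i]))

    norm = arr / sf_arr[None, :]
    mean_a = norm[:, groups == 0].mean(axis=1)
    mean_b = norm[:, groups == 1].mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    result = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_common": p_common,
            "p_trended": p_trended,
            "fdr_common": bh_adjust(p_common),
            "fdr_trended": bh_adjust(p_trended),
            "untestable": (ka + kb) == 0,
        },
        index=counts.index,
    )
    result = call_deg(result, fdr_standard, fdr_strict, lfc_strict)
    result.attrs["comparison"] = {
        "cell_line": cell_line,
        "pd_from": pd_from,
        "pd_to": pd_to,
        "samples_a": list(samples_a),
        "samples_b": list(samples_b),
        "alpha_common": alpha_c,
        "trend_coef": disp_trended.trend_coef,
    }
    return result
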