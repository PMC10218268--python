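"""Per-site differential methylation tests and p-value adjustment.

Three test families are provided, matching the main families used for
methylation data:

- :func:`welch_t_test` — unequal-variance t-test on beta values or
  methylation ratios (the standard array-style test);
- :func:`beta_binomial_test` — per-site likelihood-ratio test of equal
  group means under a beta-binomial count model with a shared,
  method-of-moments dispersion (the DSS/MethylSig/RADMeth family);
- :func:`proportion_overdispersed_test` — pooled two-proportion
  chi-square with an optional variance-inflation correction (the
  methylKit family, with and without overdispersion correction).

Results from external tools enter through
:func:`methsig.io.read_external_dm_table` instead; the in-package tests
are self-contained representatives of the families, not
re-implementations of those packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, DMResult, GroupAssignment, MethylMatrix

__all__ = [
    "welch_t_test",
    "beta_binomial_test",
    "proportion_overdispersed_test",
    "adjust_pvalues",
    "beta_to_m",
]

_PHI_FLOOR = 1e-6
_PHI_CEIL = 0.5


def _two_group_columns(samples, groups: GroupAssignment, group1: str | None, group2: str | None):
    labels = groups.labels_for(samples)
    present = sorted(set(labels))
    if group1 is None and group2 is None:
        if len(present) != 2:
            raise ValueError(f"exactly two groups required, found {present}")
        group1, group2 = present
    if group1 not in present or group2 not in present:
        raise ValueError(f"groups {group1!r}/{group2!r} not found among {present}")
    return labels == group1, labels == group2, group1, group2


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def welch_t_test(
    matrix: MethylMatrix,
    groups: GroupAssignment,
    group1: str | None = None,
    group2: str | None = None,
) -> DMResult:
    """Two-sided Welch t-test per site on methylation levels.

    Sites with fewer than two non-missing values in either group get an
    undefined (NaN) p. Degenerate variances follow the conventions:
    both variances zero with equal means -> statistic 0, p = 1; both
    zero with different means -> infinite statistic, p = 0.
    ``diff`` is ``mean(group2) - mean(group1)``.
    """
    in1, in2, group1, group2 = _two_group_columns(matrix.samples, groups, group1, group2)
    x = matrix.values.to_numpy(float)
    a, b = x[:, in1], x[:, in2]

    def _mv(arr):
        n = np.sum(~np.isnan(arr), axis=1)
        m = np.full(arr.shape[0], np.nan)
        v = np.full(arr.shape[0], np.nan)
        with np.errstate(invalid="ignore"):
            some = n >= 1
            if some.any():
                m[some] = np.nanmean(arr[some], axis=1)
            ok = n >= 2
            if ok.any():
                v[ok] = np.nanvar(arr[ok], axis=1, ddof=1)
        return n, m, v

    n1, m1, v1 = _mv(a)
    n2, m2, v2 = _mv(b)
    valid = (n1 >= 2) & (n2 >= 2)
    diff = m2 - m1
    se2 = v1 / n1 + v2 / n2
    stat = np.full(x.shape[0], np.nan)
    p = np.full(x.shape[0], np.nan)
    df = np.full(x.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = valid & (se2 > 0)
        stat[pos] = diff[pos] / np.sqrt(se2[pos])
        df[pos] = se2[pos] ** 2 / (
            (v1[pos] / n1[pos]) ** 2 / (n1[pos] - 1) + (v2[pos] / n2[pos]) ** 2 / (n2[pos] - 1)
        )
        p[pos] = 2.0 * stats.t.sf(np.abs(stat[pos]), df[pos])
    zero_var = valid & (se2 == 0)
    same = zero_var & (np.abs(diff) <= 1e-15)
    stat[same], p[same] = 0.0, 1.0
    apart = zero_var & ~same
    stat[apart] = np.sign(diff[apart]) * np.inf
    p[apart] = 0.0

    table = pd.DataFrame(
        {
            "statistic": stat,
            "p": p,
            "p_adj": adjust_pvalues(p),
            "mean_g1": m1,
            "mean_g2": m2,
            "diff": diff,
        },
        index=matrix.sites,
    )
    return DMResult(table, group1=group1, group2=group2, method="welch_t")


# ---------------------------------------------------------------------------
# Beta-binomial likelihood-ratio test
# ---------------------------------------------------------------------------

def _bb_loglik(mu: np.ndarray, meth: np.ndarray, cov: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Summed beta-binomial log-likelihood per site.

    ``mu``, ``phi`` are per-site vectors; ``meth``/``cov`` are
    site x sample. Cells with cov == 0 contribute zero. Sites with
    phi <= _PHI_FLOOR use the binomial limit.
    """
    mu = np.clip(mu, 1e-9, 1 - 1e-9)[:, None]
    phi_col = phi[:, None]
    binom_mode = phi_col <= _PHI_FLOOR
    # binomial branch
    ll_bin = meth * np.log(mu) + (cov - meth) * np.log1p(-mu)
    # beta-binomial branch
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (1.0 - phi_col) / np.maximum(phi_col, _PHI_FLOOR / 10)
        a = mu * conc
        b = (1.0 - mu) * conc
        ll_bb = (
            gammaln(meth + a)
            + gammaln(cov - meth + b)
            - gammaln(cov + a + b)
            + gammaln(a + b)
            - gammaln(a)
            - gammaln(b)
        )
    ll = np.where(binom_mode, ll_bin, ll_bb)
    ll = np.where(cov > 0, ll, 0.0)
    return ll.sum(axis=1)


_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


def _bb_mle(meth: np.ndarray, cov: np.ndarray, phi: np.ndarray, iters: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized golden-section maximization of the per-site
    beta-binomial log-likelihood over the mean in (0, 1). Returns
    (mu_hat, loglik). The likelihood is unimodal in the mean for fixed
    dispersion, so golden-section search converges reliably."""
    lo = np.full(meth.shape[0], 1e-9)
    hi = np.full(meth.shape[0], 1.0 - 1e-9)
    for _ in range(iters):
        x1 = hi - _GOLD * (hi - lo)
        x2 = lo + _GOLD * (hi - lo)
        f1 = _bb_loglik(x1, meth, cov, phi)
        f2 = _bb_loglik(x2, meth, cov, phi)
        shrink_left = f1 >= f2
        hi = np.where(shrink_left, x2, hi)
        lo = np.where(shrink_left, lo, x1)
    mu = 0.5 * (lo + hi)
    return mu, _bb_loglik(mu, meth, cov, phi)


def _moment_dispersion(meth: np.ndarray, cov: np.ndarray, group_masks) -> np.ndarray:
    """Method-of-moments beta-binomial dispersion per site, pooled over
    groups after removing each group's mean. Floored at 1e-6 and capped
    at 0.5."""
    n_sites = meth.shape[0]
    num = np.zeros(n_sites)
    den = np.zeros(n_sites)
    samp = np.zeros(n_sites)
    for mask in group_masks:
        m = meth[:, mask].astype(float)
        n = cov[:, mask].astype(float)
        covd = n > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            phat = np.where(covd, m / np.maximum(n, 1), np.nan)
        tot_n = np.where(covd, n, 0).sum(axis=1)
        pbar = np.where(tot_n > 0, np.where(covd, m, 0).sum(axis=1) / np.maximum(tot_n, 1), np.nan)
        pq = pbar * (1 - pbar)
        resid2 = np.where(covd, (phat - pbar[:, None]) ** 2, 0.0).sum(axis=1)
        # E[(phat_j - p)^2] = p(1-p) [1 + (n_j - 1) phi] / n_j
        inv_n = np.where(covd, 1.0 / np.maximum(n, 1), 0.0).sum(axis=1)
        w = np.where(covd, (n - 1) / np.maximum(n, 1), 0.0).sum(axis=1)
        num += resid2 - np.nan_to_num(pq) * inv_n
        den += np.nan_to_num(pq) * w
        samp += covd.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(np.nan_to_num(phi), _PHI_FLOOR, _PHI_CEIL)


def beta_binomial_test(
    counts: CountTable,
    groups: GroupAssignment,
    group1: str | None = None,
    group2: str | None = None,
    shrink_dispersion: bool = False,
    fixed_phi: float | None = None,
    min_covered_per_group: int = 2,
) -> DMResult:
    """Per-site likelihood-ratio test of equal group means under a
    beta-binomial model with a shared per-site dispersion.

    The dispersion is a method-of-moments estimate pooled across groups
    (optionally shrunk halfway, in log space, toward the genome-wide
    median); ``fixed_phi`` overrides it, and values at or below the
    floor (1e-6) reduce the model to the binomial. The statistic is
    referred to chi-square(1). Sites with fewer than
    ``min_covered_per_group`` covered samples in either group get an
    undefined p. Group means and ``diff`` are means of per-sample
    ratios.
    """
    in1, in2, group1, group2 = _two_group_columns(counts.samples, groups, group1, group2)
    meth = counts.meth.astype(float)
    cov = counts.cov.astype(float)
    covd1 = (cov[:, in1] > 0).sum(axis=1)
    covd2 = (cov[:, in2] > 0).sum(axis=1)
    valid = (covd1 >= min_covered_per_group) & (covd2 >= min_covered_per_group)

    if fixed_phi is not None:
        phi = np.full(counts.n_sites, float(fixed_phi))
        phi = np.clip(phi, 0.0, _PHI_CEIL)
    else:
        phi = _moment_dispersion(counts.meth, counts.cov, [in1, in2])
        if shrink_dispersion:
            med = np.median(phi[valid]) if valid.any() else _PHI_FLOOR
            phi = np.exp(0.5 * np.log(phi) + 0.5 * np.log(max(med, _PHI_FLOOR)))
            phi = np.clip(phi, _PHI_FLOOR, _PHI_CEIL)

    _, ll1 = _bb_mle(meth[:, in1], cov[:, in1], phi)
    _, ll2 = _bb_mle(meth[:, in2], cov[:, in2], phi)
    _, ll0 = _bb_mle(meth, cov, phi)
    lr = np.clip(2.0 * (ll1 + ll2 - ll0), 0.0, None)
    p = np.where(valid, stats.chi2.sf(lr, df=1), np.nan)
    stat = np.where(valid, lr, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    m1 = np.nanmean(np.where(np.isnan(ratios[:, in1]), np.nan, ratios[:, in1]), axis=1)
    m2 = np.nanmean(np.where(np.isnan(ratios[:, in2]), np.nan, ratios[:, in2]), axis=1)

    table = pd.DataFrame(
        {
            "statistic": stat,
            "p": p,
            "p_adj": adjust_pvalues(p),
            "mean_g1": m1,
            "mean_g2": m2,
            "diff": m2 - m1,
            "phi": phi,
        },
        index=counts.site_keys,
    )
    return DMResult(table, group1=group1, group2=group2, method="beta_binomial")


# ---------------------------------------------------------------------------
# Pooled proportion test with overdispersion correction
# ---------------------------------------------------------------------------

def proportion_overdispersed_test(
    counts: CountTable,
    groups: GroupAssignment,
    group1: str | None = None,
    group2: str | None = None,
    correct: bool = False,
    min_covered_per_group: int = 2,
) -> DMResult:
    """Pooled two-proportion Pearson chi-square per site.

    Reads are pooled within each group into a 2x2 (group x
    methylated/unmethylated) table. With ``correct=True`` the statistic
    is deflated by a per-site overdispersion scale — the sum of squared
    Pearson residuals of per-sample counts around their group
    proportion, divided by (covered samples - 2) and floored at 1 — so
    the corrected p is never smaller than the uncorrected one.
    """
    in1, in2, group1, group2 = _two_group_columns(counts.samples, groups, group1, group2)
    meth = counts.meth.astype(float)
    cov = counts.cov.astype(float)

    M1 = meth[:, in1].sum(axis=1)
    N1 = cov[:, in1].sum(axis=1)
    M2 = meth[:, in2].sum(axis=1)
    N2 = cov[:, in2].sum(axis=1)
    N = N1 + N2
    M = M1 + M2
    with np.errstate(divide="ignore", invalid="ignore"):
        p_pool = np.where(N > 0, M / np.maximum(N, 1), np.nan)
        # Pearson chi-square for the 2x2 pooled table
        e1m, e1u = N1 * p_pool, N1 * (1 - p_pool)
        e2m, e2u = N2 * p_pool, N2 * (1 - p_pool)
        stat = np.zeros(counts.n_sites)
        for obs, exp in (
            (M1, e1m),
            (N1 - M1, e1u),
            (M2, e2m),
            (N2 - M2, e2u),
        ):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.maximum(exp, 1e-300), 0.0)
            stat = stat + term

    if correct:
        scale_num = np.zeros(counts.n_sites)
        n_covered = np.zeros(counts.n_sites)
        for mask, Mg, Ng in ((in1, M1, N1), (in2, M2, N2)):
            m = meth[:, mask]
            n = cov[:, mask]
            covd = n > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                pg = np.where(Ng > 0, Mg / np.maximum(Ng, 1), np.nan)[:, None]
                denom = n * pg * (1 - pg)
                r2 = np.where(covd & (denom > 0), (m - n * pg) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
            scale_num += r2.sum(axis=1)
            n_covered += covd.sum(axis=1)
        df_scale = np.maximum(n_covered - 2, 1)
        scale = np.maximum(scale_num / df_scale, 1.0)
        stat = stat / scale

    covd1 = (cov[:, in1] > 0).sum(axis=1)
    covd2 = (cov[:, in2] > 0).sum(axis=1)
    valid = (covd1 >= min_covered_per_group) & (covd2 >= min_covered_per_group)
    p = np.where(valid, stats.chi2.sf(stat, df=1), np.nan)
    stat = np.where(valid, stat, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    m1 = np.nanmean(np.where(np.isnan(ratios[:, in1]), np.nan, ratios[:, in1]), axis=1)
    m2 = np.nanmean(np.where(np.isnan(ratios[:, in2]), np.nan, ratios[:, in2]), axis=1)

    table = pd.DataFrame(
        {
            "statistic": stat,
            "p": p,
            "p_adj": adjust_pvalues(p),
            "mean_g1": m1,
            "mean_g2": m2,
            "diff": m2 - m1,
        },
        index=counts.site_keys,
    )
    tag = "proportion_overdispersed" if correct else "proportion"
    return DMResult(table, group1=group1, group2=group2, method=tag)


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Adjust raw p-values; NaNs pass through untouched.

    ``"bh"`` is Benjamini-Hochberg step-up FDR; ``"storey_q"`` is the
    Storey q-value with the pi0 estimate taken from a lambda grid
    (0.05..0.95 in steps of 0.05, cubic-polynomial smoothed at the grid
    end).
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if vals.size == 0:
        return out
    if method == "bh":
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    elif method == "storey_q":
        out[ok] = _storey_q(vals)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out


def _storey_q(p: np.ndarray) -> np.ndarray:
    m = p.size
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    if m < 20 or np.all(pi0_lam == 0):
        pi0 = 1.0
    else:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.clip(np.polyval(coef, lam.max()), 1e-8, 1.0))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0, 1)
    return out


def beta_to_m(values, eps: float = 1e-6):
    """M-value transform M = log2((beta + eps) / (1 - beta + eps)).

    ``eps`` (default 1e-6) keeps the transform finite at beta = 0 and 1.
    Accepts a MethylMatrix (returns a DataFrame of M-values) or any
    array-like of beta values.
    """
    if isinstance(values, MethylMatrix):
        beta = values.values
        return np.log2((beta + eps) / (1 - beta + eps))
    beta = np.asarray(values, dtype=float)
    return np.log2((beta + eps) / (1 - beta + eps))
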