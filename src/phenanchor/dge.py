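"""Count filtering, median-of-ratios normalization and NB Wald DEG calling.

The differential-expression stage mirrors the standard bulk RNA-seq recipe:
drop genes with zeros in >=25% of samples, average rows whose gene names
collide up to capitalization, normalize by median-of-ratios size factors,
and test each non-control concentration against control with a
negative-binomial Wald test (gene-wise ML dispersion shrunk 50/50 toward a
mean-dispersion trend) followed by Benjamini-Hochberg adjustment within each
concentration.  This is a transparent reimplementation of the DESeq2-style
workflow, not a numerical clone of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .datatypes import CountMatrix, ExperimentDesign

__all__ = [
    "DgeConfig",
    "filter_low_counts",
    "aggregate_case_collisions",
    "size_factors",
    "normalize_counts",
    "estimate_dispersions",
    "nb_wald",
    "bh_adjust",
    "deg_partition",
]

DISP_FLOOR = 1e-8
DISP_CEIL = 10.0


@dataclass(frozen=True)
class DgeConfig:
    zero_fraction_cutoff: float = 0.25
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def filter_low_counts(counts: CountMatrix, cfg: DgeConfig | None = None) -> CountMatrix:
    """Drop genes whose zero-count sample fraction reaches the cutoff.

    With the default 0.25 on a 32-sample design, a gene with zeros in 8 or
    more samples is removed; 7 zeros is kept.
    """
    cfg = cfg or DgeConfig()
    v = counts.values
    zero_frac = (v == 0).sum(axis=1) / v.shape[1]
    kept = v.loc[zero_frac < cfg.zero_fraction_cutoff]
    if kept.empty:
        import warnings

        warnings.warn("low-count filter removed every gene", stacklevel=2)
    return CountMatrix(kept)


def aggregate_case_collisions(values: pd.DataFrame) -> pd.DataFrame:
    """Average rows whose gene ids are identical up to capitalization.

    Collided rows are replaced by their arithmetic mean under the
    lowercased id; non-colliding ids are left untouched (original case).
    """
    lower = values.index.str.lower()
    if not lower.duplicated().any():
        return values
    collided = lower[lower.duplicated(keep=False)].unique()
    keep = values.loc[~lower.isin(collided)]
    merged = (
        values.loc[lower.isin(collided)]
        .groupby(values.index.str.lower()[lower.isin(collided)])
        .mean()
    )
    return pd.concat([keep, merged])


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    Only genes expressed in every sample contribute; factor_s is the median
    over those genes of count_gs / geometric-mean_g.
    """
    v = counts.values.to_numpy(float)
    all_pos = (v > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter low-count genes first"
        )
    logs = np.log(v[all_pos])
    log_ref = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalize_counts(counts: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    sf = size_factors(counts) if sf is None else sf
    return counts.values / sf


def _nb_loglik_grid(
    y: np.ndarray, mu: np.ndarray, alphas: np.ndarray, group_codes: np.ndarray
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood on a grid of dispersions.

    Returns (n_genes, n_alphas).  The adjustment, -0.5 log det(X'WX) for the
    cell-means design, removes the small-sample downward bias of the ML
    dispersion that makes the Wald test anticonservative.
    """
    r = 1.0 / alphas  # (A,)
    y3 = y[:, :, None]
    mu3 = mu[:, :, None]
    r3 = r[None, None, :]
    ll = (
        gammaln(y3 + r3)
        - gammaln(r3)
        - gammaln(y3 + 1.0)
        + r3 * np.log(r3 / (r3 + mu3))
        + y3 * np.log(mu3 / (r3 + mu3))
    ).sum(axis=1)
    # CR term: cell-means X'WX is diagonal with one entry per dose group
    w = mu3 / (1.0 + mu3 / r3)  # working weights (G, S, A)
    for g in np.unique(group_codes):
        ll -= 0.5 * np.log(np.maximum(w[:, group_codes == g, :].sum(axis=1), 1e-300))
    return ll


def estimate_dispersions(
    counts: CountMatrix, design: ExperimentDesign, sf: pd.Series | None = None
) -> pd.DataFrame:
    """Gene-wise ML dispersion with 50/50 shrinkage toward a fitted trend.

    Per gene, the NB dispersion alpha maximises the Cox-Reid adjusted
    profile likelihood on a log grid (with two zoom refinements), with cell
    means plugged in from the per-concentration group averages of
    normalized counts.  A parametric mean-dispersion trend a0 + a1/mean is
    then fitted across genes and the final dispersion is the geometric
    mean of the gene-wise and trend values, floored at 1e-8.
    """
    sf = size_factors(counts) if sf is None else sf
    v = counts.values.to_numpy(float)
    sfv = sf.loc[counts.sample_ids].to_numpy()
    conc = design.concentration_of().loc[counts.sample_ids].to_numpy()
    norm = v / sfv
    group_codes = np.searchsorted(np.unique(conc), conc)

    # plug-in fitted means: per-group mean of normalized counts, rescaled
    mu = np.empty_like(v)
    for c in np.unique(conc):
        cols = conc == c
        mu[:, cols] = norm[:, cols].mean(axis=1, keepdims=True) * sfv[cols]
    mu = np.maximum(mu, 1e-8)

    grid = np.geomspace(DISP_FLOOR, DISP_CEIL, 41)
    ll = _nb_loglik_grid(v, mu, grid, group_codes)
    alpha_hat = grid[ll.argmax(axis=1)]
    for _ in range(2):  # zoom around the current optimum
        lo = np.maximum(alpha_hat / 3.0, DISP_FLOOR)
        hi = np.minimum(alpha_hat * 3.0, DISP_CEIL)
        fine = np.exp(
            np.linspace(0, 1, 21)[None, :] * (np.log(hi) - np.log(lo))[:, None]
            + np.log(lo)[:, None]
        )
        # per-gene fine grids need the loop unrolled over the grid axis
        r = 1.0 / fine  # (G, 21)
        ll_fine = (
            gammaln(v[:, :, None] + r[:, None, :])
            - gammaln(r[:, None, :])
            - gammaln(v[:, :, None] + 1.0)
            + r[:, None, :] * np.log(r[:, None, :] / (r[:, None, :] + mu[:, :, None]))
            + v[:, :, None] * np.log(mu[:, :, None] / (r[:, None, :] + mu[:, :, None]))
        ).sum(axis=1)
        w = mu[:, :, None] / (1.0 + mu[:, :, None] / r[:, None, :])
        for g in np.unique(group_codes):
            ll_fine -= 0.5 * np.log(np.maximum(w[:, group_codes == g, :].sum(axis=1), 1e-300))
        alpha_hat = fine[np.arange(v.shape[0]), ll_fine.argmax(axis=1)]

    base_mean = norm.mean(axis=1)
    trend = _dispersion_trend(base_mean, alpha_hat)
    alpha_trend = np.maximum(trend[0] + trend[1] / np.maximum(base_mean, 1e-8), DISP_FLOOR)
    log_hat = np.log(np.maximum(alpha_hat, DISP_FLOOR))
    log_trend = np.log(alpha_trend)
    # Empirical-Bayes shrinkage toward the trend.  The weight comes from the
    # usual variance decomposition: the sampling variance of a log ML
    # dispersion is ~ trigamma((m - k)/2) and the prior (biological) variance
    # is the residual scatter around the trend beyond that.  When true
    # dispersions scatter widely around the trend (as when dispersion is
    # unrelated to the mean), shrinkage weakens; a fixed 50/50 blend would
    # bias high-dispersion genes low and inflate the Wald tail.
    from scipy.special import polygamma

    m, k = v.shape[1], len(np.unique(conc))
    s2_samp = float(polygamma(1, max(m - k, 2) / 2.0))
    resid = log_hat - log_trend
    mad = 1.4826 * np.median(np.abs(resid - np.median(resid))) if len(resid) > 1 else 0.5
    s2_prior = max(mad**2 - s2_samp, 0.25)
    w = s2_samp / (s2_samp + s2_prior)
    alpha_final = np.exp((1.0 - w) * log_hat + w * log_trend)
    # dispersion outliers far above the trend stay unshrunk
    outlier = resid > 2.0 * max(mad, 0.1)
    alpha_final[outlier] = alpha_hat[outlier]
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "dispersion_ml": alpha_hat,
            "dispersion_trend": alpha_trend,
            "dispersion": np.maximum(alpha_final, DISP_FLOOR),
        },
        index=counts.gene_ids,
    )


def _dispersion_trend(base_mean: np.ndarray, alpha_hat: np.ndarray) -> tuple[float, float]:
    """Fit alpha ~ a0 + a1/mean over genes with an interior ML estimate."""
    ok = (alpha_hat > DISP_FLOOR * 10) & (alpha_hat < DISP_CEIL / 2) & (base_mean > 0)
    if ok.sum() < 10:
        med = float(np.median(alpha_hat)) if len(alpha_hat) else 0.1
        return max(med, DISP_FLOOR), 0.0
    x, y = base_mean[ok], alpha_hat[ok]
    try:
        (a0, a1), _ = optimize.curve_fit(
            lambda m, a0, a1: a0 + a1 / m,
            x,
            y,
            p0=(np.median(y), 1.0),
            bounds=([DISP_FLOOR, 0.0], [DISP_CEIL, np.inf]),
            maxfev=10000,
        )
        return float(a0), float(a1)
    except RuntimeError:
        return float(np.median(y)), 0.0


def _irls_two_group(
    y: np.ndarray,
    treat: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for the per-gene NB GLM  log mu = b0 + b1*treat + offset.

    Returns (beta, se) with shape (n_genes, 2); natural-log scale.
    """
    n_genes = y.shape[0]
    X = np.column_stack([np.ones_like(treat, dtype=float), treat.astype(float)])  # (S, 2)
    # moment start from group means of sf-normalized counts
    norm = y / np.exp(log_sf)
    m0 = np.maximum(norm[:, treat == 0].mean(axis=1), 1e-8)
    m1 = np.maximum(norm[:, treat == 1].mean(axis=1), 1e-8)
    beta = np.column_stack([np.log(m0), np.log(m1) - np.log(m0)])
    for _ in range(n_iter):
        eta = beta @ X.T + log_sf[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)  # (G, S)
        z = (eta - log_sf[None, :]) + (y - mu) / mu
        # normal equations per gene: (X^T W X) beta = X^T W z
        a11 = w.sum(axis=1)
        a12 = (w * X[:, 1]).sum(axis=1)
        a22 = (w * X[:, 1] ** 2).sum(axis=1)
        b1 = (w * z).sum(axis=1)
        b2 = (w * z * X[:, 1]).sum(axis=1)
        det = np.maximum(a11 * a22 - a12**2, 1e-300)
        new0 = (a22 * b1 - a12 * b2) / det
        new1 = (a11 * b2 - a12 * b1) / det
        new = np.column_stack([new0, new1])
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = beta @ X.T + log_sf[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    a11 = w.sum(axis=1)
    a12 = (w * X[:, 1]).sum(axis=1)
    a22 = (w * X[:, 1] ** 2).sum(axis=1)
    det = np.maximum(a11 * a22 - a12**2, 1e-300)
    se1 = np.sqrt(a11 / det)  # var(beta1) = [ (X'WX)^-1 ]_22
    return beta, se1


def nb_wald(
    counts: CountMatrix, design: ExperimentDesign, cfg: DgeConfig | None = None
) -> pd.DataFrame:
    """NB Wald test of every non-control concentration against control.

    Returns one row per gene per concentration with ``log2fc`` (log2 scale),
    ``se``, two-sided ``p``, BH-adjusted ``padj`` (within concentration) and
    the ``is_deg`` call at ``cfg.alpha``.  The Wald statistic is referred to
    a t distribution with ``n_samples - n_groups`` degrees of freedom (the
    residual df of the dispersion fit) rather than a normal: with 4
    replicates per group the normal reference is anticonservative in the
    far tail.
    """
    cfg = cfg or DgeConfig()
    counts.check_design(design)
    sf = size_factors(counts)
    disp = estimate_dispersions(counts, design, sf)
    alpha = disp["dispersion"].to_numpy()
    conc_of = design.concentration_of().loc[counts.sample_ids]
    control_cols = np.asarray([s in set(design.control_samples) for s in counts.sample_ids])
    v = counts.values.to_numpy(float)
    log_sf_all = np.log(sf.loc[counts.sample_ids].to_numpy())
    ln2 = np.log(2.0)

    frames = []
    wald_df = max(v.shape[1] - len(design.concentrations), 1)
    test_concs = sorted(c for c in design.concentrations if c > 0)
    for c in test_concs:
        cols = control_cols | np.isclose(conc_of.to_numpy(), c)
        y = v[:, cols]
        treat = (~control_cols[cols]).astype(int)
        # reorder so control first (treat indicator already encodes groups)
        beta, se_nat = _irls_two_group(y, treat, log_sf_all[cols], alpha)
        log2fc = beta[:, 1] / ln2
        se = se_nat / ln2
        zero = y.sum(axis=1) == 0
        z = np.zeros_like(log2fc)
        ok = se_nat > 0
        z[ok] = beta[ok, 1] / se_nat[ok]
        p = 2.0 * stats.t.sf(np.abs(z), wald_df)
        log2fc[zero] = 0.0
        p[zero] = 1.0
        padj = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.gene_ids,
                    "concentration": c,
                    "log2fc": log2fc,
                    "se": se,
                    "p": p,
                    "padj": padj,
                    "is_deg": padj < cfg.alpha,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def deg_partition(
    results: pd.DataFrame, teratogenic_concs: set[float]
) -> dict[str, set[str]]:
    """Split the union of DEG sets by teratogenicity of the concentration.

    ``overlap`` holds genes called at >=1 non-teratogenic AND >=1
    teratogenic concentration; the other two sets are exclusive.
    """
    tested = set(results["concentration"].unique())
    if not set(teratogenic_concs) <= tested:
        raise ValueError("teratogenic_concs must be a subset of tested concentrations")
    degs = results[results["is_deg"]]
    terat = set(degs.loc[degs["concentration"].isin(teratogenic_concs), "gene_id"])
    nonterat = set(degs.loc[~degs["concentration"].isin(teratogenic_concs), "gene_id"])
    return {
        "nonteratogenic_only": nonterat - terat,
        "overlap": nonterat & terat,
        "teratogenic_only": terat - nonterat,
    }
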