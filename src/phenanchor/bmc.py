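"""Williams-trend-gated benchmark concentration (BMC) modeling.

The continuous BMC workflow screens each gene for a monotone expression
trend across the concentration series (two-sided Williams test, permutation
p-values), fits the genes that pass to ten parametric concentration-response
families, selects the model with the lowest AIC (with the Hill-k flag rule),
and computes the BMC at which the fitted curve departs from control by
``bmr_factor`` times the residual standard deviation (BMR factor 1.349 ~ a
10% departure under normality).  BMDL/BMDU come from a parametric bootstrap.
Gene-set summaries report the median BMC over set members with a defined,
in-range BMC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import DoseResponseFitRecord, ExperimentDesign

__all__ = [
    "BmcConfig",
    "TrendResult",
    "williams_statistics",
    "williams_trend_matrix",
    "williams_trend",
    "fit_family",
    "fit_all_families",
    "select_model",
    "compute_bmc",
    "geneset_bmc",
    "gene_bmc_table",
    "MODEL_FAMILIES",
]

DEFAULT_FAMILIES = (
    "linear",
    "poly2",
    "poly3",
    "poly4",
    "power",
    "hill",
    "exp2",
    "exp3",
    "exp4",
    "exp5",
)


@dataclass(frozen=True)
class BmcConfig:
    trend_alpha: float = 0.05
    bmr_factor: float = 1.349
    confidence: float = 0.95
    max_iterations: int = 250
    hill_k_flag_fraction: float = 1.0 / 3.0
    model_families: tuple[str, ...] = DEFAULT_FAMILIES
    constant_variance: bool = True
    n_permutations: int = 10_000
    gof_alpha: float = 0.05
    n_bootstrap: int = 2000

    def __post_init__(self) -> None:
        if self.bmr_factor <= 0:
            raise ValueError("bmr_factor must be positive")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")


@dataclass(frozen=True)
class TrendResult:
    gene_id: str
    statistic: float
    direction: str  # "up" | "down"
    p: float
    passes: bool


# ---------------------------------------------------------------------------
# Williams trend test


def _group_layout(design: ExperimentDesign, sample_ids: Sequence[str]):
    conc = design.concentration_of().loc[list(sample_ids)].to_numpy()
    levels = np.sort(np.unique(conc))
    assign = np.zeros((len(sample_ids), len(levels)))
    for j, c in enumerate(levels):
        assign[np.isclose(conc, c), j] = 1.0
    return levels, assign


def williams_statistics(expr: np.ndarray, assign: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Williams statistics for both directions, vectorized over genes.

    ``expr`` is (genes x samples), ``assign`` a binary (samples x groups)
    matrix with ascending-concentration columns, control first.  The
    isotonic (non-decreasing) estimate at the top group equals the maximum
    over u of the pooled mean of groups u..K — the closed-form value of the
    PAVA solution at the last level — and symmetrically the antitonic
    estimate is the minimum of those suffix means.  Returns (t_up, t_down).
    """
    n_g = assign.sum(axis=0)  # group sizes
    sums = expr @ assign
    means = sums / n_g
    sq = (expr**2) @ assign
    n_tot, n_groups = assign.shape[0], assign.shape[1]
    ss_within = sq.sum(axis=1) - (n_g * means**2).sum(axis=1)
    dof = n_tot - n_groups
    s2 = np.maximum(ss_within, 0.0) / dof

    # suffix pooled means over groups u..K
    csum = np.cumsum(sums[:, ::-1], axis=1)[:, ::-1]
    cn = np.cumsum(n_g[::-1])[::-1]
    suffix_means = csum / cn
    iso_top = suffix_means.max(axis=1)
    anti_top = suffix_means.min(axis=1)

    denom = np.sqrt(s2 * (1.0 / n_g[-1] + 1.0 / n_g[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_up = (iso_top - means[:, 0]) / denom
        t_down = (means[:, 0] - anti_top) / denom
    zero = denom == 0
    t_up[zero] = 0.0
    t_down[zero] = 0.0
    return t_up, t_down


def williams_trend_matrix(
    expr: pd.DataFrame,
    design: ExperimentDesign,
    cfg: BmcConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Williams trend test for every row of ``expr``.

    Sample labels are permuted jointly for all genes; per-direction p-values
    use the add-one estimator and the two-sided p is ``2 * min(p_up,
    p_down)`` capped at 1.
    """
    cfg = cfg or BmcConfig()
    levels, assign = _group_layout(design, expr.columns)
    x = expr.to_numpy(float)
    t_up, t_down = williams_statistics(x, assign)

    rng = np.random.default_rng(seed)
    b = cfg.n_permutations
    ge_up = np.zeros(x.shape[0])
    ge_down = np.zeros(x.shape[0])
    n_samp = x.shape[1]
    for _ in range(b):
        perm = rng.permutation(n_samp)
        pu, pdn = williams_statistics(x, assign[perm])
        ge_up += pu >= t_up - 1e-12
        ge_down += pdn >= t_down - 1e-12
    p_up = (1.0 + ge_up) / (1.0 + b)
    p_down = (1.0 + ge_down) / (1.0 + b)
    p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    zero_var = (t_up == 0) & (t_down == 0)
    p[zero_var] = 1.0
    direction = np.where(p_up <= p_down, "up", "down")
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "statistic": np.where(direction == "up", t_up, t_down),
            "direction": direction,
            "p": p,
            "passes": p < cfg.trend_alpha,
        }
    ).set_index("gene_id", drop=False)


def williams_trend(
    expr: pd.Series, design: ExperimentDesign, cfg: BmcConfig | None = None, seed: int = 0
) -> TrendResult:
    """Single-gene convenience wrapper around :func:`williams_trend_matrix`."""
    df = williams_trend_matrix(expr.to_frame().T, design, cfg, seed=seed)
    row = df.iloc[0]
    return TrendResult(
        gene_id=str(expr.name),
        statistic=float(row["statistic"]),
        direction=str(row["direction"]),
        p=float(row["p"]),
        passes=bool(row["passes"]),
    )


# ---------------------------------------------------------------------------
# Model families

def _f_linear(d, b0, b1):
    return b0 + b1 * d


def _f_poly2(d, b0, b1, b2):
    return b0 + b1 * d + b2 * d**2


def _f_poly3(d, b0, b1, b2, b3):
    return b0 + b1 * d + b2 * d**2 + b3 * d**3


def _f_poly4(d, b0, b1, b2, b3, b4):
    return b0 + b1 * d + b2 * d**2 + b3 * d**3 + b4 * d**4


def _f_power(d, g, b, delta):
    return g + b * np.power(d, delta)


def _f_hill(d, g, v, k, n):
    dn = np.power(d, n)
    return g + v * dn / (np.power(k, n) + dn)


def _f_exp2(d, a, b):
    return a * np.exp(np.clip(b * d, -500, 500))


def _f_exp3(d, a, b, c):
    return a * np.exp(np.clip(np.sign(b) * np.power(np.abs(b) * d, c), -500, 500))


def _f_exp4(d, a, b, c):
    return a * (c - (c - 1.0) * np.exp(-b * d))


def _f_exp5(d, a, b, c, g):
    return a * (c - (c - 1.0) * np.exp(-np.power(b * d, g)))


def _inits_common(d, y):
    y0 = float(np.mean(y[d == d.min()])) if (d == d.min()).any() else float(y[0])
    ytop = float(np.mean(y[d == d.max()]))
    rng_ = ytop - y0
    dmax = float(d.max())
    dmid = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
    return y0, ytop, rng_, dmax, dmid


# family -> (func, param names, list of inits, (lower, upper) bounds)
def _family_spec(name: str, d: np.ndarray, y: np.ndarray):
    y0, ytop, rng_, dmax, dmid = _inits_common(d, y)
    big = 1e6
    eps = 1e-8
    if name == "power":
        return (
            _f_power,
            ["g", "b", "delta"],
            [
                [y0, rng_ / max(dmax, eps), 1.0],
                [y0, rng_ / max(dmax**2, eps), 2.0],
                [y0, np.sign(rng_ or 1.0) * 1e-3, 4.0],
            ],
            ([-big, -big, 1.0], [big, big, 18.0]),
        )
    if name == "hill":
        return (
            _f_hill,
            ["g", "v", "k", "n"],
            [
                [y0, rng_, dmid, 1.5],
                [y0, rng_ * 1.2, dmax / 2, 3.0],
                [y0, rng_, dmax / 10, 1.0],
            ],
            ([-big, -big, 1e-6, 1.0], [big, big, dmax * 100, 18.0]),
        )
    if name == "exp2":
        a0 = y0 if abs(y0) > eps else (rng_ or 1.0)
        b0 = np.log(max(ytop, eps) / max(abs(a0), eps)) / max(dmax, eps) if a0 * ytop > 0 else 0.01
        return (
            _f_exp2,
            ["a", "b"],
            [[a0, b0], [a0, -b0 if b0 else -0.01], [a0, 1e-3]],
            ([-big, -10.0], [big, 10.0]),
        )
    if name == "exp3":
        a0 = y0 if abs(y0) > eps else (rng_ or 1.0)
        return (
            _f_exp3,
            ["a", "b", "c"],
            [[a0, 1.0 / max(dmax, eps), 1.0], [a0, -1.0 / max(dmax, eps), 1.0], [a0, 0.1, 2.0]],
            ([-big, -10.0, 1.0], [big, 10.0, 18.0]),
        )
    if name == "exp4":
        a0 = y0 if abs(y0) > eps else 1.0
        c0 = ytop / a0 if abs(a0) > eps else 2.0
        return (
            _f_exp4,
            ["a", "b", "c"],
            [[a0, 1.0 / max(dmid, eps), max(c0, 1.1)], [a0, 0.1, 0.5], [a0, 1.0, 2.0]],
            ([-big, 1e-8, 1e-8], [big, 100.0, 1e4]),
        )
    if name == "exp5":
        a0 = y0 if abs(y0) > eps else 1.0
        c0 = ytop / a0 if abs(a0) > eps else 2.0
        return (
            _f_exp5,
            ["a", "b", "c", "g"],
            [
                [a0, 1.0 / max(dmid, eps), max(c0, 1.1), 1.5],
                [a0, 0.1, 0.5, 3.0],
                [a0, 1.0, 2.0, 1.0],
            ],
            ([-big, 1e-8, 1e-8, 1.0], [big, 100.0, 1e4, 18.0]),
        )
    raise ValueError(f"unknown family {name!r}")


MODEL_FAMILIES: dict[str, Callable] = {
    "linear": _f_linear,
    "poly2": _f_poly2,
    "poly3": _f_poly3,
    "poly4": _f_poly4,
    "power": _f_power,
    "hill": _f_hill,
    "exp2": _f_exp2,
    "exp3": _f_exp3,
    "exp4": _f_exp4,
    "exp5": _f_exp5,
}

_POLY_DEGREE = {"linear": 1, "poly2": 2, "poly3": 3, "poly4": 4}


def _gaussian_ml_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _pooled_within_group_sd(d: np.ndarray, y: np.ndarray) -> float:
    """Pooled within-dose-group SD under the constant-variance assumption.

    This is the BMR reference: unlike a model's own residual SD it is free
    of model-selection bias.
    """
    levels = np.unique(d)
    rss = float(sum(np.sum((y[d == c] - y[d == c].mean()) ** 2) for c in levels))
    dof = len(y) - len(levels)
    if dof <= 0:
        return float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
    return float(np.sqrt(rss / dof))


def _lack_of_fit_p(d: np.ndarray, y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    """F-test of the fitted curve against the per-group cell-means model."""
    rss_model = float(np.sum((y - yhat) ** 2))
    levels = np.unique(d)
    group_means = {c: y[d == c].mean() for c in levels}
    rss_pe = float(sum(np.sum((y[d == c] - group_means[c]) ** 2) for c in levels))
    df_lof = len(levels) - n_params
    df_pe = len(y) - len(levels)
    if df_lof <= 0 or df_pe <= 0:
        return 1.0
    if rss_pe <= 1e-300:
        return 1.0 if rss_model - rss_pe <= 1e-12 else 0.0
    f = max(rss_model - rss_pe, 0.0) / df_lof / (rss_pe / df_pe)
    return float(stats.f.sf(f, df_lof, df_pe))


def fit_family(
    dose: Sequence[float],
    response: Sequence[float],
    family: str,
    cfg: BmcConfig | None = None,
    gene_id: str = "",
) -> DoseResponseFitRecord:
    """Least-squares fit of one model family (Gaussian ML under constant
    variance).

    ``aic = 2k - 2 loglik`` with ``k = n_params + 1`` (the variance counts
    as a parameter); ``gof_p`` is the lack-of-fit F-test against the
    cell-means model.  Non-convergence yields a flagged record with
    infinite AIC.
    """
    cfg = cfg or BmcConfig()
    d = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    rec = DoseResponseFitRecord(gene_id=gene_id, family=family)
    try:
        if family in _POLY_DEGREE:
            deg = _POLY_DEGREE[family]
            coef = np.polyfit(d, y, deg)
            names = [f"b{i}" for i in range(deg + 1)]
            params = dict(zip(names, coef[::-1].tolist()))
            func = MODEL_FAMILIES[family]
            yhat = np.polyval(coef, d)
            n_params = deg + 1
        else:
            func, names, init_list, bounds = _family_spec(family, d, y)
            best = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for x0 in init_list:
                    x0 = np.clip(x0, bounds[0], bounds[1])
                    try:
                        res = optimize.least_squares(
                            lambda th: func(d, *th) - y,
                            x0,
                            bounds=bounds,
                            max_nfev=cfg.max_iterations * 4,
                        )
                    except Exception:
                        continue
                    if best is None or res.cost < best.cost - 1e-12:
                        best = res
            if best is None:
                raise RuntimeError("no start converged")
            params = dict(zip(names, best.x.tolist()))
            yhat = func(d, *best.x)
            n_params = len(names)
    except Exception:
        rec.converged = False
        rec.aic = np.inf
        return rec

    rss = float(np.sum((y - yhat) ** 2))
    rec.params = params
    rec.loglik = _gaussian_ml_loglik(rss, n)
    rec.aic = 2.0 * (n_params + 1) - 2.0 * rec.loglik
    rec.gof_p = _lack_of_fit_p(d, y, yhat, n_params)
    dof = max(n - n_params, 1)
    rec.residual_sd = float(np.sqrt(rss / dof))
    rec.pooled_sd = _pooled_within_group_sd(d, y)
    rec._dose = d  # kept for BMC root-finding and the bootstrap
    rec._response = y
    return rec


def fit_all_families(
    dose, response, cfg: BmcConfig | None = None, gene_id: str = ""
) -> list[DoseResponseFitRecord]:
    cfg = cfg or BmcConfig()
    return [fit_family(dose, response, fam, cfg, gene_id) for fam in cfg.model_families]


def predict(rec: DoseResponseFitRecord, d) -> np.ndarray:
    func = MODEL_FAMILIES[rec.family]
    return func(np.asarray(d, dtype=float), *rec.params.values())


def select_model(
    fits: list[DoseResponseFitRecord],
    lowest_positive_dose: float,
    cfg: BmcConfig | None = None,
) -> DoseResponseFitRecord:
    """Lowest-AIC model with the Hill-k flag rule.

    A winning Hill fit whose half-max parameter k falls below one-third of
    the lowest positive dose is flagged; the next-best model with adequate
    goodness of fit (gof p > alpha) replaces it, or the flagged Hill is
    returned if none qualifies.  AIC ties break by family order (simpler
    families first).
    """
    cfg = cfg or BmcConfig()
    if not fits:
        raise ValueError("fits must be non-empty")
    order = {f: i for i, f in enumerate(cfg.model_families)}
    ranked = sorted(fits, key=lambda r: (r.aic, order.get(r.family, 99)))
    best = ranked[0]
    if not np.isfinite(best.aic):
        best.selected = False
        return best
    if best.family == "hill":
        k = best.params.get("k", np.inf)
        if k < lowest_positive_dose * cfg.hill_k_flag_fraction:
            best.hill_flagged = True
            for alt in ranked[1:]:
                if np.isfinite(alt.aic) and alt.gof_p > cfg.gof_alpha:
                    alt.selected = True
                    return alt
            best.selected = True
            return best
    best.selected = True
    return best


def _bmc_root(
    rec: DoseResponseFitRecord, target: float, max_dose: float
) -> Optional[float]:
    """Smallest d in (0, max_dose] with |f(d) - f(0)| = target."""
    f0 = float(predict(rec, 0.0))

    def g(dv):
        return np.abs(predict(rec, dv) - f0) - target

    grid = np.concatenate(
        [np.geomspace(max_dose * 1e-6, max_dose, 400), [max_dose]]
    )
    vals = g(grid)
    if vals[0] >= 0:
        return float(grid[0])
    idx = np.nonzero(vals >= 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    return float(optimize.brentq(lambda dv: float(g(dv)), grid[i - 1], grid[i], xtol=1e-10))


def compute_bmc(
    rec: DoseResponseFitRecord,
    control_sd: float,
    cfg: BmcConfig | None = None,
    max_dose: Optional[float] = None,
    n_boot: Optional[int] = None,
    seed: int = 0,
    candidate_families: Optional[Sequence[str]] = None,
    lowest_positive_dose: Optional[float] = None,
) -> DoseResponseFitRecord:
    """BMC, BMDL and BMDU for a selected fit.

    The BMC is the smallest concentration at which the fitted curve departs
    from its value at 0 by ``bmr_factor * control_sd``, located by a
    log-spaced bracketing grid plus Brent root refinement.  BMDL/BMDU are
    percentile bounds from a parametric bootstrap: responses are
    resimulated from the fitted curve with Gaussian noise at the residual
    SD, the model selection is re-run over ``candidate_families`` (default:
    the selected family only) and each draw's BMC uses that draw's own
    residual SD as the BMR reference, so both model-selection and
    variance-estimation uncertainty propagate into the interval.  The
    bounds are clipped to bracket the point estimate.  When the curve never
    reaches the BMR within ``max_dose`` the record is marked
    ``removed_above_max``.
    """
    cfg = cfg or BmcConfig()
    if not np.isfinite(rec.aic):
        rec.bmc = None
        rec.removed_above_max = False
        return rec
    d = rec._dose
    if max_dose is None:
        max_dose = float(np.max(d))
    if lowest_positive_dose is None:
        pos = d[d > 0]
        lowest_positive_dose = float(pos.min()) if len(pos) else 0.0
    target = cfg.bmr_factor * control_sd
    bmc = _bmc_root(rec, target, max_dose)
    if bmc is None or bmc > max_dose:
        rec.bmc = None
        rec.removed_above_max = True
        return rec
    rec.bmc = bmc
    rec.removed_above_max = False

    n_boot = cfg.n_bootstrap if n_boot is None else n_boot
    if n_boot > 0:
        families = list(candidate_families or [rec.family])
        rng = np.random.default_rng(seed)
        yhat = predict(rec, d)
        sd = rec.pooled_sd if np.isfinite(rec.pooled_sd) and rec.pooled_sd > 0 else rec.residual_sd
        draws = []
        for _ in range(n_boot):
            yb = yhat + rng.normal(0.0, sd, len(d))
            fits_b = [fit_family(d, yb, fam, cfg, rec.gene_id) for fam in families]
            sel_b = select_model(fits_b, lowest_positive_dose, cfg)
            if not np.isfinite(sel_b.aic):
                continue
            b = _bmc_root(sel_b, cfg.bmr_factor * sel_b.pooled_sd, max_dose)
            draws.append(np.inf if b is None else b)
        if draws:
            arr = np.asarray(draws)
            # bias-corrected percentile bounds: the BMC bootstrap
            # distribution is typically median-biased relative to the point
            # estimate (the plain percentile interval undercovers), so the
            # quantile levels are shifted by 2*z0 in the usual BC fashion
            frac_below = np.clip(np.mean(arr < bmc), 1.0 / (len(arr) + 1), len(arr) / (len(arr) + 1.0))
            z0 = stats.norm.ppf(frac_below)
            a = (1.0 - cfg.confidence) / 2.0
            lo_q = stats.norm.cdf(2.0 * z0 + stats.norm.ppf(a))
            hi_q = stats.norm.cdf(2.0 * z0 + stats.norm.ppf(1.0 - a))
            finite = arr[np.isfinite(arr)]
            if len(finite) >= max(0.5 * len(arr), 10):
                bmdl = float(np.quantile(finite, lo_q))
                bmdu = float(np.quantile(arr, hi_q)) if np.isfinite(np.quantile(arr, hi_q)) else np.inf
                rec.bmdl = min(bmdl, bmc)
                rec.bmdu = None if not np.isfinite(bmdu) else max(bmdu, bmc)
    return rec


def geneset_bmc(
    records: Sequence[DoseResponseFitRecord], gene_set: set[str]
) -> dict:
    """Median BMC/BMDL/BMDU over set members with a defined, in-range BMC."""
    hits = [
        r
        for r in records
        if r.gene_id in gene_set and r.bmc is not None and not r.removed_above_max
    ]
    if not hits:
        import warnings

        warnings.warn("no modeled genes intersect the gene set", stacklevel=2)
        return {
            "median_bmc": None,
            "median_bmdl": None,
            "median_bmdu": None,
            "mean_bmc": None,
            "n_modeled": 0,
        }

    def med(vals):
        vals = [v for v in vals if v is not None]
        return float(np.median(vals)) if vals else None

    return {
        "median_bmc": med([r.bmc for r in hits]),
        "median_bmdl": med([r.bmdl for r in hits]),
        "median_bmdu": med([r.bmdu for r in hits]),
        "mean_bmc": float(np.mean([r.bmc for r in hits])),
        "n_modeled": len(hits),
    }


def gene_bmc_table(
    expr: pd.DataFrame,
    design: ExperimentDesign,
    cfg: BmcConfig | None = None,
    seed: int = 0,
    n_boot: int = 0,
    genes: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, list[DoseResponseFitRecord]]:
    """Full trend -> fit -> select -> BMC pipeline for an expression matrix.

    ``expr`` holds per-sample (log2) normalized expression, rows = genes.
    Genes failing the Williams gate are reported with NaN model fields and
    are never fitted.  Returns the summary table and the selected records.
    """
    cfg = cfg or BmcConfig()
    if genes is not None:
        expr = expr.loc[list(genes)]
    trend = williams_trend_matrix(expr, design, cfg, seed=seed)
    conc = design.concentration_of().loc[expr.columns].to_numpy()
    lowest_pos = float(np.min(conc[conc > 0]))
    max_dose = float(np.max(conc))

    rows = []
    records: list[DoseResponseFitRecord] = []
    for i, gid in enumerate(expr.index):
        t = trend.loc[gid]
        row = {
            "gene_id": gid,
            "trend_statistic": t["statistic"],
            "trend_direction": t["direction"],
            "trend_p": t["p"],
            "trend_passes": bool(t["passes"]),
            "family": None,
            "aic": np.nan,
            "gof_p": np.nan,
            "bmc": np.nan,
            "bmdl": np.nan,
            "bmdu": np.nan,
            "hill_flagged": False,
            "removed_above_max": False,
        }
        if t["passes"]:
            y = expr.loc[gid].to_numpy(float)
            fits = fit_all_families(conc, y, cfg, gene_id=gid)
            sel = select_model(fits, lowest_pos, cfg)
            if np.isfinite(sel.aic):
                # bootstrap re-selects among the competitive families
                cand = [
                    f.family for f in fits if np.isfinite(f.aic) and f.aic <= sel.aic + 10.0
                ]
                sel = compute_bmc(
                    sel,
                    control_sd=sel.pooled_sd,
                    cfg=cfg,
                    max_dose=max_dose,
                    n_boot=n_boot,
                    seed=seed + 7919 * (i + 1),
                    candidate_families=cand,
                    lowest_positive_dose=lowest_pos,
                )
                records.append(sel)
                row.update(
                    family=sel.family,
                    aic=sel.aic,
                    gof_p=sel.gof_p,
                    bmc=np.nan if sel.bmc is None else sel.bmc,
                    bmdl=np.nan if sel.bmdl is None else sel.bmdl,
                    bmdu=np.nan if sel.bmdu is None else sel.bmdu,
                    hill_flagged=sel.hill_flagged,
                    removed_above_max=sel.removed_above_max,
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id", drop=False), records
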