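"""Binomial log-logistic dose-response modeling of the morphology screen.

Fits ``P(d) = bg + (1 - bg) / (1 + (ec50/d)**h)`` to per-concentration
affected/exposed counts by maximum likelihood, reports a profile-likelihood
confidence interval for the EC50, and derives a benchmark concentration
(BMC) at a given added risk over background, with a profile-likelihood BMDL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import PhenotypeTable

__all__ = [
    "NonIdentifiableError",
    "PhenotypeFit",
    "incidence_table",
    "fit_loglogistic",
    "phenotype_bmc",
    "bmc_closed_form",
    "bmc_bisection",
    "plot_fit",
]

BACKGROUND_MAX = 0.2  # screening backgrounds are small


class NonIdentifiableError(ValueError):
    """The incidence data carry no dose-response signal to fit."""


def _loglogistic_p(d: np.ndarray, bg: float, ec50: float, h: float) -> np.ndarray:
    p = np.full_like(d, bg, dtype=float)
    pos = d > 0
    p[pos] = bg + (1.0 - bg) / (1.0 + (ec50 / d[pos]) ** h)
    return p


@dataclass
class PhenotypeFit:
    """Maximum-likelihood log-logistic fit for one endpoint/group."""

    endpoint: str
    group: str
    ec50: float
    hill_slope: float
    background: float
    loglik: float
    ec50_ci: tuple[float, float]
    converged: bool = True
    extrapolated: bool = False  # EC50 outside the tested range
    bmc: Optional[float] = None
    bmdl: Optional[float] = None
    bmr_added_risk: Optional[float] = None
    bmc_undefined: bool = False
    risk_convention: str = "added"
    # fitted data, kept for profiling
    dose: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    n_exposed: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    n_affected: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def predict(self, d) -> np.ndarray:
        return _loglogistic_p(
            np.asarray(d, dtype=float), self.background, self.ec50, self.hill_slope
        )

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "group": self.group,
            "ec50": self.ec50,
            "hill_slope": self.hill_slope,
            "background": self.background,
            "loglik": self.loglik,
            "ec50_ci": list(self.ec50_ci),
            "converged": self.converged,
            "extrapolated": self.extrapolated,
            "bmc": self.bmc,
            "bmdl": self.bmdl,
            "bmr_added_risk": self.bmr_added_risk,
            "bmc_undefined": self.bmc_undefined,
            "risk_convention": self.risk_convention,
        }


def incidence_table(
    pheno: PhenotypeTable,
    endpoints_to_pool: Optional[set[str]] = None,
    per_animal: Optional[pd.DataFrame] = None,
) -> PhenotypeTable:
    """Collapse endpoint-level counts into one ``any_effect`` row per
    concentration/group.

    An animal counts as affected if it shows at least one pooled endpoint,
    so pooling endpoint-level *counts* is only possible from per-animal data
    (``per_animal`` with columns concentration, group, animal_id, endpoint,
    affected) or when a single (already pooled) endpoint is supplied.
    """
    if per_animal is not None:
        df = per_animal
        if endpoints_to_pool is not None:
            df = df[df["endpoint"].isin(endpoints_to_pool)]
        hit = (
            df.assign(affected=df["affected"].astype(bool))
            .groupby(["concentration", "group", "animal_id"])["affected"]
            .any()
            .reset_index()
        )
        agg = (
            hit.groupby(["concentration", "group"])["affected"]
            .agg(n_exposed="size", n_affected="sum")
            .reset_index()
        )
        agg.insert(1, "endpoint", "any_effect")
        return PhenotypeTable(agg)

    t = pheno.table
    pool = set(t["endpoint"]) if endpoints_to_pool is None else endpoints_to_pool
    t = t[t["endpoint"].isin(pool)]
    if t.empty:
        raise ValueError("no rows match the requested endpoints")
    n_endpoints = t.groupby(["concentration", "group"])["endpoint"].nunique()
    if (n_endpoints > 1).any():
        raise ValueError(
            "cannot pool multiple endpoint rows without per-animal data: "
            "affected animals would be double-counted"
        )
    out = t.copy()
    out["endpoint"] = "any_effect"
    return PhenotypeTable(out.reset_index(drop=True))


def _nll(theta: np.ndarray, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    bg, log_ec50, log_h = theta
    p = _loglogistic_p(d, bg, np.exp(log_ec50), np.exp(log_h))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _aggregate(pheno: PhenotypeTable, endpoint: str, group: Optional[str]):
    t = pheno.table
    t = t[t["endpoint"] == endpoint]
    if group is not None:
        t = t[t["group"] == group]
    if t.empty:
        raise ValueError(f"no rows for endpoint {endpoint!r} / group {group!r}")
    agg = t.groupby("concentration")[["n_exposed", "n_affected"]].sum().reset_index()
    agg = agg[agg["n_exposed"] > 0]
    return (
        agg["concentration"].to_numpy(float),
        agg["n_exposed"].to_numpy(float),
        agg["n_affected"].to_numpy(float),
    )


def fit_loglogistic(
    pheno: PhenotypeTable,
    endpoint: str = "any_effect",
    group: Optional[str] = None,
    fix_background: Optional[float] = None,
) -> PhenotypeFit:
    """Fit the 3-parameter log-logistic incidence curve by binomial ML.

    Background is estimated freely but bounded to [0, 0.2] unless
    ``fix_background`` pins it (e.g. at the observed control incidence).
    The EC50 confidence interval is a 95% profile-likelihood interval.
    """
    d, n, k = _aggregate(pheno, endpoint, group)
    if len(d) < 3:
        raise ValueError("need >=3 distinct concentrations with exposed animals")
    inc = k / n
    if np.allclose(inc, inc[0]):
        raise NonIdentifiableError(
            "incidence is constant across concentrations; no dose-response to fit"
        )

    pos = d[d > 0]
    ec50_grid = np.geomspace(pos.min() / 10, pos.max() * 10, 25)
    best = None
    bg0 = min(float(inc[d == 0][0]) if (d == 0).any() else 0.0, BACKGROUND_MAX)
    bounds = [
        (0.0, BACKGROUND_MAX) if fix_background is None else (fix_background, fix_background),
        (np.log(pos.min() / 1e3), np.log(pos.max() * 1e3)),
        (np.log(0.05), np.log(30.0)),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ec50_start in ec50_grid[:: max(1, len(ec50_grid) // 6)]:
            x0 = np.array(
                [bg0 if fix_background is None else fix_background, np.log(ec50_start), np.log(1.5)]
            )
            res = optimize.minimize(
                _nll, x0, args=(d, n, k), method="L-BFGS-B", bounds=bounds
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    assert best is not None
    bg, ec50, h = best.x[0], float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    nll_min = best.fun

    ci = _profile_ci_ec50(d, n, k, best.x, nll_min, bounds, fix_background)
    fit = PhenotypeFit(
        endpoint=endpoint,
        group=group if group is not None else "all",
        ec50=ec50,
        hill_slope=h,
        background=float(bg),
        loglik=-nll_min,
        ec50_ci=ci,
        converged=bool(best.success),
        extrapolated=not (pos.min() <= ec50 <= pos.max()),
        dose=d,
        n_exposed=n,
        n_affected=k,
    )
    return fit


def _profile_ci_ec50(d, n, k, x_hat, nll_min, bounds, fix_background, level=0.95):
    """Profile-likelihood CI by bisection on each side of the MLE."""
    crit = stats.chi2.ppf(level, df=1) / 2.0
    inner = [bounds[0], bounds[2]]

    def profile(log_ec50: float) -> float:
        def f(theta2):
            return _nll(np.array([theta2[0], log_ec50, theta2[1]]), d, n, k)

        x0 = np.array([x_hat[0], x_hat[2]])
        res = optimize.minimize(f, x0, method="L-BFGS-B", bounds=inner)
        return res.fun - nll_min - crit

    lo_edge, hi_edge = bounds[1]
    out = []
    for edge in (lo_edge, hi_edge):
        if profile(edge) <= 0:  # never crosses: unbounded on this side
            out.append(float(np.exp(edge)))
            continue
        try:
            root = optimize.brentq(profile, min(x_hat[1], edge), max(x_hat[1], edge), xtol=1e-4)
            out.append(float(np.exp(root)))
        except ValueError:
            out.append(float(np.exp(edge)))
    return (min(out), max(out))


def bmc_closed_form(bg: float, ec50: float, h: float, bmr: float) -> Optional[float]:
    """Concentration with added risk ``bmr`` over background, analytically.

    Solves ``P(d) - P(0) = bmr``:  ``d = ec50 / ((1-bg)/bmr - 1)**(1/h)``.
    Returns None when the curve cannot add ``bmr`` risk (bmr >= 1 - bg).
    """
    if bmr <= 0 or bmr >= 1.0 - bg:
        return None
    return float(ec50 / ((1.0 - bg) / bmr - 1.0) ** (1.0 / h))


def bmc_bisection(
    bg: float, ec50: float, h: float, bmr: float, d_max: float, rtol: float = 1e-6
) -> Optional[float]:
    """Numeric BMC by bracketed bisection; oracle twin of the closed form."""

    def added(dv: float) -> float:
        return float(_loglogistic_p(np.array([dv]), bg, ec50, h)[0]) - bg - bmr

    if added(d_max) < 0:
        return None
    lo, hi = 0.0, d_max
    while hi - lo > rtol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if added(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def phenotype_bmc(
    fit: PhenotypeFit, bmr_added_risk: float = 0.10, level: float = 0.95
) -> PhenotypeFit:
    """Benchmark concentration at ``bmr_added_risk`` added risk, with BMDL.

    The BMC solves ``P(d) - P(0) = bmr`` on the fitted curve (closed form).
    The BMDL is the lower bound of the 95% profile-likelihood interval for
    the BMC, obtained by reparameterising the EC50 in terms of the BMC and
    profiling out background and slope.  When the curve never reaches the
    BMR within 10x the top tested concentration the BMC is flagged
    undefined.
    """
    fit.bmr_added_risk = bmr_added_risk
    bmc = bmc_closed_form(fit.background, fit.ec50, fit.hill_slope, bmr_added_risk)
    d_max = float(fit.dose.max()) if fit.dose.size else np.inf
    if bmc is None or (np.isfinite(d_max) and bmc > 10.0 * d_max):
        fit.bmc = None
        fit.bmdl = None
        fit.bmc_undefined = True
        return fit
    fit.bmc = bmc
    fit.bmc_undefined = False
    if fit.dose.size:
        fit.bmdl = _profile_bmdl(fit, bmr_added_risk, level)
    return fit


def plot_fit(fit: PhenotypeFit, path) -> None:
    """Write the fitted incidence curve over the observed points to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    obs = fit.n_affected / fit.n_exposed
    ax.scatter(fit.dose, obs, color="k", zorder=3, label="observed")
    pos = fit.dose[fit.dose > 0]
    grid = np.geomspace(max(pos.min() / 5, 1e-3), fit.dose.max() * 1.2, 200)
    ax.plot(grid, fit.predict(grid), color="tab:red", label="log-logistic fit")
    ax.axvline(fit.ec50, ls="--", color="grey", lw=0.8)
    if fit.bmc is not None:
        ax.axvline(fit.bmc, ls=":", color="tab:blue", lw=0.8)
    ax.set_xscale("symlog", linthresh=max(pos.min() / 2, 1e-3))
    ax.set_xlabel("concentration (µM)")
    ax.set_ylabel(f"{fit.endpoint} incidence")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _profile_bmdl(fit: PhenotypeFit, bmr: float, level: float) -> float:
    """Lower profile bound on the BMC.

    For a fixed candidate BMC b, ec50 = b * ((1-bg)/bmr - 1)**(1/h); the
    constrained deviance in (bg, h) is compared against the chi-square
    cutoff.
    """
    d, n, k = fit.dose, fit.n_exposed, fit.n_affected
    crit = stats.chi2.ppf(level, df=1) / 2.0
    nll_min = -fit.loglik
    bounds = [(0.0, BACKGROUND_MAX), (np.log(0.05), np.log(30.0))]

    def profile(log_b: float) -> float:
        b = np.exp(log_b)

        def f(theta):
            bg, log_h = theta
            h = np.exp(log_h)
            if bmr >= 1.0 - bg:
                return 1e9
            ec50 = b * ((1.0 - bg) / bmr - 1.0) ** (1.0 / h)
            return _nll(np.array([bg, np.log(ec50), log_h]), d, n, k)

        x0 = np.array([fit.background, np.log(fit.hill_slope)])
        res = optimize.minimize(f, x0, method="L-BFGS-B", bounds=bounds)
        return res.fun - nll_min - crit

    log_bmc = np.log(fit.bmc)
    lo = log_bmc + np.log(1e-3)
    if profile(lo) <= 0:
        return float(np.exp(lo))
    root = optimize.brentq(profile, lo, log_bmc, xtol=1e-5)
    return float(np.exp(root))
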