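"""Seeded synthetic data with the statistical structure of an 8-point
concentration-response RNA-seq experiment plus a teratogenicity screen.

The generator emulates the study design the downstream pipeline assumes:

* a 0.4x geometric dilution series topping out at 50 µM (8 levels incl. a
  0 µM vehicle control), 4 replicate pools per level (32 samples);
* negative-binomial counts whose log2 fold change against control follows a
  Hill curve in concentration, with four gene classes — a co-regulated
  "AHR-like" responsive module, sensitive low-threshold genes,
  high-concentration-only genes, and null genes;
* within-module co-expression induced by a shared per-sample latent deviate;
* binary teratogenicity outcomes drawn from a log-logistic incidence curve
  whose defaults (EC50 16.5 µM, slope 2) put the 10%-added-risk benchmark
  concentration at 5.5 µM.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    ExperimentDesign,
    GeneTruth,
    InvalidParameterError,
    PhenotypeTable,
    PhenotypeTruth,
)

__all__ = [
    "dilution_series",
    "hill_log2fc",
    "make_design",
    "make_gene_truths",
    "generate_counts",
    "simulate_phenotypes",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
]

LN2_SQ = math.log(2.0) ** 2


def round_sig(x: float, sig_figs: int) -> float:
    """Round ``x`` to ``sig_figs`` significant figures."""
    if x == 0:
        return 0.0
    return float(round(x, sig_figs - 1 - int(math.floor(math.log10(abs(x))))))


def dilution_series(
    top: float, factor: float, n_levels: int, sig_figs: int = 3
) -> list[float]:
    """Geometric dilution series with a 0 control prepended, ascending.

    ``top * factor**(n_levels-1) ... top``, each value rounded to
    ``sig_figs`` significant figures.  A 0.4x series from 50 µM over 7
    levels gives the canonical 0, 0.205, 0.512, 1.28, 3.2, 8, 20, 50 µM.
    """
    if top <= 0:
        raise InvalidParameterError("top concentration must be positive")
    if not (0.0 < factor < 1.0):
        raise InvalidParameterError("dilution factor must be in (0, 1)")
    if n_levels < 1:
        raise InvalidParameterError("n_levels must be >= 1")
    if sig_figs < 1:
        raise InvalidParameterError("sig_figs must be >= 1")
    levels = [round_sig(top * factor**k, sig_figs) for k in range(n_levels - 1, -1, -1)]
    series = [0.0] + levels
    if any(b <= a for a, b in zip(series, series[1:])):
        raise InvalidParameterError(
            "series not strictly increasing after rounding; increase sig_figs"
        )
    return series


def hill_log2fc(d, truth: GeneTruth):
    """Ground-truth log2 fold change at concentration ``d`` (µM).

    ``emax * d**n / (ec50**n + d**n)``: 0 at the control, half-maximal at
    ``ec50``, monotone in ``d``.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise InvalidParameterError("concentration must be non-negative")
    dn = np.power(d, truth.hill_n)
    out = truth.emax * dn / (truth.ec50**truth.hill_n + dn)
    return float(out) if out.ndim == 0 else out


def make_design(
    concentrations: Sequence[float], n_replicates: int = 4
) -> ExperimentDesign:
    """Build the sample table: ``n_replicates`` pools per concentration."""
    rows = []
    for conc in concentrations:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"c{conc:g}_r{rep}",
                    "concentration": float(conc),
                    "replicate": rep,
                    "is_control": conc == 0,
                }
            )
    return ExperimentDesign(pd.DataFrame(rows))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Class sizes default to a 2,000-gene budget: 100 co-regulated AHR-like
    module genes (large induction, half-max in the teens of µM so their
    expression benchmark concentrations cluster near the 5.5 µM phenotype
    threshold), 100 sensitive genes responding below ~1.5 µM, 100 steep
    high-concentration-only genes, and 1,700 nulls.  Dispersions are drawn
    log-uniform on [0.005, 0.5], spanning typical bulk RNA-seq values.
    """

    concentrations: tuple[float, ...] = (0.0, 0.205, 0.512, 1.28, 3.2, 8.0, 20.0, 50.0)
    n_replicates: int = 4
    n_ahr_module: int = 100
    n_sensitive: int = 100
    n_high_only: int = 100
    n_null: int = 1700
    module_rho: float = 0.6
    dispersion_range: tuple[float, float] = (0.005, 0.5)
    baseline_range: tuple[float, float] = (10.0, 5000.0)
    phenotype_truth: PhenotypeTruth = field(default_factory=PhenotypeTruth)
    n_fish_per_conc: int = 36
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_ahr_module + self.n_sensitive + self.n_high_only + self.n_null


@dataclass(frozen=True)
class SyntheticDataset:
    counts: CountMatrix
    design: ExperimentDesign
    truths: list[GeneTruth]
    phenotype: PhenotypeTable
    phenotype_truth: PhenotypeTruth
    seed: int

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": t.gene_id,
                "klass": t.klass,
                "emax": t.emax,
                "ec50": t.ec50,
                "hill_n": t.hill_n,
                "baseline_mean": t.baseline_mean,
                "dispersion": t.dispersion,
                "module_id": t.module_id if t.module_id is not None else -1,
            }
            for t in self.truths
        ]
        return pd.DataFrame(rows)


def _draw_common(rng: np.random.Generator, cfg: SimulationConfig, n: int):
    lo_d, hi_d = cfg.dispersion_range
    lo_b, hi_b = cfg.baseline_range
    disp = np.exp(rng.uniform(np.log(lo_d), np.log(hi_d), n))
    base = np.exp(rng.uniform(np.log(lo_b), np.log(hi_b), n))
    return base, disp


def make_gene_truths(cfg: SimulationConfig, seed: Optional[int] = None) -> list[GeneTruth]:
    """Draw per-gene ground truth curves for the four gene classes."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truths: list[GeneTruth] = []

    base, disp = _draw_common(rng, cfg, cfg.n_ahr_module)
    for i in range(cfg.n_ahr_module):
        truths.append(
            GeneTruth(
                gene_id=f"ahr{i:04d}",
                klass="ahr_module",
                emax=float(rng.uniform(3.0, 10.0)),
                ec50=float(np.exp(rng.uniform(np.log(10.0), np.log(25.0)))),
                hill_n=float(rng.uniform(1.5, 3.0)),
                baseline_mean=float(base[i]),
                dispersion=float(disp[i]),
                module_id=1,
            )
        )

    base, disp = _draw_common(rng, cfg, cfg.n_sensitive)
    for i in range(cfg.n_sensitive):
        sign = -1.0 if rng.random() < 0.25 else 1.0
        truths.append(
            GeneTruth(
                gene_id=f"sen{i:04d}",
                klass="sensitive",
                emax=sign * float(rng.uniform(1.5, 4.0)),
                ec50=float(np.exp(rng.uniform(np.log(0.3), np.log(1.5)))),
                hill_n=float(rng.uniform(1.0, 2.0)),
                baseline_mean=float(base[i]),
                dispersion=float(disp[i]),
            )
        )

    base, disp = _draw_common(rng, cfg, cfg.n_high_only)
    for i in range(cfg.n_high_only):
        sign = -1.0 if rng.random() < 0.25 else 1.0
        truths.append(
            GeneTruth(
                gene_id=f"hig{i:04d}",
                klass="high_only",
                emax=sign * float(rng.uniform(2.0, 6.0)),
                ec50=float(np.exp(rng.uniform(np.log(25.0), np.log(60.0)))),
                hill_n=float(rng.uniform(3.0, 6.0)),
                baseline_mean=float(base[i]),
                dispersion=float(disp[i]),
            )
        )

    base, disp = _draw_common(rng, cfg, cfg.n_null)
    for i in range(cfg.n_null):
        truths.append(
            GeneTruth(
                gene_id=f"nul{i:04d}",
                klass="null",
                emax=0.0,
                ec50=1.0,
                hill_n=1.0,
                baseline_mean=float(base[i]),
                dispersion=float(disp[i]),
            )
        )
    return truths


def generate_counts(
    design: ExperimentDesign,
    truths: Sequence[GeneTruth],
    seed: int,
    module_rho: float = 0.6,
) -> CountMatrix:
    """Draw the negative-binomial count matrix.

    Gene g in sample s at concentration d has mean
    ``baseline * 2**(hill_log2fc(d) + b_ms)`` where ``b_ms`` is a latent
    normal deviate shared by all genes of a module in sample s.  Its
    variance is scaled so that the within-module pairwise correlation of
    log expression is approximately ``module_rho``; non-module genes get
    ``b = 0``.  Counts are NB with ``variance = mu + dispersion * mu**2``.
    """
    if not truths:
        raise InvalidParameterError("truths must be non-empty")
    if not (0.0 <= module_rho < 1.0):
        raise InvalidParameterError("module_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = design.sample_ids
    concs = design.concentration_of().loc[samples].to_numpy()
    n_genes, n_samp = len(truths), len(samples)

    log2fc = np.zeros((n_genes, n_samp))
    for i, t in enumerate(truths):
        log2fc[i] = hill_log2fc(concs, t)

    # Shared latent per-module per-sample deviate (log2 units).  The target
    # pairwise log-expression correlation rho fixes sigma_b^2 =
    # rho/(1-rho) * vbar, with vbar the module-average NB log variance
    # (1/mu + alpha)/ln(2)^2 at baseline.
    module_ids = sorted({t.module_id for t in truths if t.module_id is not None})
    b = np.zeros((n_genes, n_samp))
    for m in module_ids:
        members = [i for i, t in enumerate(truths) if t.module_id == m]
        vbar = float(
            np.mean(
                [
                    (1.0 / truths[i].baseline_mean + truths[i].dispersion) / LN2_SQ
                    for i in members
                ]
            )
        )
        sigma_b = math.sqrt(module_rho / (1.0 - module_rho) * vbar) if module_rho > 0 else 0.0
        z = rng.normal(0.0, sigma_b, n_samp)
        b[members, :] = z[None, :]

    baseline = np.array([t.baseline_mean for t in truths])[:, None]
    mu = baseline * np.exp2(log2fc + b)
    alpha = np.array([t.dispersion for t in truths])[:, None]
    # NB(r, p) with r = 1/alpha, p = r/(r+mu) has the right mean/variance.
    r = 1.0 / alpha
    counts = rng.negative_binomial(r, r / (r + mu))
    values = pd.DataFrame(
        counts, index=[t.gene_id for t in truths], columns=samples, dtype=np.int64
    )
    return CountMatrix(values)


def simulate_phenotypes(
    concentrations: Sequence[float],
    n_per_conc: int,
    truth: PhenotypeTruth,
    seed: int,
    endpoint: str = "any_effect",
    group: str = "wild_type",
) -> PhenotypeTable:
    """Binomial draws from the log-logistic incidence curve.

    ``P(d) = background + (1-background) / (1 + (ec50/d)**slope)`` with
    ``P(0) = background``; default n is 36 animals per concentration.
    """
    if n_per_conc < 1:
        raise InvalidParameterError("n_per_conc must be >= 1")
    rng = np.random.default_rng(seed)
    p = truth.incidence(np.asarray(concentrations, dtype=float))
    affected = rng.binomial(n_per_conc, p)
    table = pd.DataFrame(
        {
            "concentration": list(concentrations),
            "endpoint": endpoint,
            "group": group,
            "n_exposed": n_per_conc,
            "n_affected": affected,
        }
    )
    return PhenotypeTable(table)


def simulate_dataset(cfg: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate the full synthetic dataset for one seed.

    Sub-seeds for truths, counts and phenotypes are spawned from the config
    seed so the three draws are independent streams.
    """
    cfg = cfg or SimulationConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    design = make_design(cfg.concentrations, cfg.n_replicates)
    truths = make_gene_truths(cfg, seed=seeds[0])
    counts = generate_counts(design, truths, seed=seeds[1], module_rho=cfg.module_rho)
    phenotype = simulate_phenotypes(
        cfg.concentrations, cfg.n_fish_per_conc, cfg.phenotype_truth, seed=seeds[2]
    )
    return SyntheticDataset(
        counts=counts,
        design=design,
        truths=truths,
        phenotype=phenotype,
        phenotype_truth=cfg.phenotype_truth,
        seed=cfg.seed,
    )
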