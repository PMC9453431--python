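"""Core containers shared across the pipeline.

The pipeline passes around a small number of tabular objects: a gene x sample
count matrix tied to an experiment design, per-concentration phenotype counts,
fitted dose-response records, and network objects.  These are thin, validated
wrappers over pandas DataFrames so that every stage can rely on the same
invariants (unique ids, consistent dimensions, a single control level at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentDesign",
    "CountMatrix",
    "PhenotypeTable",
    "GeneTruth",
    "PhenotypeTruth",
    "DoseResponseFitRecord",
]


class InvalidParameterError(ValueError):
    """Raised when an operation receives parameters outside its domain."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample layout of a concentration series experiment.

    ``table`` has columns ``sample_id``, ``concentration`` (µM),
    ``replicate`` (1-based), ``is_control``.  Exactly one concentration is
    flagged as control and it must be 0 µM.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "concentration", "replicate", "is_control"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")
        if (t["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        ctrl_concs = set(t.loc[t["is_control"], "concentration"])
        if ctrl_concs != {0.0}:
            raise ValueError(
                "exactly one control concentration equal to 0 is required, "
                f"got {sorted(ctrl_concs)}"
            )
        counts = t.loc[~t["is_control"]].groupby("concentration").size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"non-control concentrations need >=2 replicates: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def concentrations(self) -> np.ndarray:
        """Distinct concentrations in ascending order (control first)."""
        return np.sort(self.table["concentration"].unique())

    @property
    def control_samples(self) -> list[str]:
        return self.table.loc[self.table["is_control"], "sample_id"].tolist()

    def samples_at(self, concentration: float) -> list[str]:
        mask = np.isclose(self.table["concentration"], concentration)
        return self.table.loc[mask, "sample_id"].tolist()

    def concentration_of(self) -> pd.Series:
        """sample_id -> concentration mapping."""
        return self.table.set_index("sample_id")["concentration"]

    def subset(self, sample_ids: Sequence[str]) -> "ExperimentDesign":
        keep = self.table["sample_id"].isin(set(sample_ids))
        return ExperimentDesign(self.table.loc[keep].reset_index(drop=True))


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample raw counts (non-negative integers)."""

    values: pd.DataFrame  # index: gene_id, columns: sample_id

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("gene_ids must be unique")
        if v.columns.duplicated().any():
            raise ValueError("sample_ids must be unique")
        if (v.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_design(self, design: ExperimentDesign) -> None:
        if list(self.values.columns) != design.sample_ids:
            raise ValueError("count matrix columns do not match design sample_ids")


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-concentration morphology screen counts.

    Columns: ``concentration`` (µM), ``endpoint``, ``group``, ``n_exposed``,
    ``n_affected``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"concentration", "endpoint", "group", "n_exposed", "n_affected"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if (t["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        if ((t["n_affected"] < 0) | (t["n_affected"] > t["n_exposed"])).any():
            raise ValueError("need 0 <= n_affected <= n_exposed")

    def incidence(self) -> pd.DataFrame:
        out = self.table.copy()
        out["incidence"] = out["n_affected"] / out["n_exposed"]
        return out


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth concentration-response curve for one simulated gene.

    The log2 fold change follows a Hill curve
    ``emax * d**hill_n / (ec50**hill_n + d**hill_n)``; counts are negative
    binomial with ``variance = mu + dispersion * mu**2``.
    """

    gene_id: str
    klass: str  # ahr_module | sensitive | high_only | null
    emax: float  # log2FC units
    ec50: float  # µM
    hill_n: float
    baseline_mean: float  # counts
    dispersion: float  # NB alpha
    module_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.klass not in {"ahr_module", "sensitive", "high_only", "null"}:
            raise ValueError(f"unknown gene class {self.klass!r}")
        if self.klass == "null" and self.emax != 0:
            raise ValueError("null genes must have emax = 0")
        if self.ec50 <= 0 or self.hill_n <= 0:
            raise ValueError("ec50 and hill_n must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")


@dataclass(frozen=True)
class PhenotypeTruth:
    """Ground-truth log-logistic teratogenicity curve.

    Defaults place the half-maximal incidence at 16.5 µM with slope 2, so the
    10%-added-risk benchmark concentration is 16.5/sqrt(9) = 5.5 µM.
    """

    ec50: float = 16.5  # µM
    hill_slope: float = 2.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill_slope <= 0:
            raise ValueError("ec50 and hill_slope must be positive")
        if not (0.0 <= self.background < 1.0):
            raise ValueError("background must be in [0, 1)")

    def incidence(self, d) -> np.ndarray:
        """P(affected) at concentration(s) ``d``."""
        d = np.asarray(d, dtype=float)
        with np.errstate(divide="ignore"):
            p = self.background + (1.0 - self.background) / (
                1.0 + (self.ec50 / np.where(d > 0, d, np.nan)) ** self.hill_slope
            )
        return np.where(d > 0, p, self.background)


@dataclass
class DoseResponseFitRecord:
    """One fitted parametric concentration-response model for one gene."""

    gene_id: str
    family: str
    params: dict = field(default_factory=dict)
    aic: float = np.inf
    gof_p: float = np.nan
    loglik: float = np.nan
    residual_sd: float = np.nan
    pooled_sd: float = np.nan  # within-group pure-error SD (constant variance)
    bmc: Optional[float] = None
    bmdl: Optional[float] = None
    bmdu: Optional[float] = None
    hill_flagged: bool = False
    selected: bool = False
    removed_above_max: bool = False
    converged: bool = True

    def to_dict(self) -> dict:
        return asdict(self)
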