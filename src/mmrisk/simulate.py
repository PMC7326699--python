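"""Synthetic multi-cohort survival + expression data with known planted structure.

Emulates the shape of a multi-study newly-diagnosed myeloma resource: several
cohorts of 74-650 patients, each with a log-scale gene-expression matrix
(genes x patients), clinical covariates (age, ISS stage, sex, t(4;14) status)
and right-censored progression-free / overall survival in months.

The generating model is a Weibull proportional-hazards law for progression:

    h(t | x) = h0(t) * exp(eta),
    eta = beta_age * (age - mean)/10 + beta_iss * (iss - 2)
          + sum_g beta_g * z_g,

where z_g is the standardized (generating-scale) expression of each planted
prognostic gene.  Overall survival is progression time plus an independent
exponential increment, so PFS events always outnumber OS events.  Censoring is
independent uniform on (0, c_max) with c_max solved numerically so the expected
censored fraction matches ``censor_rate``.

Two genes are "designated": an MMSET-like gene whose expression is shifted up
by ``mmset_shift`` log-units in t(4;14)-positive patients, and a PHF19-like
gene.  In translocation-negative patients the two are coupled through a shared
latent factor so their population Pearson correlation equals
``within_negative_corr`` — mirroring the pattern where the correlation is
present only without the translocation.

All randomness flows from a single master seed; each cohort draws from its own
``numpy.random.SeedSequence`` spawn key, so cohorts are independent and
order-insensitive, and identical (config, cohort_index) pairs are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "simulate_challenge",
]

#: Per-cohort patient counts of the eight studies the generator emulates.
DEFAULT_COHORT_SIZES = (147, 559, 636, 282, 241, 215, 74, 293)

CLINICAL_COLUMNS = ("age", "iss", "sex", "t414")
SURVIVAL_COLUMNS = ("pfs_months", "pfs_event", "os_months", "os_event")


@dataclass(frozen=True)
class PlantedEffect:
    """A prognostic gene: log hazard ratio per 1 SD of its expression."""

    gene_index: int
    log_hazard_per_sd: float


def _default_planted() -> tuple[PlantedEffect, ...]:
    # PHF19-like gene (index 1) carries the strong effect; MMSET-like (index 0)
    # a moderate one.
    return (PlantedEffect(1, 0.7), PlantedEffect(0, 0.3))


@dataclass
class SimulationConfig:
    """Study conditions for a simulated multi-cohort challenge.

    Defaults emulate an eight-study resource: cohort sizes 74-636, ISS
    distribution (0.30, 0.30, 0.40), median PFS near 22 months (Weibull scale
    30 months, shape 1.2), 20% right-censoring, t(4;14) prevalence 15%.
    """

    n_cohorts: int = 8
    patients_per_cohort: Sequence[int] = DEFAULT_COHORT_SIZES
    n_genes: int = 1000
    planted_effects: Sequence[PlantedEffect] = field(default_factory=_default_planted)
    age_mean_sd: tuple[float, float] = (65.0, 10.0)
    iss_probs: tuple[float, float, float] = (0.30, 0.30, 0.40)
    translocation_prob: float = 0.15
    mmset_shift: float = 2.0
    within_negative_corr: float = 0.42
    baseline_hazard_scale: float = 30.0  # months
    baseline_hazard_shape: float = 1.2  # Weibull shape
    beta_age: float = 0.25  # log hazard per 10 years
    beta_iss: float = 0.35  # log hazard per ISS stage
    censor_rate: float = 0.20
    cohort_shift_sd: float = 0.30  # per-cohort, per-gene location shift (log-units)
    os_increment_mean_months: float = 12.0
    mmset_gene_index: int = 0
    phf19_gene_index: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts <= 0:
            raise ConfigError("n_cohorts must be positive")
        if len(self.patients_per_cohort) < self.n_cohorts:
            raise ConfigError(
                f"patients_per_cohort has length {len(self.patients_per_cohort)}, "
                f"need n_cohorts={self.n_cohorts}"
            )
        if any(n <= 0 for n in self.patients_per_cohort):
            raise ConfigError("patients_per_cohort entries must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if abs(sum(self.iss_probs) - 1.0) > 1e-9:
            raise ConfigError("iss_probs must sum to 1 within 1e-9")
        for p in (*self.iss_probs, self.translocation_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if not -1.0 <= self.within_negative_corr <= 1.0:
            raise ConfigError("within_negative_corr must lie in [-1, 1]")
        if self.baseline_hazard_scale <= 0 or self.baseline_hazard_shape <= 0:
            raise ConfigError("Weibull scale and shape must be positive")
        for idx in (self.mmset_gene_index, self.phf19_gene_index):
            if not 0 <= idx < self.n_genes:
                raise ConfigError(f"designated gene index {idx} out of range")
        if self.mmset_gene_index == self.phf19_gene_index:
            raise ConfigError("mmset_gene_index and phf19_gene_index must differ")
        for eff in self.planted_effects:
            if not 0 <= eff.gene_index < self.n_genes:
                raise ConfigError(
                    f"planted gene_index {eff.gene_index} outside [0, {self.n_genes})"
                )

    def gene_ids(self) -> list[str]:
        ids = [f"G{i:04d}" for i in range(self.n_genes)]
        ids[self.mmset_gene_index] = "MMSET"
        ids[self.phf19_gene_index] = "PHF19"
        return ids

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["patients_per_cohort"] = list(self.patients_per_cohort)
        d["planted_effects"] = [dataclasses.asdict(e) for e in self.planted_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["planted_effects"] = [PlantedEffect(**e) for e in d.get("planted_effects", [])]
        for key in ("age_mean_sd", "iss_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    """One study: aligned expression matrix, clinical table and survival table.

    ``expression`` is genes x patients (log scale); ``clinical`` and
    ``survival`` are patient-indexed DataFrames with columns
    (age, iss, sex, t414) and (pfs_months, pfs_event, os_months, os_event).
    """

    cohort_id: str
    expression: pd.DataFrame
    clinical: pd.DataFrame
    survival: pd.DataFrame

    def validate(self) -> None:
        pids = list(self.expression.columns)
        if len(set(pids)) != len(pids):
            raise ConfigError(f"duplicate patient ids in cohort {self.cohort_id}")
        if list(self.clinical.index) != pids or list(self.survival.index) != pids:
            raise ConfigError(
                f"cohort {self.cohort_id}: expression, clinical and survival "
                "patients are not aligned"
            )
        if (self.survival[["pfs_months", "os_months"]].to_numpy() < 0).any():
            raise ConfigError(f"cohort {self.cohort_id}: negative survival time")

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.expression.columns)

    def equals_within(self, other: "Cohort", tol: float = 1e-9) -> bool:
        """Numeric equality within ``tol``; exact on ids and categorical fields."""
        if self.cohort_id != other.cohort_id:
            return False
        if self.gene_ids != other.gene_ids or self.patient_ids != other.patient_ids:
            return False
        if not np.allclose(self.expression.to_numpy(), other.expression.to_numpy(),
                           atol=tol, rtol=0):
            return False
        if not np.allclose(self.survival.to_numpy(float), other.survival.to_numpy(float),
                           atol=tol, rtol=0):
            return False
        a, b = self.clinical, other.clinical
        return (
            bool(np.allclose(a["age"].to_numpy(), b["age"].to_numpy(), atol=tol, rtol=0))
            and a["iss"].tolist() == b["iss"].tolist()
            and a["sex"].tolist() == b["sex"].tolist()
            and a["t414"].astype(bool).tolist() == b["t414"].astype(bool).tolist()
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _gene_panel(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene location/scale, drawn once per challenge (shared by cohorts)."""
    rng = _rng(config.seed, 0)
    means = rng.normal(8.0, 1.5, config.n_genes)
    sds = rng.uniform(0.5, 1.5, config.n_genes)
    return means, sds


def _censoring_times(rng: np.random.Generator, event_times: np.ndarray,
                     censor_rate: float) -> np.ndarray:
    """Uniform(0, c_max) censoring with c_max solved so that the expected
    censored fraction equals ``censor_rate``.

    P(censored_i) = P(C < T_i) = min(T_i / c_max, 1); solve the mean for c_max.
    """
    n = event_times.shape[0]
    if censor_rate == 0.0:
        return np.full(n, np.inf)

    def expected_censored(c_max: float) -> float:
        return float(np.mean(np.minimum(event_times / c_max, 1.0))) - censor_rate

    hi = float(event_times.max()) / censor_rate + 1.0
    lo = min(1e-9, float(event_times.min()) / 2 + 1e-12)
    c_max = brentq(expected_censored, lo, hi, xtol=1e-10)
    return rng.uniform(0.0, c_max, n)


def simulate_cohort(config: SimulationConfig, cohort_index: int) -> Cohort:
    """Generate one cohort; bit-identical for identical (config, cohort_index)."""
    config.validate()
    if not 0 <= cohort_index < config.n_cohorts:
        raise ConfigError(
            f"cohort_index {cohort_index} outside [0, {config.n_cohorts})"
        )
    gene_means, gene_sds = _gene_panel(config)
    rng = _rng(config.seed, 1, cohort_index)

    n = int(config.patients_per_cohort[cohort_index])
    cohort_id = f"C{cohort_index:02d}"
    patient_ids = [f"{cohort_id}-P{j:04d}" for j in range(n)]

    age_mean, age_sd = config.age_mean_sd
    age = np.clip(rng.normal(age_mean, age_sd, n), 25.0, 95.0)
    iss = rng.choice(np.array([1, 2, 3]), size=n, p=np.asarray(config.iss_probs))
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    t414 = rng.random(n) < config.translocation_prob

    z = rng.standard_normal((config.n_genes, n))
    # couple the designated genes through a shared latent factor in
    # translocation-negative patients only
    mi, pi = config.mmset_gene_index, config.phf19_gene_index
    rho = config.within_negative_corr
    latent = rng.standard_normal(n)
    neg = ~t414
    a, b = np.sqrt(abs(rho)), np.sqrt(1.0 - abs(rho))
    z[mi, neg] = a * latent[neg] + b * z[mi, neg]
    z[pi, neg] = np.sign(rho) * a * latent[neg] + b * z[pi, neg]

    shift = rng.normal(0.0, config.cohort_shift_sd, config.n_genes)
    loc = gene_means + shift
    expr = loc[:, None] + gene_sds[:, None] * z
    expr[mi] += config.mmset_shift * t414

    # standardized (generating-scale) expression drives the hazard, so the
    # t(4;14) shift of the MMSET-like gene feeds into any planted MMSET effect
    x_std = (expr - loc[:, None]) / gene_sds[:, None]
    eta = (config.beta_age * (age - age_mean) / 10.0
           + config.beta_iss * (iss.astype(float) - 2.0))
    for eff in config.planted_effects:
        eta = eta + eff.log_hazard_per_sd * x_std[eff.gene_index]

    u = rng.uniform(size=n)
    shape, scale = config.baseline_hazard_shape, config.baseline_hazard_scale
    t_prog = scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / shape)
    t_death = t_prog + rng.exponential(config.os_increment_mean_months, n)
    c = _censoring_times(rng, t_prog, config.censor_rate)

    survival = pd.DataFrame(
        {
            "pfs_months": np.minimum(t_prog, c),
            "pfs_event": (t_prog <= c).astype(int),
            "os_months": np.minimum(t_death, c),
            "os_event": (t_death <= c).astype(int),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    clinical = pd.DataFrame(
        {"age": age, "iss": iss.astype(int), "sex": sex, "t414": t414},
        index=pd.Index(patient_ids, name="patient_id"),
    )
    expression = pd.DataFrame(
        expr, index=pd.Index(config.gene_ids(), name="gene_id"), columns=patient_ids
    )
    cohort = Cohort(cohort_id, expression, clinical, survival)
    cohort.validate()
    return cohort


def simulate_challenge(
    config: SimulationConfig, n_train: int, n_validation: int
) -> tuple[list[Cohort], list[Cohort]]:
    """Split the configured cohorts into disjoint training / validation lists."""
    config.validate()
    if n_train < 0 or n_validation < 0 or n_train + n_validation != config.n_cohorts:
        raise ConfigError(
            f"n_train + n_validation must equal n_cohorts={config.n_cohorts}, "
            f"got {n_train} + {n_validation}"
        )
    cohorts = [simulate_cohort(config, i) for i in range(config.n_cohorts)]
    return cohorts[:n_train], cohorts[n_train:]
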