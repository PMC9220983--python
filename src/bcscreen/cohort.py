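"""Synthetic life-history generation for a 1970 birth cohort of women.

This is the "population demographics" plus "natural history inputs" layer of
the simulator.  Each woman receives an other-cause death age drawn from a
life table and, with probability ``lifetime_bc_risk``, a single breast tumor.
A tumor carries:

* an onset age, at which it has diameter 0.01 cm;
* an exponential growth rate (diameter doubles every ``ln 2 / rate`` years);
* unique threshold diameters for clinical diagnosis and fatality, plus a
  detectability quantile that each screening scenario maps through its own
  Weibull to obtain the screen-detectability diameter ``d_screen``;
* optionally a ductal carcinoma in situ (DCIS) pre-invasive phase with a
  dwell time and one of three fates: regress, progress to invasive disease,
  or surface clinically as DCIS.

The cohort is stored as a structure of arrays for speed; indexing yields
:class:`LifeHistory` records for inspection and unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .config import (
    ConfigError,
    Distribution,
    DomainError,
    Exponential,
    Lognormal,
    TruncNormal,
    distribution_from_dict,
    substream,
)

BIRTH_YEAR = 1970
ONSET_DIAMETER = 0.01  # cm; diameter of every tumor at onset
MAX_AGE = 110.0

# DCIS fate codes (int8); NOT_DCIS marks invasive-from-onset tumors and
# tumor-free women.
FATE_NOT_DCIS = -1
FATE_REGRESS = 0
FATE_PROGRESS = 1
FATE_CLINICAL_DCIS = 2

FATE_NAMES = {FATE_REGRESS: "regress", FATE_PROGRESS: "progress_to_invasive", FATE_CLINICAL_DCIS: "clinical_dcis"}


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Inputs of the natural-history model.

    Defaults are calibrated so that the comparator screening test (median
    detection size 1.21 cm, DCIS sensitivity 91%, biennial 50-74) yields a
    screen-detected share of cancers near 89% for DCIS and ~74% combined;
    they are a stylised stand-in for a registry-calibrated parameter set, not
    a fit to registry data.
    """

    lifetime_bc_risk: float = 0.17
    onset_age_distribution: Distribution = TruncNormal(mean=57.0, sd=10.0, low=30.0, high=100.0)
    growth_rate_distribution: Distribution = Lognormal(median=0.465, sigma=0.25)
    detect_threshold_shape: float = 2.0
    clinical_diameter_distribution: Distribution = Lognormal(median=2.6, sigma=0.30)
    fatal_diameter_distribution: Distribution = Lognormal(median=2.2, sigma=0.60)
    dcis_onset_fraction: float = 0.22
    dcis_fate_probs: tuple[float, float, float] = (0.40, 0.38, 0.22)  # regress, progress, clinical
    dcis_dwell_distribution: Distribution = Exponential(mean=2.1)
    survival_after_fatal_distribution: Distribution = Exponential(mean=3.0)
    life_table: Optional[pd.DataFrame] = None  # columns: age, hazard; default shipped fixture
    stage_thresholds: tuple[float, float] = (2.0, 5.0)  # local/regional and regional/distant, cm

    def validate(self) -> None:
        for name in ("lifetime_bc_risk", "dcis_onset_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}: probability must lie in [0, 1], got {v}")
        if not (self.detect_threshold_shape > 0):
            raise ConfigError(f"detect_threshold_shape: must be > 0, got {self.detect_threshold_shape}")
        probs = np.asarray(self.dcis_fate_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise ConfigError(f"dcis_fate_probs: need 3 non-negative values, got {self.dcis_fate_probs}")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError(f"dcis_fate_probs: must sum to 1 within 1e-12, got sum {probs.sum()!r}")
        for name in (
            "onset_age_distribution",
            "growth_rate_distribution",
            "clinical_diameter_distribution",
            "fatal_diameter_distribution",
            "dcis_dwell_distribution",
            "survival_after_fatal_distribution",
        ):
            getattr(self, name).validate(name)
        lo, hi = self.stage_thresholds
        if not (0 < lo < hi):
            raise ConfigError(f"stage_thresholds: need 0 < local < distant bound, got {self.stage_thresholds}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "NaturalHistoryParams":
        kwargs = {}
        for key, value in cfg.items():
            if key.endswith("_distribution"):
                kwargs[key] = distribution_from_dict(value, key)
            elif key == "dcis_fate_probs":
                kwargs[key] = tuple(float(v) for v in value)
            elif key == "stage_thresholds":
                kwargs[key] = tuple(float(v) for v in value)
            elif key == "life_table":
                kwargs[key] = load_life_table(value) if isinstance(value, str) else value
            else:
                kwargs[key] = float(value)
        params = cls(**kwargs)
        params.validate()
        return params


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


def gompertz_makeham_life_table(
    makeham: float = 3.0e-4,
    gompertz_b: float = 1.2e-5,
    gompertz_theta: float = 0.105,
    max_age: int = int(MAX_AGE),
) -> pd.DataFrame:
    """Annual other-cause mortality hazards for a US-1970-like female cohort.

    hazard(age) = makeham + b * exp(theta * age).  The default constants give
    a life expectancy near 80 years with essentially nobody surviving past
    ``max_age``; the table is a stand-in for a national cohort life table.
    """
    ages = np.arange(0, max_age + 1)
    hazard = makeham + gompertz_b * np.exp(gompertz_theta * ages)
    return pd.DataFrame({"age": ages, "hazard": hazard})


def load_life_table(path) -> pd.DataFrame:
    """Read a 2-column CSV life table (age, annual other-cause hazard)."""
    table = pd.read_csv(path)
    missing = {"age", "hazard"} - set(table.columns)
    if missing:
        raise ConfigError(f"life_table: missing columns {sorted(missing)}")
    if (table["hazard"] < 0).any():
        raise ConfigError("life_table: hazards must be non-negative")
    return table[["age", "hazard"]].reset_index(drop=True)


def default_life_table() -> pd.DataFrame:
    """The shipped life-table fixture (synthetic Gompertz-Makeham hazards)."""
    with resources.files("bcscreen.data").joinpath("life_table.csv").open("rb") as fh:
        return load_life_table(fh)


def sample_death_ages(life_table: pd.DataFrame, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample other-cause death ages by inverting the life-table survival curve.

    The hazard is piecewise constant on single years of age; everyone still
    alive at the end of the table dies within its final year.
    """
    hazard = life_table["hazard"].to_numpy(dtype=float)
    ages = life_table["age"].to_numpy(dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(hazard)])  # cumulative hazard at year starts
    u = rng.uniform(size=n)
    target = -np.log1p(-u)
    target = np.minimum(target, cum[-1] - 1e-12)  # force death within the table
    idx = np.searchsorted(cum, target, side="right") - 1
    idx = np.clip(idx, 0, len(hazard) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (target - cum[idx]) / hazard[idx]
    frac = np.clip(np.nan_to_num(frac), 0.0, 1.0)
    # survivors of the final tabulated year are assigned its closing age
    return np.minimum(ages[idx] + frac, ages[-1])


# ---------------------------------------------------------------------------
# Weibull screen-detectability thresholds
# ---------------------------------------------------------------------------


def weibull_scale(median_size: float, shape: float) -> float:
    """Weibull scale such that the distribution's median equals ``median_size``."""
    if not (median_size > 0):
        raise ConfigError(f"median_size: must be > 0, got {median_size}")
    if not (shape > 0):
        raise ConfigError(f"shape: must be > 0, got {shape}")
    return median_size / math.log(2) ** (1.0 / shape)


def detection_threshold_from_quantile(q, median_size: float, shape: float):
    """Map uniform quantiles to Weibull detectability diameters (inverse CDF)."""
    scale = weibull_scale(median_size, shape)
    return scale * (-np.log1p(-np.asarray(q))) ** (1.0 / shape)


def sample_detection_threshold(
    median_size: float, shape: float, stream: np.random.Generator, size: int | None = None
):
    """Draw screen-detectability diameters from the Weibull with the given median."""
    q = stream.uniform(size=size)
    return detection_threshold_from_quantile(q, median_size, shape)


# ---------------------------------------------------------------------------
# Cohort container and record views
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TumorBiology:
    """Per-tumor natural-history attributes (record view of one cohort row)."""

    age_at_onset: float
    growth_rate: float
    d_clinical: float
    d_fatal: float
    starts_as_dcis: bool
    dcis_fate: str | None
    dcis_dwell: float
    survival_after_fatal: float
    detect_quantile: float
    d_screen: float | None = None  # filled per screening scenario
    onset_diameter: float = ONSET_DIAMETER


@dataclass(frozen=True)
class LifeHistory:
    """One simulated woman."""

    woman_id: int
    age_other_cause_death: float
    tumor: TumorBiology | None
    birth_year: int = BIRTH_YEAR


@dataclass
class Cohort:
    """Structure-of-arrays cohort; tumor fields are NaN where there is no tumor."""

    seed: int
    params: NaturalHistoryParams
    age_other_cause_death: np.ndarray
    has_tumor: np.ndarray
    age_at_onset: np.ndarray
    growth_rate: np.ndarray
    detect_quantile: np.ndarray
    d_clinical: np.ndarray
    d_fatal: np.ndarray
    starts_as_dcis: np.ndarray
    dcis_fate: np.ndarray
    dcis_dwell: np.ndarray
    survival_after_fatal: np.ndarray
    birth_year: int = BIRTH_YEAR

    def __len__(self) -> int:
        return self.age_other_cause_death.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    @property
    def invasive_start_age(self) -> np.ndarray:
        """Age at which exponential invasive growth starts (NaN if never invasive).

        Invasive-from-onset tumors start at onset; progressing DCIS starts
        after its dwell; regressing and clinically surfacing DCIS never
        develop an invasive component.
        """
        start = np.where(self.has_tumor, self.age_at_onset, np.nan)
        start = np.where(self.dcis_fate == FATE_PROGRESS, self.age_at_onset + self.dcis_dwell, start)
        never = self.starts_as_dcis & np.isin(self.dcis_fate, (FATE_REGRESS, FATE_CLINICAL_DCIS))
        return np.where(never, np.nan, start)

    def __getitem__(self, i: int) -> LifeHistory:
        i = int(i)
        tumor = None
        if self.has_tumor[i]:
            fate = int(self.dcis_fate[i])
            tumor = TumorBiology(
                age_at_onset=float(self.age_at_onset[i]),
                growth_rate=float(self.growth_rate[i]),
                d_clinical=float(self.d_clinical[i]),
                d_fatal=float(self.d_fatal[i]),
                starts_as_dcis=bool(self.starts_as_dcis[i]),
                dcis_fate=FATE_NAMES.get(fate),
                dcis_dwell=float(self.dcis_dwell[i]),
                survival_after_fatal=float(self.survival_after_fatal[i]),
                detect_quantile=float(self.detect_quantile[i]),
            )
        return LifeHistory(
            woman_id=i,
            age_other_cause_death=float(self.age_other_cause_death[i]),
            tumor=tumor,
        )

    def __iter__(self) -> Iterator[LifeHistory]:
        return (self[i] for i in range(len(self)))

    def to_frame(self) -> pd.DataFrame:
        """One row per woman; the documented CSV export of the cohort."""
        fate = np.array(["", "regress", "progress_to_invasive", "clinical_dcis"], dtype=object)[
            np.clip(self.dcis_fate, -1, 2) + 1
        ]
        return pd.DataFrame(
            {
                "woman_id": np.arange(len(self)),
                "birth_year": self.birth_year,
                "age_other_cause_death": self.age_other_cause_death,
                "has_tumor": self.has_tumor,
                "age_at_onset": self.age_at_onset,
                "growth_rate": self.growth_rate,
                "detect_quantile": self.detect_quantile,
                "d_clinical": self.d_clinical,
                "d_fatal": self.d_fatal,
                "starts_as_dcis": self.starts_as_dcis,
                "dcis_fate": fate,
                "dcis_dwell": self.dcis_dwell,
                "survival_after_fatal": self.survival_after_fatal,
            }
        )


def sample_life_histories(n: int, params: NaturalHistoryParams, seed: int) -> Cohort:
    """Generate ``n`` seeded life histories with the configured natural history.

    Identical ``(n, params, seed)`` reproduce identical cohorts bitwise.  All
    per-tumor attributes are drawn for every woman (then masked), so the
    draws consumed by one woman do not depend on which other women have
    tumors.
    """
    if n < 1:
        raise ConfigError(f"n: need at least one woman, got {n}")
    params.validate()
    life_table = params.life_table if params.life_table is not None else default_life_table()

    ocd = sample_death_ages(life_table, n, substream(seed, "other_cause"))

    rng_onset = substream(seed, "onset")
    has_tumor = rng_onset.uniform(size=n) < params.lifetime_bc_risk
    onset_age = params.onset_age_distribution.sample(rng_onset, n)
    starts_as_dcis = rng_onset.uniform(size=n) < params.dcis_onset_fraction
    u_fate = rng_onset.uniform(size=n)
    edges = np.cumsum(params.dcis_fate_probs)
    fate = np.searchsorted(edges, u_fate, side="right").astype(np.int8)
    fate = np.clip(fate, 0, 2)
    dwell = params.dcis_dwell_distribution.sample(rng_onset, n)

    rng_thr = substream(seed, "thresholds")
    growth = params.growth_rate_distribution.sample(rng_thr, n)
    detect_q = rng_thr.uniform(size=n)
    d_clin = np.maximum(params.clinical_diameter_distribution.sample(rng_thr, n), ONSET_DIAMETER * 1.0001)
    d_fatal = np.maximum(params.fatal_diameter_distribution.sample(rng_thr, n), ONSET_DIAMETER * 1.0001)

    surv = params.survival_after_fatal_distribution.sample(substream(seed, "survival"), n)

    nan = np.nan
    mask = has_tumor
    dcis_mask = mask & starts_as_dcis
    return Cohort(
        seed=seed,
        params=params,
        age_other_cause_death=ocd,
        has_tumor=mask,
        age_at_onset=np.where(mask, onset_age, nan),
        growth_rate=np.where(mask, growth, nan),
        detect_quantile=np.where(mask, detect_q, nan),
        d_clinical=np.where(mask, d_clin, nan),
        d_fatal=np.where(mask, d_fatal, nan),
        starts_as_dcis=dcis_mask,
        dcis_fate=np.where(dcis_mask, fate, FATE_NOT_DCIS).astype(np.int8),
        dcis_dwell=np.where(dcis_mask, dwell, nan),
        survival_after_fatal=np.where(mask, surv, nan),
    )


# ---------------------------------------------------------------------------
# Growth curve
# ---------------------------------------------------------------------------


def diameter_at_age(tumor: TumorBiology, age: float) -> float:
    """Tumor diameter (cm) at ``age`` under exponential growth from 0.01 cm.

    For progressing DCIS the growth clock starts when the invasive phase
    begins (onset + dwell).  Ages before the start of growth are a domain
    error.
    """
    start = tumor.age_at_onset
    if tumor.starts_as_dcis:
        if tumor.dcis_fate != "progress_to_invasive":
            raise DomainError("tumor never develops an invasive growth phase")
        start = tumor.age_at_onset + tumor.dcis_dwell
    if age < start:
        raise DomainError(f"age {age} precedes invasive growth start {start}")
    return ONSET_DIAMETER * math.exp(tumor.growth_rate * (age - start))


def age_at_diameter(tumor: TumorBiology, diameter: float) -> float:
    """Inverse of :func:`diameter_at_age`: age at which the tumor reaches ``diameter``."""
    if diameter < ONSET_DIAMETER:
        raise DomainError(f"diameter {diameter} below onset diameter {ONSET_DIAMETER}")
    start = tumor.age_at_onset
    if tumor.starts_as_dcis:
        if tumor.dcis_fate != "progress_to_invasive":
            raise DomainError("tumor never develops an invasive growth phase")
        start = tumor.age_at_onset + tumor.dcis_dwell
    return start + math.log(diameter / ONSET_DIAMETER) / tumor.growth_rate


def crossing_ages(cohort: Cohort, diameters: np.ndarray) -> np.ndarray:
    """Vectorised ages at which each invasive tumor reaches the given diameters.

    Returns NaN for women without an invasive growth phase.
    """
    start = cohort.invasive_start_age
    with np.errstate(invalid="ignore", divide="ignore"):
        return start + np.log(np.asarray(diameters) / ONSET_DIAMETER) / cohort.growth_rate
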