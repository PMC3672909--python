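"""Seeded synthetic-cohort generator.

Everything downstream of this module (biomarker preprocessing, exposure
metrics, reliability, determinants models) is exercised on data produced
here: a cohort of middle-aged women, each contributing one 24-hr urine
collection and, for a configurable fraction, a second collection 3-9
months later.  Urinary cadmium is generated from a log-normal
two-variance-component model,

    ln Cd_is = mu + sum_k beta_k (x_ik - xbar_k) + b_i + e_is ,

with a person-level random intercept ``b_i ~ N(0, sigma2_between)`` and
occasion noise ``e_is ~ N(0, sigma2_within)``.  Covariates enter centred
so that the geometric mean of the generated concentrations equals
``exp(mu_log_cd)`` regardless of which effects are switched on.

Geographic layers (road segments carrying annual average daily traffic,
point-source facilities with annual cadmium emissions, and a census-tract
air-concentration lookup) and food-frequency questionnaire responses are
generated alongside, on planar kilometre coordinates, so the exposure
metrics can be computed without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point

__all__ = [
    "GeneratorConfig",
    "RoadSegment",
    "Facility",
    "GeographyLayers",
    "default_covariate_effects",
    "generate_cohort",
    "generate_samples",
    "generate_geography",
    "generate_contaminant_table",
    "generate_ffq",
]

# Substream channels: each public generator derives its own Generator from
# (seed, channel) so stages are independently reproducible.
_CHANNEL = {"cohort": 0, "samples": 1, "geography": 2, "ffq": 3, "contaminants": 4}


def _rng(seed: int, channel: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _CHANNEL[channel]])


def default_covariate_effects() -> dict[str, float]:
    """Log-scale slopes used by default when generating ln U-Cd.

    Magnitudes correspond to percent changes per unit that are typical of
    determinants analyses in low-exposure female populations: +15% per
    0.1 g/L creatinine, +1.4%/year of age, +1.1%/pack-year, -4.6% per
    pregnancy, -16% per alcohol category, +0.2% per passive intensity-year
    (never-smokers), -1.5% per year since quitting (former smokers).
    Dietary and ambient environmental metrics carry no effect by default.
    """
    return {
        "creatinine": math.log(1.15) / 0.1,       # per g/L
        "age": math.log(1.014),                   # per year
        "pack_years": math.log(1.011),            # per pack-year
        "parity": math.log(0.954),                # per pregnancy
        "alcohol_category": math.log(0.84),       # per ordinal step
        "passive_intensity_years": math.log(1.002),
        "years_since_quit": math.log(0.985),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, in one seeded configuration.

    The defaults describe the study conditions the package analyses: 296
    women, 141 of whom (repeat_fraction ~ 0.476) provide a second 24-hr
    sample, log-scale between/within-person variance components
    0.216/0.221 (variance ratio ~ 1.0), geometric-mean urinary cadmium
    0.27 ug/L, assay limit of detection 0.1 ug/L.
    """

    n_participants: int = 296
    repeat_fraction: float = 141 / 296
    sigma2_between: float = 0.216
    sigma2_within: float = 0.221
    mu_log_cd: float = math.log(0.27)
    covariate_effects: Mapping[str, float] = field(default_factory=default_covariate_effects)
    lod: float = 0.1                      # ug/L
    interval_drift: float = 0.0           # log-scale drift per month between occasions
    seed: int = 0

    # --- creatinine and urine volume (per-sample dilution variables) ---
    creatinine_gm: float = 0.71           # g/L
    creatinine_log_sd: float = math.log(1.6)
    volume_gm: float = 1.7                # L/day
    volume_log_sd: float = math.log(1.35)

    # --- geography ---
    region_km: float = 60.0               # square study region side
    tract_km: float = 5.0                 # census-tract grid cell side
    n_facilities: int = 12
    road_fraction_near: float = 0.66      # fraction of residences with a road inside the buffer
    n_background_roads: int = 30
    air_range: tuple[float, float] = (0.05, 0.65)   # ng/m^3
    emissions_max_kg: float = 1760.0
    max_aadt_near: float = 90_000.0       # caps traffic density below 427,000 VKT/km^2
    max_aadt_background: float = 30_000.0

    # --- food-frequency questionnaire ---
    n_food_items: int = 20
    dietary_gm: float = math.sqrt(7.9 * 14.0)   # ug/day; quartiles ~ 7.9 and 14
    dietary_log_sd: float = math.log(14.0 / 7.9) / (2 * 0.6745)
    ffq_missing_fraction: float = 3 / 296
    portion_weights: Mapping[str, float] = field(
        default_factory=lambda: {"small": 0.5, "medium": 1.0, "large": 1.5}
    )

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must lie in [0, 1]")
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")
        if self.lod <= 0:
            raise ValueError("lod must be positive")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RoadSegment:
    geometry: LineString
    aadt: float   # vehicles/day, both directions


@dataclass(frozen=True)
class Facility:
    geometry: Point
    emissions_kg: float   # annual cadmium emissions


@dataclass
class GeographyLayers:
    roads: list[RoadSegment]
    facilities: list[Facility]
    air_by_tract: pd.DataFrame   # columns: tract_id, air_cd_ng_m3


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _tract_id(x: float, y: float, tract_km: float) -> str:
    return f"T{int(x // tract_km)}_{int(y // tract_km)}"


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw participant covariates with the marginals of the study cohort.

    Returns one row per participant: age ~ truncated normal (55, 12) on
    [31, 84]; 70% never smokers, former smokers with recorded (1997)
    years since quitting; passive-smoke intensity-years for never-smokers
    only; parity, alcohol category, breastfeeding, anthropometry, caloric
    intake, and a planar residence with its tract identifier.
    """
    config.validate()
    rng = _rng(config.seed, "cohort")
    n = config.n_participants

    age = stats.truncnorm.rvs(
        (31 - 55) / 12, (84 - 55) / 12, loc=55, scale=12, size=n, random_state=rng
    )
    height = rng.normal(163.0, 6.5, n)
    bmi = np.exp(rng.normal(math.log(26.0), 0.20, n)).clip(16, 61)
    weight = bmi * (height / 100.0) ** 2

    status = rng.choice(["never", "former", "current"], size=n, p=[0.70, 0.236, 0.064])
    pack_years = np.where(
        status == "never", 0.0, np.exp(rng.normal(math.log(8.0), 1.4, n)).clip(0.1, 61)
    )
    years_since_quit_1997 = np.where(
        status == "former", rng.uniform(1.0, 25.0, n), np.nan
    )
    passive = np.where(
        status == "never",
        np.exp(rng.normal(math.log(18.0), 1.15, n)).clip(0.0, 203.0),
        np.nan,
    )

    parity = rng.choice(
        [0, 1, 2, 3, 4, 5, 6], size=n, p=[0.26, 0.245, 0.245, 0.15, 0.05, 0.03, 0.02]
    )
    breastfeeding = rng.gamma(2.0, 1.6, n).clip(0.0, 9.0)
    alcohol = rng.choice([0, 1, 2], size=n, p=[0.32, 0.59, 0.09])
    oc_ever = rng.random(n) < 0.72
    hrt_ever = rng.random(n) < 0.48
    kcal = rng.normal(1900.0, 420.0, n).clip(700.0, 4800.0)

    x = rng.uniform(0.0, config.region_km, n)
    y = rng.uniform(0.0, config.region_km, n)
    tract = [_tract_id(xi, yi, config.tract_km) for xi, yi in zip(x, y)]

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": age,
            "height_cm": height,
            "weight_kg": weight,
            "parity": parity.astype(int),
            "breastfeeding_months": breastfeeding,
            "smoking_status": status,
            "pack_years": pack_years,
            "years_since_quit_1997": years_since_quit_1997,
            "passive_intensity_years": passive,
            "alcohol_category": alcohol.astype(int),
            "oc_ever": oc_ever,
            "hrt_ever": hrt_ever,
            "kcal_per_day": kcal,
            "x_km": x,
            "y_km": y,
            "tract_id": tract,
        }
    )


# ---------------------------------------------------------------------------
# urine samples
# ---------------------------------------------------------------------------

def _centered(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Centre values on their mean; outside ``mask`` the contribution is 0."""
    if mask is None:
        return values - np.nanmean(values)
    out = np.zeros_like(values, dtype=float)
    if mask.any():
        out[mask] = values[mask] - np.nanmean(values[mask])
    return out


def generate_samples(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Generate repeat 24-hr urine samples for a cohort.

    Every participant contributes occasion 1; a seeded subset of size
    ``round(repeat_fraction * n)`` contributes occasion 2 at an interval
    of 3, 6 or 9 months.  ln(cadmium) follows the centred mixed model in
    the module docstring; creatinine (g/L) and 24-hr volume (L/day) are
    log-normal with person- and occasion-level variation.  Values below
    the configured LOD are flagged (the raw draw is retained; LOD
    substitution is a preprocessing step, not a generation step).
    """
    config.validate()
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    rng = _rng(config.seed, "samples")
    n = len(cohort)

    n_repeat = int(round(config.repeat_fraction * n))
    repeat_ids = set(rng.permutation(cohort["participant_id"].to_numpy())[:n_repeat])

    b = rng.normal(0.0, math.sqrt(config.sigma2_between), n)
    # person-level components of the dilution variables (60/40 and 50/50
    # person/occasion splits of the total log variance)
    cr_person = rng.normal(0.0, math.sqrt(0.6) * config.creatinine_log_sd, n)
    vol_person = rng.normal(0.0, math.sqrt(0.5) * config.volume_log_sd, n)

    occasions = []
    for i, pid in enumerate(cohort["participant_id"]):
        occasions.append((i, pid, 1, 0))
        if pid in repeat_ids:
            occasions.append((i, pid, 2, int(rng.choice([3, 6, 9]))))

    m = len(occasions)
    e = rng.normal(0.0, math.sqrt(config.sigma2_within), m)
    cr_occ = rng.normal(0.0, math.sqrt(0.4) * config.creatinine_log_sd, m)
    vol_occ = rng.normal(0.0, math.sqrt(0.5) * config.volume_log_sd, m)

    idx = np.array([o[0] for o in occasions])
    creatinine = np.exp(math.log(config.creatinine_gm) + cr_person[idx] + cr_occ)
    volume = np.exp(math.log(config.volume_gm) + vol_person[idx] + vol_occ)

    # centred covariate contribution per sample
    eff = np.zeros(m)
    effects = dict(config.covariate_effects)
    never = (cohort["smoking_status"] == "never").to_numpy()
    former = (cohort["smoking_status"] == "former").to_numpy()
    person_terms = {
        "age": _centered(cohort["age"].to_numpy()),
        "pack_years": _centered(cohort["pack_years"].to_numpy()),
        "parity": _centered(cohort["parity"].to_numpy(dtype=float)),
        "alcohol_category": _centered(cohort["alcohol_category"].to_numpy(dtype=float)),
        "passive_intensity_years": _centered(
            cohort["passive_intensity_years"].to_numpy(), mask=never
        ),
        "years_since_quit": _centered(
            cohort["years_since_quit_1997"].to_numpy() + 3.0, mask=former
        ),
    }
    for name, beta in effects.items():
        if name == "creatinine":
            # theoretical mean of the log-normal creatinine draw
            cr_mean = config.creatinine_gm * math.exp(config.creatinine_log_sd**2 / 2)
            eff += beta * (creatinine - cr_mean)
        elif name in person_terms:
            eff += beta * person_terms[name][idx]
        else:
            raise ValueError(f"unknown covariate effect {name!r}")

    interval = np.array([o[3] for o in occasions], dtype=float)
    log_cd = config.mu_log_cd + eff + b[idx] + e + config.interval_drift * interval
    cadmium = np.exp(log_cd)

    return pd.DataFrame(
        {
            "participant_id": [o[1] for o in occasions],
            "occasion": [o[2] for o in occasions],
            "interval_months": interval.astype(int),
            "cadmium_ugL": cadmium,
            "below_lod": cadmium < config.lod,
            "creatinine_gL": creatinine,
            "volume_L": volume,
        }
    )


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def generate_geography(cohort: pd.DataFrame, config: GeneratorConfig) -> GeographyLayers:
    """Generate road, facility and tract-air layers on planar km coordinates.

    Roads: for a seeded ``road_fraction_near`` subset of residences one
    segment passes within 250 m (so most, but not all, participants have
    nonzero traffic density), plus sparse background segments.  AADT caps
    keep every 300-m-buffer traffic density below 427,000 VKT/km^2.
    Facilities: a handful of point sources with heavy-tailed annual
    emissions capped at ``emissions_max_kg``.  Air: every tract of the
    grid covering the region gets a concentration inside ``air_range``.
    """
    config.validate()
    rng = _rng(config.seed, "geography")

    roads: list[RoadSegment] = []
    near = rng.random(len(cohort)) < config.road_fraction_near
    for (xi, yi), is_near in zip(cohort[["x_km", "y_km"]].to_numpy(), near):
        if not is_near:
            continue
        theta = rng.uniform(0, 2 * math.pi)
        offset = rng.uniform(0.0, 0.25)
        # segment through a point `offset` km from the residence
        px = xi + offset * math.cos(theta)
        py = yi + offset * math.sin(theta)
        phi = rng.uniform(0, math.pi)
        half = rng.uniform(0.25, 1.0)
        p0 = (px - half * math.cos(phi), py - half * math.sin(phi))
        p1 = (px + half * math.cos(phi), py + half * math.sin(phi))
        aadt = float(np.exp(rng.normal(math.log(6000.0), 1.3)).clip(100, config.max_aadt_near))
        roads.append(RoadSegment(LineString([p0, p1]), aadt))
    for _ in range(config.n_background_roads):
        cx, cy = rng.uniform(0, config.region_km, 2)
        phi = rng.uniform(0, math.pi)
        half = rng.uniform(0.5, 2.0)
        p0 = (cx - half * math.cos(phi), cy - half * math.sin(phi))
        p1 = (cx + half * math.cos(phi), cy + half * math.sin(phi))
        aadt = float(np.exp(rng.normal(math.log(4000.0), 1.0)).clip(100, config.max_aadt_background))
        roads.append(RoadSegment(LineString([p0, p1]), aadt))

    facilities = [
        Facility(
            Point(rng.uniform(0, config.region_km), rng.uniform(0, config.region_km)),
            float(np.exp(rng.normal(math.log(0.01), 3.5)).clip(1e-4, config.emissions_max_kg)),
        )
        for _ in range(config.n_facilities)
    ]

    n_cells = int(math.ceil(config.region_km / config.tract_km))
    lo, hi = config.air_range
    records = []
    for ix in range(n_cells):
        for iy in range(n_cells):
            air = float(np.exp(rng.normal(math.log(0.15), 0.5)).clip(lo, hi))
            records.append({"tract_id": f"T{ix}_{iy}", "air_cd_ng_m3": air})
    air_by_tract = pd.DataFrame(records)

    return GeographyLayers(roads=roads, facilities=facilities, air_by_tract=air_by_tract)


# ---------------------------------------------------------------------------
# food-frequency questionnaire
# ---------------------------------------------------------------------------

def generate_contaminant_table(config: GeneratorConfig) -> pd.DataFrame:
    """A market-basket style table of cadmium and energy per medium serving."""
    rng = _rng(config.seed, "contaminants")
    k = config.n_food_items
    cd = rng.uniform(0.4, 4.0, k)                  # ug per medium serving
    kcal = cd * rng.uniform(120.0, 260.0, k)       # kcal per medium serving
    return pd.DataFrame(
        {
            "item_id": [f"F{j:03d}" for j in range(k)],
            "cd_per_medium_serving": cd,
            "kcal_per_medium_serving": kcal,
        }
    )


def generate_ffq(
    cohort: pd.DataFrame,
    contaminant_table: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Generate item-level questionnaire responses.

    Each responding participant is assigned a total dietary cadmium target
    drawn log-normally (geometric mean ``dietary_gm``, log-sd
    ``dietary_log_sd``, so the implied intake quartiles sit near 7.9 and
    14 ug/day), split across items by a Dirichlet draw, and converted to
    servings/day given a random portion-size category per item.  A small
    seeded fraction of participants returns no questionnaire.
    """
    config.validate()
    if len(contaminant_table) == 0:
        raise ValueError("contaminant table must be nonempty")
    rng = _rng(config.seed, "ffq")
    items = contaminant_table["item_id"].to_numpy()
    cd = contaminant_table["cd_per_medium_serving"].to_numpy()
    portions = np.array(["small", "medium", "large"])
    pw = config.portion_weights

    n = len(cohort)
    missing = rng.random(n) < config.ffq_missing_fraction
    rows = []
    for i, pid in enumerate(cohort["participant_id"]):
        if missing[i]:
            continue
        total = math.exp(rng.normal(math.log(config.dietary_gm), config.dietary_log_sd))
        w = rng.dirichlet(np.full(len(items), 1.5))
        portion = rng.choice(portions, size=len(items), p=[0.25, 0.5, 0.25])
        for j, item in enumerate(items):
            weight = pw[str(portion[j])]
            freq = total * w[j] / (weight * cd[j])
            rows.append(
                {
                    "participant_id": pid,
                    "item_id": item,
                    "frequency_per_day": freq,
                    "portion": portion[j],
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "item_id", "frequency_per_day", "portion"])
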