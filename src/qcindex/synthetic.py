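"""Synthetic GBD-shaped burden worlds with a known latent care-quality gradient.

The generator emulates the table shape of a single-cause GBD extract
(incidence, prevalence, deaths, YLLs, YLDs, DALYs by country, year, sex and
5-year age group, as counts and rates per 100 000) while making the ground
truth available: a latent care quality ``q`` in [0, 1] per country-year-sex
drives case fatality downward and survival duration upward, so every
downstream care-quality statistic can be checked against ``q``.

Generative model per (country c, year y, sex s, age band a):

* ``q``: Beta(2, 2) country baseline drifting upward by a per-country
  linear slope, clipped to [0, 1]; females offset by ``sex_quality_gap``.
* incidence rate ``I = I_c · profile(a)`` with ``I_c`` lognormal across
  countries and a fixed age profile rising with age (carcinoma-like).
* mortality-to-incidence ratio ``m = mir_max − (mir_max − mir_min)·q``;
  deaths ``D = I·m``.
* prevalent-case duration ``d = d_min + (d_max − d_min)·q`` years;
  prevalence ``P = I·d``.
* ``YLD = P · disability_weight``; ``YLL = D · remaining_life(a)``;
  ``DALY = YLL + YLD`` exactly.
* independent multiplicative lognormal(0, ``noise_sigma``) measurement
  noise on I, P and D; YLL/YLD/DALY are recomputed from the noisy D and P
  so the DALY identity survives the noise.

Counts come from rates through a fixed per-stratum population;
``both``-sex rows are exact sums of the sex-specific counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .gbd_tables import BurdenTable, format_age_label

#: WHO world-standard population shares (percent) by 5-year band.
WORLD_STANDARD_WEIGHTS = {
    "0-4": 8.86, "5-9": 8.69, "10-14": 8.60, "15-19": 8.47, "20-24": 8.22,
    "25-29": 7.93, "30-34": 7.61, "35-39": 7.15, "40-44": 6.59,
    "45-49": 6.04, "50-54": 5.37, "55-59": 4.55, "60-64": 3.72,
    "65-69": 2.96, "70-74": 2.21, "75-79": 1.52, "80-84": 0.91,
    "85-89": 0.44, "90-94": 0.15, "95 plus": 0.04,
}

#: the standard 5-year bands, 0-4 .. 90-94 plus the open-ended "95 plus"
DEFAULT_AGE_GROUPS: tuple[tuple[float, float], ...] = tuple(
    [(float(lo), float(lo + 5)) for lo in range(0, 95, 5)] + [(95.0, math.inf)]
)

SDI_CLASSES = ("low", "low-middle", "middle", "high-middle", "high")
INCOME_CLASSES = ("low", "lower-middle", "upper-middle", "high")


def _band_midpoint(lo: float, hi: float) -> float:
    return lo + 2.5 if math.isinf(hi) else (lo + hi) / 2.0


def default_remaining_life(age_groups) -> np.ndarray:
    """Reference-life-table-style expected remaining years per band.

    Linear decline from ~87 years at birth, floored at 2 years in the
    oldest bands; monotone non-increasing by construction.
    """
    mids = np.array([_band_midpoint(lo, hi) for lo, hi in age_groups])
    return np.maximum(87.0 - mids, 2.0)


def default_age_profile(age_groups) -> np.ndarray:
    """Relative incidence multiplier per band, mean 1, rising with age."""
    mids = np.array([_band_midpoint(lo, hi) for lo, hi in age_groups])
    raw = np.exp(0.05 * (mids - 40.0))
    return raw / raw.mean()


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults describe a 100-country, 1990–2017 world with mild (5%)
    multiplicative measurement noise, case fatality spanning 0.9 (worst
    care) to 0.1 (best care) and survival duration spanning 1 to 10 years.
    """

    n_countries: int = 100
    year_start: int = 1990
    year_end: int = 2017
    age_groups: tuple = DEFAULT_AGE_GROUPS
    seed: int = 0
    incidence_gm: float = 5.0          # geometric-mean rate per 100 000
    incidence_gsd: float = 0.5         # lognormal sigma across countries
    mir_bounds: tuple[float, float] = (0.1, 0.9)
    duration_bounds: tuple[float, float] = (1.0, 10.0)
    disability_weight: float = 0.3
    remaining_life: np.ndarray | None = None
    noise_sigma: float = 0.05
    sex_quality_gap: float = 0.0       # additive offset on q for females
    sex_gap_drift: float = 0.0         # per-year change of that offset
    quality_drift_max: float = 0.01    # max per-year upward drift of q
    stratum_population: float = 1_000_000.0
    q_override: float | None = None    # pin q everywhere (limit checks)

    def __post_init__(self) -> None:
        mir_min, mir_max = self.mir_bounds
        d_min, d_max = self.duration_bounds
        if not (0 < mir_min < mir_max <= 1):
            raise ContractError("mir_bounds must satisfy 0 < min < max <= 1")
        if not (0 < d_min < d_max):
            raise ContractError("duration_bounds must satisfy 0 < min < max")
        if not (0 < self.disability_weight < 1):
            raise ContractError("disability_weight must lie in (0, 1)")
        if self.noise_sigma < 0 or self.incidence_gsd <= 0:
            raise ContractError("sigmas must be positive")
        if self.n_countries < 1 or self.year_end < self.year_start:
            raise ContractError("need >= 1 country and a non-empty year range")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass
class LatentTruth:
    """Hidden state of a synthetic world.

    ``q`` has one row per (location, year, sex in {male, female}) with the
    latent care quality in [0, 1]; ``classes`` fixes each country's
    development (SDI-like, quintiles of mean q) and income (quartiles of
    mean q) stratum for the whole period.
    """

    q: pd.DataFrame
    classes: pd.DataFrame

    def q_lookup(self) -> pd.Series:
        return self.q.set_index(["location", "year", "sex"])["quality"]


def standard_population(age_groups, weights=None) -> np.ndarray:
    """Standard-population weights aligned with ``age_groups``, summing to 1.

    ``weights`` may be a sequence aligned with the bands or a mapping from
    band label to weight; when omitted, the bundled WHO world-standard
    table is used. A band absent from the table is a contract error.
    """
    labels = [format_age_label(lo, hi) for lo, hi in age_groups]
    if weights is None:
        weights = WORLD_STANDARD_WEIGHTS
    if isinstance(weights, dict):
        missing = [lab for lab in labels if lab not in weights]
        if missing:
            raise ContractError(
                f"no standard-population weight for band(s) {missing}")
        w = np.array([float(weights[lab]) for lab in labels])
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(labels):
            raise ContractError("weight vector length does not match bands")
    if (w < 0).any() or w.sum() <= 0:
        raise ContractError("weights must be non-negative with positive sum")
    return w / w.sum()


def _latent_quality(cfg: SyntheticConfig, rng: np.random.Generator):
    """q array of shape (countries, years, 2 sexes) plus country classes."""
    n_c, years = cfg.n_countries, cfg.years
    base = rng.beta(2.0, 2.0, size=n_c)
    slope = rng.uniform(0.0, cfg.quality_drift_max, size=n_c)
    t = years - years[0]
    q = base[:, None] + slope[:, None] * t[None, :]
    q = np.clip(q, 0.0, 1.0)
    gap = cfg.sex_quality_gap + cfg.sex_gap_drift * t[None, :]
    q = np.stack([q, np.clip(q + gap, 0.0, 1.0)], axis=2)
    if cfg.q_override is not None:
        q = np.full_like(q, float(cfg.q_override))
    return q


def _country_classes(names, q_mean) -> pd.DataFrame:
    ranks = pd.Series(q_mean, index=names).rank(method="first")
    frac = (ranks - 0.5) / len(names)
    sdi = np.array(SDI_CLASSES)[np.minimum((frac * 5).astype(int), 4)]
    income = np.array(INCOME_CLASSES)[np.minimum((frac * 4).astype(int), 3)]
    return pd.DataFrame({"location": names, "sdi_class": sdi,
                         "income_class": income})


def generate_world(cfg: SyntheticConfig) -> tuple[BurdenTable, LatentTruth]:
    """Simulate a burden table and its latent truth; deterministic per seed.

    Random draws are split into independent streams (quality, incidence,
    noise) via ``SeedSequence.spawn`` so adding a stage never perturbs the
    draws of an earlier one.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_q, rng_i, rng_n = (np.random.default_rng(s) for s in ss.spawn(3))

    names = [f"Country-{i:03d}" for i in range(cfg.n_countries)]
    years = cfg.years
    bands = list(cfg.age_groups)
    labels = [format_age_label(lo, hi) for lo, hi in bands]
    profile = default_age_profile(bands)
    life = (np.asarray(cfg.remaining_life, dtype=float)
            if cfg.remaining_life is not None
            else default_remaining_life(bands))
    if len(life) != len(bands) or np.any(np.diff(life) > 0):
        raise ContractError("remaining_life must give one non-increasing "
                            "value per age band")

    q = _latent_quality(cfg, rng_q)                      # (C, Y, 2)
    base_rate = rng_i.lognormal(np.log(cfg.incidence_gm), cfg.incidence_gsd,
                                size=cfg.n_countries)    # per country

    mir_min, mir_max = cfg.mir_bounds
    d_min, d_max = cfg.duration_bounds
    shape = (cfg.n_countries, len(years), 2, len(bands))
    inc = base_rate[:, None, None, None] * profile[None, None, None, :]
    inc = np.broadcast_to(inc, shape).copy()
    mir = mir_max - (mir_max - mir_min) * q[..., None]
    dur = d_min + (d_max - d_min) * q[..., None]
    deaths = inc * mir
    prev = inc * dur
    if cfg.noise_sigma > 0:
        inc = inc * rng_n.lognormal(0.0, cfg.noise_sigma, size=shape)
        prev = prev * rng_n.lognormal(0.0, cfg.noise_sigma, size=shape)
        deaths = deaths * rng_n.lognormal(0.0, cfg.noise_sigma, size=shape)
    yld = prev * cfg.disability_weight
    yll = deaths * life[None, None, None, :]
    daly = yll + yld

    pop = cfg.stratum_population
    rates = {"incidence": inc, "prevalence": prev, "deaths": deaths,
             "yll": yll, "yld": yld, "daly": daly}

    frames = []
    c_idx = np.repeat(np.arange(cfg.n_countries), len(years) * 2 * len(bands))
    y_idx = np.tile(np.repeat(years, 2 * len(bands)), cfg.n_countries)
    s_idx = np.tile(np.repeat(np.arange(2), len(bands)),
                    cfg.n_countries * len(years))
    a_idx = np.tile(np.arange(len(bands)),
                    cfg.n_countries * len(years) * 2)
    sex_names = np.array(["male", "female"], dtype=object)
    base_cols = {
        "location": np.array(names, dtype=object)[c_idx],
        "year": y_idx,
        "sex": sex_names[s_idx],
        "age_group": np.array(labels, dtype=object)[a_idx],
        "age_lo": np.array([b[0] for b in bands])[a_idx],
        "age_hi": np.array([b[1] for b in bands])[a_idx],
    }
    # "both"-sex strata computed directly: counts are exact sums of the
    # sex-specific counts; rates re-derived from the pooled population,
    # which has equal strata so they reduce to plain means of the rates.
    b_idx = np.repeat(np.arange(cfg.n_countries), len(years) * len(bands))
    by_idx = np.tile(np.repeat(years, len(bands)), cfg.n_countries)
    ba_idx = np.tile(np.arange(len(bands)), cfg.n_countries * len(years))
    both_cols = {
        "location": np.array(names, dtype=object)[b_idx],
        "year": by_idx,
        "sex": "both",
        "age_group": np.array(labels, dtype=object)[ba_idx],
        "age_lo": np.array([b[0] for b in bands])[ba_idx],
        "age_hi": np.array([b[1] for b in bands])[ba_idx],
    }
    for measure, rate in rates.items():
        flat = rate.reshape(-1)
        both_rate = rate.sum(axis=2).reshape(-1) / 2.0
        for metric, value, bvalue in (
                ("rate_per_100k", flat, both_rate),
                ("count", flat * pop / 1e5, both_rate * 2 * pop / 1e5)):
            frames.append(pd.DataFrame({**base_cols, "measure": measure,
                                        "metric": metric, "value": value}))
            frames.append(pd.DataFrame({**both_cols, "measure": measure,
                                        "metric": metric, "value": bvalue}))
    df = pd.concat(frames, ignore_index=True)

    pops = pd.concat([
        pd.DataFrame({"location": base_cols["location"],
                      "year": base_cols["year"], "sex": base_cols["sex"],
                      "age_group": base_cols["age_group"],
                      "population": pop}),
        pd.DataFrame({"location": both_cols["location"],
                      "year": both_cols["year"], "sex": "both",
                      "age_group": both_cols["age_group"],
                      "population": 2 * pop}),
    ], ignore_index=True)

    q_rows = pd.DataFrame({
        "location": np.array(names, dtype=object)[np.repeat(np.arange(cfg.n_countries),
                                              len(years) * 2)],
        "year": np.tile(np.repeat(years, 2), cfg.n_countries),
        "sex": np.tile(sex_names, cfg.n_countries * len(years)),
        "quality": q.reshape(-1),
    })
    classes = _country_classes(names, q.mean(axis=(1, 2)))
    table = BurdenTable(df, pops)
    return table, LatentTruth(q_rows, classes)
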