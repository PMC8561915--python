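"""Gender disparity ratio, age-band summaries and six-sigma outliers.

The gender disparity ratio (GDR) is the male-to-female ratio of QCI,
classified into five printed bands — ≤ 0.5, (0.5, 0.95], (0.95, 1.05],
(1.05, 1.5], > 1.5 — of which (0.95, 1.05] is the optimal (near-parity)
category. Age groups collapse to three life stages: childhood and
adolescence (< 20 y), adulthood ([20, 65)), the elderly (≥ 65 y).
Extreme performers are flagged by a six-sigma rule: values outside the
open interval (μ − 3σ, μ + 3σ) of the indicator's distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError

logger = logging.getLogger(__name__)

GDR_QUINTILES = ("≤0.5", "(0.5,0.95]", "(0.95,1.05]", "(1.05,1.5]", ">1.5")
GDR_OPTIMAL = "(0.95,1.05]"

#: life-stage bands; adulthood is [20, 65) so the 5-year GBD bands
#: partition cleanly (the 65–69 band belongs to the elderly)
AGE_BANDS = {
    "childhood_adolescence": (0.0, 20.0),
    "adulthood": (20.0, 65.0),
    "elderly": (65.0, math.inf),
}


def gender_disparity_ratio(qci_male: float, qci_female: float) -> float:
    """Male-to-female QCI ratio; undefined (contract error) at female 0."""
    if not np.isfinite(qci_female) or qci_female <= 0:
        raise ContractError(
            f"GDR undefined for female QCI {qci_female!r} (must be > 0)")
    if not np.isfinite(qci_male) or qci_male < 0:
        raise ContractError(f"male QCI {qci_male!r} must be finite and >= 0")
    return qci_male / qci_female


def classify_gdr(gdr: float) -> tuple[str, bool]:
    """Quintile label and optimal flag for a GDR value.

    Intervals are left-open, right-closed, except the first which is
    closed at 0.5: 0.95 falls in ``(0.5,0.95]``, 1.05 in ``(0.95,1.05]``.
    """
    if not np.isfinite(gdr) or gdr < 0:
        raise ContractError(f"GDR must be finite and >= 0, got {gdr!r}")
    if gdr <= 0.5:
        label = GDR_QUINTILES[0]
    elif gdr <= 0.95:
        label = GDR_QUINTILES[1]
    elif gdr <= 1.05:
        label = GDR_QUINTILES[2]
    elif gdr <= 1.5:
        label = GDR_QUINTILES[3]
    else:
        label = GDR_QUINTILES[4]
    return label, label == GDR_OPTIMAL


def assign_age_band(age_lo: float, age_hi: float,
                    bands: dict | None = None) -> str:
    """Life-stage label for a 5-year age group ``[age_lo, age_hi)``.

    The group must lie entirely inside one life stage; a straddling group
    is a contract error.
    """
    bands = bands or AGE_BANDS
    for label, (lo, hi) in bands.items():
        if age_lo >= lo and (age_hi <= hi or
                             (math.isinf(age_hi) and math.isinf(hi))):
            return label
    raise ContractError(
        f"age group [{age_lo}, {age_hi}) straddles a life-stage boundary")


@dataclass
class OutlierReport:
    """Six-sigma outcome: distribution moments plus the flagged keys."""

    mean: float
    sd: float
    outliers: pd.DataFrame  # columns: key, value, direction {low, high}


def six_sigma_outliers(values: pd.Series) -> OutlierReport:
    """Flag values outside the open interval (μ − 3σ, μ + 3σ).

    ``values`` is keyed (e.g. by country). σ is the sample standard
    deviation (n − 1 denominator); because the interval is open, a value
    sitting exactly at μ ± 3σ is flagged. With σ = 0 nothing is flagged
    and a warning is logged.
    """
    s = pd.Series(values).dropna()
    if len(s) < 2:
        raise ContractError("six-sigma rule needs at least 2 values")
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    if sd == 0:
        logger.warning("all %d values identical; no outliers flagged",
                       len(s))
        flagged = s.iloc[0:0]
    else:
        low = s[s <= mean - 3 * sd]
        high = s[s >= mean + 3 * sd]
        flagged = pd.concat([low, high])
    direction = np.where(flagged <= mean, "low", "high")
    out = pd.DataFrame({"key": flagged.index, "value": flagged.to_numpy(),
                        "direction": direction})
    return OutlierReport(mean=mean, sd=sd, outliers=out)


def rank_locations(scores: pd.DataFrame, year: int,
                   order: str = "descending") -> pd.DataFrame:
    """Order locations by QCI for one year; ties break alphabetically.

    ``scores`` needs columns ``location, year, qci`` with at most one row
    per location for the requested year.
    """
    if order not in ("ascending", "descending"):
        raise ContractError(f"order must be ascending|descending, not "
                            f"{order!r}")
    sub = scores[scores["year"] == year]
    dup = sub["location"].duplicated()
    if dup.any():
        raise ContractError(
            f"duplicate score for location(s) "
            f"{sorted(sub.loc[dup, 'location'].unique())} in {year}")
    ordered = sub.sort_values(["qci", "location"],
                              ascending=[order == "ascending", True],
                              kind="mergesort")
    ordered = ordered.reset_index(drop=True)
    ordered.index = ordered.index + 1
    return ordered.rename_axis("rank").reset_index()


def gdr_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per (location, year[, age_group]) GDR with quintile classification.

    ``scores`` carries one male and one female QCI row per unit; units
    whose female QCI is 0 are reported with a NaN GDR (and logged) rather
    than dropped silently.
    """
    keys = [c for c in ("location", "year", "age_group")
            if c in scores.columns]
    wide = scores.pivot_table(index=keys, columns="sex", values="qci",
                              aggfunc="first")
    if not {"male", "female"} <= set(wide.columns):
        raise ContractError("scores must contain male and female rows")
    rows = []
    n_undefined = 0
    for key, row in wide.iterrows():
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        try:
            g = gender_disparity_ratio(row["male"], row["female"])
        except ContractError:
            n_undefined += 1
            rec.update(gdr=np.nan, quintile="", optimal=False)
        else:
            label, opt = classify_gdr(g)
            rec.update(gdr=g, quintile=label, optimal=opt)
        rows.append(rec)
    if n_undefined:
        logger.warning("%d unit(s) with zero female QCI: GDR undefined",
                       n_undefined)
    return pd.DataFrame(rows)
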