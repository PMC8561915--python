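"""The four care-quality ratio indices and age standardisation.

For each analysis unit the module derives, from summed counts:

* ``pir`` — prevalence / incidence (survival-duration proxy),
* ``mir`` — deaths / incidence (case-fatality proxy; lower is better),
* ``dpr`` — DALYs / prevalence (burden per prevalent case),
* ``ylr`` — YLLs / YLDs (mortality share of the burden; lower is better).

Ratios are always computed from counts so that aggregation over strata is
exact; a zero denominator yields an explicit missing value (NaN) and a
logged warning rather than a silent drop.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ContractError
from .gbd_tables import BurdenTable

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("pir", "mir", "dpr", "ylr")

#: numerator/denominator measures for each ratio
RATIO_DEFS = {
    "pir": ("prevalence", "incidence"),
    "mir": ("deaths", "incidence"),
    "dpr": ("daly", "prevalence"),
    "ylr": ("yll", "yld"),
}


def compute_indices(table: BurdenTable, unit_spec: list[str]) -> pd.DataFrame:
    """Compute the four ratios per unit defined by ``unit_spec``.

    ``unit_spec`` is the subset of ``{location, year, sex, age_group}``
    defining one analysis unit; counts are summed within units first
    (dropping ``both``-sex rows when sex is summed out, to avoid double
    counting). Returns a tidy frame with the unit key columns, the four
    ratio columns (NaN marks an undefined ratio) and a ``count_based``
    provenance flag.
    """
    counts = table.data[table.data["metric"] == "count"]
    if "sex" not in unit_spec and (counts["sex"] != "both").any():
        # avoid double counting: drop the pre-summed "both" stratum when
        # sex-specific rows are available to be summed instead
        counts = counts[counts["sex"] != "both"]
    if counts.empty or not (counts["measure"] == "incidence").any():
        raise ContractError("no incidence count rows for the requested units")
    summed = counts.groupby(list(unit_spec) + ["measure"],
                            as_index=False)["value"].sum()
    wide = summed.pivot_table(index=unit_spec, columns="measure",
                              values="value", aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    n_missing = 0
    for name, (num, den) in RATIO_DEFS.items():
        numer = wide.get(num)
        denom = wide.get(den)
        if numer is None or denom is None:
            out[name] = np.nan
            n_missing += len(out)
            continue
        ratio = numer / denom.where(denom > 0)
        n_missing += int(ratio.isna().sum())
        out[name] = ratio
    if n_missing:
        logger.warning("%d ratio value(s) undefined (zero or absent "
                       "denominator); marked missing", n_missing)
    out["count_based"] = True
    return out.reset_index()


def age_standardize(values, weights, renormalise: bool = False) -> float:
    """Weighted sum of per-age-band ``values`` with standard-population
    ``weights`` (aligned, weights summing to 1).

    A missing (NaN) value is a contract error unless ``renormalise`` is
    set, in which case the surviving bands' weights are rescaled to 1.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ContractError(
            f"values ({v.shape}) and weights ({w.shape}) are misaligned")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ContractError("weights must be normalised to sum to 1")
    missing = np.isnan(v)
    if missing.any():
        if not renormalise:
            raise ContractError(
                f"{int(missing.sum())} band value(s) missing; pass "
                "renormalise=True to drop them explicitly")
        if missing.all():
            raise ContractError("all band values missing")
        w = w[~missing] / w[~missing].sum()
        v = v[~missing]
    return float(v @ w)


def age_standardize_indices(index_table: pd.DataFrame,
                            weights_by_band: dict[str, float],
                            renormalise: bool = False) -> pd.DataFrame:
    """Collapse age-specific index rows to one age-standardised row per
    remaining key, weight-averaging each ratio over bands.

    ``index_table`` must carry an ``age_group`` column and the four ratio
    columns; ``weights_by_band`` maps band label → normalised weight and
    must cover every band present.
    """
    missing = sorted(set(index_table["age_group"]) - set(weights_by_band))
    if missing:
        raise ContractError(f"no weight for age band(s) {missing}")
    keys = [c for c in ("location", "year", "sex")
            if c in index_table.columns]
    if not np.isclose(sum(weights_by_band.values()), 1.0, atol=1e-9):
        raise ContractError("band weights must sum to 1")

    flat = index_table.reset_index(drop=True)
    w = flat["age_group"].map(weights_by_band).to_numpy(float)
    out_rows = []
    for key, grp in flat.groupby(keys, sort=True):
        gw = w[grp.index.to_numpy()]
        if not np.isclose(gw.sum(), 1.0, atol=1e-6):
            raise ContractError(
                f"unit {key}: band weights sum to {gw.sum():.6f}, not 1 "
                "(incomplete band coverage)")
        row = {k: v for k, v in zip(keys, key if isinstance(key, tuple)
                                    else (key,))}
        for col in INDEX_COLUMNS:
            row[col] = age_standardize(grp[col].to_numpy(float), gw,
                                       renormalise=renormalise)
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    out["age_group"] = "age-standardised"
    out["count_based"] = True
    return out
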