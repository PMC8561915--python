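"""Long-format burden-of-disease tables in the GBD query-tool shape.

A :class:`BurdenTable` holds one row per
``(location, year, sex, age_group, measure, metric)`` cell for a single
cause, with six epidemiological measures (incidence, prevalence, deaths,
YLLs, YLDs, DALYs) recorded either as counts or as rates per 100 000.
The module reads and writes the CSV dialect produced by the public GBD
results tool, validates internal consistency (non-negativity, key
uniqueness, DALY = YLL + YLD), and aggregates count cells to coarser
strata such as income or development-level regions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

MEASURES = ("incidence", "prevalence", "deaths", "yll", "yld", "daly")
SEXES = ("male", "female", "both")
METRICS = ("count", "rate_per_100k")

#: canonical key columns identifying one cell
KEY_COLUMNS = ["location", "year", "sex", "age_group", "measure", "metric"]

#: full canonical column set of :attr:`BurdenTable.data`
DATA_COLUMNS = ["location", "year", "sex", "age_group", "age_lo", "age_hi",
                "measure", "metric", "value"]

# GBD results-tool spellings → canonical measure names
MEASURE_SYNONYMS = {
    "incidence": "incidence",
    "prevalence": "prevalence",
    "deaths": "deaths",
    "death": "deaths",
    "ylls (years of life lost)": "yll",
    "ylls": "yll",
    "yll": "yll",
    "ylds (years lived with disability)": "yld",
    "ylds": "yld",
    "yld": "yld",
    "dalys (disability-adjusted life years)": "daly",
    "dalys": "daly",
    "daly": "daly",
}

METRIC_SYNONYMS = {
    "number": "count",
    "count": "count",
    "rate": "rate_per_100k",
    "rate_per_100k": "rate_per_100k",
}

SEX_SYNONYMS = {"male": "male", "females": "female", "female": "female",
                "males": "male", "both": "both", "both sexes": "both"}

#: default mapping canonical field → CSV column header (GBD export dialect)
DEFAULT_DIALECT = {
    "measure": "measure",
    "location": "location",
    "sex": "sex",
    "age": "age",
    "year": "year",
    "metric": "metric",
    "value": "val",
}

_AGE_OPEN = re.compile(r"^(\d+)\s*(?:plus|\+)$")
_AGE_RANGE = re.compile(r"^(\d+)\s*(?:to|[-–])\s*(\d+)$")
_AGE_UNDER = re.compile(r"^(?:<|under)\s*(\d+)$")


def parse_age_label(label: str) -> tuple[float, float]:
    """Parse a GBD age-group label into numeric bounds ``[lo, hi)`` in years.

    ``"15 to 19"`` / ``"15-19"`` cover integer ages 15..19 and therefore map
    to ``[15, 20)``; the terminal group ``"95 plus"`` maps to ``[95, inf)``.
    """
    s = str(label).strip().lower()
    m = _AGE_OPEN.match(s)
    if m:
        return float(m.group(1)), math.inf
    m = _AGE_RANGE.match(s)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        if not lo <= hi:
            raise FormatError(f"age label {label!r} has lo > hi")
        return lo, hi + 1.0
    m = _AGE_UNDER.match(s)
    if m:
        return 0.0, float(m.group(1))
    raise FormatError(f"unrecognised age-group label {label!r}")


def format_age_label(lo: float, hi: float) -> str:
    """Inverse of :func:`parse_age_label` for canonical bounds."""
    if math.isinf(hi):
        return f"{int(lo)} plus"
    return f"{int(lo)}-{int(hi) - 1}"


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`: hard-rule violations and warnings.

    Each entry is ``(rule_id, key, message)`` where ``key`` is the offending
    cell key (or ``None`` for table-level rules).
    """

    errors: list[tuple[str, object, str]] = field(default_factory=list)
    warnings: list[tuple[str, object, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class BurdenTable:
    """Long-format burden table plus optional per-stratum population.

    ``data`` uses the canonical columns of :data:`DATA_COLUMNS`;
    ``population`` (needed to convert counts to rates) has columns
    ``location, year, sex, age_group, population``.
    """

    data: pd.DataFrame
    population: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"burden table missing columns {missing}")
        already_canonical = (list(self.data.columns) == DATA_COLUMNS
                             and isinstance(self.data.index, pd.RangeIndex)
                             and self.data.index.start == 0
                             and self.data.index.step == 1)
        if not already_canonical:
            self.data = self.data[DATA_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, **conditions) -> "BurdenTable":
        """Rows matching equality ``conditions`` on canonical columns."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in conditions.items():
            allowed = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= self.data[col].isin(list(allowed))
        return BurdenTable(self.data[mask].copy(), self.population)

    def counts(self) -> "BurdenTable":
        return self.subset(metric="count")

    def pivot_measures(self, metric: str = "count") -> pd.DataFrame:
        """Wide frame, one column per measure, indexed by the unit key."""
        sub = self.data[self.data["metric"] == metric]
        return sub.pivot_table(index=["location", "year", "sex", "age_group"],
                               columns="measure", values="value",
                               aggfunc="first")

    def equals(self, other: "BurdenTable") -> bool:
        a = self.data.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other.data.sort_values(KEY_COLUMNS).reset_index(drop=True)
        if len(a) != len(b):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=0,
                                          atol=1e-9)
        except AssertionError:
            return False
        return True


def _canonical_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalise measure/metric/sex spellings and parse age labels."""
    df = raw.copy()
    for col, table in (("measure", MEASURE_SYNONYMS),
                       ("metric", METRIC_SYNONYMS),
                       ("sex", SEX_SYNONYMS)):
        lowered = df[col].astype(str).str.strip().str.lower()
        unknown = sorted(set(lowered) - set(table))
        if unknown:
            raise FormatError(f"unknown {col} value(s) {unknown}")
        df[col] = lowered.map(table)
    bounds = df["age_group"].map(parse_age_label)
    df["age_lo"] = [b[0] for b in bounds]
    df["age_hi"] = [b[1] for b in bounds]
    df["year"] = df["year"].astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
    return df[DATA_COLUMNS]


def read_burden_csv(path, dialect: dict | None = None,
                    population_path=None) -> BurdenTable:
    """Read a GBD query-tool CSV export into a :class:`BurdenTable`.

    ``dialect`` maps canonical fields (measure, location, sex, age, year,
    metric, value) to the file's column headers; matching is
    case-insensitive. Duplicate cell keys and negative values are rejected.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path)
    lower_map = {c.lower(): c for c in raw.columns}
    cols = {}
    for canon, name in dialect.items():
        actual = lower_map.get(str(name).lower())
        if actual is None:
            raise FormatError(f"required column {name!r} (for {canon!r}) "
                              f"not found in {path}")
        cols[canon] = actual
    df = raw.rename(columns={cols["measure"]: "measure",
                             cols["location"]: "location",
                             cols["sex"]: "sex",
                             cols["age"]: "age_group",
                             cols["year"]: "year",
                             cols["metric"]: "metric",
                             cols["value"]: "value"})
    df = _canonical_frame(df)
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise FormatError(f"negative value at row(s) {list(neg[:5])}")
    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        key = tuple(df.loc[dup.idxmax(), KEY_COLUMNS])
        raise FormatError(f"duplicate cell key {key}")
    pop = pd.read_csv(population_path) if population_path else None
    return BurdenTable(df, pop)


def write_burden_csv(table: BurdenTable, path) -> None:
    """Write ``table`` in the GBD export dialect; round-trips with
    :func:`read_burden_csv`."""
    out = table.data.copy()
    metric_back = {"count": "Number", "rate_per_100k": "Rate"}
    measure_back = {"incidence": "Incidence", "prevalence": "Prevalence",
                    "deaths": "Deaths",
                    "yll": "YLLs (Years of Life Lost)",
                    "yld": "YLDs (Years Lived with Disability)",
                    "daly": "DALYs (Disability-Adjusted Life Years)"}
    out = pd.DataFrame({
        "measure": out["measure"].map(measure_back),
        "location": out["location"],
        "sex": out["sex"].str.capitalize(),
        "age": out["age_group"],
        "year": out["year"],
        "metric": out["metric"].map(metric_back),
        "val": out["value"],
    })
    # default float repr is shortest-round-trip: read(write(t)) == t exactly
    out.to_csv(path, index=False)


def validate_table(table: BurdenTable,
                   daly_rel_tol: float = 1e-6) -> ValidationReport:
    """Check every hard invariant; violations become report entries.

    Rules: ``nonnegative`` (value >= 0), ``unique_key``, ``age_bounds``
    (lo < hi), ``daly_consistency`` (|DALY − (YLL + YLD)| <= rel_tol·DALY
    wherever all three are present for one stratum and metric).
    """
    report = ValidationReport()
    df = table.data
    for idx in df.index[df["value"] < 0]:
        key = tuple(df.loc[idx, KEY_COLUMNS])
        report.errors.append(("nonnegative", key,
                              f"value {df.loc[idx, 'value']} < 0"))
    dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
    for key, grp in df[dup].groupby(KEY_COLUMNS):
        report.errors.append(("unique_key", key,
                              f"{len(grp)} rows share this key"))
    bad_age = df.index[~(df["age_lo"] < df["age_hi"])]
    for idx in bad_age:
        key = tuple(df.loc[idx, KEY_COLUMNS])
        report.errors.append(("age_bounds", key, "age bounds require lo < hi"))
    for metric in df["metric"].unique():
        wide = table.pivot_measures(metric)
        if not {"daly", "yll", "yld"} <= set(wide.columns):
            continue
        sub = wide[["daly", "yll", "yld"]].dropna()
        gap = (sub["daly"] - (sub["yll"] + sub["yld"])).abs()
        tol = daly_rel_tol * sub["daly"].abs().clip(lower=1e-300)
        for key in sub.index[gap > tol]:
            report.errors.append(
                ("daly_consistency", key + (metric,),
                 f"DALY {sub.loc[key, 'daly']:.6g} != YLL + YLD "
                 f"{(sub.loc[key, 'yll'] + sub.loc[key, 'yld']):.6g}"))
    return report


_COLLAPSED = {"location": "All locations", "sex": "both",
              "age_group": "All ages"}


def aggregate(table: BurdenTable, grouping: list[str],
              region_map: dict[str, str] | None = None) -> BurdenTable:
    """Sum count cells to the strata named in ``grouping``.

    ``grouping`` is the subset of ``{location, year, sex, age_group}`` to
    keep; the remaining key dimensions are summed out. Rates must never be
    summed, so any rate-metric cell in the input is a contract error.
    When ``sex`` is collapsed, pre-existing ``both`` rows are dropped first
    so nothing is double counted. ``region_map`` optionally relabels
    locations (country → region) before grouping.
    """
    bad = [g for g in grouping if g not in ("location", "year", "sex",
                                            "age_group")]
    if bad:
        raise ContractError(f"unknown grouping dimension(s) {bad}")
    df = table.data
    if (df["metric"] != "count").any():
        raise ContractError("aggregate requires count-metric cells only; "
                            "rates must not be summed (use .counts() first)")
    df = df.copy()
    if region_map is not None:
        df["location"] = df["location"].map(lambda x: region_map.get(x, x))
    if "sex" not in grouping:
        df = df[df["sex"] != "both"]
    keys = list(grouping) + ["measure", "metric"]
    agg = df.groupby(keys, as_index=False)["value"].sum()
    for dim, label in _COLLAPSED.items():
        if dim not in grouping:
            agg[dim] = label
    if "year" not in grouping:
        agg["year"] = -1  # sentinel: summed over the full period
    if "age_group" in grouping:
        lookup = df.drop_duplicates("age_group").set_index("age_group")
        agg["age_lo"] = agg["age_group"].map(lookup["age_lo"])
        agg["age_hi"] = agg["age_group"].map(lookup["age_hi"])
    else:
        agg["age_lo"], agg["age_hi"] = 0.0, math.inf
    pop = None
    if table.population is not None:
        p = table.population.copy()
        if region_map is not None:
            p["location"] = p["location"].map(lambda x: region_map.get(x, x))
        if "sex" not in grouping:
            p = p[p["sex"] != "both"]
        pkeys = [g for g in grouping]
        pop = p.groupby(pkeys, as_index=False)["population"].sum()
        for dim, label in _COLLAPSED.items():
            if dim not in grouping:
                pop[dim] = label
        if "year" not in grouping:
            pop["year"] = -1
    return BurdenTable(agg, pop)
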