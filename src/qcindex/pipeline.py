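"""End-to-end orchestration: synthetic world (or CSV input) → four care
ratios → QCI → disparity, regional summaries, outliers, validation.

`run_pipeline` produces a deterministic artifact bundle of tidy CSVs plus
a JSON run manifest, mirroring the publication-style outputs of a
care-quality study: a score table, a gender-disparity table, a regional
summary (burden rate and QCI at the period ends with percent changes),
a six-sigma outlier report and a mixed-model validation result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ContractError, QCIndexError
from .gbd_tables import (BurdenTable, aggregate, format_age_label,
                         read_burden_csv, write_burden_csv)
from .indices import age_standardize_indices, compute_indices
from .qci import QCIScorer
from .disparity import gdr_table, six_sigma_outliers
from .synthetic import (LatentTruth, SyntheticConfig, generate_world,
                        standard_population)
from .validation import ValidationDesign, fit_random_intercept

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class PipelineError(QCIndexError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_path: str | None = None       # read a burden CSV instead
    out_dir: str = "qci_run"
    start_year: int | None = None       # default: the world's first year
    end_year: int | None = None
    asr_mode: str = "scores"            # "scores" | "indices"
    fit_sexes: tuple = ("male", "female")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.asr_mode not in ("scores", "indices"):
            raise ContractError("asr_mode must be 'scores' or 'indices'")
        start = self.start_year if self.start_year is not None \
            else self.synthetic.year_start
        end = self.end_year if self.end_year is not None \
            else self.synthetic.year_end
        if not start < end:
            raise ContractError(
                f"start year {start} must precede end year {end}")
        self.start_year, self.end_year = int(start), int(end)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        syn = d["synthetic"]
        syn["age_groups"] = [list(b) for b in syn["age_groups"]]
        if syn["remaining_life"] is not None:
            syn["remaining_life"] = list(map(float, syn["remaining_life"]))
        return d


@dataclass
class ArtifactBundle:
    """In-memory results of a run (also written as CSV/JSON artifacts)."""

    scorer: QCIScorer
    qci_scores: pd.DataFrame
    gdr: pd.DataFrame
    region_summary: pd.DataFrame
    outliers: pd.DataFrame
    validation: dict
    trend: pd.DataFrame
    crossings: list
    manifest: dict
    truth: LatentTruth | None = None
    table: BurdenTable | None = None


def percent_change(start: float, end: float) -> float:
    """100 × (end − start) / start; undefined at start = 0."""
    if start == 0:
        raise ContractError("percent change undefined for start = 0")
    return 100.0 * (end - start) / start


def trend_series(scores: pd.DataFrame, group: str,
                 years: range) -> tuple[pd.DataFrame, list]:
    """Per-group QCI time series over ``years`` with crossing detection.

    Returns a wide frame (index year, one column per group; missing years
    carry NaN gap markers, never interpolated values) and a list of
    crossings ``{year, overtaker, overtaken}`` where one group's series
    passes another's (intersection year by linear inversion between the
    two bracketing observations).
    """
    wide = scores.pivot_table(index="year", columns=group, values="qci",
                              aggfunc="first")
    wide = wide.reindex(list(years))
    crossings = []
    cols = list(wide.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            d = (wide[a] - wide[b]).to_numpy(float)
            yrs = wide.index.to_numpy(float)
            # track the last non-zero, non-NaN difference so a series
            # touching zero exactly still registers a single crossing
            last_sign, last_k = 0, -1
            for k in range(len(d)):
                if np.isnan(d[k]) or d[k] == 0:
                    continue
                sign = 1 if d[k] > 0 else -1
                if last_sign and sign != last_sign:
                    frac = d[last_k] / (d[last_k] - d[k])
                    year_x = yrs[last_k] + frac * (yrs[k] - yrs[last_k])
                    overtaker = b if last_sign > 0 else a
                    overtaken = a if overtaker == b else b
                    crossings.append({"year": float(year_x),
                                      "overtaker": overtaker,
                                      "overtaken": overtaken})
                last_sign, last_k = sign, k
    return wide, crossings


def _asr_weights(table: BurdenTable) -> dict[str, float]:
    bands = (table.data[["age_group", "age_lo", "age_hi"]]
             .drop_duplicates().sort_values("age_lo"))
    bands = bands[bands["age_group"] != "All ages"]
    pairs = list(zip(bands["age_lo"], bands["age_hi"]))
    w = standard_population(pairs)
    return dict(zip(bands["age_group"], w))


def _score_asr(scorer: QCIScorer, idx_age: pd.DataFrame,
               asr_idx: pd.DataFrame, weights: dict[str, float],
               mode: str) -> pd.DataFrame:
    """Age-standardised QCI per (location, year, sex).

    ``mode='indices'`` scores the age-standardised index vector directly;
    ``mode='scores'`` averages the age-specific scores with the standard
    population weights.
    """
    if mode == "indices":
        return scorer.score_frame(asr_idx)
    per_age = scorer.score_frame(idx_age)
    w = per_age["age_group"].map(weights)
    per_age = per_age.assign(_w=w, _wq=w * per_age["qci"],
                             _wr=w * per_age["raw_score"])
    agg = per_age.groupby(["location", "year", "sex"], as_index=False)[
        ["_w", "_wq", "_wr"]].sum()
    agg["qci"] = agg["_wq"] / agg["_w"]
    agg["raw_score"] = agg["_wr"] / agg["_w"]
    agg["age_group"] = "age-standardised"
    return agg[["location", "year", "sex", "age_group", "raw_score", "qci"]]


def _region_rows(table: BurdenTable, truth: LatentTruth,
                 scorer: QCIScorer, weights: dict[str, float],
                 years: tuple[int, int]) -> pd.DataFrame:
    """Table-1-style summary: ASR DALY rate and QCI at the period ends,
    with percent changes, globally and per income / development stratum."""
    class_map = truth.classes.set_index("location")
    specs = [("global", {loc: "Global" for loc in class_map.index}),
             ("world_bank", class_map["income_class"].to_dict()),
             ("sdi", class_map["sdi_class"].to_dict())]
    counts = table.subset(metric="count", sex=["male", "female"],
                          year=list(years))
    rows = []
    for region_type, mapping in specs:
        agg = aggregate(counts, ["location", "year", "age_group"],
                        region_map=mapping)
        idx = compute_indices(agg, ["location", "year", "age_group"])
        asr_idx = age_standardize_indices(idx, weights)
        asr_idx["sex"] = "both"
        scored = scorer.score_frame(asr_idx)
        pop = agg.population.set_index(["location", "year", "age_group"])
        daly = agg.subset(measure="daly").data
        daly = daly.set_index(["location", "year", "age_group"])
        rate = (daly["value"] / pop["population"] * 1e5).rename("rate")
        rate = rate.reset_index()
        rate["w"] = rate["age_group"].map(weights)
        asr_daly = (rate.assign(wr=rate["w"] * rate["rate"])
                    .groupby(["location", "year"])["wr"].sum())
        for region in sorted(set(mapping.values())):
            rec = {"region_type": region_type, "region": region}
            for tag, year in zip(("start", "end"), years):
                rec[f"daly_rate_{tag}"] = float(asr_daly.get((region, year),
                                                             np.nan))
                sel = scored[(scored["location"] == region)
                             & (scored["year"] == year)]
                rec[f"qci_{tag}"] = (float(sel["qci"].iloc[0])
                                     if len(sel) else np.nan)
            rec["daly_change_pct"] = percent_change(rec["daly_rate_start"],
                                                    rec["daly_rate_end"])
            rec["qci_change_pct"] = (
                percent_change(rec["qci_start"], rec["qci_end"])
                if rec["qci_start"] not in (0.0,) else np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)


def build_validation_design(asr_scores: pd.DataFrame, truth: LatentTruth,
                            table: BurdenTable, weights: dict[str, float],
                            seed: int) -> ValidationDesign:
    """Synthetic counterpart of the published validation design.

    Response: both-sex age-standardised QCI per country-year. Covariates:
    inpatient / outpatient utilisation and risk-attributable death are
    noisy linear functions of the latent quality; cause-specific death and
    prevalence are the age-standardised rates taken from the burden table.
    The reference index (an access-and-quality stand-in) is
    ``100·q + N(0, 10)``.
    """
    # spawn_key keeps this stream disjoint from the generator's streams
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(100,)))
    q = (truth.q.groupby(["location", "year"])["quality"].mean()
         .rename("quality"))
    resp = asr_scores[asr_scores["sex"] == "both"]
    resp = resp.set_index(["location", "year"])["qci"]
    rates = table.subset(metric="rate_per_100k", sex="both").data
    rates["w"] = rates["age_group"].map(weights)
    asr = (rates.assign(wv=rates["w"] * rates["value"])
           .groupby(["location", "year", "measure"])["wv"].sum()
           .unstack("measure"))
    df = pd.DataFrame({"qci": resp, "quality": q,
                       "cause_death": asr["deaths"],
                       "cause_prevalence": asr["prevalence"]}).dropna()
    n = len(df)
    df["inpatient_util"] = 2.0 + 3.0 * df["quality"] \
        + rng.normal(0.0, 0.3, n)
    df["outpatient_util"] = 5.0 + 4.0 * df["quality"] \
        + rng.normal(0.0, 0.5, n)
    df["risk_death"] = 10.0 - 5.0 * df["quality"] + rng.normal(0.0, 1.0, n)
    df["reference_index"] = 100.0 * df["quality"] + rng.normal(0.0, 10.0, n)
    df = df.reset_index()
    return ValidationDesign(data=df)


def run_pipeline(config: RunConfig) -> ArtifactBundle:
    """Execute every stage and write the artifact bundle to ``out_dir``.

    Deterministic for a fixed config (all randomness flows from the
    config's seed); every CSV written round-trips through pandas.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "world"
        if config.input_path:
            table = read_burden_csv(config.input_path)
            truth = None
        else:
            table, truth = generate_world(config.synthetic)
        weights = _asr_weights(table)

        stage = "indices"
        idx_age = compute_indices(
            table, ["location", "year", "sex", "age_group"])
        asr_idx = age_standardize_indices(idx_age, weights)

        stage = "qci"
        fit_rows = asr_idx[asr_idx["sex"].isin(config.fit_sexes)]
        scorer = QCIScorer().fit(fit_rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            asr_scores = _score_asr(scorer, idx_age, asr_idx, weights,
                                    config.asr_mode)
            per_age_scores = scorer.score_frame(idx_age)
        qci_scores = pd.concat([per_age_scores, asr_scores],
                               ignore_index=True)
        qci_scores = qci_scores.sort_values(
            ["location", "year", "sex", "age_group"]).reset_index(drop=True)

        stage = "disparity"
        gdr = gdr_table(asr_scores)

        stage = "outliers"
        end = asr_scores[(asr_scores["year"] == config.end_year)
                         & (asr_scores["sex"] == "both")]
        rep = six_sigma_outliers(end.set_index("location")["qci"])

        stage = "regions"
        if truth is not None:
            region_summary = _region_rows(
                table, truth, scorer, weights,
                (config.start_year, config.end_year))
        else:
            region_summary = pd.DataFrame()

        stage = "trend"
        global_counts = table.subset(metric="count",
                                     sex=["male", "female"])
        gagg = aggregate(global_counts, ["year", "sex", "age_group"])
        gidx = compute_indices(gagg, ["location", "year", "sex",
                                      "age_group"])
        gasr = age_standardize_indices(gidx, weights)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gscores = _score_asr(scorer, gidx, gasr, weights,
                                 config.asr_mode)
        trend, crossings = trend_series(
            gscores, "sex", range(config.start_year, config.end_year + 1))

        stage = "validation"
        if truth is not None:
            design = build_validation_design(asr_scores, truth, table,
                                             weights, config.synthetic.seed)
            vres = fit_random_intercept(design).to_dict()
        else:
            vres = {"skipped": "no latent truth (CSV input)"}

        stage = "write"
        qci_scores.to_csv(out / "qci_scores.csv", index=False,
                          float_format=FLOAT_FMT)
        gdr.to_csv(out / "gdr.csv", index=False, float_format=FLOAT_FMT)
        region_summary.to_csv(out / "region_summary.csv", index=False,
                              float_format=FLOAT_FMT)
        rep.outliers.to_csv(out / "outliers.csv", index=False,
                            float_format=FLOAT_FMT)
        trend.to_csv(out / "trend_by_sex.csv", float_format=FLOAT_FMT)
        with open(out / "validation.json", "w") as fh:
            json.dump(vres, fh, indent=2, sort_keys=True, default=float)
        config_echo = config.to_dict()
        config_echo.pop("out_dir")  # bundle location is not part of the run
        manifest = {
            "package_version": __version__,
            "config": config_echo,
            "outlier_mean": rep.mean,
            "outlier_sd": rep.sd,
            "crossings": crossings,
            "n_fit_units": scorer.n_fit_units_,
            "explained_share_pc1": float(scorer.explained_share_[0]),
            "outputs": ["qci_scores.csv", "gdr.csv", "region_summary.csv",
                        "outliers.csv", "trend_by_sex.csv",
                        "validation.json"],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    except QCIndexError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return ArtifactBundle(scorer=scorer, qci_scores=qci_scores, gdr=gdr,
                          region_summary=region_summary,
                          outliers=rep.outliers, validation=vres,
                          trend=trend, crossings=crossings,
                          manifest=manifest, truth=truth, table=table)


def write_world(table: BurdenTable, truth: LatentTruth, out_dir) -> None:
    """Persist a synthetic world (burden CSV + latent truth CSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_burden_csv(table, out / "world.csv")
    truth.q.to_csv(out / "latent_quality.csv", index=False,
                   float_format=FLOAT_FMT)
    truth.classes.to_csv(out / "country_classes.csv", index=False)
    if table.population is not None:
        table.population.to_csv(out / "population.csv", index=False,
                                float_format=FLOAT_FMT)
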