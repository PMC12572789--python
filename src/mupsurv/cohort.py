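"""Cohort construction: exclusion criteria, follow-up time, model covariates.

The analysis cohort is carved out of the recall-completing population by
seven exclusion criteria applied in a fixed order with first-hit
attribution (a participant is counted once, at the first criterion that
removes them):

  1. missing lifestyle factors (physical activity, smoking status)
  2. implausible event/censoring data (death before study entry)
  3. missing socio-economic factors (ethnic background, general health,
     highest qualification, Townsend deprivation index)
  4. missing exam parameters (BMI, systolic blood pressure)
  5. pre-existing malabsorption
  6. pre-existing diabetes mellitus
  7. implausible energy intake: 0 kcal, < 1.1*BMR - 500, > 2.5*BMR + 500
     (strict inequalities; equality retains) or above the population's
     99.9th percentile of energy intake.

BMR comes from the Oxford (Henry) equations, shipped as an editable
sex × age-band coefficient table.  Follow-up runs from the last dietary
assessment to death or censoring (loss to follow-up or the administrative
cut-off, 2022-12-19), whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_CUTOFF",
    "KJ_PER_KCAL",
    "ExclusionReport",
    "load_bmr_table",
    "oxford_bmr",
    "energy_plausible",
    "apply_exclusions",
    "build_survival",
    "build_survival_frame",
    "derive_covariates",
]

DEFAULT_CUTOFF = date(2022, 12, 19)
KJ_PER_KCAL = 4.184

EXCLUSION_LABELS = {
    1: "missing lifestyle factors",
    2: "implausible event/censoring data",
    3: "missing socio-economic factors",
    4: "missing exam parameters",
    5: "pre-existing malabsorption",
    6: "pre-existing diabetes mellitus",
    7: "implausible energy intake",
}

_QUINTILE_COVARIATES = ("age_years", "met_per_week", "sbp_mmHg", "townsend")
_CATEGORICAL_PASSTHROUGH = (
    "ethnicity",
    "general_health",
    "qualification",
    "psychiatric_history",
    "income_band",
    "sex",
    "smoking_status",
)


def load_bmr_table(path: str | Path | None = None) -> dict:
    """Load the Oxford-equation coefficient table (shipped Henry values)."""
    if path is None:
        path = Path(__file__).parent / "data" / "bmr_oxford.yaml"
    with open(path, "r", encoding="utf-8") as fh:
        table = yaml.safe_load(fh)
    if "bands" not in table:
        raise ValueError("BMR table lacks 'bands'")
    return table


def oxford_bmr(
    sex: str,
    age_years: float,
    weight_kg: float,
    height_m: float,
    coefficients: Mapping | None = None,
) -> float:
    """Basal metabolic rate in kcal/day from the configured linear form.

    BMR = a*weight + b*height + c for the (sex, age-band) row of the
    coefficient table; the shipped table stores MJ/day coefficients and a
    conversion factor to kcal.
    """
    table = coefficients if coefficients is not None else load_bmr_table()
    factor = float(table.get("mj_to_kcal", 1.0))
    try:
        bands = table["bands"][sex]
    except KeyError as exc:
        raise KeyError(f"no BMR coefficients for sex {sex!r}") from exc
    for band in bands:
        if band["age_lo"] <= age_years < band["age_hi"]:
            mj = band["a"] * weight_kg + band["b"] * height_m + band["c"]
            return float(mj * factor)
    raise ValueError(f"age {age_years} outside configured BMR bands for {sex!r}")


def energy_plausible(
    total_kcal: float,
    bmr_kcal: float,
    population_kcal: Sequence[float] | np.ndarray,
    *,
    top_percentile: float = 99.9,
) -> bool:
    """Plausibility screen for reported daily energy intake.

    Implausible iff total is 0, strictly below 1.1*BMR - 500, strictly
    above 2.5*BMR + 500, or strictly above the population's
    ``top_percentile`` (default 99.9th, i.e. the top 0.1%).  Values exactly
    on a bound are retained.
    """
    if not bmr_kcal > 0:
        raise ValueError("bmr_kcal must be positive")
    if total_kcal == 0:
        return False
    if total_kcal < 1.1 * bmr_kcal - 500.0:
        return False
    if total_kcal > 2.5 * bmr_kcal + 500.0:
        return False
    cut = float(np.percentile(np.asarray(population_kcal, dtype=float), top_percentile))
    if total_kcal > cut:
        return False
    return True


@dataclass
class ExclusionReport:
    """Ordered per-criterion removal counts.  Counts always conserve:
    initial_n = final_n + sum(removed)."""

    initial_n: int
    removed: dict[int, int] = field(default_factory=dict)

    @property
    def final_n(self) -> int:
        return self.initial_n - sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "initial_n": self.initial_n,
            "removed": {
                f"({k}) {EXCLUSION_LABELS[k]}": v for k, v in sorted(self.removed.items())
            },
            "final_n": self.final_n,
        }


def _missing(df: pd.DataFrame, cols: Sequence[str]) -> pd.Series:
    out = pd.Series(False, index=df.index)
    for c in cols:
        if c in df.columns:
            out |= df[c].isna()
        else:
            out |= True
    return out


def apply_exclusions(
    cohort: pd.DataFrame,
    exposures: pd.DataFrame | None = None,
    *,
    cutoff: date = DEFAULT_CUTOFF,
    bmr_table: Mapping | None = None,
    top_percentile: float = 99.9,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the seven exclusion criteria in order with first-hit attribution.

    ``cohort`` is one row per participant (see module docstring for the
    expected fields); ``exposures`` supplies ``total_energy_kj`` per
    participant for criterion 7 and is joined on the index.  Returns the
    analysis cohort and the per-criterion report.
    """
    df = cohort.copy()
    if exposures is not None and "total_energy_kj" not in df.columns:
        df = df.join(exposures[["total_energy_kj"]], how="left")

    report = ExclusionReport(initial_n=len(df))
    alive = pd.Series(True, index=df.index)

    def drop(criterion: int, mask: pd.Series) -> None:
        hit = mask & alive
        report.removed[criterion] = int(hit.sum())
        alive[hit] = False

    drop(1, _missing(df, ["met_per_week", "smoking_status"]))

    entry = pd.to_datetime(df["last_assessment_date"])
    death = pd.to_datetime(df["death_date"]) if "death_date" in df.columns else pd.Series(
        pd.NaT, index=df.index
    )
    drop(2, death.notna() & (death < entry))

    drop(3, _missing(df, ["ethnicity", "general_health", "qualification", "townsend"]))
    drop(4, _missing(df, ["bmi_kg_m2", "sbp_mmHg"]))
    drop(5, df.get("malabsorption", pd.Series(False, index=df.index)).fillna(False).astype(bool))
    drop(6, df.get("diabetes", pd.Series(False, index=df.index)).fillna(False).astype(bool))

    # criterion 7: energy plausibility, percentile over the pre-exclusion
    # recall-completing population
    if "total_energy_kj" in df.columns:
        total_kcal = df["total_energy_kj"].astype(float) / KJ_PER_KCAL
        table = bmr_table if bmr_table is not None else load_bmr_table()
        bmr = pd.Series(
            [
                oxford_bmr(s, a, w, h, coefficients=table)
                for s, a, w, h in zip(
                    df["sex"], df["age_years"], df["weight_kg"], df["height_m"]
                )
            ],
            index=df.index,
        )
        pop = total_kcal.dropna().to_numpy()
        cut = float(np.percentile(pop, top_percentile)) if len(pop) else np.inf
        implausible = (
            (total_kcal == 0)
            | (total_kcal < 1.1 * bmr - 500.0)
            | (total_kcal > 2.5 * bmr + 500.0)
            | (total_kcal > cut)
            | total_kcal.isna()
        )
        drop(7, implausible)
    else:
        report.removed[7] = 0

    return df[alive].copy(), report


def build_survival(
    entry_date: date,
    death_date: date | None,
    censor_date: date | None,
    cutoff: date = DEFAULT_CUTOFF,
) -> tuple[float, int]:
    """Follow-up time (years) and event indicator for one participant.

    Entry is the last dietary assessment.  The participant is an event
    (1) if death occurs on or before both the cut-off and any
    loss-to-follow-up date; otherwise censored (0) at the earlier of the
    loss date and the cut-off.  Death before entry is implausible.
    """
    end_censor = min(censor_date, cutoff) if censor_date is not None else cutoff
    if death_date is not None and death_date <= end_censor:
        if death_date < entry_date:
            raise ValueError("implausible event/censoring data: death before entry")
        return ((death_date - entry_date).days / 365.25, 1)
    if end_censor < entry_date:
        raise ValueError("implausible event/censoring data: censoring before entry")
    return ((end_censor - entry_date).days / 365.25, 0)


def build_survival_frame(
    cohort: pd.DataFrame, cutoff: date = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Vectorised ``build_survival`` over a cohort table.

    Returns a frame indexed like ``cohort`` with ``time_years`` and
    ``event`` columns.
    """
    entry = pd.to_datetime(cohort["last_assessment_date"])
    death = (
        pd.to_datetime(cohort["death_date"])
        if "death_date" in cohort.columns
        else pd.Series(pd.NaT, index=cohort.index)
    )
    censor = (
        pd.to_datetime(cohort["censor_date"])
        if "censor_date" in cohort.columns
        else pd.Series(pd.NaT, index=cohort.index)
    )
    cut = pd.Timestamp(cutoff)
    end_censor = censor.fillna(cut).clip(upper=cut)
    is_event = death.notna() & (death <= end_censor)
    end = end_censor.where(~is_event, death)
    if (end < entry).any():
        bad = cohort.index[(end < entry)].tolist()[:5]
        raise ValueError(f"implausible event/censoring data for participants {bad}")
    return pd.DataFrame(
        {
            "time_years": (end - entry).dt.days / 365.25,
            "event": is_event.astype(int),
        },
        index=cohort.index,
    )


def _band(x: pd.Series, edges: list[float], labels: list[str]) -> pd.Series:
    return pd.cut(x, bins=edges, labels=labels, right=False, include_lowest=True)


def derive_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Build the categorical model covariates.

    Age, physical activity (MET/week), SBP and Townsend index are split at
    the analysis cohort's own quintiles; alcohol uses the fixed bands
    <1, 1–<8, 8–<16, ≥16 g/day and BMI the fixed bands <18.5, 18.5–<25,
    25–<30, ≥30 kg/m².  Remaining covariates pass through as categoricals.
    """
    if cohort.empty:
        raise ValueError("analysis cohort is empty")
    out = pd.DataFrame(index=cohort.index)
    qlabels = ["Q1", "Q2", "Q3", "Q4", "Q5"]
    for col in _QUINTILE_COVARIATES:
        x = cohort[col].astype(float)
        if x.nunique() < 5:
            raise ValueError(f"covariate {col!r} has fewer than 5 distinct values")
        out[f"{col}_q"] = pd.qcut(x, 5, labels=qlabels, duplicates="drop")
    out["alcohol_band"] = _band(
        cohort["alcohol_g_day"].astype(float),
        [-np.inf, 1, 8, 16, np.inf],
        ["<1", "1 to <8", "8 to <16", ">=16"],
    )
    out["bmi_band"] = _band(
        cohort["bmi_kg_m2"].astype(float),
        [-np.inf, 18.5, 25, 30, np.inf],
        ["<18.5", "18.5 to <25", "25 to <30", ">=30"],
    )
    for col in _CATEGORICAL_PASSTHROUGH:
        if col in cohort.columns:
            out[col] = cohort[col].astype("category")
    return out
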